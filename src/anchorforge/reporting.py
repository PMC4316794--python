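"""Per-chromosome anchoring summaries and assay-validation summaries.

Also bundles the published anchoring summary of the melon genome assembly
v3.5.1 against the PS x SC F2 genetic map (one row per linkage group plus
totals), from which the classic worked-example statistics — genome-wide
recombination rate, per-chromosome rates, marker spacing, mean anchored
scaffold size and SNP validation percentages — can be recomputed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: headline printed counts of the melon v3.5.1 anchoring study
PUBLISHED = {
    "map_span_cm": 1153.0,       # text total of the 12 linkage groups
    "table_total_cm": 1162.0,    # per-LG column total as printed
    "snps_mapped": 580,
    "anchored_scaffolds": 141,
    "anchored_bp": 354_835_875,
    "panel_designed": 768,
    "panel_successful": 599,
    "subset1_designed": 435,
    "subset1_validated": 288,
}


def load_published_summary() -> pd.DataFrame:
    """The published per-linkage-group anchoring table (plus Total row)."""
    with resources.files("anchorforge").joinpath(
        "data/melon_anchoring_v351.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_anchoring(
    assignments: pd.DataFrame,
    map_df: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    assembly_total_bp: int | None = None,
) -> pd.DataFrame:
    """One summary row per linkage group plus a Total row.

    Columns mirror the classic anchoring table: map length (cM), SNPs used,
    scaffolds/bases anchored and their percentage of the scaffold assembly,
    scaffolds/bases oriented, and the average recombination rate
    (map length / anchored Mb). cM values and rates carry 1 decimal,
    percentages 1 decimal.
    """
    total_bp = assembly_total_bp or sum(scaffold_lengths.values())
    anchored = assignments[assignments["status"].str.startswith("anchored")]
    rows = []
    for group in sorted(anchored["group"].unique()):
        grp = anchored[anchored["group"] == group]
        cm_len = float(map_df.loc[map_df["group"] == group, "cm"].max())
        snps = int((map_df["group"] == group).sum())
        bp = int(sum(scaffold_lengths[s] for s in grp["scaffold"]))
        oriented = grp[grp["orientation"].isin(["+", "-"])]
        obp = int(sum(scaffold_lengths[s] for s in oriented["scaffold"]))
        rows.append({
            "lg": int(group),
            "map_cm": round(cm_len, 1),
            "snps": snps,
            "scaffolds_anchored": len(grp),
            "anchored_bp": bp,
            "pct_assembly": round(100.0 * bp / total_bp, 1),
            "scaffolds_oriented": len(oriented),
            "oriented_bp": obp,
            "pct_oriented": round(100.0 * obp / total_bp, 1),
            "rate_cm_per_mb": round(cm_len / (bp / 1e6), 1) if bp else np.nan,
        })
    df = pd.DataFrame(rows)
    total = {
        "lg": 0,
        "map_cm": round(float(df["map_cm"].sum()), 1),
        "snps": int(df["snps"].sum()),
        "scaffolds_anchored": int(df["scaffolds_anchored"].sum()),
        "anchored_bp": int(df["anchored_bp"].sum()),
        "pct_assembly": round(100.0 * df["anchored_bp"].sum() / total_bp, 1),
        "scaffolds_oriented": int(df["scaffolds_oriented"].sum()),
        "oriented_bp": int(df["oriented_bp"].sum()),
        "pct_oriented": round(100.0 * df["oriented_bp"].sum() / total_bp, 1),
        "rate_cm_per_mb": round(
            float(df["map_cm"].sum()) / (df["anchored_bp"].sum() / 1e6), 1
        ) if df["anchored_bp"].sum() else np.nan,
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df


def derived_statistics(total_cm: float, total_snps: int,
                       anchored_bp: int, anchored_scaffolds: int) -> dict:
    """Worked-example statistics from printed totals: genome-wide marker
    spacing (cM/SNP, 2 decimals) and mean anchored scaffold size (Mb,
    1 decimal)."""
    return {
        "marker_spacing_cm_per_snp": round(total_cm / total_snps, 2),
        "mean_scaffold_size_mb": round(anchored_bp / anchored_scaffolds / 1e6, 1),
    }


def summarize_validation(designed: int, successful: int,
                         subsets: dict[str, tuple[int, int]] | None = None) -> dict:
    """Integer-rounded validation percentages, overall and per subset."""
    if designed < 0 or successful < 0 or successful > designed:
        raise ValueError("invalid designed/successful counts")
    out = {
        "designed": designed,
        "successful": successful,
        "validated_pct": (int(round(100.0 * successful / designed))
                          if designed else None),
        "subsets": {},
    }
    for name, (d, s) in (subsets or {}).items():
        out["subsets"][name] = {
            "designed": d,
            "successful": s,
            "validated_pct": int(round(100.0 * s / d)) if d else None,
        }
    return out
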