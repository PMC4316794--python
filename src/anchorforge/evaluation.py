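"""Scoring pipeline output against simulator ground truth.

Only meaningful for synthetic runs: linkage-group recovery (count and
marker purity), marker-order concordance (Kendall tau up to reversal),
scaffold chromosome/orientation accuracy modulo the arbitrary direction of
each recovered linkage group, chimera-detection scoring, and lifting of
true chromosome intervals into pseudomolecule coordinates for
suppression-zone overlap checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pseudomolecules import liftover
from .simulate import TruthAnchoring


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = max(a[1], b[1]) - min(a[0], b[0]) + 1
    return inter / union if union > 0 else 0.0


def group_purity(map_df: pd.DataFrame, marker_truth: pd.DataFrame):
    """Per recovered group: majority true chromosome and marker purity.

    Returns (summary DataFrame, group -> chromosome dict). Purity is the
    fraction of the group's markers whose true chromosome is the group
    majority.
    """
    truth = marker_truth.set_index("marker")["chrom"]
    rows = []
    mapping = {}
    for group, grp in map_df.groupby("group", sort=True):
        chroms = truth.loc[grp["marker"]].to_numpy()
        vals, counts = np.unique(chroms, return_counts=True)
        major = vals[int(np.argmax(counts))]
        purity = counts.max() / counts.sum()
        mapping[int(group)] = str(major)
        rows.append({"group": int(group), "n_markers": len(grp),
                     "chrom": str(major), "purity": float(purity)})
    return pd.DataFrame(rows), mapping


def order_taus(map_df: pd.DataFrame, marker_truth: pd.DataFrame) -> dict[int, float]:
    """|Kendall tau| between recovered order and true chromosome position,
    per group (absolute value: a fully reversed group is a correct order).

    The map's ordered units are its distinct cM positions — markers that
    cosegregate are mapped to one position and carry no internal order
    claim — so tau is computed between the distinct map positions and the
    mean true position of the markers at each."""
    truth = marker_truth.set_index("marker")
    taus = {}
    for group, grp in map_df.groupby("group", sort=True):
        grp = grp.sort_values("order")
        sub = truth.loc[grp["marker"]]
        major = sub["chrom"].mode().iloc[0]
        keep = (sub["chrom"] == major).to_numpy()
        if keep.sum() < 3:
            continue
        est_cm = grp["cm"].to_numpy()[keep]
        true_pos = sub["chrom_pos"].to_numpy()[keep]
        df = pd.DataFrame({"cm": est_cm, "pos": true_pos})
        units = df.groupby("cm", sort=True)["pos"].mean()
        tau = stats.kendalltau(units.index.to_numpy(),
                               units.to_numpy()).statistic
        taus[int(group)] = float(abs(tau))
    return taus


def group_directions(
    assignments: pd.DataFrame, truth: TruthAnchoring
) -> dict[int, int]:
    """Direction (+1/-1) of each recovered group's cM axis relative to its
    chromosome's physical axis, from the rank correlation of scaffold
    anchor positions vs true scaffold starts."""
    single = truth.fragments.groupby("scaffold").filter(lambda g: len(g) == 1)
    merged = assignments.merge(single, on="scaffold")
    out = {}
    for group, grp in merged.groupby("group"):
        if len(grp) < 2 or grp["anchor_cm"].nunique() < 2:
            out[int(group)] = 1
            continue
        rho = stats.spearmanr(grp["chrom_start"], grp["anchor_cm"]).statistic
        out[int(group)] = -1 if (rho is not None and rho < 0) else 1
    return out


def anchoring_accuracy(
    assignments: pd.DataFrame,
    truth: TruthAnchoring,
    group_to_chrom: dict[int, str],
) -> dict:
    """Chromosome + orientation accuracy over orientable scaffolds.

    Considers non-chimeric scaffolds anchored from >= 2 markers at
    distinct cM (orientation in {+,-} with marker provenance). Expected
    orientation is the true one, flipped when the recovered group runs
    antiparallel to its chromosome.
    """
    directions = group_directions(assignments, truth)
    single = truth.fragments.groupby("scaffold").filter(lambda g: len(g) == 1)
    merged = assignments.merge(single, on="scaffold", suffixes=("", "_true"))
    eligible = merged[
        (merged["status"] == "anchored")
        & (merged["provenance"] == "markers")
        & (merged["orientation"].isin(["+", "-"]))
    ]
    n_chrom_ok = n_both_ok = 0
    for row in eligible.itertuples():
        chrom_ok = group_to_chrom.get(int(row.group)) == row.chrom
        expected = row.orientation_true
        if directions.get(int(row.group), 1) < 0:
            expected = "-" if expected == "+" else "+"
        orient_ok = row.orientation == expected
        n_chrom_ok += chrom_ok
        n_both_ok += chrom_ok and orient_ok
    n = len(eligible)
    return {
        "n_eligible": n,
        "n_chrom_correct": int(n_chrom_ok),
        "n_fully_correct": int(n_both_ok),
        "accuracy": (n_both_ok / n) if n else float("nan"),
    }


def chimera_detection(splits, truth: TruthAnchoring) -> dict:
    """Score chimera splits against injected truth: every true chimera
    detected, and each cut inside the true junction N-track."""
    by_parent = {sp.parent: sp for sp in splits}
    detected = cut_in_junction = 0
    for ch in truth.chimeras.itertuples():
        sp = by_parent.get(ch.scaffold)
        if sp is None:
            continue
        detected += 1
        if ch.junction_start <= sp.cut_pos <= ch.junction_end:
            cut_in_junction += 1
    return {
        "n_true": int(len(truth.chimeras)),
        "n_detected": detected,
        "n_cut_in_junction": cut_in_junction,
        "n_called": len(by_parent),
    }


def true_interval_on_pm(
    truth: TruthAnchoring,
    placements: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    splits=None,
) -> tuple[str, int, int] | None:
    """Lift a true chromosome interval into pseudomolecule coordinates via
    the pipeline's own placements; returns the hull on the PM carrying the
    largest share of the interval (None if nothing was placed). ``splits``
    translates coordinates on split parents into their children."""
    pl = placements.set_index("scaffold")
    split_map = {sp.parent: sp for sp in splits or []}
    raw = list(truth.chrom_interval_to_scaffold(chrom, start, end))
    translated: list[tuple[str, int, int]] = []
    for sid, s, e, _o in raw:
        sp = split_map.get(sid)
        if sp is None:
            translated.append((sid, s, e))
            continue
        cut = sp.cut_pos
        if s <= cut:
            translated.append((sp.children[0], s, min(e, cut)))
        if e > cut:
            translated.append((sp.children[1], max(s, cut + 1) - cut, e - cut))
    pieces: dict[str, list[tuple[int, int, int]]] = {}
    for sid, s, e in translated:
        if sid not in pl.index:
            continue
        p = pl.loc[sid]
        a, b, _ = liftover(int(s), int(e), ".", int(p["offset"]),
                           int(p["length"]), str(p["orientation"]))
        if a > b:
            a, b = b, a
        pieces.setdefault(str(p["pm"]), []).append((a, b, b - a + 1))
    if not pieces:
        return None
    pm_id = max(pieces, key=lambda k: sum(x[2] for x in pieces[k]))
    lo = min(x[0] for x in pieces[pm_id])
    hi = max(x[1] for x in pieces[pm_id])
    return pm_id, lo, hi
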