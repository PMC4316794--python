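"""Scaffold anchoring and orientation from mapped markers.

Each scaffold inherits the linkage group of its mapped markers. Scaffolds
whose markers hit two groups are either cleaned (a single stray marker is
dropped when enough recombination-separated markers support the majority
group) or flagged as chimera candidates when both sides carry real marker
blocks; candidates are split at an N-gap inside the block boundary.
Orientation is the sign of the rank correlation between marker scaffold
positions (bp) and genetic positions (cM); scaffolds that cannot be
oriented from markers may adopt the orientation recorded in a prior
anchoring table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Scaffold


def filter_placements(placements: pd.DataFrame,
                      evalue_cutoff: float = 1e-30) -> pd.DataFrame:
    """Drop marker placements weaker than the homology-search cutoff (rows
    without an e-value column pass unchanged)."""
    if "evalue" not in placements.columns:
        return placements
    return placements[placements["evalue"] <= evalue_cutoff]


def orient_scaffold(bp: np.ndarray, cm: np.ndarray) -> str:
    """'+' / '-' by the sign of the Spearman correlation of bp vs cM;
    '?' with fewer than two distinct cM values or zero correlation."""
    bp, cm = np.asarray(bp, float), np.asarray(cm, float)
    if len(bp) < 2 or len(np.unique(cm)) < 2:
        return "?"
    rho = stats.spearmanr(bp, cm).statistic
    if np.isnan(rho) or rho == 0:
        return "?"
    return "+" if rho > 0 else "-"


def anchor_position(cm: np.ndarray) -> float:
    """Ordering key of a scaffold along its group: median marker cM."""
    return float(np.median(np.asarray(cm, dtype=float)))


@dataclass
class ChimeraCandidate:
    scaffold: str
    boundary: tuple[int, int]      # scaffold bp interval between marker blocks
    left_group: int
    right_group: int
    left_markers: list[str]
    right_markers: list[str]


@dataclass
class ChimeraSplit:
    parent: str
    cut_pos: int                   # last base of the first child
    children: tuple[str, str]
    child_groups: dict[str, int]
    in_gap: bool                   # cut landed inside an N-track


def _direct_recombination_events(markers: pd.DataFrame, genotypes) -> float:
    """Estimated recombination events between the scaffold's two bp-extreme
    markers, straight from the genotype calls (r_hat x 2n). Cumulative map
    positions can accumulate phantom distance across recombination-suppressed
    regions; direct two-point evidence cannot."""
    from .linkage import estimate_two_point

    srt = markers.sort_values("pos", kind="mergesort")
    m1, m2 = srt["marker"].iloc[0], srt["marker"].iloc[-1]
    if m1 == m2 or m1 not in genotypes.calls.index or m2 not in genotypes.calls.index:
        return 0.0
    est = estimate_two_point(genotypes.calls.loc[m1].to_numpy(),
                             genotypes.calls.loc[m2].to_numpy())
    return est.r_hat * 2 * est.n_informative


def _assignment_row(sid, group, markers, dropped, prior=None,
                    genotypes=None, min_orient_events: float = 2.0):
    bp = markers["pos"].to_numpy()
    cm = markers["cm"].to_numpy()
    orientation = orient_scaffold(bp, cm)
    if orientation in "+-" and genotypes is not None:
        if _direct_recombination_events(markers, genotypes) < min_orient_events:
            orientation = "?"
    provenance = "markers"
    if orientation == "?" and prior is not None and sid in prior.index:
        orientation = str(prior.loc[sid, "orientation"])
        provenance = "prior_map"
    return {
        "scaffold": sid,
        "group": int(group),
        "orientation": orientation,
        "anchor_cm": round(anchor_position(cm), 6),
        "mean_cm": round(float(np.mean(cm)), 6),
        "n_markers": len(markers),
        "supporting_markers": ",".join(markers["marker"]),
        "dropped_markers": ",".join(dropped),
        "provenance": provenance,
        "status": "anchored",
    }


def assign_scaffolds(
    placements: pd.DataFrame,
    scaffolds: list[Scaffold],
    prior_map: pd.DataFrame | None = None,
    genotypes=None,
    min_orient_events: float = 2.0,
):
    """Assign scaffolds to linkage groups from mapped-marker placements.

    ``placements`` needs columns marker, scaffold, pos, group, cm (the join
    of the marker placement table with the genetic map). Returns
    (assignments DataFrame, chimera candidates, dropped-marker ids).
    Scaffolds without mapped markers get status ``unanchored``. When
    ``genotypes`` is supplied, orientation additionally requires at least
    ``min_orient_events`` directly observed recombination events between
    the scaffold's outermost markers (map positions alone can drift apart
    inside recombination-suppressed regions without any real recombination
    separating the markers).
    """
    prior = None
    if prior_map is not None and len(prior_map):
        prior = prior_map.set_index("scaffold")
    rows: list[dict] = []
    candidates: list[ChimeraCandidate] = []
    dropped_all: list[str] = []

    by_scaffold = dict(tuple(placements.groupby("scaffold", sort=False)))
    for sc in scaffolds:
        m = by_scaffold.get(sc.id)
        if m is None or m.empty:
            rows.append({"scaffold": sc.id, "group": 0, "orientation": "?",
                         "anchor_cm": np.nan, "mean_cm": np.nan, "n_markers": 0,
                         "supporting_markers": "", "dropped_markers": "",
                         "provenance": "none", "status": "unanchored"})
            continue
        m = m.sort_values("pos", kind="mergesort")
        counts = m.groupby("group").size().sort_values(ascending=False)
        if len(counts) == 1:
            rows.append(_assignment_row(sc.id, counts.index[0], m, [], prior,
                                        genotypes, min_orient_events))
            continue

        major = counts.index[0]
        major_m = m[m["group"] == major]
        minor_counts = counts.iloc[1:]
        if (minor_counts == 1).all() and len(major_m) > 2 and \
                major_m["cm"].nunique() >= 2:
            # isolated stray markers against a recombination-separated block
            dropped = list(m.loc[m["group"] != major, "marker"])
            dropped_all.extend(dropped)
            rows.append(_assignment_row(sc.id, major, major_m, dropped, prior,
                                        genotypes, min_orient_events))
            continue

        two_sided = [g for g in counts.index if counts[g] >= 2]
        if len(two_sided) >= 2:
            g1, g2 = two_sided[0], two_sided[1]
            m1, m2 = m[m["group"] == g1], m[m["group"] == g2]
            if m1["pos"].median() > m2["pos"].median():
                g1, g2, m1, m2 = g2, g1, m2, m1
            lo, hi = int(m1["pos"].max()), int(m2["pos"].min())
            if lo < hi:
                extra = list(m.loc[~m["group"].isin([g1, g2]), "marker"])
                dropped_all.extend(extra)
                candidates.append(ChimeraCandidate(
                    sc.id, (lo, hi), int(g1), int(g2),
                    list(m1["marker"]), list(m2["marker"])))
                rows.append({"scaffold": sc.id, "group": 0, "orientation": "?",
                             "anchor_cm": np.nan, "mean_cm": np.nan,
                             "n_markers": len(m),
                             "supporting_markers": ",".join(m["marker"]),
                             "dropped_markers": ",".join(extra),
                             "provenance": "markers",
                             "status": "chimera_candidate"})
                continue
        # interleaved or thin evidence: keep the majority group, drop the rest
        dropped = list(m.loc[m["group"] != major, "marker"])
        dropped_all.extend(dropped)
        row = _assignment_row(sc.id, major, major_m, dropped, prior,
                                    genotypes, min_orient_events)
        row["status"] = "anchored_ambiguous"
        rows.append(row)

    assignments = pd.DataFrame(rows)
    return assignments, candidates, dropped_all


def split_chimera(scaffold: Scaffold, boundary: tuple[int, int]) -> ChimeraSplit:
    """Cut a chimeric scaffold inside ``boundary``.

    The cut goes through the N-gap whose midpoint lies nearest the boundary
    midpoint (the misjoin must sit between the marker blocks, and assembly
    joins are bridged by N-tracks); without any gap in the boundary the cut
    falls back to the boundary midpoint, flagged via ``in_gap=False``.
    """
    lo, hi = boundary
    if not (1 <= lo < hi <= scaffold.length):
        raise ValueError(f"boundary {boundary} not inside {scaffold.id}")
    mid = (lo + hi) / 2.0
    gaps = [(s, e) for s, e in scaffold.gaps if lo <= (s + e) / 2.0 <= hi]
    if gaps:
        s, e = min(gaps, key=lambda g: (abs((g[0] + g[1]) / 2.0 - mid), g[0]))
        cut = int((s + e) // 2)
        in_gap = True
    else:
        warnings.warn(f"no N-gap in boundary of {scaffold.id}; "
                      "cutting at the boundary midpoint")
        cut = int(mid)
        in_gap = False
    children = (f"{scaffold.id}_split1", f"{scaffold.id}_split2")
    return ChimeraSplit(scaffold.id, cut, children, {}, in_gap)


def resolve_chimeras(
    candidates: list[ChimeraCandidate], scaffolds: list[Scaffold]
) -> list[ChimeraSplit]:
    """Turn chimera candidates into concrete splits with child group labels."""
    by_id = {sc.id: sc for sc in scaffolds}
    splits = []
    for cand in candidates:
        split = split_chimera(by_id[cand.scaffold], cand.boundary)
        split.child_groups = {split.children[0]: cand.left_group,
                              split.children[1]: cand.right_group}
        splits.append(split)
    return splits


def order_assignments(
    assignments: pd.DataFrame, scaffolds: list[Scaffold]
) -> pd.DataFrame:
    """Order anchored scaffolds within each group by anchor cM (median
    marker cM); ties break by mean marker cM (sorts scaffolds straddling a
    suppression-region edge toward the correct side), then prior assembly
    order (input scaffold order), then descending length, then id."""
    order_idx = {sc.id: k for k, sc in enumerate(scaffolds)}
    lengths = {sc.id: sc.length for sc in scaffolds}
    df = assignments[assignments["status"].str.startswith("anchored")].copy()
    df["_asm"] = df["scaffold"].map(order_idx)
    df["_len"] = df["scaffold"].map(lengths)
    df = df.sort_values(
        ["group", "anchor_cm", "mean_cm", "_asm", "_len", "scaffold"],
        ascending=[True, True, True, True, False, True],
        kind="mergesort",
    ).drop(columns=["_asm", "_len"])
    return df.reset_index(drop=True)
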