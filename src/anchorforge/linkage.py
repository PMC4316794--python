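"""F2 two-point linkage mapping.

The recombination fraction between two codominant markers is estimated by
maximum likelihood on the 9-class two-locus F2 multinomial. With phase
known from the parental lines, each genotype class probability is the
product of two independent gamete probabilities — parental gametes with
probability (1-r)/2 each, recombinants r/2 — except the double
heterozygote, which sums its two phase configurations to
((1-r)^2 + r^2) / 2. The likelihood depends on the data only through four
sufficient statistics:

* ``n_par``  — both loci homozygous parental (AA/AA, BB/BB): (1-r)^2/4
* ``n_rec2`` — opposite homozygotes (AA/BB, BB/AA):           r^2/4
* ``n_mix``  — one homozygote, one heterozygote:              r(1-r)/2
* ``n_hh``   — double heterozygote:                 ((1-r)^2 + r^2)/2

The MLE is found by EM (the double-heterozygote class contributes
2r^2/((1-r)^2 + r^2) expected recombinant gametes), run simultaneously for
all marker pairs as vectorized array updates. LOD is the base-10
log-likelihood ratio against free recombination (r = 0.5). Grouping takes
connected components of the LOD graph; ordering minimizes the sum of
adjacent recombination fractions (greedy insertion refined by 2-opt); map
positions accumulate Haldane (default) or Kosambi distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_qc import MISSING, GenotypeData

LN10 = np.log(10.0)
MIN_INFORMATIVE = 10


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------


def haldane_d(r):
    """Map distance (cM) from recombination fraction, no interference."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def haldane_r(d):
    return 0.5 * (1.0 - np.exp(-np.asarray(d, dtype=float) / 50.0))


def kosambi_d(r):
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_r(d):
    t = np.tanh(np.asarray(d, dtype=float) / 50.0)
    return 0.5 * t


MAP_FUNCTIONS = {"haldane": (haldane_d, haldane_r),
                 "kosambi": (kosambi_d, kosambi_r)}


# ---------------------------------------------------------------------------
# two-point likelihood / EM
# ---------------------------------------------------------------------------


def pair_counts(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[int, int, int, int]:
    """Sufficient statistics (n_par, n_rec2, n_mix, n_hh) for one pair;
    individuals missing at either locus are excluded."""
    ok = (calls_i != MISSING) & (calls_j != MISSING)
    a, b = calls_i[ok], calls_j[ok]
    n_par = int(np.sum((a == 0) & (b == 0)) + np.sum((a == 2) & (b == 2)))
    n_rec2 = int(np.sum((a == 0) & (b == 2)) + np.sum((a == 2) & (b == 0)))
    n_hh = int(np.sum((a == 1) & (b == 1)))
    n_mix = int(ok.sum()) - n_par - n_rec2 - n_hh
    return n_par, n_rec2, n_mix, n_hh


def loglik(n_par, n_rec2, n_mix, n_hh, r):
    """Variable part of the two-locus log-likelihood at recombination
    fraction ``r`` (constants independent of r omitted; they cancel in all
    ratios). Vectorized over both counts and r; 0*log(0) is taken as 0."""
    n_par, n_rec2 = np.asarray(n_par, float), np.asarray(n_rec2, float)
    n_mix, n_hh = np.asarray(n_mix, float), np.asarray(n_hh, float)
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.where(r > 0, np.log(np.where(r > 0, r, 1.0)), -np.inf)
        log_q = np.where(r < 1, np.log(np.where(r < 1, 1.0 - r, 1.0)), -np.inf)
        t_rec = np.where(2 * n_rec2 + n_mix > 0, (2 * n_rec2 + n_mix) * log_r, 0.0)
        t_par = np.where(2 * n_par + n_mix > 0, (2 * n_par + n_mix) * log_q, 0.0)
        t_hh = n_hh * np.log((1.0 - r) ** 2 + r**2)
    return t_rec + t_par + t_hh


def _em(n_par, n_rec2, n_mix, n_hh, tol: float = 1e-10, max_iter: int = 600):
    """Vectorized EM for the recombination fraction; returns r_hat."""
    n = n_par + n_rec2 + n_mix + n_hh
    n_safe = np.where(n > 0, n, 1)
    r = np.full(np.shape(n), 0.25, dtype=float)
    for _ in range(max_iter):
        w = 2.0 * r**2 / ((1.0 - r) ** 2 + r**2)
        r_new = (n_mix + 2.0 * n_rec2 + n_hh * w) / (2.0 * n_safe)
        r_new = np.clip(r_new, 1e-12, 0.5)
        delta = np.max(np.abs(r_new - r)) if np.size(r) else 0.0
        r = r_new
        if delta < tol:
            break
    # snap exact boundaries: no recombinant evidence at all -> r = 0
    r = np.where((n_mix + n_rec2 == 0) & (r < 1e-6), 0.0, r)
    return np.where(n > 0, r, 0.5)


@dataclass
class TwoPointEstimate:
    r_hat: float
    lod: float
    n_informative: int
    reliable: bool


def estimate_two_point(calls_i: np.ndarray, calls_j: np.ndarray) -> TwoPointEstimate:
    """ML recombination fraction and LOD for one marker pair."""
    n_par, n_rec2, n_mix, n_hh = pair_counts(np.asarray(calls_i),
                                             np.asarray(calls_j))
    n = n_par + n_rec2 + n_mix + n_hh
    r = float(_em(np.array(n_par), np.array(n_rec2), np.array(n_mix),
                  np.array(n_hh)))
    ll_r = float(loglik(n_par, n_rec2, n_mix, n_hh, r))
    ll_half = float(loglik(n_par, n_rec2, n_mix, n_hh, 0.5))
    lod = max((ll_r - ll_half) / LN10, 0.0)
    return TwoPointEstimate(r, lod, n, n >= MIN_INFORMATIVE)


def grid_two_point(calls_i, calls_j, step: float = 0.0005) -> float:
    """Grid-search ML estimate of r (dense evaluation of the same
    likelihood); serves as a slow, optimizer-free reference."""
    n_par, n_rec2, n_mix, n_hh = pair_counts(np.asarray(calls_i),
                                             np.asarray(calls_j))
    rs = np.arange(0.0, 0.5 + step / 2, step)
    ll = loglik(n_par, n_rec2, n_mix, n_hh, rs)
    return float(rs[int(np.argmax(ll))])


def pairwise_two_point(data: GenotypeData):
    """All-pairs recombination fractions and LODs.

    Returns (r, lod, n) square DataFrames indexed by marker id. The 9-class
    counts for every pair come from one-hot matrix products, and EM runs on
    all pairs at once.
    """
    calls = data.calls.to_numpy()
    markers = data.calls.index
    X = [(calls == g).astype(np.float64) for g in (0, 1, 2)]
    n9 = {(a, b): X[a] @ X[b].T for a in range(3) for b in range(3)}
    n_par = n9[(0, 0)] + n9[(2, 2)]
    n_rec2 = n9[(0, 2)] + n9[(2, 0)]
    n_hh = n9[(1, 1)]
    n_mix = n9[(0, 1)] + n9[(1, 0)] + n9[(1, 2)] + n9[(2, 1)]

    r = _em(n_par, n_rec2, n_mix, n_hh)
    ll_r = loglik(n_par, n_rec2, n_mix, n_hh, r)
    ll_half = loglik(n_par, n_rec2, n_mix, n_hh, 0.5)
    lod = np.maximum((ll_r - ll_half) / LN10, 0.0)
    n = n_par + n_rec2 + n_mix + n_hh
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    wrap = lambda m: pd.DataFrame(m, index=markers, columns=markers)
    return wrap(r), wrap(lod), wrap(n.astype(int))


# ---------------------------------------------------------------------------
# grouping / ordering / positions
# ---------------------------------------------------------------------------


def build_groups(lod: pd.DataFrame, lod_threshold: float = 10.0) -> list[list[str]]:
    """Linkage groups = connected components of the marker graph with edges
    where pairwise LOD >= threshold. Groups are numbered by decreasing size
    (ties by first marker id); members keep input order."""
    markers = list(lod.index)
    g = nx.Graph()
    g.add_nodes_from(markers)
    vals = lod.to_numpy()
    ii, jj = np.where(np.triu(vals >= lod_threshold, k=1))
    g.add_edges_from((markers[i], markers[j]) for i, j in zip(ii, jj))
    comps = [sorted(c, key=markers.index) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def _sarf(order: list[int], d: np.ndarray) -> float:
    return float(sum(d[order[k], order[k + 1]] for k in range(len(order) - 1)))


def order_group(group: list[str], rf: pd.DataFrame) -> list[str]:
    """Order markers to minimize the sum of adjacent recombination
    fractions: greedy insertion seeded by the most distant pair, then 2-opt
    segment reversals until no move improves. Output direction is
    canonicalized (first id < last id), the reversal being equivalent."""
    if len(group) <= 2:
        return sorted(group)
    d = rf.loc[group, group].to_numpy().astype(float)
    d = np.minimum(d, 0.49999)
    k = len(group)

    iu = np.triu_indices(k, 1)
    far = int(np.argmax(d[iu]))
    i0, j0 = int(iu[0][far]), int(iu[1][far])
    order = [i0, j0]
    for m in range(k):
        if m in order:
            continue
        best_pos, best_cost = 0, np.inf
        for pos in range(len(order) + 1):
            trial = order[:pos] + [m] + order[pos:]
            cost = _sarf(trial, d)
            if cost < best_cost - 1e-15:
                best_cost, best_pos = cost, pos
        order.insert(best_pos, m)

    improved = True
    while improved:
        improved = False
        for i in range(k - 1):
            for j in range(i + 1, k):
                a = d[order[i - 1], order[i]] if i > 0 else 0.0
                b = d[order[j], order[j + 1]] if j < k - 1 else 0.0
                a2 = d[order[i - 1], order[j]] if i > 0 else 0.0
                b2 = d[order[i], order[j + 1]] if j < k - 1 else 0.0
                if a2 + b2 < a + b - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    result = [group[i] for i in order]
    if result[0] > result[-1]:
        result.reverse()
    return result


def compute_positions(
    ordered: list[str],
    rf: pd.DataFrame,
    map_function: str = "haldane",
    max_gap_cm: float = 50.0,
) -> pd.DataFrame:
    """Cumulative cM positions from adjacent recombination fractions; the
    first marker sits at 0. Adjacent r >= 0.5 is capped at ``max_gap_cm``."""
    to_d, _ = MAP_FUNCTIONS[map_function]
    pos = [0.0]
    for a, b in zip(ordered[:-1], ordered[1:]):
        r = float(rf.loc[a, b])
        if r >= 0.5:
            warnings.warn(f"adjacent pair {a}-{b} unlinked (r=0.5); "
                          f"distance capped at {max_gap_cm} cM")
            dist = max_gap_cm
        else:
            dist = min(float(to_d(r)), max_gap_cm)
        pos.append(pos[-1] + dist)
    return pd.DataFrame({"marker": ordered, "cm": np.round(pos, 6)})


def cosegregation_bins(
    rf: pd.DataFrame, n: pd.DataFrame, group: list[str],
    max_events: float = 3.0,
) -> list[list[str]]:
    """Cluster a group's markers into co-segregation bins.

    Two markers join a bin (single linkage) when fewer than ``max_events``
    recombination events separate them in the whole population
    (r_hat * 2n): such markers carry no reliable internal ordering
    information and are mapped to a single position, as classic mapping
    software does for cosegregating loci."""
    g = nx.Graph()
    g.add_nodes_from(group)
    sub_r = rf.loc[group, group].to_numpy()
    sub_n = n.loc[group, group].to_numpy()
    events = sub_r * 2.0 * sub_n
    ii, jj = np.where(np.triu(events < max_events, k=1))
    g.add_edges_from((group[i], group[j]) for i, j in zip(ii, jj))
    bins = [sorted(c) for c in nx.connected_components(g)]
    bins.sort(key=lambda b: b[0])
    return bins


def _bin_rf(rf: pd.DataFrame, bins: list[list[str]]) -> pd.DataFrame:
    """Between-bin recombination fractions: mean over member pairs."""
    labels = [b[0] for b in bins]
    k = len(bins)
    out = np.zeros((k, k))
    arr = rf
    for i in range(k):
        for j in range(i + 1, k):
            block = arr.loc[bins[i], bins[j]].to_numpy()
            out[i, j] = out[j, i] = float(block.mean())
    return pd.DataFrame(out, index=labels, columns=labels)


def build_map(
    data: GenotypeData,
    lod_threshold: float = 10.0,
    map_function: str = "haldane",
    prune_max_missing: float | None = None,
    bin_max_events: float | None = 3.0,
) -> pd.DataFrame:
    """Genotypes -> genetic map (marker, group, order, cm).

    Groups come from the full matrix; each group is then optionally pruned
    of individuals with too many missing calls over the group's markers and
    re-estimated. Markers separated by fewer than ``bin_max_events``
    observed recombination events collapse into cosegregation bins mapped
    at one position (set ``bin_max_events=None`` to order every marker
    individually); bins are ordered by greedy insertion + 2-opt on the sum
    of adjacent recombination fractions.
    """
    from .genotype_qc import prune_individuals_within_group

    rf, lod, n = pairwise_two_point(data)
    groups = build_groups(lod, lod_threshold)
    frames = []
    for gi, group in enumerate(groups, start=1):
        sub = data.subset_markers(group)
        if prune_max_missing is not None and len(group) >= 2:
            sub = prune_individuals_within_group(sub, group, prune_max_missing)
            rf_g, _, n_g = pairwise_two_point(sub)
        else:
            rf_g, n_g = rf.loc[group, group], n.loc[group, group]
        if bin_max_events is not None:
            bins = cosegregation_bins(rf_g, n_g, group, bin_max_events)
        else:
            bins = [[m] for m in group]
        if len(bins) > 1:
            rf_b = _bin_rf(rf_g, bins)
            ordered_bins = order_group(list(rf_b.index), rf_b)
            posdf_b = compute_positions(ordered_bins, rf_b, map_function)
        else:
            ordered_bins = [bins[0][0]]
            posdf_b = pd.DataFrame({"marker": ordered_bins, "cm": [0.0]})
        by_label = {b[0]: b for b in bins}
        rows = []
        order_idx = 0
        for label, cm in zip(posdf_b["marker"], posdf_b["cm"]):
            for marker in by_label[label]:
                rows.append({"marker": marker, "group": gi,
                             "order": order_idx, "cm": cm})
                order_idx += 1
        frames.append(pd.DataFrame(rows))
    out = pd.concat(frames, ignore_index=True)
    return out
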