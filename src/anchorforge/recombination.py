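"""Marey maps and the recombination-rate landscape.

A Marey map plots each mapped marker's genetic position (cM) against its
physical position on the pseudomolecule (Mb); its local slope is the local
recombination rate. Marker series are deduplicated and forced monotone by
isotonic regression (a derivative needs a nondecreasing cumulative curve;
small inversions are mapping noise), then a cubic smoothing spline (GCV
smoothing) provides the cumulative curve whose finite-difference slope
over a 1-Mb sliding window is the windowed rate in cM/Mb. Genome-wide and
per-chromosome average rates are plain length ratios: total map length
divided by physical size. Suppression zones are maximal runs of windows
below a rate threshold spanning at least a minimum physical distance; on
real chromosomes they coincide with centromeric/heterochromatic regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from scipy.optimize import isotonic_regression

from .pseudomolecules import pm_positions


@dataclass
class MareySeries:
    pm: str
    mb: np.ndarray        # physical positions, strictly increasing
    cm_raw: np.ndarray    # mean cM per physical position
    cm: np.ndarray        # monotonized cM (isotonic regression)


@dataclass
class RecombinationProfile:
    pm: str
    window_mb: float
    centers_mb: np.ndarray
    rates: np.ndarray     # cM/Mb, >= 0
    method: str = "spline"
    per_pm_rate: float | None = None
    zones: list[tuple[int, int]] = field(default_factory=list)


def marey_points(
    map_df: pd.DataFrame,
    placements: pd.DataFrame,
    marker_table: pd.DataFrame,
    min_points: int = 3,
    outlier_cm: float = 2.0,
) -> dict[str, MareySeries]:
    """Build one Marey series per pseudomolecule.

    ``map_df`` holds marker/group/cm, ``marker_table`` maps markers to
    (scaffold, pos), ``placements`` places scaffolds on PMs. Marker PM
    positions are orientation-adjusted through the placements; duplicate
    physical positions collapse to their mean cM; isotonic regression
    enforces a nondecreasing series. Points whose cM deviates from the
    pooled monotone trend by more than ``outlier_cm`` are local ordering
    noise (e.g. a scaffold placed at an arbitrary position within a
    recombination-suppressed region) and are dropped before the final
    pooling. PMs with fewer than ``min_points`` distinct positions are
    skipped.
    """
    merged = map_df.merge(marker_table[["marker", "scaffold", "pos"]], on="marker")
    lifted = pm_positions(placements, merged)
    out: dict[str, MareySeries] = {}
    for pm_id, grp in lifted.groupby("pm", sort=True):
        if pm_id.endswith("00"):
            continue  # chromosome zero is unordered by construction
        mb = grp["pm_pos"].to_numpy() / 1e6
        cm = grp["cm"].to_numpy().astype(float)
        order = np.argsort(mb, kind="mergesort")
        mb, cm = mb[order], cm[order]
        uniq, inv = np.unique(mb, return_inverse=True)
        mean_cm = np.bincount(inv, weights=cm) / np.bincount(inv)
        if len(uniq) < min_points:
            continue
        mono = isotonic_regression(mean_cm, increasing=True).x
        # iterative trim: drop the single most discordant point and re-pool
        # (dropping in bulk would let one misplaced block veto its whole
        # neighbourhood)
        while len(uniq) > min_points:
            dev = np.abs(mean_cm - mono)
            worst = int(np.argmax(dev))
            if dev[worst] <= outlier_cm:
                break
            uniq = np.delete(uniq, worst)
            mean_cm = np.delete(mean_cm, worst)
            mono = isotonic_regression(mean_cm, increasing=True).x
        out[pm_id] = MareySeries(pm_id, uniq, mean_cm, mono)
    return out


def fit_profile(
    series: MareySeries,
    window_mb: float = 1.0,
    step_mb: float = 0.1,
    method: str = "pchip",
    lam: float | None = None,
) -> RecombinationProfile | None:
    """Windowed recombination rates along one pseudomolecule.

    A cubic spline through the monotonized Marey points provides the
    cumulative curve S; the local rate at a window center c is
    (S(c + w/2) - S(c - w/2)) / w, clamped at zero. The default cubic is a
    monotone (PCHIP) interpolant: the window difference already smooths at
    the 1-Mb scale, and an interpolating monotone cubic preserves sharp
    transitions between recombining arms and suppressed plateaus that a
    cross-validated smoothing spline (``method='spline'``, smoothing by
    GCV unless ``lam`` is given) tends to round off. With too few points,
    or a singular fit, piecewise-linear interpolation substitutes
    (``method='linear'`` in the result).
    """
    x, y = series.mb, series.cm
    lo, hi = x[0] + window_mb / 2, x[-1] - window_mb / 2
    if hi <= lo:
        return None
    centers = np.arange(lo, hi + 1e-9, step_mb)
    used = method
    try:
        if len(x) < 5:
            raise ValueError("too few points for a cubic fit")
        if method == "spline":
            spline = make_smoothing_spline(x, y, lam=lam)
        else:
            spline = PchipInterpolator(x, y)
        upper = spline(centers + window_mb / 2)
        lower = spline(centers - window_mb / 2)
    except (ValueError, np.linalg.LinAlgError):
        used = "linear"
        upper = np.interp(centers + window_mb / 2, x, y)
        lower = np.interp(centers - window_mb / 2, x, y)
    rates = np.maximum((upper - lower) / window_mb, 0.0)
    return RecombinationProfile(series.pm, window_mb, centers, rates, used)


def rates(map_lengths_cm: dict[str, float],
          pm_lengths_bp: dict[str, int]) -> tuple[float, dict[str, float]]:
    """Average recombination rates (cM/Mb).

    Genome-wide rate = total map length / total physical length; per-PM
    rates analogously. Keys of the two dicts must correspond.
    """
    per_pm: dict[str, float] = {}
    for pm_id, cm in map_lengths_cm.items():
        bp = pm_lengths_bp[pm_id]
        if bp <= 0:
            raise ValueError(f"non-positive physical length for {pm_id}")
        per_pm[pm_id] = cm / (bp / 1e6)
    total_bp = sum(pm_lengths_bp[p] for p in map_lengths_cm)
    gwrr = sum(map_lengths_cm.values()) / (total_bp / 1e6)
    return gwrr, per_pm


def suppression_zones(
    profile: RecombinationProfile,
    rate_threshold: float = 0.5,
    min_span_mb: float = 2.0,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive windows with rate < threshold whose
    physical extent (outer window edges) reaches ``min_span_mb``; returned
    as 1-based bp intervals."""
    zones = []
    c, r = profile.centers_mb, profile.rates
    w = profile.window_mb
    below = r < rate_threshold
    start = None
    for k in range(len(c) + 1):
        if k < len(c) and below[k]:
            if start is None:
                start = k
        elif start is not None:
            lo, hi = c[start] - w / 2, c[k - 1] + w / 2
            if hi - lo >= min_span_mb:
                zones.append((int(lo * 1e6) + 1, int(hi * 1e6)))
            start = None
    return zones


def landscape(
    map_df: pd.DataFrame,
    placements: pd.DataFrame,
    marker_table: pd.DataFrame,
    pm_lengths_bp: dict[str, int],
    window_mb: float = 1.0,
    step_mb: float = 0.1,
    rate_threshold: float = 0.5,
    min_span_mb: float = 2.0,
):
    """Full landscape: profiles + zones per PM and the average rates.

    Returns (profiles dict, gwrr, per_pm_rates). Map length per PM is the
    cM span of the corresponding linkage group.
    """
    series = marey_points(map_df, placements, marker_table)
    profiles: dict[str, RecombinationProfile] = {}
    map_lengths: dict[str, float] = {}
    for pm_id, s in series.items():
        prof = fit_profile(s, window_mb, step_mb)
        map_lengths[pm_id] = float(s.cm[-1] - s.cm[0])
        if prof is None:
            continue
        prof.zones = suppression_zones(prof, rate_threshold, min_span_mb)
        profiles[pm_id] = prof
    gwrr, per_pm = rates(map_lengths,
                         {p: pm_lengths_bp[p] for p in map_lengths})
    for pm_id, prof in profiles.items():
        prof.per_pm_rate = per_pm[pm_id]
    return profiles, gwrr, per_pm
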