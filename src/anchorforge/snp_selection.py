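"""Targeted "inverse mapping" SNP selection.

Candidate variants are filtered on call quality, read depth and a clean
flanking window, with a stringency ladder that is relaxed per scaffold
until enough candidates survive; markers are then chosen concentrated at
scaffold extremes (at least two per end where possible) so that anchored
scaffolds can also be oriented, with a per-scaffold total that scales with
scaffold size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError

DEFAULT_LADDER = ((999.0, 15.0), (200.0, 10.0), (50.0, 8.0))
#: markers per scaffold by size class (upper bp bound -> count)
DEFAULT_SIZE_SCHEDULE = ((100_000, 1), (500_000, 2), (1_000_000, 3),
                         (3_000_000, 4), (None, 5))

REQUIRED_COLUMNS = ("scaffold", "pos", "quality", "depth")


@dataclass
class SelectionEntry:
    """Chosen markers for one scaffold plus the relaxation level used."""

    scaffold: str
    relaxation_level: int | None  # None when the ladder was exhausted empty
    chosen: pd.DataFrame = field(default_factory=pd.DataFrame)
    unanchorable: bool = False


def filter_candidates(
    variants: pd.DataFrame,
    min_quality: float,
    min_depth: float,
    flank_bp: int = 50,
) -> pd.DataFrame:
    """Variants with quality >= min_quality, depth >= min_depth and no other
    candidate within ``flank_bp``.

    Flank clearance is recomputed from the table's own positions (per
    scaffold) and combined with a ``flank_clear`` column when present, so
    variants invisible to this table can still veto a site.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in variants.columns]
    if missing:
        raise KeyError(f"variant table lacks columns {missing}")
    df = variants
    clear = np.ones(len(df), dtype=bool)
    for _, idx in df.groupby("scaffold").groups.items():
        pos = df.loc[idx, "pos"].to_numpy()
        order = np.argsort(pos)
        sp = pos[order]
        d = np.diff(sp, prepend=-(10**12), append=10**12)
        ok = (d[:-1] > flank_bp) & (d[1:] > flank_bp)
        sub = np.ones(len(idx), dtype=bool)
        sub[order] = ok
        clear[df.index.get_indexer(idx)] = sub
    keep = (
        (df["quality"].to_numpy() >= min_quality)
        & (df["depth"].to_numpy() >= min_depth)
        & clear
    )
    if "flank_clear" in df.columns:
        keep &= df["flank_clear"].to_numpy().astype(bool)
    return df[keep]


def relax_and_select(
    scaffold: str,
    variants: pd.DataFrame,
    ladder=DEFAULT_LADDER,
    n_target: int = 2,
    flank_bp: int = 50,
) -> SelectionEntry:
    """Walk the stringency ladder until >= ``n_target`` candidates survive
    (or the ladder is exhausted); a single level is used per scaffold."""
    if not ladder:
        raise ConfigurationError("empty relaxation ladder")
    sub = variants[variants["scaffold"] == scaffold]
    passed = sub.iloc[0:0]
    level = None
    for level, (q, d) in enumerate(ladder):
        passed = filter_candidates(sub, q, d, flank_bp)
        if len(passed) >= n_target:
            return SelectionEntry(scaffold, level, passed)
    # ladder exhausted: keep whatever the least stringent level yields
    if len(passed) == 0:
        return SelectionEntry(scaffold, None, passed, unanchorable=True)
    return SelectionEntry(scaffold, level, passed)


def markers_for_size(length: int, schedule=DEFAULT_SIZE_SCHEDULE) -> int:
    for bound, n in schedule:
        if bound is None or length < bound:
            return n
    return schedule[-1][1]


def _pick_in_window(cands: pd.DataFrame, n: int, terminal_pos) -> list:
    """Up to n candidates, highest designability first, then most terminal,
    with (pos, variant id) as the deterministic tail tie-break."""
    if cands.empty or n <= 0:
        return []
    df = cands.assign(_term=(cands["pos"] - terminal_pos).abs())
    df = df.sort_values(
        ["designability", "_term", "pos", "variant"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    return list(df.index[:n])


def select_targeted(
    scaffold: str,
    length: int,
    filtered: pd.DataFrame,
    n_per_end: int = 2,
    end_window_frac: float = 0.20,
    end_window_cap: int = 500_000,
    size_schedule=DEFAULT_SIZE_SCHEDULE,
) -> pd.DataFrame:
    """Choose markers at the scaffold extremes.

    The total follows the size schedule (1-5 markers) and is allocated to
    the two terminal windows round-robin (left first, at most ``n_per_end``
    per end); any remainder is placed in the interior, maximally spread.
    Returns the chosen variants with an ``end_label`` column.
    """
    window = min(int(end_window_frac * length), end_window_cap)
    if window >= length / 2:
        warnings.warn(
            f"end window {window} bp >= half of {scaffold}; windows clipped")
        window = length // 2
    cands = filtered[filtered["scaffold"] == scaffold]
    n_total = markers_for_size(length, size_schedule)
    n_left = min(n_per_end, (n_total + 1) // 2)
    n_right = min(n_per_end, n_total - n_left)

    left = cands[cands["pos"] <= window]
    right = cands[cands["pos"] > length - window]
    interior = cands.drop(left.index.union(right.index))

    chosen: dict[int, str] = {}
    for i in _pick_in_window(left, n_left, 1):
        chosen[i] = "left"
    for i in _pick_in_window(right, n_right, length):
        chosen[i] = "right"

    # degenerate scaffolds: no terminal candidates -> fall back to the most
    # terminal interior candidates so the scaffold still anchors
    short = (n_left - sum(1 for v in chosen.values() if v == "left"),
             n_right - sum(1 for v in chosen.values() if v == "right"))
    for n_missing, term in zip(short, (1, length)):
        if n_missing > 0:
            pool = interior.drop([i for i in chosen if i in interior.index],
                                 errors="ignore")
            df = pool.assign(_term=(pool["pos"] - term).abs()).sort_values(
                ["_term", "pos", "variant"], kind="mergesort")
            for i in df.index[:n_missing]:
                chosen[i] = "interior"

    # interior fill for the largest size class: maximally spread positions
    n_remaining = n_total - len(chosen)
    pool = cands.drop(list(chosen), errors="ignore")
    while n_remaining > 0 and not pool.empty:
        taken = cands.loc[list(chosen), "pos"].to_numpy()
        if len(taken):
            dist = pool["pos"].apply(
                lambda p: np.min(np.abs(taken - p))
            )
        else:
            dist = pool["pos"] * 0 + 1
        df = pool.assign(_d=dist).sort_values(
            ["_d", "designability", "pos", "variant"],
            ascending=[False, False, True, True], kind="mergesort")
        pick = df.index[0]
        chosen[pick] = "interior"
        pool = pool.drop(pick)
        n_remaining -= 1

    out = cands.loc[list(chosen)].copy()
    out["end_label"] = [chosen[i] for i in out.index]
    return out.sort_values("pos", kind="mergesort")


def select_panel(
    scaffolds,  # list of Scaffold (id, length)
    variants: pd.DataFrame,
    panel_size: int | None = None,
    ladder=DEFAULT_LADDER,
    n_per_end: int = 2,
    end_window_frac: float = 0.20,
    end_window_cap: int = 500_000,
    size_schedule=DEFAULT_SIZE_SCHEDULE,
    flank_bp: int = 50,
) -> pd.DataFrame:
    """Per-scaffold targeted selection for a whole assembly, topped up to a
    fixed genotyping-panel size.

    After the per-scaffold schedule is satisfied, remaining panel capacity
    is filled from the largest scaffolds round-robin, mirroring a
    fixed-size assay in which large scaffolds carry extra markers:
    multi-megabase scaffolds (>= 2 Mb) receive interior markers placed to
    maximize physical coverage (large internal marker gaps blur the
    recombination landscape), smaller scaffolds additional end-window
    markers (alternating ends).
    """
    frames = []
    per_scaffold: dict[str, SelectionEntry] = {}
    lengths = {sc.id: sc.length for sc in scaffolds}
    for sc in scaffolds:
        entry = relax_and_select(sc.id, variants, ladder, n_target=2,
                                 flank_bp=flank_bp)
        per_scaffold[sc.id] = entry
        if entry.unanchorable:
            continue
        chosen = select_targeted(
            sc.id, sc.length, entry.chosen, n_per_end, end_window_frac,
            end_window_cap, size_schedule,
        )
        chosen = chosen.assign(relaxation_level=entry.relaxation_level)
        frames.append(chosen)
    panel = pd.concat(frames) if frames else variants.iloc[0:0]

    if panel_size is not None and len(panel) < panel_size:
        chosen_ids = set(panel["variant"])
        big = sorted([sc for sc in scaffolds if sc.id in per_scaffold
                      and not per_scaffold[sc.id].unanchorable],
                     key=lambda s: (-s.length, s.id))
        extra_rows = []
        side = {}
        exhausted: set[str] = set()
        need = panel_size - len(panel)
        while need > 0 and len(exhausted) < len(big):
            for sc in big:
                if need == 0:
                    break
                if sc.id in exhausted:
                    continue
                window = min(int(end_window_frac * sc.length), end_window_cap,
                             sc.length // 2)
                cands = per_scaffold[sc.id].chosen
                cands = cands[~cands["variant"].isin(chosen_ids)]
                if sc.length >= 2_000_000 and not cands.empty:
                    taken = panel.loc[panel["scaffold"] == sc.id, "pos"]
                    taken = np.concatenate(
                        [taken.to_numpy()]
                        + [[r["pos"]] for r in extra_rows
                           if r["scaffold"] == sc.id])
                    dist = cands["pos"].apply(
                        lambda p: np.min(np.abs(taken - p)) if len(taken)
                        else sc.length)
                    df = cands.assign(_d=dist).sort_values(
                        ["_d", "designability", "pos", "variant"],
                        ascending=[False, False, True, True],
                        kind="mergesort")
                    row = df.iloc[0].drop("_d").copy()
                    row["end_label"] = "interior"
                    row["relaxation_level"] = per_scaffold[sc.id].relaxation_level
                    extra_rows.append(row)
                    chosen_ids.add(row["variant"])
                    need -= 1
                    continue
                use_left = side.get(sc.id, True)
                for lab, sub, term in (
                    ("left", cands[cands["pos"] <= window], 1),
                    ("right", cands[cands["pos"] > sc.length - window],
                     sc.length),
                )[:: 1 if use_left else -1]:
                    pick = _pick_in_window(sub, 1, term)
                    if pick:
                        row = cands.loc[pick[0]].copy()
                        row["end_label"] = lab
                        row["relaxation_level"] = per_scaffold[sc.id].relaxation_level
                        extra_rows.append(row)
                        chosen_ids.add(row["variant"])
                        need -= 1
                        break
                else:
                    exhausted.add(sc.id)
                side[sc.id] = not use_left
        if extra_rows:
            panel = pd.concat([panel, pd.DataFrame(extra_rows)])

    panel = panel.rename(columns={"variant": "marker"})
    panel = panel.sort_values(["scaffold", "pos"], kind="mergesort")
    cols = ["marker", "scaffold", "pos", "end_label", "relaxation_level",
            "quality", "depth", "designability"]
    unanchorable = [s for s, e in per_scaffold.items() if e.unanchorable]
    panel = panel[cols].reset_index(drop=True)
    panel.attrs["unanchorable"] = sorted(unanchorable)
    panel.attrs["scaffold_lengths"] = lengths
    return panel
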