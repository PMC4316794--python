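"""Pseudomolecule assembly, assembly correction and coordinate lift-over.

Anchored scaffolds are concatenated in map order into one pseudomolecule
(PM) per linkage group, each neighbour joined by a fixed 1,000-N spacer;
scaffolds anchored in reverse orientation are reverse-complemented.
Unanchored scaffolds are concatenated, by descending length, into the
non-ordered chromosome zero. Assembly corrections (chimera splits, rejoin
of a mis-split terminal segment) are applied to the scaffold set first and
bump the assembly version tag. Feature coordinates lift between scaffold
and PM space through the component placements, flipping strand for
reverse-placed components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anchoring import ChimeraSplit
from .simulate import Scaffold, reverse_complement


class IntegrityError(RuntimeError):
    """An edit or build violates assembly bookkeeping invariants."""


@dataclass
class Rejoin:
    """Move the first ``length_bp`` bases of ``donor`` onto the 3' end of
    ``acceptor`` (correction of an earlier mis-placed split point)."""

    donor: str
    length_bp: int
    acceptor: str


def _clip_gaps(gaps, lo, hi, shift):
    """Gap intervals intersected with [lo, hi], re-based by ``shift``."""
    out = []
    for s, e in gaps:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2 + shift, e2 + shift))
    return out


def apply_splits_to_assembly(
    scaffolds: list[Scaffold],
    splits: list[ChimeraSplit],
    rejoins: list[Rejoin] | None = None,
    version: str = "v1",
) -> tuple[list[Scaffold], str]:
    """Apply chimera splits (children replace parents) and rejoins; total
    assembly bases are conserved and the version tag is incremented."""
    edits: dict[str, list] = {}
    for sp in splits:
        edits.setdefault(sp.parent, []).append(sp)
    for rj in rejoins or []:
        edits.setdefault(rj.donor, []).append(rj)
        edits.setdefault(rj.acceptor, []).append(rj)
    for sid, lst in edits.items():
        if len(lst) > 1:
            raise IntegrityError(f"overlapping edits on scaffold {sid}")
    by_id = {sc.id: sc for sc in scaffolds}
    for sid in edits:
        if sid not in by_id:
            raise IntegrityError(f"edit references unknown scaffold {sid}")

    total_before = sum(sc.length for sc in scaffolds)
    out: list[Scaffold] = []
    moved_prefix: dict[str, Scaffold] = {}
    for rj in rejoins or []:
        donor = by_id[rj.donor]
        if not 0 < rj.length_bp < donor.length:
            raise IntegrityError(f"rejoin segment outside {rj.donor}")
        moved_prefix[rj.acceptor] = donor

    for sc in scaffolds:
        edit = edits.get(sc.id, [None])[0]
        if isinstance(edit, ChimeraSplit):
            cut = edit.cut_pos
            if not 0 < cut < sc.length:
                raise IntegrityError(f"cut {cut} outside {sc.id}")
            c1 = Scaffold(edit.children[0], cut, _clip_gaps(sc.gaps, 1, cut, 0),
                          sc.sequence[:cut] if sc.sequence else None)
            c2 = Scaffold(edit.children[1], sc.length - cut,
                          _clip_gaps(sc.gaps, cut + 1, sc.length, -cut),
                          sc.sequence[cut:] if sc.sequence else None)
            out.extend([c1, c2])
        elif isinstance(edit, Rejoin) and edit.donor == sc.id:
            k = edit.length_bp
            out.append(Scaffold(sc.id, sc.length - k,
                                _clip_gaps(sc.gaps, k + 1, sc.length, -k),
                                sc.sequence[k:] if sc.sequence else None))
        elif isinstance(edit, Rejoin):  # acceptor
            donor = by_id[edit.donor]
            k = edit.length_bp
            seg_gaps = _clip_gaps(donor.gaps, 1, k, sc.length)
            seq = None
            if sc.sequence is not None and donor.sequence is not None:
                seq = sc.sequence + donor.sequence[:k]
            out.append(Scaffold(sc.id, sc.length + k,
                                list(sc.gaps) + seg_gaps, seq))
        else:
            out.append(sc)
    if sum(sc.length for sc in out) != total_before:
        raise IntegrityError("assembly bases not conserved by edits")

    # corrections add a patch level to the assembly version (v3.5 -> v3.5.1)
    return out, f"{version}.1"


# ---------------------------------------------------------------------------
# builds
# ---------------------------------------------------------------------------


def build_pms(
    ordered_assignments: pd.DataFrame,
    scaffolds: list[Scaffold],
    spacer: int = 1_000,
    pm_prefix: str = "PM",
):
    """Assemble pseudomolecules from ordered scaffold assignments.

    Returns (placements, agp_rows, sequences): ``placements`` has one row
    per placed scaffold (pm, scaffold, offset of preceding bases, length,
    orientation); ``sequences`` maps pm id to sequence (None when scaffold
    sequences are not realized). Every scaffold appears exactly once —
    anchored ones on their group's PM, the rest on chromosome zero
    (``<prefix>00``), ordered by descending length then id.
    """
    by_id = {sc.id: sc for sc in scaffolds}
    seen: set[str] = set()
    placements: list[dict] = []
    agp_rows: list[dict] = []
    sequences: dict[str, str | None] = {}

    anchored_ids = list(ordered_assignments["scaffold"])
    for sid in anchored_ids:
        if sid in seen:
            raise IntegrityError(f"scaffold {sid} placed twice")
        seen.add(sid)
    unanchored = sorted(
        (sc for sc in scaffolds if sc.id not in seen),
        key=lambda sc: (-sc.length, sc.id),
    )

    def emit(pm_id: str, members: list[tuple[str, str]]):
        offset = 0
        part = 0
        chunks: list[str] = []
        have_seq = all(by_id[sid].sequence is not None for sid, _ in members)
        for k, (sid, orient) in enumerate(members):
            sc = by_id[sid]
            if k > 0:
                part += 1
                agp_rows.append({"object": pm_id, "object_beg": offset + 1,
                                 "object_end": offset + spacer,
                                 "part_number": part, "component_type": "U",
                                 "gap_length": spacer, "gap_type": "scaffold",
                                 "linkage": "yes", "evidence": "map"})
                if have_seq:
                    chunks.append("N" * spacer)
                offset += spacer
            part += 1
            agp_rows.append({"object": pm_id, "object_beg": offset + 1,
                             "object_end": offset + sc.length,
                             "part_number": part, "component_type": "W",
                             "component_id": sid, "component_beg": 1,
                             "component_end": sc.length,
                             "orientation": orient})
            placements.append({"pm": pm_id, "scaffold": sid, "offset": offset,
                               "length": sc.length, "orientation": orient})
            if have_seq:
                chunks.append(reverse_complement(sc.sequence)
                              if orient == "-" else sc.sequence)
            offset += sc.length
        sequences[pm_id] = "".join(chunks) if have_seq else None

    for group, grp in ordered_assignments.groupby("group", sort=True):
        pm_id = f"{pm_prefix}{int(group):02d}"
        emit(pm_id, [(r.scaffold, r.orientation) for r in grp.itertuples()])
    if unanchored:
        emit(f"{pm_prefix}00", [(sc.id, "?") for sc in unanchored])

    placements_df = pd.DataFrame(placements)
    return placements_df, agp_rows, sequences


# ---------------------------------------------------------------------------
# lift-over
# ---------------------------------------------------------------------------


def liftover(start: int, end: int, strand: str,
             offset: int, length: int, orientation: str):
    """Scaffold feature -> PM coordinates through one component placement.

    Forward components shift by the component offset; reverse components
    mirror coordinates (p' = L - p + 1) and flip strand. 1-based inclusive;
    feature length is preserved exactly.
    """
    if not (1 <= start <= end <= length):
        raise ValueError(f"feature ({start},{end}) outside component of "
                         f"length {length}")
    if orientation == "-":
        new_start = offset + (length - end + 1)
        new_end = offset + (length - start + 1)
        new_strand = {"+": "-", "-": "+", ".": "."}[strand]
    else:
        new_start, new_end = offset + start, offset + end
        new_strand = strand
    return new_start, new_end, new_strand


def inverse_liftover(start: int, end: int, strand: str,
                     offset: int, length: int, orientation: str):
    """PM coordinates back to scaffold coordinates (inverse of liftover)."""
    if orientation == "-":
        s = length - (end - offset) + 1
        e = length - (start - offset) + 1
        new_strand = {"+": "-", "-": "+", ".": "."}[strand]
    else:
        s, e = start - offset, end - offset
        new_strand = strand
    if not (1 <= s <= e <= length):
        raise ValueError("PM interval does not map inside the component")
    return s, e, new_strand


def lift_features(features: pd.DataFrame, placements: pd.DataFrame) -> pd.DataFrame:
    """Lift a scaffold-space feature table (seqid, start, end, strand, ...)
    into PM space. Every feature must sit on a placed scaffold."""
    pl = placements.set_index("scaffold")
    rows = []
    for ft in features.itertuples():
        p = pl.loc[ft.seqid]
        s, e, st = liftover(int(ft.start), int(ft.end), ft.strand,
                            int(p["offset"]), int(p["length"]),
                            str(p["orientation"]))
        row = ft._asdict()
        row.pop("Index", None)
        row.update({"seqid": p["pm"], "start": s, "end": e, "strand": st,
                    "source_scaffold": ft.seqid, "source_start": int(ft.start),
                    "source_end": int(ft.end)})
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["seqid", "start"], kind="mergesort").reset_index(drop=True)


def pm_positions(placements: pd.DataFrame, scaffold_pos: pd.DataFrame) -> pd.DataFrame:
    """PM coordinates of point loci given as (scaffold, pos) rows; loci on
    unplaced scaffolds are dropped."""
    pl = placements.set_index("scaffold")
    rows = []
    for loc in scaffold_pos.itertuples():
        if loc.scaffold not in pl.index:
            continue
        p = pl.loc[loc.scaffold]
        s, _e, _ = liftover(int(loc.pos), int(loc.pos), ".",
                            int(p["offset"]), int(p["length"]),
                            str(p["orientation"]))
        row = loc._asdict()
        row.pop("Index", None)
        row.update({"pm": p["pm"], "pm_pos": s})
        rows.append(row)
    return pd.DataFrame(rows)
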