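"""Seeded synthetic genome, scaffold set and F2 intercross.

This module manufactures everything the anchoring pipeline consumes, plus
the ground truth needed to score it: a multi-chromosome genome with a
piecewise-linear Marey function (suppressed recombination across a
centromeric plateau), centromeric satellite and rDNA arrays, a gene
annotation, a scaffold set with internal N-gaps and injected chimeric
scaffolds, a candidate-variant table, and a codominant F2 genotype matrix
simulated with Poisson (no-interference, Haldane) crossovers, genotyping
error, missing data and viability-driven segregation distortion.

Sequences are realized lazily: truth objects carry lengths and intervals
only, and random nucleotides (with planted repeat monomers) are generated
on demand, so map-recovery studies never pay for sequence synthesis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .genotype_qc import MISSING, GenotypeData

CENTROMERIC_FAMILIES = ("pSat107", "CentSpA", "CentSpB", "CentSpC")
RDNA_45S_FAMILIES = ("rDNA_18S", "rDNA_5.8S", "rDNA_26S")
RDNA_5S_FAMILY = "rDNA_5S"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    h = int.from_bytes(hashlib.md5(stage.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeTruth:
    """One chromosome: length, true Marey curve and structural features."""

    id: str
    length: int
    marey_x: np.ndarray          # bp breakpoints, [0 .. length]
    marey_y: np.ndarray          # cM at breakpoints, nondecreasing, y[0] = 0
    centromere: tuple[int, int]  # 1-based inclusive interval
    rdna: list[tuple[int, int, str]] = field(default_factory=list)

    def cm_at(self, bp):
        """True genetic position (cM) of physical position(s) in bp."""
        return np.interp(bp, self.marey_x, self.marey_y)

    @property
    def map_length_cm(self) -> float:
        return float(self.marey_y[-1])


@dataclass
class TruthGenome:
    chromosomes: list[ChromosomeTruth]
    genes: pd.DataFrame          # chrom, start, end, strand (1-based inclusive)
    repeat_arrays: pd.DataFrame  # chrom, family, start, end

    def chrom(self, cid: str) -> ChromosomeTruth:
        return next(c for c in self.chromosomes if c.id == cid)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass
class Scaffold:
    """An assembly scaffold: length, N-gap intervals, optional sequence."""

    id: str
    length: int
    gaps: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    sequence: str | None = None

    def in_gap(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.gaps)


@dataclass
class TruthAnchoring:
    """True placement of every scaffold fragment on the chromosomes.

    ``fragments`` rows: scaffold, scaf_start, scaf_end, chrom, chrom_start,
    chrom_end, orientation. Plain scaffolds have one fragment covering the
    whole sequence; injected chimeras have two, from different chromosomes,
    separated by the junction N-track recorded in ``chimeras``.
    """

    fragments: pd.DataFrame
    chimeras: pd.DataFrame  # scaffold, junction_start, junction_end (scaffold bp)

    def scaffold_to_chrom(self, scaffold: str, pos: int) -> tuple[str, int]:
        """Map a scaffold coordinate to its true chromosome coordinate."""
        frs = self.fragments[self.fragments["scaffold"] == scaffold]
        for fr in frs.itertuples():
            if fr.scaf_start <= pos <= fr.scaf_end:
                if fr.orientation == "+":
                    return fr.chrom, fr.chrom_start + (pos - fr.scaf_start)
                return fr.chrom, fr.chrom_start + (fr.scaf_end - pos)
        raise ValueError(f"position {pos} on {scaffold} falls in the junction gap")

    def chrom_interval_to_scaffold(self, chrom: str, start: int, end: int):
        """Yield (scaffold, s_start, s_end, orientation) pieces covering the
        chromosome interval [start, end] (clipped per fragment)."""
        frs = self.fragments[self.fragments["chrom"] == chrom]
        for fr in frs.itertuples():
            lo, hi = max(start, fr.chrom_start), min(end, fr.chrom_end)
            if lo > hi:
                continue
            if fr.orientation == "+":
                a = fr.scaf_start + (lo - fr.chrom_start)
                b = fr.scaf_start + (hi - fr.chrom_start)
            else:
                a = fr.scaf_start + (fr.chrom_end - hi)
                b = fr.scaf_start + (fr.chrom_end - lo)
            yield fr.scaffold, a, b, fr.orientation


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> TruthGenome:
    """Generate chromosome truths: Marey curves, centromeres, repeats, genes.

    Each Marey curve is piecewise linear and strictly monotone, with a
    near-flat plateau (``centromere_slope`` cM/Mb) across the centromere and
    higher, slightly asymmetric slopes on the two arms; the per-chromosome
    map length is drawn around ``chrom_map_length_cm``. Every centromere
    receives tandem arrays from pSat107 plus at least one CentSp family.
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    chroms: list[ChromosomeTruth] = []
    repeat_rows: list[dict] = []
    gene_rows: list[dict] = []

    for ci in range(config.n_chrom):
        cid = f"chr{ci + 1:02d}"
        length = int(
            max(
                rng.normal(config.chrom_length_mean, config.chrom_length_sd),
                0.75 * config.chrom_length_mean,
            )
        )
        span = min(config.centromere_span, int(0.6 * length))
        center = rng.uniform(0.38, 0.58) * length
        c_start = int(np.clip(center - span / 2, 0.05 * length, length - span - 1))
        c_end = c_start + span

        map_len = max(rng.normal(config.chrom_map_length_cm,
                                 config.chrom_map_length_sd), 60.0)
        flat = getattr(config, "flat_slope", None)
        if flat is not None:
            # exactly linear curve for calibration studies
            marey_x = np.array([0.0, float(length)])
            marey_y = np.array([0.0, flat * length / 1e6])
        else:
            plateau_cm = span / 1e6 * config.centromere_slope
            arm_cm = max(map_len - plateau_cm, 10.0)
            a_mb, b_mb = c_start / 1e6, (length - c_end) / 1e6
            u = rng.uniform(-config.arm_asymmetry, config.arm_asymmetry)
            base = arm_cm / (a_mb * (1 + u) + b_mb * (1 - u))
            s_left, s_right = base * (1 + u), base * (1 - u)
            marey_x = np.array([0.0, float(c_start), float(c_end), float(length)])
            marey_y = np.cumsum(
                [0.0, s_left * a_mb, plateau_cm, s_right * b_mb]
            )
        chrom = ChromosomeTruth(cid, length, marey_x, marey_y, (c_start + 1, c_end))

        # centromeric satellite arrays: pSat107 + 1-2 CentSp families
        n_extra = int(rng.integers(1, 3))
        extras = list(rng.choice(CENTROMERIC_FAMILIES[1:], size=n_extra, replace=False))
        families = ["pSat107"] + extras
        # satellite arrays interleave family-by-family across dense slots in
        # the centromere core: families genuinely co-localize (inter-array
        # gaps well inside the clustering distance), flank the midpoint, and
        # any scaffold overlapping a few hundred kb of core carries several
        # families — robust to uncertain scaffold order inside the region
        slots = np.linspace(c_start + 0.3 * span, c_end - 0.3 * span, 8)
        for si, pos in enumerate(slots):
            if si in (3, 4):
                continue  # the core slots are taken by the midpoint pair
            fam = families[si % len(families)]
            pos = int(pos)
            alen = int(rng.uniform(15_000, 40_000))
            repeat_rows.append(
                {"chrom": cid, "family": fam, "start": pos + 1,
                 "end": min(pos + alen, c_end)}
            )
        # a pSat107 + CentSp array pair abutting the centromere midpoint:
        # the functional core carries the densest satellite occupancy
        mid = (c_start + c_end) // 2
        repeat_rows.append({"chrom": cid, "family": "pSat107",
                            "start": mid - 30_000, "end": mid})
        repeat_rows.append({"chrom": cid, "family": extras[0],
                            "start": mid + 1, "end": mid + 30_000})

        # rDNA arrays (pericentromeric 45S components; 5S on an arm)
        if ci in config.rdna_45s_chroms:
            pos = c_end + 200_000
            for fam, alen in zip(RDNA_45S_FAMILIES, (10_000, 3_000, 15_000)):
                repeat_rows.append(
                    {"chrom": cid, "family": fam, "start": pos + 1, "end": pos + alen}
                )
                chrom.rdna.append((pos + 1, pos + alen, fam.replace("rDNA_", "")))
                pos += alen + 1_000
        if ci in config.rdna_5s_chroms:
            pos = int(0.15 * length)
            repeat_rows.append(
                {"chrom": cid, "family": RDNA_5S_FAMILY,
                 "start": pos + 1, "end": pos + 30_000}
            )
            chrom.rdna.append((pos + 1, pos + 30_000, "5S"))

        # genes: non-overlapping intervals spread along the chromosome
        n_genes = int(round(length / 1e6 * config.genes_per_mb))
        starts = np.sort(rng.choice(length - 10_000, size=n_genes, replace=False))
        prev_end = 0
        for s in starts:
            s = int(max(s, prev_end + 200))
            glen = int(rng.uniform(2_000, 6_000))
            e = min(s + glen, length - 1)
            if e <= s:
                continue
            gene_rows.append(
                {"chrom": cid, "start": s + 1, "end": e + 1,
                 "strand": "+" if rng.random() < 0.5 else "-"}
            )
            prev_end = e
        chroms.append(chrom)

    genes = pd.DataFrame(gene_rows)
    genes["gene_id"] = [f"gene{j + 1:05d}" for j in range(len(genes))]
    repeats = pd.DataFrame(repeat_rows)
    return TruthGenome(chroms, genes, repeats)


# ---------------------------------------------------------------------------
# fragmentation into scaffolds (with chimera injection)
# ---------------------------------------------------------------------------


def _contig_gaps(length: int, config: SimConfig,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    """Internal N-gap intervals: contigs of roughly equal size with small
    positional jitter, separated by short N tracks."""
    n_gaps = max(0, int(round(length / config.contig_target_length)) - 1)
    gaps = []
    for k in range(1, n_gaps + 1):
        contig = length / (n_gaps + 1)
        center = k * contig + rng.uniform(-0.05, 0.05) * contig
        half = config.contig_gap_length // 2
        s = int(np.clip(center - half, 1_000, length - config.contig_gap_length - 1_000))
        gaps.append((s + 1, s + config.contig_gap_length))
    return gaps


def fragment_into_scaffolds(
    genome: TruthGenome, config: SimConfig
) -> tuple[list[Scaffold], TruthAnchoring]:
    """Tile each chromosome into scaffolds, flip a random subset, then
    splice pairs of similar-length scaffolds from different chromosomes
    into chimeras joined across a long N-track (the recorded cut point)."""
    rng = _rng(config.seed, "fragment")
    pieces: list[dict] = []  # one per pre-chimera scaffold
    for chrom in genome.chromosomes:
        pos = 0
        while pos < chrom.length:
            mu = np.log(config.scaffold_length_mean) - config.scaffold_length_sigma**2 / 2
            ln = int(rng.lognormal(mu, config.scaffold_length_sigma))
            ln = max(ln, config.scaffold_min_length)
            if chrom.length - pos - ln < config.scaffold_min_length:
                ln = chrom.length - pos
            orient = "-" if rng.random() < config.flip_probability else "+"
            pieces.append(
                {"chrom": chrom.id, "chrom_start": pos + 1,
                 "chrom_end": pos + ln, "length": ln, "orientation": orient}
            )
            pos += ln

    if config.chimera_count > len(pieces):
        raise ConfigurationError("chimera_count exceeds scaffold count")

    # choose chimera partners: similar length, different chromosomes, and
    # few internal gaps so the junction N-track dominates the cut search
    order = sorted(range(len(pieces)), key=lambda i: pieces[i]["length"])
    eligible = [
        i for i in order if 550_000 <= pieces[i]["length"] <= 850_000
    ]
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for a_idx in range(len(eligible)):
        if len(pairs) == config.chimera_count:
            break
        i = eligible[a_idx]
        if i in used:
            continue
        for b_idx in range(a_idx + 1, len(eligible)):
            j = eligible[b_idx]
            if j in used or pieces[i]["chrom"] == pieces[j]["chrom"]:
                continue
            ratio = pieces[i]["length"] / pieces[j]["length"]
            if ratio < 0.92:
                break  # lengths sorted; no closer partner further on
            pairs.append((i, j))
            used.update((i, j))
            break
    if len(pairs) < config.chimera_count:
        raise ConfigurationError(
            f"could only form {len(pairs)} of {config.chimera_count} chimeras; "
            "widen the scaffold size distribution"
        )

    scaffolds: list[Scaffold] = []
    frag_rows: list[dict] = []
    chimera_rows: list[dict] = []
    consumed = set(used)

    entries: list[dict] = []  # interim records with fragments attached
    for i, p in enumerate(pieces):
        if i in consumed:
            continue
        gaps = _contig_gaps(p["length"], config, rng)
        entries.append({"length": p["length"], "gaps": gaps, "frags": [
            {"scaf_start": 1, "scaf_end": p["length"], **{k: p[k] for k in
             ("chrom", "chrom_start", "chrom_end", "orientation")}}]})
    for i, j in pairs:
        a, b = pieces[i], pieces[j]
        gap = config.chimera_gap_length
        gaps_a = _contig_gaps(a["length"], config, rng)
        gaps_b = _contig_gaps(b["length"], config, rng)
        off = a["length"] + gap
        gaps = gaps_a + [(a["length"] + 1, a["length"] + gap)] + [
            (s + off, e + off) for s, e in gaps_b
        ]
        entries.append({
            "length": a["length"] + gap + b["length"],
            "gaps": gaps,
            "junction": (a["length"] + 1, a["length"] + gap),
            "frags": [
                {"scaf_start": 1, "scaf_end": a["length"], **{k: a[k] for k in
                 ("chrom", "chrom_start", "chrom_end", "orientation")}},
                {"scaf_start": off + 1, "scaf_end": off + b["length"],
                 **{k: b[k] for k in
                    ("chrom", "chrom_start", "chrom_end", "orientation")}},
            ],
        })

    # assembly-style ids: numbered by descending length
    entries.sort(key=lambda e: (-e["length"], e["frags"][0]["chrom"],
                                e["frags"][0]["chrom_start"]))
    for k, ent in enumerate(entries):
        sid = f"scaffold{k + 1:04d}"
        scaffolds.append(Scaffold(sid, ent["length"], ent["gaps"]))
        for fr in ent["frags"]:
            frag_rows.append({"scaffold": sid, **fr})
        if "junction" in ent:
            chimera_rows.append(
                {"scaffold": sid, "junction_start": ent["junction"][0],
                 "junction_end": ent["junction"][1]}
            )

    fragments = pd.DataFrame(frag_rows)
    chimeras = pd.DataFrame(chimera_rows,
                            columns=["scaffold", "junction_start", "junction_end"])
    return scaffolds, TruthAnchoring(fragments, chimeras)


# ---------------------------------------------------------------------------
# sequence realization
# ---------------------------------------------------------------------------


def _family_monomer(family: str, length: int = 352) -> str:
    rng = _rng(7, f"monomer:{family}")
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def realize_sequences(
    scaffolds: list[Scaffold],
    truth: TruthAnchoring,
    genome: TruthGenome,
    config: SimConfig,
) -> None:
    """Fill in random nucleotide sequences, plant tandem repeat-monomer
    arrays at the true repeat positions, and blank N-gap intervals."""
    rng = _rng(config.seed, "sequence")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    monomers = {f: _family_monomer(f) for f in
                set(genome.repeat_arrays["family"])} if len(genome.repeat_arrays) else {}

    by_scaffold: dict[str, list] = {}
    for arr in genome.repeat_arrays.itertuples():
        for sid, s, e, _orient in truth.chrom_interval_to_scaffold(
            arr.chrom, arr.start, arr.end
        ):
            by_scaffold.setdefault(sid, []).append((s, e, arr.family))

    for sc in scaffolds:
        arr = bases[rng.integers(0, 4, sc.length)]
        for s, e, fam in by_scaffold.get(sc.id, []):
            mono = monomers[fam]
            reps = (e - s) // len(mono) + 1
            tile = np.frombuffer((mono * reps).encode(), dtype="S1")[: e - s + 1]
            arr[s - 1 : e] = tile
        for s, e in sc.gaps:
            arr[s - 1 : e] = b"N"
        sc.sequence = arr.tobytes().decode()


# ---------------------------------------------------------------------------
# candidate variants
# ---------------------------------------------------------------------------


def generate_variants(
    scaffolds: list[Scaffold], config: SimConfig
) -> pd.DataFrame:
    """Candidate variant table (VCF-like TSV columns): scaffold, pos,
    quality, depth, flank_clear, designability.

    Quality is a mixture (most calls at the 999 ceiling, a tail of lower
    confidence calls), depth is Poisson around the study's coverage, and a
    few percent of variants get a close companion so the 50-bp flank rule
    has something to reject.
    """
    rng = _rng(config.seed, "variants")
    rows = []
    for sc in scaffolds:
        n = max(4, sc.length // config.variant_spacing)
        pos = np.sort(rng.choice(np.arange(100, sc.length - 100), size=n,
                                 replace=False))
        pos = np.array([p for p in pos if not sc.in_gap(int(p))], dtype=int)
        extra = []
        for p in pos:
            if rng.random() < 0.04:  # plant a flank violation
                extra.append(int(p) + int(rng.integers(15, 45)))
        allpos = np.sort(np.concatenate([pos, np.array(extra, dtype=int)]))
        u = rng.random(len(allpos))
        quality = np.where(
            u < 0.70, 999.0,
            np.where(u < 0.90, rng.uniform(200, 998, len(allpos)),
                     rng.uniform(20, 199, len(allpos)))
        )
        depth = rng.poisson(22, len(allpos))
        gap_dist = np.diff(allpos, prepend=-(10**9), append=10**9)
        clear = (gap_dist[:-1] > 50) & (gap_dist[1:] > 50)
        design = np.round(rng.beta(9, 1, len(allpos)), 3)
        for k, p in enumerate(allpos):
            rows.append(
                {"variant": f"{sc.id}_{int(p)}", "scaffold": sc.id, "pos": int(p),
                 "quality": round(float(quality[k]), 1), "depth": int(depth[k]),
                 "flank_clear": bool(clear[k]),
                 "designability": float(design[k])}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F2 intercross
# ---------------------------------------------------------------------------


def marker_truth(markers: pd.DataFrame, truth: TruthAnchoring,
                 genome: TruthGenome) -> pd.DataFrame:
    """Annotate a (marker, scaffold, pos) table with the true chromosome,
    chromosome position and genetic position of every marker."""
    chroms, cpos, cms = [], [], []
    for m in markers.itertuples():
        c, p = truth.scaffold_to_chrom(m.scaffold, m.pos)
        chroms.append(c)
        cpos.append(p)
        cms.append(float(genome.chrom(c).cm_at(p)))
    out = markers.copy()
    out["chrom"] = chroms
    out["chrom_pos"] = cpos
    out["cm"] = cms
    return out


def _gamete(cm_positions: np.ndarray, map_len_cm: float,
            rng: np.random.Generator) -> np.ndarray:
    """Alleles (0/1) transmitted by one F1 gamete at the given cM positions:
    Poisson crossover count, uniform crossover cM placement (Haldane)."""
    n_cx = rng.poisson(map_len_cm / 100.0)
    start = int(rng.integers(2))
    if n_cx == 0:
        return np.full(len(cm_positions), start, dtype=np.int8)
    cx = np.sort(rng.uniform(0.0, map_len_cm, n_cx))
    return ((start + np.searchsorted(cx, cm_positions)) % 2).astype(np.int8)


def simulate_f2(
    genome: TruthGenome,
    markers: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
) -> GenotypeData:
    """Simulate the F2 genotype matrix at the given markers.

    ``markers`` must carry ``chrom``/``chrom_pos`` truth columns (see
    :func:`marker_truth`). Each individual is the fusion of two independent
    F1 gametes; viability selection at the configured distortion loci is
    applied by rejection sampling, then genotyping error and missingness.
    """
    for col in ("chrom", "chrom_pos"):
        if col not in markers.columns:
            raise ValueError(f"marker table lacks {col!r}; run marker_truth first")
    bad = markers[~markers["chrom"].isin([c.id for c in genome.chromosomes])]
    if len(bad):
        raise ValueError(f"markers on unknown chromosomes: {list(bad['marker'])[:3]}")
    for m in markers.itertuples():
        if not 1 <= m.chrom_pos <= genome.chrom(m.chrom).length:
            raise ValueError(f"marker {m.marker} off chromosome {m.chrom}")

    rng = _rng(config.seed if seed is None else seed, "f2")
    by_chrom: dict[str, np.ndarray] = {}
    idx_by_chrom: dict[str, np.ndarray] = {}
    for c in genome.chromosomes:
        mask = (markers["chrom"] == c.id).to_numpy()
        idx_by_chrom[c.id] = np.where(mask)[0]
        by_chrom[c.id] = c.cm_at(markers["chrom_pos"].to_numpy()[mask])

    dist = [
        (genome.chromosomes[d.chrom_index].id,
         float(genome.chromosomes[d.chrom_index].cm_at(
             d.rel_pos * genome.chromosomes[d.chrom_index].length)),
         np.array([d.w_aa, d.w_ab, d.w_bb]) / max(d.w_aa, d.w_ab, d.w_bb))
        for d in config.distortion_loci
    ]

    n_mark = len(markers)
    calls = np.empty((n_mark, config.n_individuals), dtype=np.int8)
    for ind in range(config.n_individuals):
        while True:
            geno = np.empty(n_mark, dtype=np.int8)
            dist_geno: dict[tuple[str, float], int] = {}
            for c in genome.chromosomes:
                pos_cm = by_chrom[c.id]
                extra = [cm for cid, cm, _w in dist if cid == c.id]
                allpos = np.concatenate([pos_cm, np.array(extra)])
                g = (_gamete(allpos, c.map_length_cm, rng)
                     + _gamete(allpos, c.map_length_cm, rng))
                geno[idx_by_chrom[c.id]] = g[: len(pos_cm)]
                for k, cm in enumerate(extra):
                    dist_geno[(c.id, cm)] = int(g[len(pos_cm) + k])
            accept = 1.0
            for cid, cm, w in dist:
                accept *= w[dist_geno[(cid, cm)]]
            if rng.random() < accept:
                break
        calls[:, ind] = geno

    # genotyping error: replace with one of the two other classes
    err = rng.random(calls.shape) < config.error_rate
    shift = rng.integers(1, 3, size=calls.shape)
    calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    # missing data
    calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    individuals = [f"F2_{i + 1:03d}" for i in range(config.n_individuals)]
    calls_df = pd.DataFrame(calls, index=markers["marker"].to_numpy(),
                            columns=individuals)
    calls_df.index.name = "marker"

    # per-marker assay quality scores: mostly clean clusters, a small
    # contaminated fraction that the q1/q2 thresholds will catch
    lowq = rng.random(n_mark) < 0.03
    q1 = np.where(lowq, rng.beta(2, 2, n_mark), rng.beta(14, 2, n_mark))
    q2 = np.where(rng.random(n_mark) < 0.02, rng.beta(2, 4, n_mark),
                  rng.beta(10, 1.5, n_mark))
    meta = markers.copy().set_index("marker")
    meta["q1"] = np.round(q1, 3)
    meta["q2"] = np.round(q2, 3)
    return GenotypeData(calls_df, meta)


# ---------------------------------------------------------------------------
# repeat-hit table (alignment-style evidence for centromere calling)
# ---------------------------------------------------------------------------


def generate_repeat_hits(
    genome: TruthGenome, truth: TruthAnchoring, config: SimConfig
) -> pd.DataFrame:
    """BED-like hit table in scaffold coordinates, emulating homology-search
    output: true arrays yield high-identity/high-coverage hits; decoy hits
    (low identity, or isolated single-family arm hits) exercise the filters."""
    rng = _rng(config.seed, "repeat_hits")
    rows = []
    for arr in genome.repeat_arrays.itertuples():
        for sid, s, e, _o in truth.chrom_interval_to_scaffold(
            arr.chrom, arr.start, arr.end
        ):
            rows.append(
                {"scaffold": sid, "start": int(s), "end": int(e),
                 "family": arr.family,
                 "identity": round(float(rng.uniform(0.82, 0.99)), 3),
                 "coverage": round(float(rng.uniform(0.85, 1.0)), 3)}
            )
    # low-identity noise hits scattered across the genome
    frags = truth.fragments
    for _ in range(3 * len(genome.chromosomes)):
        fr = frags.iloc[int(rng.integers(len(frags)))]
        span = fr["scaf_end"] - fr["scaf_start"]
        if span < 20_000:
            continue
        s = int(fr["scaf_start"] + rng.integers(0, span - 10_000))
        fam = str(rng.choice(CENTROMERIC_FAMILIES))
        rows.append(
            {"scaffold": fr["scaffold"], "start": s, "end": s + int(rng.integers(300, 5_000)),
             "family": fam,
             "identity": round(float(rng.uniform(0.45, 0.79)), 3),
             "coverage": round(float(rng.uniform(0.5, 1.0)), 3)}
        )
    # isolated high-identity single-family hits on two chromosome arms:
    # they pass the filters but must not become centromere calls
    for ci in (1, 6):
        if ci >= len(genome.chromosomes):
            continue
        chrom = genome.chromosomes[ci]
        pos = int(0.08 * chrom.length)
        for sid, s, e, _o in truth.chrom_interval_to_scaffold(
            chrom.id, pos, pos + 3_000
        ):
            rows.append(
                {"scaffold": sid, "start": int(s), "end": int(e),
                 "family": "CentSpA",
                 "identity": round(float(rng.uniform(0.85, 0.95)), 3),
                 "coverage": round(float(rng.uniform(0.85, 1.0)), 3)}
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["scaffold", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation in scaffold coordinates
# ---------------------------------------------------------------------------


def genes_to_scaffold_gff(genome: TruthGenome, truth: TruthAnchoring) -> pd.DataFrame:
    """Project the true gene set (plus rRNA features at the rDNA arrays)
    onto scaffold coordinates. Genes spanning a scaffold junction (possible
    only at chimera joins) are dropped."""
    rows = []
    for g in genome.genes.itertuples():
        pieces = list(truth.chrom_interval_to_scaffold(g.chrom, g.start, g.end))
        if len(pieces) != 1:
            continue
        sid, s, e, orient = pieces[0]
        strand = g.strand if orient == "+" else ("-" if g.strand == "+" else "+")
        rows.append({"seqid": sid, "type": "gene", "start": int(s), "end": int(e),
                     "strand": strand, "attr_id": g.gene_id, "name": g.gene_id})
    rrna = genome.repeat_arrays[
        genome.repeat_arrays["family"].str.startswith("rDNA_")
    ]
    for k, arr in enumerate(rrna.itertuples()):
        unit = arr.family.replace("rDNA_", "")
        for sid, s, e, orient in truth.chrom_interval_to_scaffold(
            arr.chrom, arr.start, arr.end
        ):
            rows.append({"seqid": sid, "type": "rRNA", "start": int(s), "end": int(e),
                         "strand": "+", "attr_id": f"rrna{k + 1:03d}",
                         "name": f"{unit}_rRNA"})
    df = pd.DataFrame(rows)
    return df.sort_values(["seqid", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# fixture set on disk
# ---------------------------------------------------------------------------


def write_fixture_set(outdir, config: SimConfig) -> dict:
    """Run the full simulation and write every downstream input plus truth.

    Emits scaffolds FASTA, candidate-variant TSV, genes GFF3, repeat-hit
    TSV, truth AGP (chromosome tiling) and a truth JSON sidecar; returns the
    in-memory objects so callers can continue without re-reading.
    """
    from pathlib import Path

    from . import io as afio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    scaffolds, truth = fragment_into_scaffolds(genome, config)
    realize_sequences(scaffolds, truth, genome, config)
    variants = generate_variants(scaffolds, config)
    gff = genes_to_scaffold_gff(genome, truth)
    hits = generate_repeat_hits(genome, truth, config)

    afio.write_fasta(outdir / "scaffolds.fasta",
                     [(sc.id, sc.sequence) for sc in scaffolds])
    afio.write_tsv(outdir / "variants.tsv", variants)
    afio.write_gff3(outdir / "genes.gff3", gff)
    afio.write_tsv(outdir / "repeat_hits.tsv", hits)

    agp_rows = []
    for cid, grp in truth.fragments.groupby("chrom", sort=True):
        grp = grp.sort_values("chrom_start")
        for k, fr in enumerate(grp.itertuples()):
            agp_rows.append(
                {"object": cid, "object_beg": int(fr.chrom_start),
                 "object_end": int(fr.chrom_end), "part_number": k + 1,
                 "component_type": "W", "component_id": fr.scaffold,
                 "component_beg": int(fr.scaf_start),
                 "component_end": int(fr.scaf_end),
                 "orientation": fr.orientation}
            )
    afio.write_agp(outdir / "truth.agp", agp_rows)

    truth_json = {
        "chromosomes": [
            {"id": c.id, "length": c.length,
             "marey_x": [float(x) for x in c.marey_x],
             "marey_y": [float(y) for y in c.marey_y],
             "centromere": list(c.centromere),
             "rdna": [[int(s), int(e), kind] for s, e, kind in c.rdna]}
            for c in genome.chromosomes
        ],
        "chimeras": truth.chimeras.to_dict(orient="records"),
        "scaffolds": [
            {"id": sc.id, "length": sc.length,
             "gaps": [[int(s), int(e)] for s, e in sc.gaps]}
            for sc in scaffolds
        ],
        "fragments": truth.fragments.to_dict(orient="records"),
        "seed": config.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)

    return {"genome": genome, "scaffolds": scaffolds, "truth": truth,
            "variants": variants, "gff": gff, "repeat_hits": hits}
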