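"""End-to-end orchestration: simulate -> select -> genotype -> QC -> map ->
anchor -> correct -> build PMs -> recombination landscape -> centromeres ->
report, with every stage's outputs written to the run directory and a
manifest recording the seed, config digest and SHA-256 of every artifact
(manifests of two runs with the same seed and config are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as afio
from .anchoring import assign_scaffolds, order_assignments, resolve_chimeras
from .centromeres import annotate_rdna, call_centromeres, filter_hits, overlap_report
from .config import PipelineConfig
from .genotype_qc import (drop_extreme_distortion, filter_individuals,
                          filter_markers, segregation_report)
from .linkage import build_map
from .pseudomolecules import apply_splits_to_assembly, build_pms, lift_features
from .recombination import landscape
from .reporting import summarize_anchoring, summarize_validation
from .simulate import marker_truth, simulate_f2, write_fixture_set
from .snp_selection import select_panel


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _remap_markers(panel: pd.DataFrame, splits) -> pd.DataFrame:
    """Translate marker scaffold coordinates onto split children."""
    if not splits:
        return panel
    by_parent = {sp.parent: sp for sp in splits}
    out = panel.copy()
    for i in out.index:
        sid = out.at[i, "scaffold"]
        sp = by_parent.get(sid)
        if sp is None:
            continue
        pos = out.at[i, "pos"]
        if pos <= sp.cut_pos:
            out.at[i, "scaffold"] = sp.children[0]
        else:
            out.at[i, "scaffold"] = sp.children[1]
            out.at[i, "pos"] = pos - sp.cut_pos
    return out


def _remap_features(df: pd.DataFrame, splits, seq_col: str = "seqid") -> pd.DataFrame:
    """Translate interval features from split parents onto children; a
    feature straddling the cut is clipped to the side holding most of it."""
    if not splits:
        return df
    by_parent = {sp.parent: sp for sp in splits}
    out = df.copy()
    for i in out.index:
        sp = by_parent.get(out.at[i, seq_col])
        if sp is None:
            continue
        s, e, cut = int(out.at[i, "start"]), int(out.at[i, "end"]), sp.cut_pos
        if e <= cut:
            out.at[i, seq_col] = sp.children[0]
        elif s > cut:
            out.at[i, seq_col] = sp.children[1]
            out.at[i, "start"], out.at[i, "end"] = s - cut, e - cut
        elif cut - s >= e - cut:  # straddles: keep the larger side
            out.at[i, seq_col] = sp.children[0]
            out.at[i, "end"] = cut
        else:
            out.at[i, seq_col] = sp.children[1]
            out.at[i, "start"], out.at[i, "end"] = 1, e - cut
    return out


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run the full synthetic analysis; returns the in-memory results and
    leaves all artifacts plus ``manifest.json`` in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.sim.seed = int(seed)
    cfg = config
    log: list[str] = []
    res: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
                log.append(f"stage {name}: ok")
            except Exception as exc:  # noqa: BLE001 - halting with stage name
                log.append(f"stage {name}: FAILED ({exc})")
                (outdir / "log.txt").write_text("\n".join(log) + "\n")
                raise StageError(name, exc) from exc
        return deco

    @stage("simulate")
    def _simulate():
        res.update(write_fixture_set(outdir, cfg.sim))
        log.append(
            f"  genome: {len(res['genome'].chromosomes)} chromosomes, "
            f"{res['genome'].total_length} bp; "
            f"{len(res['scaffolds'])} scaffolds"
        )

    @stage("select")
    def _select():
        panel = select_panel(
            res["scaffolds"], res["variants"],
            panel_size=cfg.sim.n_markers, ladder=cfg.quality_ladder,
            n_per_end=cfg.sim.n_per_end, end_window_frac=cfg.end_window_frac,
            end_window_cap=cfg.end_window_cap, flank_bp=cfg.flank_bp,
        )
        res["panel"] = panel
        afio.write_tsv(outdir / "selection.tsv", panel)
        log.append(f"  panel: {len(panel)} markers on "
                   f"{panel['scaffold'].nunique()} scaffolds")

    @stage("genotype")
    def _genotype():
        enriched = marker_truth(res["panel"], res["truth"], res["genome"])
        res["panel_truth"] = enriched
        data = simulate_f2(res["genome"], enriched, cfg.sim)
        res["genotypes_raw"] = data
        data.to_tsv(outdir / "genotypes.tsv")
        log.append(f"  genotypes: {data.n_markers} x {data.n_individuals}")

    @stage("qc")
    def _qc():
        data = res["genotypes_raw"]
        if cfg.qc_enabled:
            data = filter_individuals(data, cfg.min_call_rate)
            data = filter_markers(data, cfg.min_q1, cfg.min_q2)
            report = segregation_report(data, cfg.alpha_extreme, cfg.alpha_flag)
            data = drop_extreme_distortion(data, report)
            afio.write_tsv(outdir / "qc_report.tsv",
                           report.reset_index(names="marker"))
            log.append(
                f"  qc: {data.n_markers} markers, {data.n_individuals} "
                f"individuals kept; "
                f"{int((report['status'] == 'flagged_distorted').sum())} "
                f"markers flagged distorted"
            )
        else:
            log.append("  qc: disabled; map stage consumes the raw matrix")
        res["genotypes"] = data

    @stage("map")
    def _map():
        map_df = build_map(res["genotypes"], cfg.lod_threshold,
                           cfg.map_function,
                           prune_max_missing=cfg.max_group_missing)
        res["map"] = map_df
        afio.write_tsv(outdir / "map.tsv", map_df)
        log.append(f"  map: {map_df['group'].nunique()} linkage groups, "
                   f"{len(map_df)} markers")

    @stage("anchor")
    def _anchor():
        placements = res["map"].merge(
            res["panel"][["marker", "scaffold", "pos"]], on="marker")
        assignments, candidates, dropped = assign_scaffolds(
            placements, res["scaffolds"], genotypes=res["genotypes"])
        splits = resolve_chimeras(candidates, res["scaffolds"])
        corrected, version = apply_splits_to_assembly(
            res["scaffolds"], splits, version="v1")
        panel2 = _remap_markers(res["panel"], splits)
        placements2 = res["map"].merge(
            panel2[["marker", "scaffold", "pos"]], on="marker")
        final, cands2, dropped2 = assign_scaffolds(
            placements2, corrected, genotypes=res["genotypes"])
        res.update({"assignments": final, "splits": splits,
                    "scaffolds_corrected": corrected, "panel_final": panel2,
                    "assembly_version": version,
                    "dropped_markers": sorted(set(dropped) | set(dropped2))})
        afio.write_tsv(outdir / "anchoring.tsv", final)
        chim = pd.DataFrame(
            [{"parent": sp.parent, "cut_pos": sp.cut_pos,
              "child1": sp.children[0], "child2": sp.children[1],
              "group1": sp.child_groups.get(sp.children[0]),
              "group2": sp.child_groups.get(sp.children[1]),
              "cut_in_gap": sp.in_gap} for sp in splits])
        afio.write_tsv(outdir / "chimeras.tsv", chim)
        log.append(f"  anchor: {int((final['status'] != 'unanchored').sum())} "
                   f"scaffolds anchored, {len(splits)} chimeras split, "
                   f"assembly {version}")

    @stage("build-pm")
    def _build():
        ordered = order_assignments(res["assignments"], res["scaffolds_corrected"])
        placements, agp_rows, seqs = build_pms(
            ordered, res["scaffolds_corrected"], spacer=cfg.spacer)
        res["pm_placements"] = placements
        res["pm_lengths"] = {
            pm: max(r["object_end"] for r in agp_rows if r["object"] == pm)
            for pm in {r["object"] for r in agp_rows}
        }
        afio.write_agp(outdir / "pm.agp", agp_rows)
        if all(s is not None for s in seqs.values()):
            afio.write_fasta(outdir / "pm.fasta", sorted(seqs.items()))
        gff = _remap_features(res["gff"], res["splits"])
        lifted = lift_features(gff, placements)
        res["gff_pm"] = lifted
        afio.write_gff3(outdir / "genes_pm.gff3", lifted)
        hits = res["repeat_hits"].rename(columns={"scaffold": "seqid"})
        hits["strand"] = "."
        hits = _remap_features(hits, res["splits"])
        lifted_hits = lift_features(hits, placements).rename(
            columns={"seqid": "pm"})
        res["repeat_hits_pm"] = lifted_hits
        afio.write_tsv(outdir / "repeat_hits_pm.tsv", lifted_hits)
        log.append(f"  build-pm: {len(res['pm_lengths'])} pseudomolecules, "
                   f"{sum(res['pm_lengths'].values())} bp")

    @stage("recomb")
    def _recomb():
        profiles, gwrr, per_pm = landscape(
            res["map"], res["pm_placements"],
            res["panel_final"], res["pm_lengths"],
            window_mb=cfg.window_mb, step_mb=cfg.step_mb,
            rate_threshold=cfg.suppress_threshold,
            min_span_mb=cfg.min_zone_span_mb,
        )
        res.update({"profiles": profiles, "gwrr": gwrr, "per_pm_rates": per_pm})
        rows = [
            {"pm": p.pm, "center_mb": round(float(c), 3),
             "rate_cm_per_mb": round(float(r), 4)}
            for p in profiles.values()
            for c, r in zip(p.centers_mb, p.rates)
        ]
        afio.write_tsv(outdir / "recomb_profile.tsv", pd.DataFrame(rows))
        zones = pd.DataFrame(
            [{"seqid": p.pm, "start": s, "end": e, "name": "suppression"}
             for p in profiles.values() for s, e in p.zones])
        afio.write_bed(outdir / "suppression_zones.bed",
                       zones if len(zones) else
                       pd.DataFrame(columns=["seqid", "start", "end", "name"]))
        log.append(f"  recomb: GWRR {gwrr:.2f} cM/Mb, "
                   f"{sum(len(p.zones) for p in profiles.values())} "
                   f"suppression zones")

    @stage("centromeres")
    def _cent():
        hits = filter_hits(res["repeat_hits_pm"], cfg.min_coverage,
                           cfg.min_identity)
        calls = call_centromeres(hits, cfg.cluster_gap, cfg.require_psat107)
        rdna = annotate_rdna(res["gff_pm"], cfg.rdna_merge_gap)
        zones_by_pm = {p.pm: p.zones for p in res["profiles"].values()}
        report = overlap_report(calls, rdna, zones_by_pm)
        res.update({"centromere_calls": calls, "rdna": rdna,
                    "overlaps": report})
        afio.write_bed(outdir / "centromere_calls.bed", pd.DataFrame(
            [{"seqid": c.pm, "start": c.start, "end": c.end,
              "name": ",".join(c.families)} for c in calls]
            if calls else [], columns=["seqid", "start", "end", "name"]))
        afio.write_tsv(outdir / "rdna.tsv", rdna)
        afio.write_tsv(outdir / "overlap_report.tsv", report)
        log.append(f"  centromeres: {len(calls)} calls, "
                   f"{len(rdna)} rDNA loci")

    @stage("report")
    def _report():
        lengths = {sc.id: sc.length for sc in res["scaffolds_corrected"]}
        summary = summarize_anchoring(res["assignments"], res["map"], lengths)
        res["summary"] = summary
        afio.write_tsv(outdir / "summary.tsv", summary)
        validation = summarize_validation(
            designed=len(res["panel"]),
            successful=res["genotypes"].n_markers,
        )
        res["validation"] = validation
        with open(outdir / "validation.json", "w") as fh:
            json.dump(validation, fh, indent=1, sort_keys=True)
        log.append(f"  report: {len(summary) - 1} linkage groups summarized")

    (outdir / "log.txt").write_text("\n".join(log) + "\n")

    files = sorted(p.name for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": cfg.sim.seed,
        "config_digest": cfg.digest(),
        "files": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
        "stats": {
            "n_scaffolds": len(res["scaffolds"]),
            "n_markers_panel": len(res["panel"]),
            "n_markers_mapped": int(len(res["map"])),
            "n_linkage_groups": int(res["map"]["group"].nunique()),
            "n_chimeras_split": len(res["splits"]),
            "gwrr_cm_per_mb": round(float(res["gwrr"]), 4),
            "assembly_version": res["assembly_version"],
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    res["manifest"] = manifest
    return res
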