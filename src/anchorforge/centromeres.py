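"""In-silico centromere demarcation and rDNA annotation.

Putative centromeres are called where alignments of two or more distinct
centromeric satellite families (pSat107 and the CentSp A/B/C families)
co-localize, after filtering hits on alignment coverage and identity
(>= 80% each by default). Hits on one pseudomolecule are clustered by
single linkage with a maximum gap; a cluster becomes a call only with >= 2
distinct families (optionally requiring pSat107 specifically). 45S rDNA
(NOR) intervals are assembled by merging nearby 18S/5.8S/26S rRNA
annotations; 5S arrays merge separately. An overlap report relates calls
and rDNA intervals to recombination-suppression zones.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CENTROMERIC = ("pSat107", "CentSpA", "CentSpB", "CentSpC")
RDNA_45S_UNITS = ("18S", "5.8S", "26S")


def filter_hits(
    hits: pd.DataFrame, min_coverage: float = 0.80, min_identity: float = 0.80
) -> pd.DataFrame:
    """Keep hits with coverage >= min_coverage and identity >= min_identity
    (inclusive bounds)."""
    keep = (hits["coverage"] >= min_coverage) & (hits["identity"] >= min_identity)
    return hits[keep]


@dataclass
class CentromereCall:
    pm: str
    start: int
    end: int
    families: tuple[str, ...]
    n_hits: int


def call_centromeres(
    hits: pd.DataFrame,
    cluster_gap: int = 500_000,
    require_psat107: bool = False,
    seq_col: str = "pm",
) -> list[CentromereCall]:
    """Cluster filtered centromeric-satellite hits and emit co-localization
    calls. Only centromeric families participate; a cluster is reported iff
    it contains >= 2 distinct families (and pSat107 among them when
    ``require_psat107``). The call interval spans all supporting hits.
    Output is independent of input row order."""
    cen = hits[hits["family"].isin(CENTROMERIC)]
    calls: list[CentromereCall] = []
    for pm_id, grp in cen.groupby(seq_col, sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        cluster: list = []
        cur_end = None
        for h in grp.itertuples():
            if cur_end is not None and h.start - cur_end > cluster_gap:
                calls.extend(_emit(pm_id, cluster, require_psat107))
                cluster = []
            cluster.append(h)
            cur_end = max(cur_end, h.end) if cur_end is not None else h.end
        calls.extend(_emit(pm_id, cluster, require_psat107))
    return calls


def _emit(pm_id, cluster, require_psat107):
    if not cluster:
        return []
    families = tuple(sorted({h.family for h in cluster}))
    if len(families) < 2:
        return []
    if require_psat107 and "pSat107" not in families:
        return []
    return [CentromereCall(pm_id, min(h.start for h in cluster),
                           max(h.end for h in cluster), families, len(cluster))]


def annotate_rdna(features: pd.DataFrame, merge_gap: int = 100_000) -> pd.DataFrame:
    """Merge rRNA gene annotations into rDNA locus intervals.

    18S/5.8S/26S features within ``merge_gap`` of each other merge into 45S
    (NOR) intervals; 5S features merge separately. ``features`` must carry
    seqid, type, start, end, name; returns (seqid, start, end, kind, units).
    """
    rrna = features[features["type"] == "rRNA"]
    if rrna.empty:
        import warnings

        warnings.warn("no rRNA features found; rDNA annotation is empty")
        return pd.DataFrame(columns=["seqid", "start", "end", "kind", "units"])
    rows = []
    for kind in ("45S", "5S"):
        if kind == "45S":
            sub = rrna[rrna["name"].str.contains("|".join(
                u.replace(".", r"\.") for u in RDNA_45S_UNITS))]
        else:
            sub = rrna[rrna["name"].str.startswith("5S")]
        for seqid, grp in sub.groupby("seqid", sort=True):
            grp = grp.sort_values("start", kind="mergesort")
            cur = None
            for ft in grp.itertuples():
                unit = ft.name.split("_")[0]
                if cur is not None and ft.start - cur["end"] <= merge_gap:
                    cur["end"] = max(cur["end"], ft.end)
                    cur["units"].add(unit)
                else:
                    if cur is not None:
                        rows.append(cur)
                    cur = {"seqid": seqid, "start": int(ft.start),
                           "end": int(ft.end), "kind": kind, "units": {unit}}
            if cur is not None:
                rows.append(cur)
    out = pd.DataFrame(rows)
    out["units"] = out["units"].map(lambda s: ",".join(sorted(s)))
    return out.sort_values(["seqid", "start"], kind="mergesort").reset_index(drop=True)


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def overlap_report(
    calls: list[CentromereCall],
    rdna: pd.DataFrame,
    zones_by_pm: dict[str, list[tuple[int, int]]],
) -> pd.DataFrame:
    """Per feature (centromere call or rDNA interval): the best-overlapping
    suppression zone with bp overlap and Jaccard index."""
    rows = []
    feats = [("centromere", c.pm, c.start, c.end, ",".join(c.families))
             for c in calls]
    for r in rdna.itertuples():
        feats.append((f"rDNA_{r.kind}", r.seqid, int(r.start), int(r.end), r.units))
    for kind, pm_id, start, end, detail in feats:
        best = (0, None)
        for zs, ze in zones_by_pm.get(pm_id, []):
            ov = _overlap(start, end, zs, ze)
            if ov > best[0]:
                best = (ov, (zs, ze))
        ov, zone = best
        union = (end - start + 1)
        if zone:
            union = max(end, zone[1]) - min(start, zone[0]) + 1
        rows.append({"kind": kind, "pm": pm_id, "start": start, "end": end,
                     "detail": detail,
                     "zone_start": zone[0] if zone else 0,
                     "zone_end": zone[1] if zone else 0,
                     "overlap_bp": ov,
                     "jaccard": round(ov / union, 4) if zone else 0.0})
    return pd.DataFrame(rows)
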