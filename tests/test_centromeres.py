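import numpy as np
import pandas as pd
import pytest

from anchorforge.centromeres import (annotate_rdna, call_centromeres,
                                     filter_hits, overlap_report)


def hits(rows):
    return pd.DataFrame(rows, columns=["pm", "start", "end", "family",
                                       "identity", "coverage"])


class TestFilter:
    def test_inclusive_boundaries(self):
        h = hits([("PM01", 1, 100, "pSat107", 0.80, 0.80),
                  ("PM01", 200, 300, "pSat107", 0.99, 0.79),
                  ("PM01", 400, 500, "pSat107", 0.79, 0.99)])
        kept = filter_hits(h)
        assert list(kept["start"]) == [1]

    def test_zero_thresholds_identity(self):
        h = hits([("PM01", 1, 100, "CentSpA", 0.1, 0.1)])
        assert len(filter_hits(h, 0.0, 0.0)) == 1

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(4)
        h = hits([("PM01", k, k + 10, "pSat107",
                   round(float(rng.uniform(0.5, 1)), 3),
                   round(float(rng.uniform(0.5, 1)), 3))
                  for k in range(0, 1000, 10)])
        for lo, hi in [(0.6, 0.7), (0.7, 0.8), (0.8, 0.9)]:
            a = set(filter_hits(h, lo, lo).index)
            b = set(filter_hits(h, hi, hi).index)
            assert b <= a


class TestCalls:
    def test_two_families_within_gap_one_call(self):
        h = hits([("PM01", 1_000_000, 1_010_000, "pSat107", 0.9, 0.9),
                  ("PM01", 1_200_000, 1_210_000, "CentSpB", 0.9, 0.9)])
        calls = call_centromeres(h, cluster_gap=500_000)
        assert len(calls) == 1
        c = calls[0]
        assert c.families == ("CentSpB", "pSat107")
        assert (c.start, c.end) == (1_000_000, 1_210_000)

    def test_single_family_requires_flag_modes(self):
        h = hits([("PM01", 1_000_000, 1_010_000, "CentSpA", 0.9, 0.9),
                  ("PM01", 1_100_000, 1_110_000, "CentSpA", 0.9, 0.9)])
        assert call_centromeres(h) == []
        h2 = hits([("PM01", 1_000_000, 1_010_000, "CentSpA", 0.9, 0.9),
                   ("PM01", 1_100_000, 1_110_000, "CentSpB", 0.9, 0.9)])
        assert len(call_centromeres(h2, require_psat107=False)) == 1
        assert call_centromeres(h2, require_psat107=True) == []

    def test_distant_single_family_clusters_no_calls(self):
        h = hits([("PM01", 1_000_000, 1_010_000, "pSat107", 0.9, 0.9),
                  ("PM01", 6_000_000, 6_010_000, "pSat107", 0.9, 0.9)])
        assert call_centromeres(h) == []

    def test_calls_invariant_to_input_order(self):
        rng = np.random.default_rng(9)
        rows = [("PM01", int(p), int(p) + 5_000,
                 ["pSat107", "CentSpA", "CentSpC"][k % 3], 0.9, 0.9)
                for k, p in enumerate(range(2_000_000, 2_800_000, 100_000))]
        h = hits(rows)
        shuffled = h.sample(frac=1, random_state=1).reset_index(drop=True)
        a = call_centromeres(h)
        b = call_centromeres(shuffled)
        assert [(c.pm, c.start, c.end, c.families) for c in a] == \
            [(c.pm, c.start, c.end, c.families) for c in b]

    def test_rdna_families_do_not_contribute(self):
        h = hits([("PM01", 1_000_000, 1_010_000, "pSat107", 0.9, 0.9),
                  ("PM01", 1_100_000, 1_110_000, "rDNA_5S", 0.9, 0.9)])
        assert call_centromeres(h) == []


class TestRdna:
    def features(self, rows):
        return pd.DataFrame(rows, columns=["seqid", "type", "start", "end",
                                           "strand", "attr_id", "name"])

    def test_45s_components_merge(self):
        f = self.features([
            ("PM01", "rRNA", 1_000_000, 1_010_000, "+", "r1", "18S_rRNA"),
            ("PM01", "rRNA", 1_011_000, 1_014_000, "+", "r2", "5.8S_rRNA"),
            ("PM01", "rRNA", 1_015_000, 1_030_000, "+", "r3", "26S_rRNA"),
        ])
        rdna = annotate_rdna(f)
        assert len(rdna) == 1
        row = rdna.iloc[0]
        assert row["kind"] == "45S"
        assert (row["start"], row["end"]) == (1_000_000, 1_030_000)
        assert row["units"] == "18S,26S,5.8S"

    def test_lone_5s_interval(self):
        f = self.features([
            ("PM02", "rRNA", 500_000, 530_000, "+", "r1", "5S_rRNA")])
        rdna = annotate_rdna(f)
        assert list(rdna["kind"]) == ["5S"]

    def test_no_rrna_warns_empty(self):
        f = self.features([("PM01", "gene", 1, 10, "+", "g", "g")])
        with pytest.warns(UserWarning):
            rdna = annotate_rdna(f)
        assert rdna.empty

    def test_pipeline_recovers_true_rdna_arrays(self, default_run):
        truth_rdna = []
        for c in default_run["genome"].chromosomes:
            for s, e, kind in c.rdna:
                truth_rdna.append((c.id, kind))
        n_45s = sum(1 for _c, k in truth_rdna if k in ("18S", "5.8S", "26S"))
        called = default_run["rdna"]
        assert (called["kind"] == "45S").sum() == n_45s // 3
        assert (called["kind"] == "5S").sum() == \
            sum(1 for _c, k in truth_rdna if k == "5S")


class TestOverlap:
    def test_call_inside_zone_full_overlap(self):
        from anchorforge.centromeres import CentromereCall
        calls = [CentromereCall("PM01", 2_000_000, 2_500_000,
                                ("CentSpA", "pSat107"), 4)]
        zones = {"PM01": [(1_500_000, 3_000_000)]}
        rep = overlap_report(calls, pd.DataFrame(
            columns=["seqid", "start", "end", "kind", "units"]), zones)
        assert rep.iloc[0]["overlap_bp"] == 500_001

    def test_disjoint_zero_overlap(self):
        from anchorforge.centromeres import CentromereCall
        calls = [CentromereCall("PM01", 2_000_000, 2_500_000,
                                ("CentSpA", "pSat107"), 4)]
        zones = {"PM01": [(5_000_000, 8_000_000)]}
        rep = overlap_report(calls, pd.DataFrame(
            columns=["seqid", "start", "end", "kind", "units"]), zones)
        assert rep.iloc[0]["overlap_bp"] == 0

    def test_every_pipeline_call_overlaps_a_zone(self, default_run):
        rep = default_run["overlaps"]
        cen = rep[rep["kind"] == "centromere"]
        assert len(cen) >= 12
        assert (cen["overlap_bp"] > 0).all()

    def test_pipeline_calls_contain_true_midpoint(self, default_run):
        from anchorforge.evaluation import true_interval_on_pm
        per_pm: dict[str, list] = {}
        for c in default_run["centromere_calls"]:
            per_pm.setdefault(c.pm, []).append(c)
        for gi, chrom in default_run["group_to_chrom"].items():
            pm = f"PM{gi:02d}"
            c = default_run["genome"].chrom(chrom)
            mid = (c.centromere[0] + c.centromere[1]) // 2
            mv = true_interval_on_pm(
                default_run["truth"], default_run["pm_placements"], chrom,
                mid, mid, splits=default_run["splits"])
            assert any(cc.start <= mv[1] <= cc.end
                       for cc in per_pm.get(pm, [])), pm
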