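import json

import numpy as np
import pandas as pd
import pytest

from anchorforge import io as afio
from anchorforge import simulate as sim
from anchorforge.config import ConfigurationError, DistortionLocus, SimConfig
from anchorforge.genotype_qc import MISSING

from conftest import small_sim_config


class TestGenome:
    def test_flat_marey_curve_is_linear(self):
        cfg = small_sim_config(n_chrom=1, chimera_count=0, flat_slope=3.0,
                               distortion_loci=[])
        genome = sim.simulate_genome(cfg)
        c = genome.chromosomes[0]
        assert c.map_length_cm == pytest.approx(3.0 * c.length / 1e6)
        mid = c.length / 2
        assert c.cm_at(mid) == pytest.approx(3.0 * mid / 1e6)

    def test_centromere_has_at_least_two_repeat_families(self):
        genome = sim.simulate_genome(SimConfig(seed=5))
        for c in genome.chromosomes:
            arrays = genome.repeat_arrays
            inside = arrays[
                (arrays["chrom"] == c.id)
                & (arrays["start"] >= c.centromere[0])
                & (arrays["end"] <= c.centromere[1])
                & (arrays["family"].isin(sim.CENTROMERIC_FAMILIES))
            ]
            assert inside["family"].nunique() >= 2

    def test_marey_curve_monotone_and_suppressed_in_centromere(self):
        genome = sim.simulate_genome(small_sim_config())
        for c in genome.chromosomes:
            assert np.all(np.diff(c.marey_y) >= 0)
            assert c.cm_at(0) == 0.0
            cs, ce = c.centromere
            plateau_rate = (c.cm_at(ce) - c.cm_at(cs)) / ((ce - cs) / 1e6)
            arm_rate = c.cm_at(cs) / (cs / 1e6)
            assert plateau_rate < 0.2 < arm_rate

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.simulate_genome(small_sim_config(missing_rate=1.5))
        with pytest.raises(ConfigurationError):
            sim.simulate_genome(small_sim_config(
                distortion_loci=[DistortionLocus(0, 0.5, -1, 1, 1)]))


class TestFragmentation:
    def test_scaffolds_tile_chromosomes(self, small_world):
        genome, truth = small_world["genome"], small_world["truth"]
        scaffolds = small_world["scaffolds"]
        junction_bases = sum(
            1000 for _ in range(len(truth.chimeras)))
        assert sum(s.length for s in scaffolds) == \
            genome.total_length + junction_bases
        # fragments tile each chromosome without overlap
        for cid, grp in truth.fragments.groupby("chrom"):
            grp = grp.sort_values("chrom_start")
            assert grp["chrom_start"].iloc[0] == 1
            ends = grp["chrom_end"].to_numpy()
            starts = grp["chrom_start"].to_numpy()
            assert np.all(starts[1:] == ends[:-1] + 1)
            assert ends[-1] == small_world["genome"].chrom(cid).length

    def test_chimeras_join_two_chromosomes_across_n_gap(self, small_world):
        truth = small_world["truth"]
        by_id = {s.id: s for s in small_world["scaffolds"]}
        assert len(truth.chimeras) == 1
        for ch in truth.chimeras.itertuples():
            frs = truth.fragments[truth.fragments["scaffold"] == ch.scaffold]
            assert frs["chrom"].nunique() == 2
            sc = by_id[ch.scaffold]
            assert (ch.junction_start, ch.junction_end) in sc.gaps

    def test_chimera_count_exceeding_scaffolds_rejected(self):
        cfg = small_sim_config(chimera_count=10_000)
        genome = sim.simulate_genome(cfg)
        with pytest.raises(ConfigurationError):
            sim.fragment_into_scaffolds(genome, cfg)


class TestF2:
    def test_recombinant_fraction_matches_haldane_closed_form(self):
        # two markers 10 cM apart: expected F2 *genotype-pair* checks are
        # complex, so check the gamete-level recombinant fraction through a
        # large simulated population against r = (1 - e^{-2d/100}) / 2
        cfg = small_sim_config(n_chrom=1, chimera_count=0, flat_slope=2.0,
                               distortion_loci=[], missing_rate=0.0,
                               error_rate=0.0, n_individuals=2000)
        genome = sim.simulate_genome(cfg)
        c = genome.chromosomes[0]
        d_cm = 10.0
        markers = pd.DataFrame({
            "marker": ["m1", "m2"],
            "scaffold": ["x", "x"],
            "pos": [1, 2],
            "chrom": [c.id, c.id],
            "chrom_pos": [1_000_000,
                          int(1_000_000 + d_cm / 2.0 * 1e6)],
        })
        data = sim.simulate_f2(genome, markers, cfg)
        calls = data.calls.to_numpy()
        # homozygote pairs reveal both gametes unambiguously
        both_hom = np.isin(calls[0], [0, 2]) & np.isin(calls[1], [0, 2])
        rec = (calls[0] != calls[1]) & both_hom
        r_true = 0.5 * (1 - np.exp(-2 * d_cm / 100))
        # P(homozygote pair recombinant at both gametes) = r^2/ P(both hom)
        # simpler: estimate r from opposite-homozygote frequency r^2/4 and
        # same-homozygote frequency (1-r)^2/4
        n_same = int((both_hom & ~rec).sum())
        n_opp = int((both_hom & rec).sum())
        r_hat = 1.0 / (1.0 + np.sqrt(n_same / max(n_opp, 1)))
        sd = 3 * np.sqrt(r_true * (1 - r_true) / both_hom.sum())
        assert abs(r_hat - r_true) < 3 * sd + 0.01

    def test_lethal_genotype_class_absent(self):
        cfg = small_sim_config(
            n_chrom=1, chimera_count=0, missing_rate=0.0, error_rate=0.0,
            distortion_loci=[DistortionLocus(0, 0.5, 0.0, 1.0, 1.0)])
        genome = sim.simulate_genome(cfg)
        c = genome.chromosomes[0]
        locus_pos = int(0.5 * c.length)
        markers = pd.DataFrame({
            "marker": ["at_locus"], "scaffold": ["x"], "pos": [1],
            "chrom": [c.id], "chrom_pos": [locus_pos]})
        data = sim.simulate_f2(genome, markers, cfg)
        assert (data.calls.to_numpy() == 0).sum() == 0

    def test_clean_simulation_has_no_missing_calls(self):
        cfg = small_sim_config(missing_rate=0.0, error_rate=0.0,
                               n_individuals=30)
        genome = sim.simulate_genome(cfg)
        scaffolds, truth = sim.fragment_into_scaffolds(genome, cfg)
        variants = sim.generate_variants(scaffolds, cfg)
        from anchorforge.snp_selection import select_panel
        panel = select_panel(scaffolds, variants, panel_size=60)
        mt = sim.marker_truth(panel, truth, genome)
        data = sim.simulate_f2(genome, mt, cfg)
        assert (data.calls.to_numpy() == MISSING).sum() == 0

    def test_marker_off_chromosome_rejected(self, small_world):
        genome = small_world["genome"]
        markers = pd.DataFrame({
            "marker": ["bad"], "scaffold": ["x"], "pos": [1],
            "chrom": [genome.chromosomes[0].id],
            "chrom_pos": [genome.chromosomes[0].length + 5]})
        with pytest.raises(ValueError, match="off chromosome"):
            sim.simulate_f2(genome, markers, small_world["config"])


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    cfg = small_sim_config(seed=3)
    res = sim.write_fixture_set(out, cfg)
    return out, res


class TestFixtureSet:

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_sim_config(seed=3)
        sim.write_fixture_set(tmp_path / "a", cfg)
        sim.write_fixture_set(tmp_path / "b", cfg)
        for name in ("scaffolds.fasta", "variants.tsv", "genes.gff3",
                     "repeat_hits.tsv", "truth.agp", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_variant_table_round_trip(self, fixture_dir):
        out, res = fixture_dir
        back = afio.read_tsv(out / "variants.tsv")
        pd.testing.assert_frame_equal(back, res["variants"])

    def test_truth_agp_spans_sum_to_chromosome_lengths(self, fixture_dir):
        out, res = fixture_dir
        agp = afio.read_agp(out / "truth.agp")
        spans = agp.groupby("object").apply(
            lambda g: int((g["object_end"] - g["object_beg"] + 1).sum()),
            include_groups=False)
        for c in res["genome"].chromosomes:
            assert spans[c.id] == c.length

    def test_fasta_lengths_match_truth(self, fixture_dir):
        out, res = fixture_dir
        seqs = afio.read_fasta(out / "scaffolds.fasta")
        for sc in res["scaffolds"]:
            assert len(seqs[sc.id]) == sc.length
            for s, e in sc.gaps:
                assert set(seqs[sc.id][s - 1:e]) == {"N"}
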