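import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorforge.linkage import (build_groups, build_map, compute_positions,
                                 estimate_two_point, grid_two_point,
                                 haldane_d, haldane_r, kosambi_d, kosambi_r,
                                 order_group, pairwise_two_point)
from anchorforge.genotype_qc import GenotypeData

from conftest import simulate_f2_pair


class TestMapFunctions:
    def test_haldane_value(self):
        assert haldane_d(0.2) == pytest.approx(25.541281, abs=1e-5)

    def test_kosambi_value(self):
        assert kosambi_d(0.2) == pytest.approx(21.182447, abs=1e-5)

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_haldane_round_trip(self, r):
        assert float(haldane_r(haldane_d(r))) == pytest.approx(r, abs=1e-10)

    @given(st.floats(0.0, 0.49))
    @settings(max_examples=50, deadline=None)
    def test_kosambi_round_trip(self, r):
        assert float(kosambi_r(kosambi_d(r))) == pytest.approx(r, abs=1e-10)


class TestTwoPoint:
    def test_perfect_cosegregation(self):
        calls = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), 25)
        est = estimate_two_point(calls, calls)
        assert est.r_hat == 0.0
        assert est.lod > 10

    def test_unlinked_markers_low_lod(self):
        rng = np.random.default_rng(3)
        n_low = 0
        for _ in range(200):
            a = rng.choice([0, 1, 1, 2], size=139).astype(np.int8)
            b = rng.choice([0, 1, 1, 2], size=139).astype(np.int8)
            est = estimate_two_point(a, b)
            n_low += est.lod < 3
        assert n_low >= 198
        assert est.r_hat > 0.3  # last draw: far from tight linkage

    def test_linked_pair_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        a, b = simulate_f2_pair(0.1, 139, rng)
        est = estimate_two_point(a, b)
        oracle = grid_two_point(a, b)
        assert abs(est.r_hat - 0.1) < 0.05
        assert abs(est.r_hat - oracle) <= 0.001

    def test_few_informative_pairs_flagged(self):
        a = np.array([0, 1, 2, -1, -1, -1, -1, -1, -1, -1], dtype=np.int8)
        est = estimate_two_point(a, a)
        assert not est.reliable

    def test_pairwise_matches_scalar(self, small_world):
        data = small_world["genotypes"]
        sub = data.subset_markers(data.calls.index[:12])
        rf, lod, n = pairwise_two_point(sub)
        for i in (0, 3, 7):
            for j in (1, 5, 11):
                est = estimate_two_point(sub.calls.iloc[i].to_numpy(),
                                         sub.calls.iloc[j].to_numpy())
                assert rf.iloc[i, j] == pytest.approx(est.r_hat, abs=1e-6)
                assert lod.iloc[i, j] == pytest.approx(est.lod, abs=1e-6)
        assert np.allclose(rf.to_numpy(), rf.to_numpy().T)


class TestGrouping:
    def test_two_chromosomes_two_groups(self, small_world):
        data = small_world["genotypes"]
        mt = small_world["marker_truth"].set_index("marker")
        two = mt[mt["chrom"].isin(["chr01", "chr02"])].index[:60]
        _, lod, _ = pairwise_two_point(data.subset_markers(two))
        groups = build_groups(lod, 10.0)
        assert len(groups) == 2
        for g in groups:
            assert mt.loc[g, "chrom"].nunique() == 1

    def test_infinite_threshold_singletons(self, small_world):
        data = small_world["genotypes"]
        sub = data.subset_markers(data.calls.index[:8])
        _, lod, _ = pairwise_two_point(sub)
        assert len(build_groups(lod, np.inf)) == 8

    def test_single_marker_singleton_group(self):
        lod = pd.DataFrame([[0.0]], index=["m"], columns=["m"])
        assert build_groups(lod, 10.0) == [["m"]]


def rf_frame(names, d):
    return pd.DataFrame(d, index=names, columns=names, dtype=float)


class TestOrdering:
    def test_metric_chain(self):
        names = ["A", "B", "C"]
        rf = rf_frame(names, [[0, 0.05, 0.10],
                              [0.05, 0, 0.05],
                              [0.10, 0.05, 0]])
        order = order_group(names, rf)
        assert order in (["A", "B", "C"], ["C", "B", "A"])

    def test_two_marker_group_stable(self):
        names = ["z", "a"]
        rf = rf_frame(names, [[0, 0.2], [0.2, 0]])
        assert order_group(names, rf) == ["a", "z"]

    def test_sarf_never_worse_than_input_order(self):
        rng = np.random.default_rng(5)
        k = 15
        pos = np.sort(rng.uniform(0, 100, k))
        d = haldane_r(np.abs(pos[:, None] - pos[None, :]))
        noise = rng.normal(0, 0.02, (k, k))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        rf = np.clip(d + noise, 0, 0.4999)
        names = [f"m{j}" for j in rng.permutation(k)]
        frame = rf_frame(sorted(names), np.zeros((k, k)))
        for ii, a in enumerate(sorted(names)):
            for jj, b in enumerate(sorted(names)):
                frame.loc[a, b] = rf[ii, jj]
        order = order_group(sorted(names), frame)
        sarf = sum(frame.loc[a, b] for a, b in zip(order, order[1:]))
        sarf_input = sum(frame.loc[a, b]
                         for a, b in zip(sorted(names), sorted(names)[1:]))
        assert sarf <= sarf_input + 1e-12

    def test_simulated_chromosome_order_recovery(self):
        rng = np.random.default_rng(11)
        k, n = 20, 139
        true_pos = np.sort(rng.uniform(0, 80, k))
        # simulate gametes along one chromosome (Haldane)
        gametes = []
        for _ in range(2 * n):
            ncx = rng.poisson(0.8)
            cx = np.sort(rng.uniform(0, 80, ncx))
            start = rng.integers(2)
            gametes.append((start + np.searchsorted(cx, true_pos)) % 2)
        gametes = np.array(gametes)
        calls = (gametes[::2] + gametes[1::2]).T.astype(np.int8)
        names = [f"m{j:02d}" for j in range(k)]
        data = GenotypeData(pd.DataFrame(
            calls, index=names, columns=[f"i{j}" for j in range(n)]))
        rf, _, _ = pairwise_two_point(data)
        order = order_group(names, rf)
        from scipy.stats import kendalltau
        tau = kendalltau([names.index(m) for m in order],
                         range(k)).statistic
        assert abs(tau) >= 0.9


class TestPositions:
    def test_haldane_distance(self):
        rf = rf_frame(["a", "b"], [[0, 0.2], [0.2, 0]])
        pos = compute_positions(["a", "b"], rf)
        assert pos["cm"].tolist() == [0.0, pytest.approx(25.541281, abs=1e-4)]

    def test_kosambi_distance(self):
        rf = rf_frame(["a", "b"], [[0, 0.2], [0.2, 0]])
        pos = compute_positions(["a", "b"], rf, map_function="kosambi")
        assert pos["cm"].iloc[1] == pytest.approx(21.182447, abs=1e-4)

    def test_zero_recombination_zero_distance(self):
        rf = rf_frame(["a", "b"], [[0, 0.0], [0.0, 0]])
        assert compute_positions(["a", "b"], rf)["cm"].tolist() == [0.0, 0.0]

    def test_unlinked_adjacent_capped_with_warning(self):
        rf = rf_frame(["a", "b"], [[0, 0.5], [0.5, 0]])
        with pytest.warns(UserWarning, match="capped"):
            pos = compute_positions(["a", "b"], rf, max_gap_cm=50.0)
        assert pos["cm"].iloc[1] == 50.0


class TestBuildMap:
    def test_full_map_recovers_groups_and_positions(self, small_world):
        from anchorforge.genotype_qc import (drop_extreme_distortion,
                                             filter_individuals,
                                             filter_markers,
                                             segregation_report)
        data = filter_markers(filter_individuals(small_world["genotypes"]))
        rep = segregation_report(data)
        data = drop_extreme_distortion(data, rep)
        m = build_map(data, 10.0, prune_max_missing=0.10)
        assert m["group"].nunique() == 3
        for _, grp in m.groupby("group"):
            cm = grp.sort_values("order")["cm"].to_numpy()
            assert cm[0] == 0.0
            assert np.all(np.diff(cm) >= 0)
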