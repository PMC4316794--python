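import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorforge.config import ConfigurationError
from anchorforge.simulate import Scaffold
from anchorforge.snp_selection import (DEFAULT_LADDER, filter_candidates,
                                       markers_for_size, relax_and_select,
                                       select_panel, select_targeted)


def table(rows):
    df = pd.DataFrame(rows)
    if "variant" not in df.columns:
        df["variant"] = [f"{r.scaffold}_{r.pos}" for r in df.itertuples()]
    if "designability" not in df.columns:
        df["designability"] = 0.9
    return df


class TestFilter:
    def test_strict_thresholds_keep_passing_variant(self):
        v = table([dict(scaffold="s", pos=1000, quality=999, depth=20,
                        flank_clear=True)])
        assert len(filter_candidates(v, 999, 15)) == 1

    def test_close_pair_excluded_by_flank_rule(self):
        v = table([
            dict(scaffold="s", pos=1000, quality=999, depth=20),
            dict(scaffold="s", pos=1030, quality=999, depth=20),
            dict(scaffold="s", pos=5000, quality=999, depth=20),
        ])
        kept = filter_candidates(v, 0, 0, flank_bp=50)
        assert list(kept["pos"]) == [5000]

    def test_zero_thresholds_identity(self):
        v = table([dict(scaffold="s", pos=p, quality=10, depth=1)
                   for p in (100, 5000, 9000)])
        assert len(filter_candidates(v, 0, 0)) == 3

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            filter_candidates(pd.DataFrame({"scaffold": ["s"]}), 0, 0)

    @given(q=st.floats(0, 1000), d=st.integers(0, 40))
    @settings(max_examples=30, deadline=None)
    def test_filter_monotone_in_thresholds(self, q, d):
        rng = np.random.default_rng(0)
        v = table([dict(scaffold="s", pos=int(p), quality=float(qq),
                        depth=int(dd))
                   for p, qq, dd in zip(
                       np.arange(30) * 1000 + 500,
                       rng.uniform(0, 1000, 30),
                       rng.integers(0, 40, 30))])
        base = set(filter_candidates(v, q, d)["variant"])
        tighter = set(filter_candidates(v, q + 50, d + 2)["variant"])
        assert tighter <= base


class TestRelaxation:
    def make_variants(self):
        # 5 strict-pass candidates + 3 that only pass level 1
        rows = [dict(scaffold="a", pos=1000 * k, quality=999, depth=20)
                for k in range(1, 6)]
        rows += [dict(scaffold="b", pos=1000 * k, quality=300, depth=12)
                 for k in range(1, 4)]
        rows += [dict(scaffold="c", pos=1000 * k, quality=5, depth=2)
                 for k in range(1, 3)]
        return table(rows)

    def test_level_zero_sufficient(self):
        entry = relax_and_select("a", self.make_variants(), DEFAULT_LADDER,
                                 n_target=4)
        assert entry.relaxation_level == 0 and len(entry.chosen) == 5

    def test_falls_back_to_relaxed_level(self):
        entry = relax_and_select("b", self.make_variants(), DEFAULT_LADDER,
                                 n_target=2)
        assert entry.relaxation_level == 1 and len(entry.chosen) == 3

    def test_exhausted_ladder_flags_unanchorable(self):
        entry = relax_and_select("c", self.make_variants(), DEFAULT_LADDER,
                                 n_target=2)
        assert entry.unanchorable and len(entry.chosen) == 0

    def test_empty_ladder_rejected(self):
        with pytest.raises(ConfigurationError):
            relax_and_select("a", self.make_variants(), (), n_target=2)


class TestTargeted:
    def test_two_markers_chosen_in_each_terminal_window(self):
        length = 2_000_000
        v = table([dict(scaffold="s", pos=p, quality=999, depth=20)
                   for p in np.linspace(50_000, length - 50_000, 10,
                                        dtype=int)])
        chosen = select_targeted("s", length, v)
        window = int(0.2 * length)
        left = chosen[chosen["end_label"] == "left"]
        right = chosen[chosen["end_label"] == "right"]
        assert len(left) == 2 and (left["pos"] <= window).all()
        assert len(right) == 2 and (right["pos"] > length - window).all()

    def test_interior_fallback_when_ends_empty(self):
        length = 2_000_000
        v = table([dict(scaffold="s", pos=p, quality=999, depth=20)
                   for p in (900_000, 950_000, 1_000_000, 1_050_000,
                             1_100_000)])
        chosen = select_targeted("s", length, v)
        assert len(chosen) == 4
        assert set(chosen["end_label"]) == {"interior"}
        # most terminal interior candidates picked first
        assert 900_000 in set(chosen["pos"]) and 1_100_000 in set(chosen["pos"])

    def test_smallest_size_class_gets_one_marker(self):
        length = 80_000
        v = table([dict(scaffold="s", pos=p, quality=999, depth=20)
                   for p in (5_000, 40_000, 75_000)])
        chosen = select_targeted("s", length, v)
        assert len(chosen) == 1

    def test_size_schedule(self):
        assert [markers_for_size(s) for s in
                (50_000, 300_000, 700_000, 2_000_000, 5_000_000)] == \
            [1, 2, 3, 4, 5]


class TestPanel:
    def test_panel_reaches_target_and_is_deterministic(self, small_world):
        panel = small_world["panel"]
        cfg = small_world["config"]
        assert len(panel) == cfg.n_markers
        again = select_panel(small_world["scaffolds"],
                             small_world["variants"],
                             panel_size=cfg.n_markers)
        pd.testing.assert_frame_equal(panel, again)

    def test_every_anchorable_scaffold_represented(self, small_world):
        panel = small_world["panel"]
        unanchorable = set(panel.attrs["unanchorable"])
        covered = set(panel["scaffold"])
        for sc in small_world["scaffolds"]:
            if sc.id not in unanchorable:
                assert sc.id in covered

    def test_large_scaffold_interior_coverage(self):
        # a >=2 Mb scaffold should not keep multi-Mb internal marker gaps
        # once the panel top-up runs
        scaffolds = [Scaffold("big", 3_000_000, []),
                     Scaffold("small", 200_000, [])]
        rng = np.random.default_rng(1)
        rows = [dict(scaffold="big", pos=int(p), quality=999, depth=20,
                     designability=round(float(d), 3))
                for p, d in zip(
                    np.sort(rng.choice(np.arange(1000, 2_999_000), 120,
                                       replace=False)),
                    rng.beta(9, 1, 120))]
        rows += [dict(scaffold="small", pos=p, quality=999, depth=20,
                      designability=0.9)
                 for p in (10_000, 190_000)]
        panel = select_panel(scaffolds, table(rows), panel_size=20)
        big = panel[panel["scaffold"] == "big"].sort_values("pos")
        gaps = np.diff(np.concatenate([[0], big["pos"], [3_000_000]]))
        assert len(panel) == 20
        assert gaps.max() < 1_200_000
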