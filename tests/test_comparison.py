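import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spectraldiff as sd


class TestAssignCategories:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("gray", "none"),
            ("spontaneous", "none"),
            ("flashes", "simple_artificial"),
            ("gabors", "simple_artificial"),
            ("shuffled_movie", "shuffled"),
            ("static_gratings", "complex_artificial"),
            ("drifting_gratings", "complex_artificial"),
            ("natural_movie", "natural"),
        ],
    )
    def test_mapping(self, name, expected):
        assert sd.assign_categories([name]) == [expected]

    def test_unknown_name_listed_in_error(self):
        with pytest.raises(ValueError, match="frogs"):
            sd.assign_categories(["gray", "frogs"])


class TestSubsampleUnits:
    def test_sample_size_and_distinctness(self):
        ids = [f"u{i}" for i in range(200)]
        out = sd.subsample_units(ids, 50, seed=0)
        assert len(out) == 50 == len(set(out))
        assert set(out) <= set(ids)

    def test_identity_when_target_is_size(self):
        ids = list("abcde")
        assert sd.subsample_units(ids, 5, seed=1) == ids

    def test_reproducible_under_seed(self):
        ids = [f"u{i}" for i in range(100)]
        assert sd.subsample_units(ids, 30, 7) == sd.subsample_units(ids, 30, 7)

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError):
            sd.subsample_units(list("abc"), 4, seed=0)


class TestGamesHowell:
    def test_identical_large_samples_p_near_one(self):
        rng = np.random.default_rng(9)
        g = rng.normal(0, 1, 500)
        table = sd.games_howell([g, g + rng.normal(0, 1e-9, 500)])
        assert table["p_raw"].iloc[0] > 0.99

    def test_separated_groups_rejected(self):
        rng = np.random.default_rng(10)
        table = sd.games_howell([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        assert table["p_raw"].iloc[0] < 0.001

    def test_matches_reference_implementation(self):
        """Cross-validation against pingouin on a fixed 3-group fixture."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        groups = {
            "a": rng.normal(0, 1, 20),
            "b": rng.normal(0.5, 2, 30),
            "c": rng.normal(1, 0.5, 25),
        }
        mine = sd.games_howell(list(groups.values()), list(groups))
        df = pd.DataFrame(
            {
                "val": np.concatenate(list(groups.values())),
                "grp": np.repeat(list(groups), [20, 30, 25]),
            }
        )
        ref = pg.pairwise_gameshowell(data=df, dv="val", between="grp")
        np.testing.assert_allclose(
            mine["p_raw"].to_numpy(), ref["pval"].to_numpy(), atol=1e-6
        )

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(11)
        gs = [rng.normal(m, 1, 25) for m in (0, 1, 2)]
        a = sd.games_howell(gs, ["x", "y", "z"])
        b = sd.games_howell(gs[::-1], ["z", "y", "x"])
        pa = {frozenset((r.group_a, r.group_b)): r.p_raw for r in a.itertuples()}
        pb = {frozenset((r.group_a, r.group_b)): r.p_raw for r in b.itertuples()}
        for key in pa:
            assert pa[key] == pytest.approx(pb[key])

    def test_degenerate_group_warns_nan(self):
        with pytest.warns(UserWarning, match="degenerate"):
            table = sd.games_howell([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        assert np.isnan(table["p_raw"].iloc[0])


class TestBenjaminiHochberg:
    def test_stepup_thresholds_all_pass(self):
        reject, _ = sd.benjamini_hochberg([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_single_large_p_not_rejected(self):
        reject, _ = sd.benjamini_hochberg([0.5], alpha=0.01)
        assert not reject.any()

    def test_empty_input(self):
        reject, p_adj = sd.benjamini_hochberg([], alpha=0.05)
        assert reject.size == 0 and p_adj.size == 0

    def test_adjusted_values_match_min_over_tail_formula(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 25)
        _, p_adj = sd.benjamini_hochberg(p, alpha=0.05)
        order = np.argsort(p)
        m = p.size
        expected = np.minimum.accumulate(
            (m * p[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        np.testing.assert_allclose(p_adj[order], np.minimum(expected, 1.0))

    def test_bh_rejections_contain_bonferroni(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.uniform(0, 0.2, 15)
            alpha = 0.05
            bh, _ = sd.benjamini_hochberg(p, alpha)
            bonf = p < alpha / p.size
            assert np.all(bh[bonf])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_adjusted_values_monotone_over_sorted_raw(self, p):
        p = np.asarray(p)
        _, p_adj = sd.benjamini_hochberg(p, alpha=0.05)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(p_adj[order]) >= -1e-12)
        assert np.all((p_adj >= 0) & (p_adj <= 1))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            sd.benjamini_hochberg([0.5, 1.2])


class TestStars:
    def test_three_levels(self):
        np.testing.assert_array_equal(
            sd.significance_stars([0.5, 0.009, 0.0009, 0.00009]),
            ["", "*", "**", "***"],
        )


class TestPartitionByRunning:
    def test_stationary_running_unknown(self):
        t = np.arange(0, 10, 0.1)
        speed = np.where(t < 5, 0.0, 30.0)
        labels = sd.partition_by_running(
            [(0, 3), (6, 9), (20, 23)], t, speed, threshold=2.0
        )
        assert labels == ["stationary", "running", "unknown"]

    def test_boundary_counts_as_running(self):
        t = np.arange(0, 3, 0.1)
        labels = sd.partition_by_running([(0, 3)], t, np.full(t.size, 2.0), 2.0)
        assert labels == ["running"]


class TestHitMissContrast:
    def test_null_difference_not_rejected(self):
        rng = np.random.default_rng(14)
        trials = pd.DataFrame(
            {
                "ensemble": ["A"] * 40,
                "outcome": ["hit", "miss"] * 20,
                "nd": rng.normal(5, 1, 40),
                "rate": rng.normal(10, 2, 40),
            }
        )
        out = sd.hit_miss_contrast(trials)
        assert len(out) == 1
        assert not out["reject_nd"].iloc[0]
        assert abs(out["diff_nd"].iloc[0]) < 2.0

    def test_one_row_per_ensemble(self):
        rng = np.random.default_rng(15)
        frames = []
        for ens in ("VISp/4", "VISl/5", "all/agg"):
            frames.append(
                pd.DataFrame(
                    {
                        "ensemble": ens,
                        "outcome": ["hit"] * 5 + ["miss"] * 5,
                        "nd": rng.normal(1, 0.1, 10),
                        "rate": rng.normal(8, 1, 10),
                    }
                )
            )
        out = sd.hit_miss_contrast(pd.concat(frames))
        assert list(out["ensemble"]) == ["VISp/4", "VISl/5", "all/agg"]

    def test_single_outcome_session_skipped(self):
        trials = pd.DataFrame(
            {
                "ensemble": ["A"] * 6,
                "outcome": ["hit"] * 6,
                "nd": np.arange(6.0),
                "rate": np.arange(6.0),
            }
        )
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = sd.hit_miss_contrast(trials)
        assert out.empty
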