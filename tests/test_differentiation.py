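import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import spectraldiff as sd
from spectraldiff.differentiation import DifferentiationConfig, resample_hold

from conftest import poisson_ensemble


def brute_force_median_distance(vectors):
    """Independent oracle: double loop over pairs, explicit even-count median."""
    d = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            d.append(math.dist(vectors[i], vectors[j]))
    d.sort()
    n = len(d)
    if n % 2 == 1:
        return d[n // 2]
    return 0.5 * (d[n // 2 - 1] + d[n // 2])


class TestConfig:
    def test_fewer_than_two_states_rejected(self):
        with pytest.raises(ValueError, match="2 states"):
            DifferentiationConfig(window=0.3, state=0.2)

    def test_state_must_hit_sample_grid(self):
        cfg = DifferentiationConfig(window=3.0, state=0.3)
        assert cfg.state_samples == 60
        assert cfg.n_states == 10

    def test_unknown_taper_rejected(self):
        with pytest.raises(ValueError, match="taper"):
            DifferentiationConfig(taper="hann")


class TestSegmentStates:
    @pytest.mark.parametrize(
        "window,state,n_expected", [(3.0, 0.3, 10), (0.3, 0.06, 5), (0.6, 0.3, 2)]
    )
    def test_state_counts(self, window, state, n_expected):
        n_s = int(round(state * 200))
        values = np.zeros((2, int(round(window * 200))))
        blocks = sd.segment_states(values, n_s)
        assert blocks.shape == (n_expected, 2, n_s)

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="median"):
            sd.segment_states(np.zeros((1, 60)), 60)


class TestStatePSD:
    def test_constant_block_all_power_at_dc(self):
        np.testing.assert_allclose(
            sd.state_psd(np.array([[1.0, 1, 1, 1]])), [16.0, 0.0, 0.0], atol=1e-12
        )

    def test_zero_block(self):
        assert not sd.state_psd(np.zeros((3, 8))).any()

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(3)
        block = rng.uniform(0, 5, (4, 60))
        np.testing.assert_allclose(
            sd.state_psd(3.0 * block), 9.0 * sd.state_psd(block)
        )

    def test_block_length_per_unit(self):
        out = sd.state_psd(np.ones((5, 60)))
        assert out.shape == (5 * 31,)  # floor(60/2)+1 per unit
        assert (out >= 0).all()


class TestMedianPairwiseDistance:
    def test_identical_states_zero(self):
        assert sd.spectral_differentiation_raw(np.ones((6, 10))) == 0.0

    def test_single_pair(self):
        states = np.array([[16.0, 0, 0], [0.0, 0, 0]])
        assert sd.spectral_differentiation_raw(states) == 16.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = rng.integers(2, 12)
            dim = rng.integers(1, 30)
            vecs = rng.uniform(0, 10, (n, dim))
            np.testing.assert_allclose(
                sd.spectral_differentiation_raw(vecs),
                brute_force_median_distance(vecs),
            )

    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 9), st.integers(1, 16)),
            elements=st.floats(0, 1e4),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, vecs):
        np.testing.assert_allclose(
            sd.spectral_differentiation_raw(vecs),
            brute_force_median_distance(vecs),
            rtol=1e-9,
            atol=1e-12,
        )

    def test_orthogonal_concatenation(self):
        """Distances of a joint ensemble are sqrt(d_A^2 + d_B^2) of the parts,
        so ND of a union is not the sum of the parts' NDs."""
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 3, (5, 7))
        b = rng.uniform(0, 3, (5, 4))
        from scipy.spatial.distance import pdist

        joint = pdist(np.hstack([a, b]))
        np.testing.assert_allclose(
            joint, np.sqrt(pdist(a) ** 2 + pdist(b) ** 2)
        )


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,n,s,expected", [(7.0, 4, 0.5, 14.0), (7.0, 1, 1.0, 7.0)]
    )
    def test_examples(self, raw, n, s, expected):
        assert sd.normalize_nd(raw, n, s) == pytest.approx(expected)

    def test_normalized_nd_scale_invariant(self, iid_ensemble):
        cfg = DifferentiationConfig()
        sub = iid_ensemble.subset(iid_ensemble.unit_ids[:12])
        base = sd.nd_timeseries(sub, [(0, 12.0)], cfg)
        scaled = sd.RateMatrix(sub.values * 7.5, 200.0)
        after = sd.nd_timeseries(scaled, [(0, 12.0)], cfg)
        np.testing.assert_allclose(after.nd, base.nd)

    def test_raw_quadratic_scaling_exact(self, iid_ensemble):
        block = iid_ensemble.values[:10, :600]
        vec = sd.state_psd(sd.segment_states(block, 60))
        raw = sd.spectral_differentiation_raw(vec)
        for q in (0.5, 2.0, 3.0):
            vec_q = sd.state_psd(sd.segment_states(q * block, 60))
            assert sd.spectral_differentiation_raw(vec_q) == pytest.approx(
                q**2 * raw, rel=1e-12
            )


class TestBounds:
    def test_printed_bound_value(self):
        assert sd.bound_normalized(50, 200) == 1e8

    def test_trivial_values(self):
        assert sd.bound_normalized(1, 200) == 4e4
        assert sd.bound_raw(1, 200, 1.0, 2) == 8e4

    def test_raw_bound_grows_with_n_and_s(self):
        assert sd.bound_raw(2.0, 200.0, 0.5, 8) == 2 * sd.bound_raw(2.0, 200.0, 0.5, 4)
        assert sd.bound_raw(2.0, 200.0, 1.0, 4) == 4 * sd.bound_raw(2.0, 200.0, 0.5, 4)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            sd.bound_normalized(0.0, 200.0)


class TestNDTimeseries:
    def test_small_ensemble_refused_citing_rule(self):
        rm = poisson_ensemble(9, 6.0, seed=1)
        with pytest.raises(ValueError, match="at least 10"):
            sd.nd_timeseries(rm, [(0, 6.0)])

    def test_constant_rates_zero_nd(self):
        rm = sd.RateMatrix(np.full((12, 1200), 5.0))
        series = sd.nd_timeseries(rm, [(0, 6.0)])
        np.testing.assert_array_equal(series.nd, 0.0)

    def test_window_tiling(self):
        rm = sd.RateMatrix(np.full((12, 6000), 5.0))
        series = sd.nd_timeseries(rm, [(0.0, 30.0)])
        assert len(series.nd) == 10  # 30 s epoch, W = 3 s

    def test_windows_do_not_straddle_epochs(self):
        rm = sd.RateMatrix(np.full((12, 2000), 5.0))
        series = sd.nd_timeseries(rm, [(0.0, 4.0), (4.0, 10.0)])
        # 4 s epoch -> 1 window (tail dropped); 6 s epoch -> 2 windows
        assert list(series.epoch_index) == [0, 1, 1]

    def test_zero_mean_rate_rejected(self):
        rm = sd.RateMatrix(np.zeros((12, 1200)))
        with pytest.raises(ValueError, match="mean rate"):
            sd.nd_timeseries(rm, [(0, 6.0)])


class TestMFRDifferentiation:
    def test_constant_rates_zero(self):
        rm = sd.RateMatrix(np.full((4, 1200), 3.0))
        series = sd.mfr_differentiation(rm, [(0, 6.0)])
        np.testing.assert_array_equal(series.nd, 0.0)

    def test_population_variance_convention(self):
        # one unit whose normalized per-state means are 1 and 3:
        # rates 1, 3 over the analysis window and 0 elsewhere -> unit mean 1
        n = 60
        values = np.concatenate([np.full(n, 1.0), np.full(n, 3.0), np.zeros(2 * n)])
        rm = sd.RateMatrix(values[None, :])
        cfg = DifferentiationConfig(window=0.6, state=0.3, min_units=1)
        series = sd.mfr_differentiation(rm, [(0.0, 0.6)], cfg)
        assert series.nd[0] == pytest.approx(1.0)

    def test_invariant_to_single_unit_rescale(self):
        rng = np.random.default_rng(6)
        values = rng.uniform(1, 5, (5, 1200))
        cfg = DifferentiationConfig()
        a = sd.mfr_differentiation(sd.RateMatrix(values), [(0, 6.0)], cfg)
        values2 = values.copy()
        values2[2] *= 11.0
        b = sd.mfr_differentiation(sd.RateMatrix(values2), [(0, 6.0)], cfg)
        np.testing.assert_allclose(a.nd, b.nd)

    def test_zero_rate_unit_dropped_with_warning(self):
        values = np.vstack([np.full((4, 1200), 3.0), np.zeros((1, 1200))])
        with pytest.warns(UserWarning, match="zero session-mean"):
            series = sd.mfr_differentiation(sd.RateMatrix(values), [(0, 6.0)])
        assert series.n_units == 4


class TestStimulusDifferentiation:
    def test_gray_movie_zero(self):
        movie = np.full((16, 1200), 127.0)
        series = sd.stimulus_differentiation(movie)
        np.testing.assert_array_equal(series.nd, 0.0)

    def test_pixel_scaling_invariance(self):
        movie = sd.gen_stimulus("static_gratings", 6.0, n_pixels=12, seed=7)
        a = sd.stimulus_differentiation(movie)
        b = sd.stimulus_differentiation(movie * 0.25)
        np.testing.assert_allclose(a.nd, b.nd)

    def test_equals_nd_timeseries_on_pixels(self):
        movie = sd.gen_stimulus("shuffled_movie", 6.0, n_pixels=12, seed=8)
        cfg = DifferentiationConfig()
        a = sd.stimulus_differentiation(movie, cfg)
        b = sd.nd_timeseries(sd.RateMatrix(movie), [(0, 6.0)], cfg)
        np.testing.assert_array_equal(a.nd, b.nd)

    def test_resample_hold_preserves_duration(self):
        movie = np.arange(60.0)[None, :].repeat(2, axis=0)
        out = resample_hold(movie, frame_rate=30.0, f=200.0)
        assert out.shape == (2, 400)
        assert out[0, 0] == 0.0 and out[0, -1] == 59.0


class TestEvokedND:
    def test_five_states_per_event(self):
        cfg = DifferentiationConfig(window=0.3, state=0.06)
        assert cfg.n_states == 5

    def test_constant_rates_zero_per_event(self):
        rm = sd.RateMatrix(np.full((10, 2000), 4.0))
        out = sd.evoked_nd(rm, [1.0, 3.0, 5.0])
        np.testing.assert_array_equal(out, 0.0)

    def test_equals_one_window_nd_timeseries(self):
        rm = poisson_ensemble(10, 10.0, seed=9)
        out = sd.evoked_nd(rm, [2.0])
        cfg = DifferentiationConfig(window=0.3, state=0.06)
        series = sd.nd_timeseries(
            rm, [(2.0, 2.3)], cfg, mean_rate=float(rm.values.mean())
        )
        assert out[0] == pytest.approx(series.nd[0])

    def test_edge_event_skipped_with_warning(self):
        rm = sd.RateMatrix(np.full((10, 400), 4.0))
        with pytest.warns(UserWarning, match="edge"):
            out = sd.evoked_nd(rm, [1.9])
        assert np.isnan(out[0])
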