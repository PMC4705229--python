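import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alclassify import (EncoderConfig, RatePattern, SpikeTrainSet, VRSet,
                        fit_neural_gas, gen_gamma_trains, gen_poisson_trains,
                        load_spike_trains, load_vrset, responses_to_rates,
                        save_spike_trains, save_vrset, vr_response,
                        vr_responses)


def _isi_cv(trains, neuron=0):
    t = np.sort(trains.times[trains.neuron_ids == neuron])
    isi = np.diff(t)
    return isi.std() / isi.mean()


class TestNeuralGas:
    def test_single_attractor(self):
        p = np.array([0.3, 0.7, 0.1])
        samples = np.tile(p, (20, 1))
        with pytest.warns(UserWarning):  # n_vr > n_samples branch also allowed
            vrs = fit_neural_gas(samples, 25, seed=0)
        assert np.all(np.abs(vrs.centroids - p) < 1e-6)

    def test_two_clusters_one_centroid_each(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.2, 0.02, size=(100, 4))
        b = rng.normal(0.8, 0.02, size=(100, 4))
        samples = np.vstack([a, b])
        vrs = fit_neural_gas(samples, 2, seed=1)
        d_a = np.linalg.norm(vrs.centroids - a.mean(axis=0), axis=1)
        d_b = np.linalg.norm(vrs.centroids - b.mean(axis=0), axis=1)
        assert min(d_a) < 0.02 and min(d_b) < 0.02
        assert np.argmin(d_a) != np.argmin(d_b)

    def test_quantization_error_improves_over_initialization(self):
        rng = np.random.default_rng(2)
        samples = rng.random((150, 6))
        init = fit_neural_gas(samples, 12, iterations=0, seed=3)
        fitted = fit_neural_gas(samples, 12, seed=3)

        def qerr(vrs):
            from scipy.spatial.distance import cdist
            return cdist(samples, vrs.centroids).min(axis=1).mean()

        assert qerr(fitted) < qerr(init)

    def test_zero_iterations_returns_seeded_initialization(self):
        rng = np.random.default_rng(4)
        samples = rng.random((50, 3))
        a = fit_neural_gas(samples, 5, iterations=0, seed=7)
        b = fit_neural_gas(samples, 5, iterations=0, seed=7)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        # initial centroids are drawn training samples
        assert all(any(np.allclose(c, s) for s in samples) for c in a.centroids)

    def test_nan_samples_rejected(self):
        samples = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            fit_neural_gas(samples, 2, seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        samples = rng.random((60, 4))
        a = fit_neural_gas(samples, 6, seed=9)
        b = fit_neural_gas(samples, 6, seed=9)
        np.testing.assert_array_equal(a.centroids, b.centroids)


class TestVrResponse:
    def setup_method(self):
        self.vrs = VRSet(centroids=np.array([[0.0, 0.0], [1.0, 0.0]]), sigma=1.0)

    def test_zero_distance_gives_unit_response(self):
        r = vr_response(np.array([0.0, 0.0]), self.vrs)
        assert r[0] == 1.0

    def test_cutoff_beyond_sigma(self):
        r = vr_response(np.array([0.0, 2.0]), self.vrs)
        assert r[0] == 0.0 and r[1] == 0.0

    def test_linear_cone_midpoint(self):
        r = vr_response(np.array([0.5, 0.0]), self.vrs)
        np.testing.assert_allclose(r, [0.5, 0.5])

    def test_strictly_decreasing_with_distance_inside_cone(self):
        ds = np.linspace(0, 0.99, 20)
        rs = [vr_response(np.array([d, 0.0]), self.vrs)[0] for d in ds]
        assert np.all(np.diff(rs) < 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vr_response(np.array([0.0, 0.0, 0.0]), self.vrs)

    def test_joint_permutation_invariance(self, rng):
        centroids = rng.random((7, 3))
        vrs = VRSet(centroids=centroids, sigma=2.0)
        x = rng.random(3)
        perm = rng.permutation(7)
        permuted = VRSet(centroids=centroids[perm], sigma=2.0)
        np.testing.assert_allclose(vr_response(x, permuted),
                                   vr_response(x, vrs)[perm])

    def test_manhattan_metric_option(self):
        vrs = VRSet(centroids=np.array([[0.0, 0.0]]), sigma=1.0, metric="manhattan")
        r = vr_response(np.array([0.25, 0.25]), vrs)
        np.testing.assert_allclose(r, [0.5])


class TestResponsesToRates:
    def test_affine_endpoints_and_midpoint(self):
        pat = responses_to_rates(np.array([0.0, 1.0, 0.5]), 10.0, 70.0)
        np.testing.assert_allclose(pat.rates, [10.0, 70.0, 40.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            responses_to_rates(np.array([1.2]), 0.0, 70.0)
        with pytest.raises(ValueError):
            responses_to_rates(np.array([0.5]), 70.0, 70.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_permuting_responses_permutes_rates(self, perm):
        resp = np.linspace(0, 1, 6)
        base = responses_to_rates(resp, 5.0, 60.0).rates
        permuted = responses_to_rates(resp[perm], 5.0, 60.0).rates
        np.testing.assert_allclose(permuted, base[perm])


class TestPoissonTrains:
    def test_zero_rate_empty(self):
        st_ = gen_poisson_trains(RatePattern(np.zeros(3)), 5, 1000.0, 1.0, seed=0)
        assert st_.n_events == 0

    def test_rate_too_high_for_timestep_rejected(self):
        with pytest.raises(ValueError):
            gen_poisson_trains(RatePattern(np.array([1500.0])), 1, 100.0, 1.0, seed=0)

    def test_count_concentration_100hz(self):
        # binomial bound: 10000 expected spikes, 4-sigma band
        st_ = gen_poisson_trains(RatePattern(np.array([100.0])), 1, 100_000.0,
                                 1.0, seed=1)
        assert abs(st_.n_events - 10000) < 4 * np.sqrt(10000)

    def test_isi_cv_near_one(self):
        st_ = gen_poisson_trains(RatePattern(np.array([50.0])), 1, 200_000.0,
                                 0.1, seed=2)
        assert 0.9 <= _isi_cv(st_) <= 1.1

    def test_empirical_rate_within_two_percent(self):
        # pooled over a 4-neuron cluster so sampling error sits well below 2%
        st_ = gen_poisson_trains(RatePattern(np.array([20.0, 50.0])), 4,
                                 400_000.0, 1.0, seed=3)
        counts = st_.counts()
        rates = [counts[:4].sum() / 1600.0, counts[4:].sum() / 1600.0]
        np.testing.assert_allclose(rates, [20, 50], rtol=0.02)

    def test_deterministic_and_grid_aligned(self):
        a = gen_poisson_trains(RatePattern(np.array([40.0])), 3, 2000.0, 0.5, seed=4)
        b = gen_poisson_trains(RatePattern(np.array([40.0])), 3, 2000.0, 0.5, seed=4)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.neuron_ids, b.neuron_ids)
        assert np.allclose(a.times / 0.5, np.round(a.times / 0.5))


class TestGammaTrains:
    def test_order_one_is_poisson_like(self):
        st_ = gen_gamma_trains(RatePattern(np.array([50.0])), 1, 1, 200_000.0,
                               seed=5, dt=0.1)
        assert 0.9 <= _isi_cv(st_) <= 1.1

    def test_order_five_regularity(self):
        st_ = gen_gamma_trains(RatePattern(np.array([50.0])), 5, 1, 200_000.0,
                               seed=6, dt=1.0)
        assert 0.40 <= _isi_cv(st_) <= 0.50  # 1/sqrt(5) ~ 0.447

    def test_order_five_lower_count_variance_than_order_one(self):
        bins = np.arange(0.0, 200_001.0, 1000.0)
        g5 = gen_gamma_trains(RatePattern(np.array([50.0])), 5, 1, 200_000.0, seed=7)
        g1 = gen_gamma_trains(RatePattern(np.array([50.0])), 1, 1, 200_000.0, seed=7)
        v5 = np.histogram(g5.times, bins)[0].var()
        v1 = np.histogram(g1.times, bins)[0].var()
        assert v5 < v1

    def test_rate_preserved_within_two_percent(self):
        st_ = gen_gamma_trains(RatePattern(np.array([20.0, 60.0])), 5, 2,
                               200_000.0, seed=8)
        rates = st_.counts() / 200.0
        np.testing.assert_allclose(rates, [20, 20, 60, 60], rtol=0.02)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            gen_gamma_trains(RatePattern(np.array([50.0])), 0, 1, 1000.0, seed=0)


class TestSerialization:
    def test_spike_train_text_round_trip(self, tmp_path, rng):
        st_ = gen_poisson_trains(RatePattern(np.array([30.0, 60.0])), 2,
                                 500.0, 0.5, seed=9)
        path = tmp_path / "raster.tsv"
        save_spike_trains(path, st_)
        back = load_spike_trains(path)
        np.testing.assert_array_equal(back.neuron_ids, st_.neuron_ids)
        np.testing.assert_allclose(back.times, st_.times)
        assert back.duration == st_.duration and back.dt == st_.dt

    def test_vrset_text_round_trip(self, tmp_path, rng):
        vrs = VRSet(centroids=rng.random((5, 4)), sigma=0.7, metric="manhattan")
        path = tmp_path / "vrs.tsv"
        save_vrset(path, vrs)
        back = load_vrset(path)
        np.testing.assert_allclose(back.centroids, vrs.centroids)
        assert back.sigma == vrs.sigma and back.metric == "manhattan"


def test_spike_train_sorted_and_windowed():
    st_ = SpikeTrainSet(np.array([1, 0, 1]), np.array([5.0, 1.0, 1.0]),
                        duration=10.0, dt=1.0, n_neurons=2)
    assert st_.times.tolist() == [1.0, 1.0, 5.0]
    assert st_.neuron_ids.tolist() == [0, 1, 1]  # ties broken by neuron index
    win = st_.window(1.0, 5.0)
    assert win.n_events == 2 and win.times.max() == 0.0


def test_encoder_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(f_min=10.0, f_max=5.0)
    with pytest.raises(ValueError):
        EncoderConfig(generator="renewal")
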