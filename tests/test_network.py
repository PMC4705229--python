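import numpy as np
import pytest

from alclassify import (NetworkParams, NeuronParams, RatePattern,
                        SpikeTrainSet, build_topology, cluster_spike_counts,
                        expand_cluster_weights, gen_poisson_trains, lif_step,
                        simulate, synapse_step)


def analytic_lif_rate(i_syn: float, p: NeuronParams) -> float:
    """Closed-form steady firing rate (Hz) of an LIF neuron under constant
    suprathreshold current."""
    drive = p.r_m * i_syn
    num = drive + p.v_rest - p.v_reset
    den = drive + p.v_rest - p.v_thresh
    return 1000.0 / (p.t_ref + p.tau_m * np.log(num / den))


class TestTopology:
    def test_standard_counts_forced_by_definition(self):
        topo = build_topology(10, 2, cluster_size=30)
        assert topo.pop("RN").size == 300
        assert topo.pop("PN").size == 300
        assert topo.pop("AN").size == 60
        assert topo.plastic_projection.weights.size == 18000

    def test_spikey_preset_small_populations(self):
        topo = build_topology(10, 2, preset="spikey")
        assert topo.pop("RN").size == 60   # 6 per VR
        assert topo.pop("PN").size == 70   # 7 per VR
        assert topo.pop("AN").size == 16   # 8 per class
        assert "LN_PN" in topo.populations and "LN_AN" in topo.populations

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_topology(10, 1)

    def test_fewer_vrs_than_classes_rejected(self):
        with pytest.raises(ValueError):
            build_topology(2, 3)

    def test_inhibition_is_cross_cluster_only(self):
        topo = build_topology(3, 2, cluster_size=4)
        pn_pn = [p for p in topo.projections
                 if p.source == "PN" and p.target == "PN"][0]
        w = pn_pn.weights
        for c in range(3):
            block = w[c * 4:(c + 1) * 4, c * 4:(c + 1) * 4]
            assert np.all(block == 0)
        assert np.all(w <= 0)

    def test_sign_conventions(self):
        topo = build_topology(3, 2, cluster_size=4)
        for proj in topo.projections:
            if proj.plastic:
                assert np.all(proj.weights >= 0)


class TestLifStep:
    def test_rest_is_fixed_point(self):
        p = NeuronParams()
        v, spiked, _ = lif_step(np.array([p.v_rest]), np.array([0.0]),
                                np.array([0.0]), p, 1.0)
        assert v[0] == pytest.approx(p.v_rest)
        assert not spiked[0]

    def test_subthreshold_asymptote_no_spike(self):
        p = NeuronParams()
        i_sub = 0.9 * (p.v_thresh - p.v_rest) / p.r_m
        v = np.array([p.v_rest])
        r = np.array([0.0])
        spikes = 0
        for _ in range(2000):
            v, s, r = lif_step(v, r, np.array([i_sub]), p, 1.0)
            spikes += int(s[0])
        assert spikes == 0
        assert v[0] == pytest.approx(p.v_rest + p.r_m * i_sub, abs=1e-6)

    @pytest.mark.parametrize("i_syn", [0.45, 0.7, 1.2])
    def test_fi_curve_matches_closed_form(self, i_syn):
        p = NeuronParams()
        dt, horizon = 0.1, 5000.0
        v = np.array([p.v_rest])
        r = np.array([0.0])
        count = 0
        for _ in range(int(horizon / dt)):
            v, s, r = lif_step(v, r, np.array([i_syn]), p, dt)
            count += int(s[0])
        simulated = count / (horizon / 1000.0)
        assert simulated == pytest.approx(analytic_lif_rate(i_syn, p), rel=0.05)

    def test_refractory_holds_at_reset(self):
        p = NeuronParams(t_ref=5.0)
        strong = 10.0
        v = np.array([p.v_thresh - 0.01])
        r = np.array([0.0])
        v, s, r = lif_step(v, r, np.array([strong]), p, 1.0)
        assert s[0] and v[0] == p.v_reset
        v, s, r = lif_step(v, r, np.array([strong]), p, 1.0)
        assert not s[0] and v[0] == p.v_reset  # held despite strong drive


class TestSynapseStep:
    def test_pure_decay(self):
        i = 2.0
        for _ in range(5):
            i = synapse_step(i, 0.0, tau_syn=10.0, dt=1.0)
        assert i == pytest.approx(2.0 * np.exp(-0.5))

    def test_impulse_response(self):
        assert synapse_step(0.0, 0.7, tau_syn=5.0, dt=1.0) == pytest.approx(0.7)

    def test_linear_superposition(self):
        both = synapse_step(1.0, 0.3 + 0.4, 5.0, 1.0)
        solo = synapse_step(1.0, 0.0, 5.0, 1.0)
        assert both == pytest.approx(solo + 0.7)

    def test_injected_charge_conservation(self):
        # summed increments over a spike sequence equal weight * spike count
        w, n_spikes = 0.25, 17
        total_in = 0.0
        i = 0.0
        for k in range(100):
            inc = w if k < n_spikes else 0.0
            total_in += inc
            i = synapse_step(i, inc, 5.0, 1.0)
        assert total_in == pytest.approx(w * n_spikes)


def _drive_trains(rates, cluster_size, duration, dt, seed, n_channels):
    full = np.zeros(n_channels)
    for ch, r in rates.items():
        full[ch] = r
    return gen_poisson_trains(RatePattern(full), cluster_size, duration, dt, seed)


class TestSimulate:
    def test_no_drive_no_spontaneous_activity(self):
        topo = build_topology(4, 2, cluster_size=5)
        rec = simulate(topo, None, duration=200.0, dt=1.0, record=("PN", "AN"))
        assert rec.spikes["PN"].n_events == 0
        assert rec.spikes["AN"].n_events == 0

    def test_driven_cluster_dominates_its_pn_partner(self):
        topo = build_topology(4, 2, cluster_size=10)
        trains = _drive_trains({1: 70.0}, 10, 500.0, 1.0, seed=0, n_channels=4)
        rec = simulate(topo, trains, duration=500.0, dt=1.0, record=("PN",))
        counts = cluster_spike_counts(rec.spikes["PN"], topo.pn_partition())
        assert counts[1] > 0
        assert counts[1] == counts.max()
        assert np.all(counts[[0, 2, 3]] < counts[1])

    def test_wta_inhibition_suppresses_weaker_cluster(self):
        # drive AN clusters through fixed PN->AN weights, one 50% stronger
        def an_counts(with_inhibition):
            params = NetworkParams() if with_inhibition else \
                NetworkParams(an_inh_w=-0.0000001)
            topo = build_topology(2, 2, cluster_size=10, params=params)
            cluster_w = np.array([[0.25, 0.0], [0.0, 0.25]])
            topo.set_plastic_weights(expand_cluster_weights(cluster_w, 10, 10))
            trains = _drive_trains({0: 70.0, 1: 45.0}, 10, 1000.0, 1.0, seed=1,
                                   n_channels=2)
            rec = simulate(topo, trains, duration=1000.0, dt=1.0, record=("AN",))
            return cluster_spike_counts(rec.spikes["AN"], topo.an_partition())

        with_wta = an_counts(True)
        without = an_counts(False)
        assert with_wta[1] < without[1]  # weaker side suppressed by WTA

    def test_determinism_bit_identical(self):
        topo1 = build_topology(3, 2, cluster_size=8)
        topo2 = build_topology(3, 2, cluster_size=8)
        trains = _drive_trains({0: 50.0, 2: 60.0}, 8, 400.0, 0.5, seed=2,
                               n_channels=3)
        rec1 = simulate(topo1, trains, 400.0, 0.5, record=("PN", "AN"))
        rec2 = simulate(topo2, trains, 400.0, 0.5, record=("PN", "AN"))
        for pop in ("PN", "AN"):
            np.testing.assert_array_equal(rec1.spikes[pop].times,
                                          rec2.spikes[pop].times)
            np.testing.assert_array_equal(rec1.spikes[pop].neuron_ids,
                                          rec2.spikes[pop].neuron_ids)

    def test_refractory_invariant(self):
        p = NeuronParams(t_ref=3.0)
        topo = build_topology(2, 2, cluster_size=6, neuron_params=p)
        trains = _drive_trains({0: 70.0, 1: 70.0}, 6, 1000.0, 1.0, seed=3,
                               n_channels=2)
        rec = simulate(topo, trains, 1000.0, 1.0, record=("PN",))
        pn = rec.spikes["PN"]
        for nid in range(topo.pop("PN").size):
            t = np.sort(pn.times[pn.neuron_ids == nid])
            if t.size > 1:
                assert np.diff(t).min() >= p.t_ref

    def test_dt_robustness_of_cluster_counts(self):
        # same grid-aligned input simulated at 1.0 and 0.5 ms
        topo = build_topology(3, 2, cluster_size=10)
        cluster_w = np.array([[0.2, 0.0], [0.0, 0.2], [0.1, 0.1]])
        trains = _drive_trains({0: 60.0, 1: 30.0}, 10, 2000.0, 1.0, seed=4,
                               n_channels=3)
        topo.set_plastic_weights(expand_cluster_weights(cluster_w, 10, 10))
        rec1 = simulate(topo, trains, 2000.0, 1.0, record=("AN",))
        counts1 = cluster_spike_counts(rec1.spikes["AN"], topo.an_partition())
        topo2 = build_topology(3, 2, cluster_size=10)
        topo2.set_plastic_weights(expand_cluster_weights(cluster_w, 10, 10))
        trains_fine = SpikeTrainSet(trains.neuron_ids, trains.times,
                                    duration=2000.0, dt=0.5,
                                    n_neurons=trains.n_neurons)
        rec2 = simulate(topo2, trains_fine, 2000.0, 0.5, record=("AN",))
        counts2 = cluster_spike_counts(rec2.spikes["AN"], topo2.an_partition())
        total1, total2 = counts1.sum(), counts2.sum()
        assert abs(total1 - total2) / max(total1, total2) < 0.10

    def test_out_of_range_events_rejected(self):
        topo = build_topology(2, 2, cluster_size=4)
        bad_time = SpikeTrainSet(np.array([0]), np.array([50.0]),
                                 duration=100.0, dt=1.0, n_neurons=8)
        with pytest.raises(ValueError):
            simulate(topo, bad_time, duration=20.0, dt=1.0)
        bad_neuron = SpikeTrainSet(np.array([99]), np.array([5.0]),
                                   duration=100.0, dt=1.0, n_neurons=100)
        with pytest.raises(ValueError):
            simulate(topo, bad_neuron, duration=100.0, dt=1.0)

    def test_spikey_preset_ln_mediated_wta(self):
        topo = build_topology(2, 2, preset="spikey")
        cluster_w = np.array([[0.5, 0.0], [0.0, 0.5]])
        topo.set_plastic_weights(expand_cluster_weights(cluster_w, 7, 8))
        trains = _drive_trains({0: 70.0}, 6, 1000.0, 1.0, seed=5, n_channels=2)
        rec = simulate(topo, trains, 1000.0, 1.0, record=("AN", "LN_AN"))
        counts = cluster_spike_counts(rec.spikes["AN"], topo.an_partition())
        assert counts[0] > counts[1]
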