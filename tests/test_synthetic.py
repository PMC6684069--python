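"""Generator: architectures, phase dynamics, burst rendering, cut design."""

import numpy as np
import pytest

from cpgnet.architectures import three_segment_architecture, two_segment_architecture
from cpgnet.synthetic import (
    GroundTruthNetwork,
    SimulationParams,
    burst_envelope,
    make_architecture_network,
    make_cut_condition,
    phases_to_recording,
    simulate_phases,
    simulate_recording,
    true_burst_onsets,
)


class TestArchitectures:
    @pytest.mark.parametrize(
        "arch_id,n_edges",
        [(1, 12), (2, 8), (3, 8), (4, 8), (5, 4), (6, 4), (7, 0)],
    )
    def test_two_segment_edge_counts(self, arch_id, n_edges):
        arch = two_segment_architecture(arch_id)
        assert arch.n_connections == n_edges

    @pytest.mark.parametrize("arch_id,n_edges", [(1, 14), (2, 18), (3, 18), (4, 16)])
    def test_three_segment_edge_counts(self, arch_id, n_edges):
        arch = three_segment_architecture(arch_id)
        assert arch.n_connections == n_edges

    def test_eight_shaped_edge_set(self):
        """The circular/eight-shaped model: contralateral within each segment
        plus ipsilateral between segments, all bidirectional."""
        arch = two_segment_architecture(2)
        idx = {lab: k for k, lab in enumerate(arch.labels)}
        expected = set()
        for a, b in [("meso_L", "meso_R"), ("meta_L", "meta_R"),
                     ("meso_L", "meta_L"), ("meso_R", "meta_R")]:
            expected.add((idx[a], idx[b]))
            expected.add((idx[b], idx[a]))
        assert set(arch.edges()) == expected

    def test_hind_to_front_feedback_is_unidirectional(self):
        arch = three_segment_architecture(4)
        idx = {lab: k for k, lab in enumerate(arch.labels)}
        assert arch.mask_A[idx["pro_L"], idx["meta_L"]]
        assert not arch.mask_A[idx["meta_L"], idx["pro_L"]]

    def test_unknown_id_names_valid_range(self):
        with pytest.raises(ValueError, match="1-7"):
            two_segment_architecture(9)
        with pytest.raises(ValueError, match="1-4"):
            three_segment_architecture(0)

    def test_network_from_architecture(self):
        net = make_architecture_network(2, 2, {"intra": 0.3, "inter": 0.2, "diag": 0.1})
        assert np.count_nonzero(net.coupling) == 8
        # strengths assigned per edge class
        assert sorted(set(np.round(net.coupling[net.coupling != 0], 6))) == [0.2, 0.3]

    def test_unconnected_network_is_all_zero(self):
        net = make_architecture_network(7, 2, 0.5)
        assert not net.coupling.any()

    def test_inhibitory_sign_constraint(self):
        net = make_architecture_network(2, 2, 0.3, sign="inhibitory")
        assert (net.coupling[net.coupling != 0] < 0).all()
        with pytest.raises(ValueError, match="excitatory"):
            GroundTruthNetwork(
                labels=["meso_L", "meso_R"],
                coupling=np.array([[0, -0.1], [0.1, 0]]),
                intrinsic_freqs=np.array([0.2, 0.2]),
                sign="excitatory",
            )


class TestSimulateParamsValidation:
    def test_rejects_bad_duty(self):
        with pytest.raises(ValueError, match="burst_duty"):
            SimulationParams(burst_duty=1.2)

    def test_rejects_noninteger_sample_count(self):
        with pytest.raises(ValueError, match="integer"):
            SimulationParams(duration=100.0005, dt=0.001)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            SimulationParams(obs_noise_sd=float("nan"))


class TestPhaseDynamics:
    def test_uncoupled_noise_free_phase_is_exact(self):
        """Zero coupling, zero noise: phase is exactly 2*pi*f*t."""
        net = GroundTruthNetwork(
            labels=["meso_L", "meso_R"],
            coupling=np.zeros((2, 2)),
            intrinsic_freqs=np.array([0.2, 0.2]),
        )
        p = SimulationParams(duration=100.0, phase_noise_sd=0.0, init_phase_spread=0.0, seed=0)
        phases = simulate_phases(net, p)
        t = np.arange(p.n_samples) * p.dt
        assert np.allclose(phases[:, 0], 2 * np.pi * 0.2 * t, atol=1e-9)

    def test_seed_determinism(self):
        net = GroundTruthNetwork(
            labels=["meso_L", "meso_R"],
            coupling=np.array([[0, 0.5], [0.5, 0]]),
            intrinsic_freqs=np.array([0.2, 0.22]),
        )
        p = SimulationParams(duration=50.0, seed=7)
        a = simulate_phases(net, p)
        b = simulate_phases(net, p)
        assert np.array_equal(a, b)

    def test_strong_coupling_locks(self):
        """K = 2 symmetric coupling: the pairwise phase difference locks;
        circular variance over the second half stays tiny."""
        net = GroundTruthNetwork(
            labels=["meso_L", "meso_R"],
            coupling=np.array([[0, 2.0], [2.0, 0]]),
            intrinsic_freqs=np.array([0.2, 0.2]),
        )
        p = SimulationParams(duration=500.0, phase_noise_sd=0.1, seed=5)
        phases = simulate_phases(net, p)
        diff = phases[p.n_samples // 2 :, 0] - phases[p.n_samples // 2 :, 1]
        circ_var = 1 - np.abs(np.exp(1j * diff).mean())
        assert circ_var < 0.05

    def test_lock_state_stable_under_finer_integration(self):
        """Halving dt twice leaves the locked difference unchanged to ~1e-2 rad."""
        net = GroundTruthNetwork(
            labels=["meso_L", "meso_R"],
            coupling=np.array([[0, 2.0], [2.0, 0]]),
            intrinsic_freqs=np.array([0.2, 0.2]),
        )
        diffs = []
        for dt in (0.001, 0.0001):
            p = SimulationParams(duration=200.0, dt=dt, phase_noise_sd=0.0,
                                 init_phase_spread=1.0, seed=9)
            ph = simulate_phases(net, p)
            diffs.append(ph[-1, 0] - ph[-1, 1])
        assert abs(diffs[0] - diffs[1]) < 1e-2


class TestBurstRendering:
    def test_zero_amplitude_recording_is_silent(self):
        net = GroundTruthNetwork(
            labels=["meso_L"], coupling=np.zeros((1, 1)), intrinsic_freqs=np.array([0.2])
        )
        p = SimulationParams(duration=20.0, burst_amplitude=0.0, obs_noise_sd=0.0, seed=0)
        phases = simulate_phases(net, p)
        rec = phases_to_recording(phases, p, net.labels)
        assert not rec.channels["meso_L"].any()

    def test_burst_envelope_count_matches_frequency(self):
        """0.2 Hz for 100 s with zero initial phase: exactly 20 envelopes."""
        net = GroundTruthNetwork(
            labels=["meso_L"], coupling=np.zeros((1, 1)), intrinsic_freqs=np.array([0.2])
        )
        p = SimulationParams(duration=100.0, phase_noise_sd=0.0, init_phase_spread=0.0,
                             burst_duty=0.4, seed=0)
        phases = simulate_phases(net, p)
        onsets = true_burst_onsets(phases, p.dt, p.burst_duty)[0]
        assert len(onsets) == 20
        env = burst_envelope(phases[:, 0], p.burst_duty)
        n_envelopes = np.count_nonzero(np.diff(env.astype(int)) == 1) + int(env[0])
        assert n_envelopes == 20

    def test_burst_count_near_duration_times_freq(self):
        net = GroundTruthNetwork(
            labels=["meso_L"], coupling=np.zeros((1, 1)), intrinsic_freqs=np.array([0.25])
        )
        p = SimulationParams(duration=160.0, phase_noise_sd=0.0, seed=4)
        phases = simulate_phases(net, p)
        n = len(true_burst_onsets(phases, p.dt, p.burst_duty)[0])
        assert abs(n - int(160 * 0.25)) <= 1

    def test_small_unit_event_count_is_poisson(self):
        """Event count lands within 3*sqrt(lambda) of rate*duration."""
        net = GroundTruthNetwork(
            labels=["meso_L"], coupling=np.zeros((1, 1)), intrinsic_freqs=np.array([0.2])
        )
        p = SimulationParams(duration=100.0, obs_noise_sd=0.0,
                             small_unit_amplitude_ratio=0.15, small_unit_rate=1.0, seed=12)
        phases = simulate_phases(net, p)
        rec = phases_to_recording(phases, p, net.labels)
        lam = 100.0
        n_events = rec.meta["n_small_unit_events"]["meso_L"]
        assert abs(n_events - lam) <= 3 * np.sqrt(lam)

    def test_contamination_absent_when_ratio_zero(self):
        net = GroundTruthNetwork(
            labels=["meso_L"], coupling=np.zeros((1, 1)), intrinsic_freqs=np.array([0.2])
        )
        p = SimulationParams(duration=50.0, burst_amplitude=0.0, obs_noise_sd=0.0,
                             small_unit_amplitude_ratio=0.0, small_unit_rate=5.0, seed=2)
        phases = simulate_phases(net, p)
        rec = phases_to_recording(phases, p, net.labels)
        assert not rec.channels["meso_L"].any()

    def test_recording_determinism(self, locked_pair):
        net, params, rec, _ = locked_pair
        rec2, _ = simulate_recording(net, params)
        for lab in rec.labels:
            assert np.array_equal(rec.channels[lab], rec2.channels[lab])


class TestCutCondition:
    def _net(self):
        return make_architecture_network(2, 2, {"intra": 0.3, "inter": 0.2, "diag": 0.1})

    def test_trial2_loses_intersegmental_edges(self):
        net = self._net()
        p = SimulationParams(duration=50.0, seed=1)
        _, _, net2 = make_cut_condition(net, p)
        assert np.count_nonzero(net2.coupling) == 4  # intrasegmental only
        for i, j in zip(*np.nonzero(net2.coupling)):
            seg_i, seg_j = net2.labels[i].split("_")[0], net2.labels[j].split("_")[0]
            assert seg_i == seg_j

    def test_compensation_rescales_intrasegmental(self):
        net = self._net()
        p = SimulationParams(duration=50.0, seed=1)
        _, _, net2 = make_cut_condition(net, p, compensation={"meso": 2.0})
        idx = {lab: k for k, lab in enumerate(net2.labels)}
        assert net2.coupling[idx["meso_L"], idx["meso_R"]] == pytest.approx(0.6)
        assert net2.coupling[idx["meta_L"], idx["meta_R"]] == pytest.approx(0.3)

    def test_single_segment_network_rejected(self):
        net = GroundTruthNetwork(
            labels=["meso_L", "meso_R"],
            coupling=np.array([[0, 0.3], [0.3, 0]]),
            intrinsic_freqs=np.array([0.2, 0.2]),
        )
        with pytest.raises(ValueError, match="two segments"):
            make_cut_condition(net, SimulationParams(duration=10.0, seed=0))
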