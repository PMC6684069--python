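"""Cross-spectra, linear node model, evidence bookkeeping, BMS algebra."""

import numpy as np
import pytest
from scipy import signal

from cpgnet.architectures import two_segment_architecture
from cpgnet.bms import BMSResult, bms, connection_class, summarize_strengths
from cpgnet.csd import CrossSpectrum, empirical_csd
from cpgnet.fitting import DegenerateDataError, ModelFit, Priors, fit_model
from cpgnet.linear_model import (
    NodeParams,
    UnstableModelError,
    discretize,
    drift_matrix,
    innovation_covariance,
    model_csd,
    simulate_linear,
    stability_margin,
)
from cpgnet.recording import Recording


def two_node_params(gamma=1.0):
    return NodeParams(
        gamma=np.array([gamma, 1.2 * gamma]),
        omega=2 * np.pi * np.array([0.2, 0.22]),
        q=np.array([0.5, 0.4]),
        sigma_obs_sq=0.01,
    )


class TestEmpiricalCSD:
    def test_duplicated_channel_coherence_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(24_000)
        rec = Recording(rate=200.0, channels={"meso_L": x, "meso_R": x.copy()},
                        stage="preprocessed")
        S = empirical_csd(rec)
        coh = S.coherence()[:, 0, 1]
        assert np.allclose(coh, 1.0, atol=1e-10)

    def test_independent_noise_coherence_small(self):
        rng = np.random.default_rng(1)
        n = 120_000  # 600 s at 200 Hz
        rec = Recording(
            rate=200.0,
            channels={"meso_L": rng.standard_normal(n), "meso_R": rng.standard_normal(n)},
            stage="preprocessed",
        )
        S = empirical_csd(rec)
        assert S.coherence()[:, 0, 1].mean() < 0.15

    def test_common_sine_coherent_at_its_frequency(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 600.0, 1 / 200.0)
        s = np.sin(2 * np.pi * 0.2 * t)
        rec = Recording(
            rate=200.0,
            channels={"meso_L": s + 0.1 * rng.standard_normal(len(t)),
                      "meso_R": s + 0.1 * rng.standard_normal(len(t))},
            stage="preprocessed",
        )
        S = empirical_csd(rec)
        k = np.argmin(np.abs(S.freqs - 0.2))
        assert S.coherence()[k, 0, 1] > 0.9

    def test_matches_scipy_csd(self):
        """Same segmentation/window/scaling as scipy.signal.csd (scipy
        computes conj(X) * Y, ours is X * conj(Y))."""
        rng = np.random.default_rng(3)
        n = 40_000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        rec = Recording(rate=200.0, channels={"meso_L": x, "meso_R": y},
                        stage="preprocessed")
        S = empirical_csd(rec, seg_len=20.0)
        f_sc, P = signal.csd(x, y, fs=200.0, nperseg=4000, window="hann",
                             detrend="constant")
        band = (f_sc >= 0.05) & (f_sc <= 2.0)
        assert np.allclose(S.S[:, 0, 1], P[band].conj(), rtol=1e-8, atol=1e-12)

    def test_too_short_recording_rejected(self):
        rec = Recording(rate=200.0, channels={"meso_L": np.zeros(2000)},
                        stage="preprocessed")
        with pytest.raises(ValueError, match="too short"):
            empirical_csd(rec, seg_len=20.0)


class TestModelCSD:
    def test_zero_coupling_gives_zero_cross_terms(self):
        node = two_node_params()
        S = model_csd(node, np.zeros((2, 2)), np.linspace(0.05, 2, 40))
        off = S.S[:, 0, 1]
        assert np.allclose(off, 0.0, atol=1e-14)

    def test_hermitian_psd_everywhere(self):
        node = two_node_params()
        A = np.array([[0, 0.3], [0.2, 0]])
        S = model_csd(node, A, np.linspace(0.05, 2, 40)).S
        assert np.allclose(S, S.conj().transpose(0, 2, 1))
        for Sf in S:
            assert np.linalg.eigvalsh(Sf).min() >= -1e-12

    def test_unstable_model_rejected(self):
        node = NodeParams(gamma=np.array([0.1, 0.1]), omega=2 * np.pi * np.array([0.2, 0.2]),
                          q=np.array([0.5, 0.5]), sigma_obs_sq=0.01)
        A = np.array([[0, 2.0], [2.0, 0]])
        assert stability_margin(drift_matrix(node, A)) >= 0
        with pytest.raises(UnstableModelError, match="not stationary"):
            model_csd(node, A, np.linspace(0.05, 2, 10))

    def test_discretization_reaches_lyapunov_covariance(self):
        """Stationary covariance of the exact discretization solves the
        continuous Lyapunov equation (independent scipy oracle)."""
        from scipy.linalg import solve_continuous_lyapunov

        node = two_node_params()
        A = np.array([[0, 0.3], [0.2, 0]])
        M = drift_matrix(node, A)
        Q = innovation_covariance(node)
        Ad, Qd = discretize(M, Q, 0.005)
        P = solve_continuous_lyapunov(M, -Q)
        assert np.allclose(Ad @ P @ Ad.T + Qd, P, rtol=1e-8, atol=1e-10)

    def test_closed_form_matches_long_welch_estimate(self):
        """Monte-Carlo oracle: Welch CSD of a 1000 s sample path agrees
        with the closed form within 10% (Frobenius) at the peak."""
        node = two_node_params()
        A = np.array([[0, 0.5], [0.4, 0]])
        y = simulate_linear(node, A, duration=1000.0, rate=200.0, seed=8)
        rec = Recording(rate=200.0, channels={"meso_L": y[:, 0], "meso_R": y[:, 1]},
                        stage="preprocessed")
        emp = empirical_csd(rec)
        mod = model_csd(node, A, emp.freqs)
        k = np.argmax(mod.S[:, 0, 0].real)
        err = np.linalg.norm(emp.S[k] - mod.S[k]) / np.linalg.norm(mod.S[k])
        assert err < 0.10


class TestFitValidation:
    def test_zero_signal_data_rejected(self):
        freqs = np.linspace(0.05, 2, 20)
        S = CrossSpectrum(freqs=freqs, S=np.zeros((20, 2, 2), dtype=complex),
                          n_segments_avg=10)
        with pytest.raises(DegenerateDataError):
            Priors.from_spectrum(S, 2, 2)

    def test_channel_count_mismatch_rejected(self):
        freqs = np.linspace(0.05, 2, 20)
        S = CrossSpectrum(freqs=freqs, S=np.tile(np.eye(2), (20, 1, 1)).astype(complex),
                          n_segments_avg=10)
        with pytest.raises(ValueError, match="match"):
            fit_model(S, two_segment_architecture(2))


class TestBMS:
    def _fit(self, log_ev, arch_id=2, data_hash="abc"):
        arch = two_segment_architecture(arch_id)
        n = arch.n_nodes
        return ModelFit(
            architecture=arch, A_hat=np.zeros((n, n)),
            node_params=NodeParams(np.ones(n), np.ones(n), np.ones(n), 0.01),
            log_evidence=log_ev, theta=np.zeros(1), posterior_cov=np.eye(1),
            data_hash=data_hash,
        )

    def test_equal_evidences_split_posterior(self):
        res = bms([self._fit(0.0, 1), self._fit(0.0, 2)])
        assert np.allclose(res.posterior_prob, [0.5, 0.5])
        assert np.allclose(res.relative_log_evidence, [0.0, 0.0])

    def test_two_model_closed_form(self):
        """log B = 3 gives winner posterior 1/(1+e^-3) exactly."""
        res = bms([self._fit(10.0, 1), self._fit(13.0, 2)])
        assert res.winner == "2seg-2"
        assert res.posterior_prob[1] == pytest.approx(1 / (1 + np.exp(-3.0)), rel=1e-12)
        assert res.relative_log_evidence.min() == 0.0

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="identical data"):
            bms([self._fit(0.0, 1, "aaa"), self._fit(1.0, 2, "bbb")])


class TestStrengthSummary:
    def _fit_with(self, strengths_by_class):
        arch = two_segment_architecture(2)
        A = np.zeros((4, 4))
        for (i, j), cls in zip(arch.edges(), arch.edge_classes()):
            A[i, j] = strengths_by_class.get(
                connection_class(arch.labels[i], arch.labels[j]), 0.1
            )
        n = arch.n_nodes
        return ModelFit(
            architecture=arch, A_hat=A,
            node_params=NodeParams(np.ones(n), np.ones(n), np.ones(n), 0.01),
            log_evidence=0.0, theta=np.zeros(1), posterior_cov=np.eye(1),
            data_hash="x",
        )

    def test_mirror_directions_averaged(self):
        arch = two_segment_architecture(2)
        A = np.zeros((4, 4))
        idx = {lab: k for k, lab in enumerate(arch.labels)}
        A[idx["meso_R"], idx["meso_L"]] = 0.4  # L -> R
        A[idx["meso_L"], idx["meso_R"]] = 0.6  # R -> L
        fit = self._fit_with({})
        fit.A_hat = A
        fit.architecture = two_segment_architecture(6)  # intra only
        summary = summarize_strengths([fit], normalization="max_to_1")
        assert summary.per_fit.loc["meso-meso", "fit0"] == pytest.approx(0.5)

    def test_max_to_one_normalization(self):
        s = summarize_strengths(
            [self._fit_with({"meso-meso": 0.8, "meta-meta": 0.4, "meso-meta": 0.2})]
        )
        assert s.class_means.max() == pytest.approx(1.0)
        assert s.class_means["meso-meso"] == pytest.approx(1.0)
        assert s.class_means["meso-meta"] == pytest.approx(0.25)

    def test_reference_connection_normalization(self):
        s = summarize_strengths(
            [self._fit_with({"meso-meso": 0.5, "meta-meta": 0.4, "meso-meta": 0.2})],
            normalization="reference_connection", reference_class="meso-meso",
        )
        assert s.class_means["meso-meso"] == pytest.approx(1.0)
        assert s.class_means["meta-meta"] == pytest.approx(0.8)

    def test_all_zero_strengths_rejected(self):
        fit = self._fit_with({})
        fit.A_hat = np.zeros((4, 4))
        with pytest.raises(ValueError, match="[Nn]othing to normalize"):
            summarize_strengths([fit])

    def test_connection_classes(self):
        assert connection_class("meso_L", "meso_R") == "meso-meso"
        assert connection_class("meta_L", "meso_L") == "meso-meta"
        assert connection_class("pro_L", "meso_R") == "pro-meso-cross"
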