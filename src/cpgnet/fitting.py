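"""Fit the linear coupled model to empirical cross-spectra; Laplace evidence.

The generative model is z' = (A + uB) z at the node level (u = 0 for
trial 1, u = 1 for trial 2), embedded in damped stochastic oscillator
nodes whose stationary cross-spectral density is closed-form
(:mod:`cpgnet.linear_model`).  Fitting maximises a Gaussian log joint of
the vectorised real/imaginary CSD residuals -- with variances scaled by
the number of averaged Welch segments, a Whittle-style approximation --
plus Gaussian priors on log-parameters, via seeded multi-start
quasi-Newton optimisation.

Coupling strengths are parameterised as sign * exp(theta) so that a
connection the architecture allows never vanishes exactly; the prior
pulls unused connections toward a minimal strength instead.  The log
model evidence is the Laplace approximation

    log p(y|m) ~= log p(y|th^) + log p(th^) + (d/2) log 2pi
                  + (1/2) log det Sigma_post,

whose Occam term penalises parameters the data do not constrain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .architectures import ModelArchitecture
from .csd import CrossSpectrum
from .linear_model import NodeParams, drift_matrix, model_csd, stability_margin

DEFAULT_N_STARTS = 8
CHANGE_THRESHOLD = 70.0  # percent, reliable condition-change flag


class DegenerateDataError(ValueError):
    """Raised when the empirical spectrum carries no usable signal."""


class FitError(RuntimeError):
    """Raised when no optimisation start converges."""


@dataclass
class Priors:
    """Gaussian priors on the log-parameter vector, set from the data scale."""

    mu: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_spectrum(cls, S_emp: CrossSpectrum, n_nodes: int, n_edges: int,
                      n_edges_b: int = 0) -> "Priors":
        diag = np.diagonal(S_emp.S, axis1=1, axis2=2).real
        power = np.trapezoid(diag, S_emp.freqs, axis=0)  # band-limited variance
        mean_power = float(np.mean(power))
        if mean_power <= 0 or not np.isfinite(mean_power):
            raise DegenerateDataError("empirical spectrum has no power in the band")
        f_peak = float(S_emp.freqs[np.argmax(diag.mean(axis=1))])
        gamma0 = 1.0
        floor = float(np.median(diag[-max(2, len(S_emp.freqs) // 10):].mean(axis=1)))
        mu = np.concatenate([
            np.full(n_nodes, math.log(gamma0)),                  # log gamma
            np.full(n_nodes, math.log(2 * math.pi * f_peak)),    # log omega
            np.full(n_nodes, math.log(2 * gamma0 * mean_power)), # log q
            [math.log(max(floor, 1e-12 * mean_power))],          # log sigma_obs^2
            np.full(n_edges + n_edges_b, math.log(0.1 * gamma0)),
        ])
        sd = np.concatenate([
            np.full(n_nodes, 0.5),
            np.full(n_nodes, 0.3),
            np.full(n_nodes, 1.0),
            [1.5],
            np.full(n_edges + n_edges_b, 0.75),
        ])
        return cls(mu=mu, sd=sd)

    def log_pdf(self, theta: np.ndarray) -> float:
        z = (theta - self.mu) / self.sd
        return float(-0.5 * np.sum(z**2) - np.sum(np.log(self.sd)) - 0.5 * len(z) * math.log(2 * math.pi))


@dataclass
class ModelFit:
    """Posterior point estimate of one architecture on one data set."""

    architecture: ModelArchitecture
    A_hat: np.ndarray
    node_params: NodeParams
    log_evidence: float
    theta: np.ndarray
    posterior_cov: np.ndarray
    data_hash: str
    B_hat: np.ndarray | None = None
    n_starts_converged: int = 0
    neg_log_joint: float = math.nan
    meta: dict = field(default_factory=dict)

    @property
    def A_trial2(self) -> np.ndarray:
        if self.B_hat is None:
            raise ValueError("single-condition fit has no trial-2 coupling")
        return self.A_hat + self.B_hat

    def percent_changes(self) -> dict[tuple[int, int], float]:
        """Per-connection condition change, 100 * ((A+B)/A - 1)."""
        if self.B_hat is None:
            raise ValueError("single-condition fit has no condition changes")
        out = {}
        for i, j in self.architecture.edges():
            out[(i, j)] = 100.0 * (self.A_trial2[i, j] / self.A_hat[i, j] - 1.0)
        return out

    def reliable_changes(self, change_threshold: float = CHANGE_THRESHOLD) -> dict[tuple[int, int], float]:
        """Changes whose magnitude exceeds the reliable-change threshold (%)."""
        return {e: c for e, c in self.percent_changes().items()
                if abs(c) > change_threshold}

    def connection_changes(self) -> dict[tuple[str, str], float]:
        """Condition change per undirected connection (reporting unit).

        Both directions between a node pair are averaged before the
        percent change is taken, e.g. the left meso-meta connection is
        the mean of meso_L->meta_L and meta_L->meso_L.
        """
        if self.B_hat is None:
            raise ValueError("single-condition fit has no condition changes")
        labels = self.architecture.labels
        groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for i, j in self.architecture.edges():
            key = tuple(sorted((labels[i], labels[j])))
            groups.setdefault(key, []).append((i, j))
        out = {}
        for key, edges in groups.items():
            a1 = np.mean([abs(self.A_hat[e]) for e in edges])
            a2 = np.mean([abs(self.A_trial2[e]) for e in edges])
            out[key] = 100.0 * (a2 / a1 - 1.0)
        return out


def _unpack(theta: np.ndarray, n: int, edges: list, sign: float, two_condition: bool):
    gamma = np.exp(theta[:n])
    omega = np.exp(theta[n : 2 * n])
    q = np.exp(theta[2 * n : 3 * n])
    sigma_obs_sq = math.exp(theta[3 * n])
    E = len(edges)
    A = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        A[i, j] = sign * math.exp(theta[3 * n + 1 + k])
    node = NodeParams(gamma=gamma, omega=omega, q=q, sigma_obs_sq=sigma_obs_sq)
    if not two_condition:
        return node, A, None
    A2 = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        A2[i, j] = sign * math.exp(theta[3 * n + 1 + E + k])
    return node, A, A2


def _residual_weights(S_emp: CrossSpectrum) -> np.ndarray:
    """Variance of each real/imag residual entry under the Whittle approximation.

    Diagonal entries: Var(S_ii) = S_ii^2 / K.  Off-diagonal real and
    imaginary parts: S_ii * S_jj / (2K) each.  Empirical diagonals --
    lightly smoothed across frequency to decorrelate the weights from
    the bin-level estimation noise -- are used, held fixed during
    optimisation.
    """
    from scipy.ndimage import uniform_filter1d

    diag = np.diagonal(S_emp.S, axis1=1, axis2=2).real
    if len(S_emp.freqs) >= 5:
        diag = uniform_filter1d(diag, size=5, axis=0, mode="nearest")
    diag = np.maximum(diag, 1e-12 * diag.max())
    K = S_emp.n_segments_avg
    n = S_emp.n_channels
    var = np.empty((len(S_emp.freqs), n, n))
    var[:] = diag[:, :, None] * diag[:, None, :] / (2 * K)
    idx = np.arange(n)
    var[:, idx, idx] = diag**2 / K
    return var


class _Objective:
    """Negative log joint of one (or a pair of) cross-spectra."""

    def __init__(self, spectra: list[CrossSpectrum], arch: ModelArchitecture, priors: Priors):
        self.spectra = spectra
        self.arch = arch
        self.priors = priors
        self.edges = arch.edges()
        self.sign = arch.sign_value
        self.n = arch.n_nodes
        self.two_condition = len(spectra) == 2
        self.var = [_residual_weights(S) for S in spectra]
        self.iu = np.triu_indices(self.n)
        self.off = self.iu[0] != self.iu[1]
        # Gaussian normalisation constants (parameter independent)
        self.const = 0.0
        for v in self.var:
            vu = v[:, self.iu[0], self.iu[1]]
            self.const += 0.5 * float(np.sum(np.log(2 * math.pi * vu)))
            self.const += 0.5 * float(np.sum(np.log(2 * math.pi * vu[:, self.off])))

    def neg_log_lik(self, theta: np.ndarray) -> float:
        node, A, A2 = _unpack(theta, self.n, self.edges, self.sign, self.two_condition)
        couplings = [A] if not self.two_condition else [A, A2]
        total = self.const
        for S_emp, var, Ak in zip(self.spectra, self.var, couplings):
            M = drift_matrix(node, Ak)
            margin = stability_margin(M)
            if margin >= -1e-6:
                return 1e8 * (1.0 + max(margin, 0.0))
            S_mod = model_csd(node, Ak, S_emp.freqs).S
            r = S_emp.S - S_mod
            ru = r[:, self.iu[0], self.iu[1]]
            vu = var[:, self.iu[0], self.iu[1]]
            total += 0.5 * float(np.sum(ru.real**2 / vu))
            total += 0.5 * float(np.sum(ru.imag[:, self.off] ** 2 / vu[:, self.off]))
        return total

    def __call__(self, theta: np.ndarray) -> float:
        nll = self.neg_log_lik(theta)
        if nll >= 1e7:  # stability penalty region: skip prior to keep the cliff monotone
            return nll
        return nll - self.priors.log_pdf(theta)


def _hessian(f, x0: np.ndarray, step: float = 1e-3) -> np.ndarray:
    d = len(x0)
    H = np.empty((d, d))
    h = step * np.maximum(1.0, np.abs(x0))
    f0 = f(x0)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = f(x0 + e)
        fm[i] = f(x0 - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h[i] * h[j]
            )
    return H


def _laplace_evidence(obj: _Objective, theta: np.ndarray) -> tuple[float, np.ndarray]:
    H = _hessian(obj, theta)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    # the prior contributes at least its own precision in every direction,
    # so smaller eigenvalues are finite-difference artifacts
    prior_prec = 1.0 / obj.priors.sd**2
    w = np.maximum(w, prior_prec.min())
    cov = (V / w) @ V.T
    log_det_cov = float(-np.sum(np.log(w)))
    d = len(theta)
    log_ev = -obj(theta) + 0.5 * d * math.log(2 * math.pi) + 0.5 * log_det_cov
    return log_ev, cov


def fit_model(
    S_emp: CrossSpectrum,
    arch: ModelArchitecture,
    priors: Priors | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    maxiter: int = 200,
) -> ModelFit:
    """Fit one architecture to one empirical cross-spectrum.

    Multi-start L-BFGS-B on the negative log joint; the best converged
    start is kept (ties broken first-found).  Raises
    :class:`DegenerateDataError` on zero-signal data and
    :class:`FitError` when every start fails.
    """
    if arch.n_nodes != S_emp.n_channels:
        raise ValueError("architecture node count must match channel count")
    edges = arch.edges()
    if priors is None:
        priors = Priors.from_spectrum(S_emp, arch.n_nodes, len(edges))
    obj = _Objective([S_emp], arch, priors)
    theta, n_ok, nlj = _optimize(obj, priors, n_starts, seed, maxiter)
    log_ev, cov = _laplace_evidence(obj, theta)
    node, A, _ = _unpack(theta, arch.n_nodes, edges, arch.sign_value, False)
    return ModelFit(
        architecture=arch, A_hat=A, node_params=node, log_evidence=log_ev,
        theta=theta, posterior_cov=cov, data_hash=S_emp.data_hash(),
        n_starts_converged=n_ok, neg_log_joint=nlj,
    )


def fit_condition_change(
    S_trial1: CrossSpectrum,
    S_trial2: CrossSpectrum,
    arch: ModelArchitecture,
    priors: Priors | None = None,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    maxiter: int = 300,
) -> ModelFit:
    """Joint two-condition fit: trial 1 uses A, trial 2 uses A + B.

    Node parameters are shared between conditions; every connection of
    the architecture is allowed to change (mask_B = mask_A, no prior
    information on which connections changed).  ``B_hat`` is the fitted
    trial-2 minus trial-1 coupling.
    """
    if not np.array_equal(S_trial1.freqs, S_trial2.freqs):
        raise ValueError("trial spectra must share one frequency grid")
    if arch.n_nodes != S_trial1.n_channels:
        raise ValueError("architecture node count must match channel count")
    edges = arch.edges()
    if priors is None:
        priors = Priors.from_spectrum(S_trial1, arch.n_nodes, len(edges), n_edges_b=len(edges))
    obj = _Objective([S_trial1, S_trial2], arch, priors)
    theta, n_ok, nlj = _optimize(obj, priors, n_starts, seed, maxiter)
    log_ev, cov = _laplace_evidence(obj, theta)
    node, A, A2 = _unpack(theta, arch.n_nodes, edges, arch.sign_value, True)
    return ModelFit(
        architecture=arch, A_hat=A, B_hat=A2 - A, node_params=node,
        log_evidence=log_ev, theta=theta, posterior_cov=cov,
        data_hash=S_trial1.data_hash() + "+" + S_trial2.data_hash(),
        n_starts_converged=n_ok, neg_log_joint=nlj,
    )


def _optimize(obj: _Objective, priors: Priors, n_starts: int, seed: int, maxiter: int):
    rng = np.random.default_rng(seed)
    bounds = list(zip(priors.mu - 6 * priors.sd, priors.mu + 6 * priors.sd))
    best = None
    n_ok = 0
    for s in range(n_starts):
        x0 = priors.mu.copy()
        if s > 0:
            x0 = x0 + 0.5 * priors.sd * rng.standard_normal(len(x0))
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter * (len(x0) + 1)},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e7:
            continue
        n_ok += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None:
        raise FitError(
            f"optimizer failed to converge in {n_starts} starts "
            f"(architecture {obj.arch.id}); data may be degenerate"
        )
    return best.x, n_ok, float(best.fun)
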