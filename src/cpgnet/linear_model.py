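"""Linear stochastic node model with closed-form cross-spectral densities.

Each CPG node is a damped stochastic oscillator: two latent states with
drift block ``[[-gamma, -omega], [omega, -gamma]]`` (eigenvalues
``-gamma +/- i*omega``) driven by white noise of intensity q on both
states.  Directed coupling ``A[i, j]`` feeds the activity (first state)
of node j into the activity derivative of node i, so the full latent
drift is ``M = blockdiag(nodes) + embed(A)`` and the observed channels
are the node activities plus white observation noise:

    dx = M x dt + dW,   Cov(dW) = Q dt,      y = G x + e.

For a stable M the stationary cross-spectral density is closed-form
(one-sided convention, matching Welch estimates):

    S(f) = 2 G (i 2 pi f I - M)^-1 Q (-i 2 pi f I - M^T)^-1 G^T + sigma_obs^2 I.  The
same system can be simulated exactly (matrix-exponential discretization)
to provide an independent Monte-Carlo oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .csd import CrossSpectrum


class UnstableModelError(ValueError):
    """Latent drift matrix has an eigenvalue with non-negative real part."""


@dataclass
class NodeParams:
    """Per-node dynamics: damping gamma (1/s), angular frequency omega
    (rad/s), innovation intensity q (units^2/s); shared observation
    noise variance sigma_obs_sq (units^2 per sample bandwidth)."""

    gamma: np.ndarray
    omega: np.ndarray
    q: np.ndarray
    sigma_obs_sq: float

    @property
    def n_nodes(self) -> int:
        return len(self.gamma)


def drift_matrix(node: NodeParams, A: np.ndarray) -> np.ndarray:
    """Assemble the 2n x 2n latent drift M from node params and coupling A."""
    n = node.n_nodes
    M = np.zeros((2 * n, 2 * n))
    for i in range(n):
        M[2 * i, 2 * i] = -node.gamma[i]
        M[2 * i + 1, 2 * i + 1] = -node.gamma[i]
        M[2 * i, 2 * i + 1] = -node.omega[i]
        M[2 * i + 1, 2 * i] = node.omega[i]
    A = np.asarray(A, dtype=float)
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] != 0:
                M[2 * i, 2 * j] += A[i, j]
    return M


def observation_matrix(n: int) -> np.ndarray:
    """G: picks the activity (first latent state) of each node."""
    G = np.zeros((n, 2 * n))
    G[np.arange(n), 2 * np.arange(n)] = 1.0
    return G


def innovation_covariance(node: NodeParams) -> np.ndarray:
    return np.repeat(node.q, 2) * np.eye(2 * node.n_nodes)


def stability_margin(M: np.ndarray) -> float:
    """Largest real part of the eigenvalues of M (negative = stable)."""
    return float(np.max(np.linalg.eigvals(M).real))


def model_csd(node: NodeParams, A: np.ndarray, freqs: np.ndarray) -> CrossSpectrum:
    """Closed-form stationary CSD of the linear model on a frequency grid.

    Hermitian positive semidefinite at every frequency; off-diagonals are
    exactly zero when the coupling is zero.  Raises
    :class:`UnstableModelError` when M is not stable (no stationary
    spectrum exists).
    """
    freqs = np.asarray(freqs, dtype=float)
    n = node.n_nodes
    M = drift_matrix(node, A)
    lam, V = np.linalg.eig(M)
    if np.max(lam.real) >= 0:
        raise UnstableModelError("model not stationary: drift matrix has unstable eigenvalue")
    G = observation_matrix(n)
    W = G @ V                      # (n, 2n)
    U = np.linalg.solve(V, np.repeat(np.sqrt(node.q), 2)[:, None] * np.eye(2 * n))
    # T(f) = W diag(1/(i w - lam)) U has S = T T^H (Q absorbed into U)
    iw = 2j * np.pi * freqs[:, None]
    D = 1.0 / (iw - lam[None, :])  # (nf, 2n)
    T = np.einsum("mk,fk,kl->fml", W, D, U)
    # one-sided density: 2x the two-sided value at positive frequencies
    S = 2.0 * (T @ T.conj().transpose(0, 2, 1))
    S += node.sigma_obs_sq * np.eye(n)
    # symmetrize away rounding
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return CrossSpectrum(freqs=freqs, S=S, n_segments_avg=np.inf)


def discretize(M: np.ndarray, Q: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact discretization (Van Loan): x_{k+1} = Ad x_k + w_k, Cov(w) = Qd."""
    d = M.shape[0]
    blk = np.zeros((2 * d, 2 * d))
    blk[:d, :d] = -M
    blk[:d, d:] = Q
    blk[d:, d:] = M.T
    E = expm(blk * h)
    Ad = E[d:, d:].T
    Qd = Ad @ E[:d, d:]
    return Ad, 0.5 * (Qd + Qd.T)


def simulate_linear(
    node: NodeParams,
    A: np.ndarray,
    duration: float,
    rate: float,
    seed: int,
    burn_in: float = 50.0,
) -> np.ndarray:
    """Sample path of the observed channels, shape (n_samples, n_nodes).

    Exact discretization at the output rate; a burn-in stretch is
    discarded so the sample is stationary.  The observation noise is
    white at the output rate with variance sigma_obs_sq * rate / 2
    (i.e. flat spectral density sigma_obs_sq, matching the closed form).
    """
    M = drift_matrix(node, A)
    if stability_margin(M) >= 0:
        raise UnstableModelError("cannot simulate an unstable model to stationarity")
    Q = innovation_covariance(node)
    h = 1.0 / rate
    Ad, Qd = discretize(M, Q, h)
    L = np.linalg.cholesky(Qd + 1e-15 * np.trace(Qd) * np.eye(len(Qd)))
    rng = np.random.default_rng(seed)
    n_burn = round(burn_in * rate)
    n_keep = round(duration * rate)
    n = node.n_nodes
    x = np.zeros(2 * n)
    out = np.empty((n_keep, n))
    zs = rng.standard_normal((n_burn + n_keep, 2 * n))
    for k in range(n_burn + n_keep):
        x = Ad @ x + L @ zs[k]
        if k >= n_burn:
            out[k - n_burn] = x[::2]
    if node.sigma_obs_sq > 0:
        out += np.sqrt(node.sigma_obs_sq * rate / 2) * rng.standard_normal(out.shape)
    return out
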