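"""Ground-truth coupled-oscillator generator for multichannel burst data.

Emulates pilocarpine-induced depressor motoneuron activity: each
hemisegmental CPG is a phase oscillator cycling at roughly 0.1-0.5 Hz,
weakly and directionally coupled to its neighbours through a
ground-truth adjacency, observed as a rectangular burst envelope gating
a fast carrier with additive noise and optional small-amplitude
tonic-unit contamination.

The phase dynamics are Kuramoto-type with Euler-Maruyama integration:

    dphi_i = [2 pi f_i + sum_j K_ij sin(phi_j - phi_i)] dt + sigma dW_i

``K[i, j]`` is the influence of node j on node i, matching the adjacency
convention used throughout the package.  The downstream analysis stages
never assume this functional form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .architectures import ModelArchitecture, architecture, edge_class
from .recording import Recording, parse_label

DEFAULT_CYCLE_FREQ = 0.2  # Hz -> ~5 s cycles
CARRIER_FREQ = 30.0  # Hz, fast oscillatory carrier inside each burst
SMALL_UNIT_KERNEL = 0.05  # s, width of one small-unit event


@dataclass
class GroundTruthNetwork:
    """Known coupling structure driving a simulation.

    ``coupling[i, j]`` is the directed influence of node j on node i
    (dimensionless phase-coupling gain); the diagonal is zero and all
    nonzero entries share the sign implied by ``sign``.
    """

    labels: list[str]
    coupling: np.ndarray
    intrinsic_freqs: np.ndarray
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.intrinsic_freqs = np.asarray(self.intrinsic_freqs, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        for lab in self.labels:
            parse_label(lab)
        if self.coupling.shape != (n, n):
            raise ValueError("coupling matrix shape must match labels")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be excitatory or inhibitory")
        nz = self.coupling[self.coupling != 0]
        want = 1.0 if self.sign == "excitatory" else -1.0
        if nz.size and np.any(np.sign(nz) != want):
            raise ValueError(f"nonzero couplings must all be {self.sign}")
        if self.intrinsic_freqs.shape != (n,) or np.any(self.intrinsic_freqs <= 0):
            raise ValueError("intrinsic_freqs must be positive, one per node")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def segments(self) -> list[str]:
        segs = []
        for lab in self.labels:
            seg = parse_label(lab)[0]
            if seg not in segs:
                segs.append(seg)
        return segs


@dataclass
class SimulationParams:
    """Knobs of the burst-recording generator (units in docstrings below).

    duration, dt in seconds; phase_noise_sd in rad/sqrt(s); burst_duty is
    the fraction of each cycle spent bursting; amplitudes in arbitrary
    units; small_unit_rate in events/s.  ``small_unit_amplitude_ratio``
    of 0 disables contamination.  ``init_phase_spread`` (radians) sets
    the width of the uniform initial-phase draw; 0 starts all nodes at
    phase zero.
    """

    duration: float = 600.0
    dt: float = 0.001
    phase_noise_sd: float = 0.1
    burst_duty: float = 0.4
    burst_amplitude: float = 1.0
    burst_amplitude_jitter: float = 0.05
    small_unit_amplitude_ratio: float = 0.0
    small_unit_rate: float = 1.0
    obs_noise_sd: float = 0.02
    init_phase_spread: float = 2 * math.pi
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "dt", "phase_noise_sd", "burst_duty", "burst_amplitude",
                     "small_unit_amplitude_ratio", "small_unit_rate", "obs_noise_sd",
                     "burst_amplitude_jitter", "init_phase_spread"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.burst_duty < 1:
            raise ValueError("burst_duty must lie in (0, 1)")
        if not 0 <= self.small_unit_amplitude_ratio < 1:
            raise ValueError("small_unit_amplitude_ratio must lie in [0, 1)")
        n_steps = self.duration / self.dt
        if abs(n_steps - round(n_steps)) > 1e-6:
            raise ValueError("duration/dt must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return round(self.duration / self.dt)

    @property
    def rate(self) -> float:
        return 1.0 / self.dt


def make_architecture_network(
    architecture_id: int,
    n_segments: int,
    strengths: dict[str, float] | float,
    seed: int = 0,
    segments: tuple[str, ...] | None = None,
    base_freq: float = DEFAULT_CYCLE_FREQ,
    freq_jitter_sd: float = 0.005,
    sign: str = "excitatory",
) -> GroundTruthNetwork:
    """Ground-truth network with the edge set of a model-space architecture.

    ``strengths`` is either one number for every connection or a map from
    edge class (``intra``/``inter``/``diag``) to coupling gain.  Intrinsic
    cycle frequencies are ``base_freq`` plus a small seeded per-node
    jitter (Hz), emulating slightly detuned segmental rhythms.
    """
    kwargs = {"sign": sign}
    if segments is not None:
        kwargs["segments"] = segments
    arch = architecture(architecture_id, n_segments, **kwargs)
    if not isinstance(strengths, dict):
        strengths = {cls: float(strengths) for cls in ("intra", "inter", "diag")}
    coupling = np.zeros((arch.n_nodes, arch.n_nodes))
    for (i, j), cls in zip(arch.edges(), arch.edge_classes()):
        try:
            s = strengths[cls]
        except KeyError as exc:
            raise ValueError(f"no strength given for edge class {cls!r}") from exc
        coupling[i, j] = arch.sign_value * abs(float(s))
    rng = np.random.default_rng(seed)
    freqs = base_freq + freq_jitter_sd * rng.standard_normal(arch.n_nodes)
    return GroundTruthNetwork(
        labels=arch.labels, coupling=coupling, intrinsic_freqs=freqs, sign=sign
    )


def simulate_phases(network: GroundTruthNetwork, params: SimulationParams) -> np.ndarray:
    """Integrate the coupled phase oscillators; returns (n_samples, n_nodes) radians.

    Unwrapped phases, monotone non-decreasing when coupling and noise are
    weak relative to the intrinsic angular velocity.  Identical
    (network, params) give bitwise-identical output.
    """
    if not np.all(np.isfinite(network.coupling)):
        raise ValueError("coupling matrix contains non-finite values")
    rng = np.random.default_rng(params.seed)
    n_steps, n = params.n_samples, network.n_nodes
    dt = params.dt
    omega = 2 * math.pi * network.intrinsic_freqs
    # K > 0 attracts (in-phase lock); K < 0 repels (anti-phase lock)
    K = network.coupling
    phases = np.empty((n_steps, n))
    phi = rng.uniform(0.0, max(params.init_phase_spread, 0.0), size=n) if params.init_phase_spread > 0 else np.zeros(n)
    coupled = K.any()
    noise_scale = params.phase_noise_sd * math.sqrt(dt)
    noise = rng.standard_normal((n_steps - 1, n)) * noise_scale if params.phase_noise_sd > 0 else None
    for k in range(n_steps):
        phases[k] = phi
        if k == n_steps - 1:
            break
        drift = omega.copy()
        if coupled:
            drift += (K * np.sin(phi[None, :] - phi[:, None])).sum(axis=1)
        phi = phi + drift * dt
        if noise is not None:
            phi = phi + noise[k]
    return phases


def burst_envelope(phases: np.ndarray, duty: float) -> np.ndarray:
    """Boolean mask: burst active while the cycle fraction is below the duty."""
    return (np.mod(phases, 2 * math.pi) / (2 * math.pi)) < duty


def true_burst_onsets(phases: np.ndarray, dt: float, duty: float) -> list[np.ndarray]:
    """Ground-truth burst onset times per node: one per completed cycle.

    Onsets are the first times the running maximum of the phase reaches
    2*pi*k (the running maximum removes transient noise-induced
    backtracking across a cycle boundary, which only flickers the
    envelope edge without starting a new cycle).  A burst already active
    at t=0 counts as an onset at t=0.
    """
    out = []
    for phi in phases.T:
        mono = np.maximum.accumulate(phi)
        if np.mod(mono[0], 2 * math.pi) / (2 * math.pi) < duty:
            k0 = math.floor(mono[0] / (2 * math.pi))  # burst in progress at t=0
        else:
            k0 = math.ceil(mono[0] / (2 * math.pi))
        ks = np.arange(k0, math.floor(mono[-1] / (2 * math.pi)) + 1)
        idx = np.searchsorted(mono, np.maximum(ks * 2 * math.pi, mono[0]))
        out.append(idx * dt)
    return out


def phases_to_recording(
    phases: np.ndarray, params: SimulationParams, labels: list[str], meta: dict | None = None
) -> Recording:
    """Render phase trajectories as a raw burst recording.

    Each channel is a zero-mean 30 Hz carrier gated by the rectangular
    burst envelope, with a small per-cycle amplitude jitter, optional
    Poisson small-unit events (50 ms mini-bursts of amplitude
    ``small_unit_amplitude_ratio * burst_amplitude``) and additive
    Gaussian observation noise.
    """
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases contain non-finite values")
    n_steps, n = phases.shape
    if len(labels) != n:
        raise ValueError("one label per phase column required")
    # independent stream so the waveform rendering does not perturb the
    # phase integration draw for the same seed
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))
    t = np.arange(n_steps) * params.dt
    env = burst_envelope(phases, params.burst_duty)
    carrier_phase = rng.uniform(0, 2 * math.pi, size=n)
    channels = {}
    event_counts = {}
    for c, lab in enumerate(labels):
        carrier = np.sin(2 * math.pi * CARRIER_FREQ * t + carrier_phase[c])
        cycle = np.floor_divide(phases[:, c], 2 * math.pi).astype(np.int64)
        cycle -= cycle.min()
        amp_per_cycle = params.burst_amplitude * (
            1.0 + params.burst_amplitude_jitter * rng.standard_normal(cycle.max() + 1)
        )
        x = env[:, c] * amp_per_cycle[cycle] * carrier
        event_counts[lab] = 0
        if params.small_unit_amplitude_ratio > 0 and params.small_unit_rate > 0:
            train, n_events = _small_unit_train(rng, t, params)
            x = x + train
            event_counts[lab] = n_events
        if params.obs_noise_sd > 0:
            x = x + params.obs_noise_sd * rng.standard_normal(n_steps)
        channels[lab] = x
    meta = dict(meta or {})
    meta.setdefault("seed", params.seed)
    meta["n_small_unit_events"] = event_counts
    return Recording(rate=params.rate, channels=channels, stage="raw", meta=meta)


def _small_unit_train(
    rng: np.random.Generator, t: np.ndarray, params: SimulationParams
) -> tuple[np.ndarray, int]:
    """Poisson small-unit events: 50 ms carrier-filled mini-bursts."""
    duration = t[-1] + params.dt
    n_events = rng.poisson(params.small_unit_rate * duration)
    x = np.zeros_like(t)
    if n_events == 0:
        return x, 0
    onsets = np.sort(rng.uniform(0, duration - SMALL_UNIT_KERNEL, size=n_events))
    kern_n = round(SMALL_UNIT_KERNEL / params.dt)
    kern_t = np.arange(kern_n) * params.dt
    # half-sine envelope x carrier, peak amplitude = ratio x burst amplitude
    kern = (
        params.small_unit_amplitude_ratio
        * params.burst_amplitude
        * np.sin(math.pi * kern_t / SMALL_UNIT_KERNEL)
        * np.sin(2 * math.pi * CARRIER_FREQ * kern_t)
    )
    for onset in onsets:
        k0 = round(onset / params.dt)
        k1 = min(k0 + kern_n, len(t))
        x[k0:k1] += kern[: k1 - k0]
    return x, int(n_events)


def simulate_recording(
    network: GroundTruthNetwork, params: SimulationParams
) -> tuple[Recording, np.ndarray]:
    """Phases + rendering in one call; returns (recording, phases).

    The recording's meta holds the ground-truth coupling matrix, labels,
    intrinsic frequencies, seed and per-channel true burst counts.
    """
    phases = simulate_phases(network, params)
    onsets = true_burst_onsets(phases, params.dt, params.burst_duty)
    meta = {
        "ground_truth_coupling": network.coupling.tolist(),
        "labels": list(network.labels),
        "intrinsic_freqs": network.intrinsic_freqs.tolist(),
        "seed": params.seed,
        "true_burst_counts": {lab: len(o) for lab, o in zip(network.labels, onsets)},
    }
    rec = phases_to_recording(phases, params, network.labels, meta=meta)
    return rec, phases


def cut_intersegmental(network: GroundTruthNetwork, compensation: dict[str, float] | None = None) -> GroundTruthNetwork:
    """Copy of the network with all intersegmental couplings removed.

    ``compensation`` optionally rescales intrasegmental couplings per
    segment (e.g. ``{"meso": 2.0}``), emulating the post-cut increase in
    intrasegmental drive.
    """
    coupling = network.coupling.copy()
    n = network.n_nodes
    for i in range(n):
        for j in range(n):
            if i == j or coupling[i, j] == 0:
                continue
            cls = edge_class(network.labels[j], network.labels[i])
            if cls in ("inter", "diag"):
                coupling[i, j] = 0.0
            elif compensation:
                seg = parse_label(network.labels[i])[0]
                coupling[i, j] *= compensation.get(seg, 1.0)
    return GroundTruthNetwork(
        labels=list(network.labels), coupling=coupling,
        intrinsic_freqs=network.intrinsic_freqs.copy(), sign=network.sign,
    )


def make_cut_condition(
    network: GroundTruthNetwork,
    params: SimulationParams,
    compensation: dict[str, float] | None = None,
) -> tuple[Recording, Recording, GroundTruthNetwork]:
    """Two-condition design: intact network (trial 1) vs cut connectives (trial 2).

    Both trials are simulated with fresh child seeds derived from
    ``params.seed``; trial 2 uses the network with intersegmental
    couplings zeroed (and optional intrasegmental compensation).
    """
    if len(network.segments) < 2:
        raise ValueError("cut-connective design needs at least two segments")
    ss = np.random.SeedSequence(params.seed)
    seed1, seed2 = (int(s) % (2**31) for s in ss.generate_state(2))
    net2 = cut_intersegmental(network, compensation)
    rec1, _ = simulate_recording(network, replace(params, seed=seed1))
    rec2, _ = simulate_recording(net2, replace(params, seed=seed2))
    rec1.meta["condition"], rec2.meta["condition"] = "connected", "cut"
    return rec1, rec2, net2
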