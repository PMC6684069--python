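"""Instantaneous phase extraction from preprocessed burst recordings.

The chain is: analytic signal (Hilbert transform), Poincare-section
crossing detection in the complex plane to mark burst onsets, optional
k-means amplitude filtering to discard onsets produced by small tonic
units, and piecewise-linear phase interpolation between retained onsets.

Internally phase is unwrapped radians with the k-th retained onset
mapped to exactly 2*pi*k; divide by 2*pi for cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from sklearn.cluster import KMeans

DEGENERACY_RATIO = 0.6


class RhythmError(ValueError):
    """Raised when a channel carries no usable rhythm."""


@dataclass
class AnalyticSeries:
    """Discrete-time analytic signal X = X_r + i*X_i of one channel."""

    X_r: np.ndarray
    X_i: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if len(self.X_r) != len(self.X_i):
            raise ValueError("real and imaginary parts must have equal length")

    @property
    def complex(self) -> np.ndarray:
        return self.X_r + 1j * self.X_i

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.X_r)) / self.rate


@dataclass
class BurstOnsets:
    """Burst onset times with per-onset amplitude and a retained mask.

    ``amplitudes[k]`` is the peak |X| between onset k and the next
    crossing (or the end of the series for the last onset).  The
    ``retained`` mask is all-True until :func:`filter_small_units` runs.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    retained: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.retained is None:
            self.retained = np.ones(len(self.times), dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("onset times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("onset amplitudes must be positive")
        if not (len(self.times) == len(self.amplitudes) == len(self.retained)):
            raise ValueError("times, amplitudes and retained must align")

    @property
    def retained_times(self) -> np.ndarray:
        return self.times[self.retained]

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhaseSeries:
    """Unwrapped phase sampled on the recording grid.

    ``phi`` is NaN outside ``valid_span`` (first to last retained onset);
    inside it is non-decreasing and gains exactly 2*pi per retained cycle.
    """

    phi: np.ndarray
    rate: float
    valid_span: tuple[float, float]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.phi)) / self.rate

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.phi)


def analytic_signal(channel: np.ndarray, rate: float) -> AnalyticSeries:
    """Analytic signal via the Hilbert transform (FFT quadrature filter)."""
    x = np.asarray(channel, dtype=float)
    if len(x) < 8:
        raise ValueError("channel too short for an analytic signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("channel contains non-finite values")
    if np.max(np.abs(x)) == 0:
        raise RhythmError("no oscillation: channel is identically zero")
    X = hilbert(x)
    return AnalyticSeries(X_r=X.real, X_i=X.imag, rate=rate)


def detect_onsets(
    a: AnalyticSeries, section_angle: float = 0.0, edge_exclude: float = 0.0
) -> BurstOnsets:
    """Burst onsets as counter-clockwise crossings of a Poincare section.

    The section is the ray at ``section_angle`` (radians) from the origin
    of the analytic plane; a crossing is a sample step where the wrapped
    angle relative to the ray passes 0 from below while increasing.
    Crossing times are refined by linear interpolation of the wrapped
    angle.  ``edge_exclude`` seconds at each end are ignored (Hilbert
    edge artifacts).
    """
    X = a.complex
    theta = np.angle(X * np.exp(-1j * section_angle))  # in (-pi, pi]
    n = len(theta)
    k0 = int(round(edge_exclude * a.rate))
    k1 = n - k0
    if k1 - k0 < 2:
        raise RhythmError("rhythm too short after edge exclusion")
    th = theta[k0:k1]
    d = th[1:] - th[:-1]
    # upward zero crossing of the wrapped angle, excluding the -pi/pi wrap
    cross = np.flatnonzero((th[:-1] < 0) & (th[1:] >= 0) & (d > 0) & (d < np.pi))
    if len(cross) < 2:
        raise RhythmError("rhythm too short: fewer than two section crossings")
    frac = -th[cross] / d[cross]
    times = (k0 + cross + frac) / a.rate
    absX = np.abs(X)
    amps = np.empty(len(cross))
    bounds = np.append(k0 + cross, k1)
    for m in range(len(cross)):
        amps[m] = absX[bounds[m] : bounds[m + 1] + 1].max()
    return BurstOnsets(times=times, amplitudes=amps)


def filter_small_units(
    onsets: BurstOnsets, degeneracy_ratio: float = DEGENERACY_RATIO
) -> BurstOnsets:
    """Keep only large-amplitude onsets via 1-D k-means with k = 2.

    Clusters onset amplitudes into two groups (centroids initialised at
    the min and max amplitude, deterministic); the cluster with the
    larger centroid is retained.  If the centroids are too close
    (small/large ratio above ``degeneracy_ratio``) the split is declared
    degenerate: all onsets are retained and a warning is emitted.

    Onset times are never changed, only the retained mask.
    """
    if len(onsets) < 4:
        raise ValueError("need at least 4 onsets for amplitude clustering")
    amps = onsets.amplitudes.reshape(-1, 1)
    init = np.array([[amps.min()], [amps.max()]])
    if init[0, 0] == init[1, 0]:
        warnings.warn("all onset amplitudes equal; no small-unit cluster found")
        return BurstOnsets(onsets.times.copy(), onsets.amplitudes.copy())
    km = KMeans(n_clusters=2, init=init, n_init=1).fit(amps)
    centers = km.cluster_centers_.ravel()
    small, large = np.sort(centers)
    if small / large > degeneracy_ratio:
        warnings.warn(
            f"amplitude clusters not separable (centroid ratio {small / large:.2f}); "
            "retaining all onsets"
        )
        retained = np.ones(len(onsets), dtype=bool)
    else:
        retained = km.labels_ == int(np.argmax(centers))
    return BurstOnsets(onsets.times.copy(), onsets.amplitudes.copy(), retained)


def interpolate_phase(onsets: BurstOnsets, rate: float, n_samples: int) -> PhaseSeries:
    """Piecewise-linear unwrapped phase through the retained onsets.

    Between retained onsets k and k+1 the phase is
    ``2*pi*(k + (t - t_k)/(t_{k+1} - t_k))``; the k-th onset maps to
    exactly ``2*pi*k``.  Samples outside [first, last] retained onset
    are NaN.
    """
    t_on = onsets.retained_times
    if len(t_on) < 2:
        raise RhythmError("need at least two retained onsets to interpolate a phase")
    t = np.arange(n_samples) / rate
    cycles = np.arange(len(t_on), dtype=float)
    phi = 2 * np.pi * np.interp(t, t_on, cycles)
    phi[(t < t_on[0]) | (t > t_on[-1])] = np.nan
    return PhaseSeries(phi=phi, rate=rate, valid_span=(float(t_on[0]), float(t_on[-1])))


def extract_phase(
    channel: np.ndarray,
    rate: float,
    section_angle: float = 0.0,
    small_unit_filter: str = "auto",
    edge_exclude: float = 0.0,
) -> tuple[PhaseSeries, BurstOnsets]:
    """Full chain for one preprocessed channel.

    ``small_unit_filter``: ``"auto"`` applies k-means filtering with the
    degeneracy fallback, ``"on"`` forces it, ``"off"`` skips it.
    """
    a = analytic_signal(channel, rate)
    onsets = detect_onsets(a, section_angle=section_angle, edge_exclude=edge_exclude)
    if small_unit_filter not in ("auto", "on", "off"):
        raise ValueError("small_unit_filter must be auto, on or off")
    if small_unit_filter != "off" and len(onsets) >= 4:
        if small_unit_filter == "on":
            onsets = filter_small_units(onsets, degeneracy_ratio=1.0 + 1e-9)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                onsets = filter_small_units(onsets)
    phase = interpolate_phase(onsets, rate, len(channel))
    return phase, onsets
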