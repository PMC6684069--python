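"""Phase-connectivity (PC) analysis of channel pairs.

Two rhythms are called coupled on an interval when their phase
difference stays (nearly) constant there.  The statistic is the mean
resultant length of the phase differences,

    R = (1/T) | sum_j exp(i * (phi1(j) - phi2(j))) |,

ranging from 0 (random differences) to 1 (identical differences).  An
interval counts as coupled when (1) R in a 15 s gliding window exceeds
0.8 for at least 50 s (about 10 cycles), and (2) the R-vector of the
whole interval exceeds 0.3, which rejects slow drift that each short
window would miss.  The coupling likelihood of a pair is the summed
length of its coupled intervals divided by the total recording length;
pairs with no coupled interval score 0.

The PC approach is undirected: reports are invariant to pair order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .phase import PhaseSeries

R_WINDOW = 15.0  # s, gliding window
R_WINDOW_THRESHOLD = 0.8
MIN_DURATION = 50.0  # s, ~10 cycles at 5 s per cycle
INTERVAL_R_THRESHOLD = 0.3


@dataclass
class RVectorSeries:
    """Gliding-window R-vector trace; ``times`` are window centers."""

    window: float
    step: float
    times: np.ndarray
    R: np.ndarray
    T_per_window: int

    def __post_init__(self) -> None:
        if np.any((self.R < 0) | (self.R > 1 + 1e-12)):
            raise ValueError("R must lie in [0, 1]")


@dataclass
class CoupledInterval:
    start: float
    end: float
    interval_R: float
    mean_phase_diff: float  # circular mean, radians in [0, 2*pi)

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class CouplingReport:
    """Per-pair result: coupled intervals plus the coupling likelihood."""

    pair: tuple[str, str]
    intervals: list[CoupledInterval]
    likelihood: float
    total_time: float
    r_series: RVectorSeries | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "likelihood": self.likelihood,
            "total_time": self.total_time,
            "intervals": [
                {
                    "start": iv.start,
                    "end": iv.end,
                    "interval_R": iv.interval_R,
                    "mean_phase_diff": iv.mean_phase_diff,
                }
                for iv in self.intervals
            ],
        }


def r_vector(phase_diff: np.ndarray) -> float:
    """Mean resultant length of a series of phase differences (radians)."""
    d = np.asarray(phase_diff, dtype=float)
    if d.size == 0:
        raise ValueError("empty phase-difference series")
    if not np.all(np.isfinite(d)):
        raise ValueError("phase differences must be finite")
    return float(np.abs(np.exp(1j * d).mean()))


def circular_mean(phase_diff: np.ndarray) -> float:
    """Circular mean of phase differences, mapped to [0, 2*pi)."""
    return float(np.angle(np.exp(1j * np.asarray(phase_diff)).mean()) % (2 * np.pi))


def _common_span(phi1: PhaseSeries, phi2: PhaseSeries) -> tuple[float, float]:
    lo = max(phi1.valid_span[0], phi2.valid_span[0])
    hi = min(phi1.valid_span[1], phi2.valid_span[1])
    return lo, hi


def gliding_r(
    phi1: PhaseSeries, phi2: PhaseSeries, window: float = R_WINDOW, step: float = 1.0
) -> RVectorSeries:
    """R-vector of phi1 - phi2 in a gliding window over the common valid span."""
    if phi1.rate != phi2.rate or len(phi1.phi) != len(phi2.phi):
        raise ValueError("phase series must share sampling grid")
    rate = phi1.rate
    lo, hi = _common_span(phi1, phi2)
    if hi - lo < window:
        raise ValueError(
            f"common valid span ({hi - lo:.1f} s) shorter than the window ({window} s)"
        )
    diff = phi1.phi - phi2.phi
    w_n = round(window * rate)
    s_n = max(1, round(step * rate))
    k_lo, k_hi = int(np.ceil(lo * rate)), int(np.floor(hi * rate))
    starts = np.arange(k_lo, k_hi - w_n + 2, s_n)
    # windowed mean resultant via cumulative sums of the unit phasors
    z = np.exp(1j * diff[k_lo : k_hi + 1])
    cz = np.concatenate(([0.0 + 0.0j], np.cumsum(z)))
    s_rel = starts - k_lo
    R = np.abs(cz[s_rel + w_n] - cz[s_rel]) / w_n
    times = (starts + w_n / 2) / rate
    return RVectorSeries(window=window, step=s_n / rate, times=times, R=np.minimum(R, 1.0),
                         T_per_window=w_n)


def detect_coupled_intervals(
    r: RVectorSeries,
    phase_diff: np.ndarray,
    rate: float,
    r_window_threshold: float = R_WINDOW_THRESHOLD,
    min_duration: float = MIN_DURATION,
    interval_R_threshold: float = INTERVAL_R_THRESHOLD,
) -> list[CoupledInterval]:
    """Apply the two coupling criteria to a gliding R-vector trace.

    Maximal runs of windows with R above ``r_window_threshold`` whose
    outer span reaches ``min_duration`` become candidates; a candidate is
    accepted iff the R-vector of the whole interval (anti-drift
    criterion) exceeds ``interval_R_threshold``.  Accepted intervals are
    disjoint by construction.
    """
    above = r.R > r_window_threshold
    intervals: list[CoupledInterval] = []
    half = r.window / 2
    k = 0
    n = len(above)
    while k < n:
        if not above[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and above[j + 1]:
            j += 1
        start = r.times[k] - half
        end = r.times[j] + half
        if end - start >= min_duration:
            lo, hi = round(start * rate), round(end * rate)
            seg = phase_diff[lo : hi + 1]
            seg = seg[np.isfinite(seg)]
            R_whole = r_vector(seg)
            if R_whole > interval_R_threshold:
                intervals.append(
                    CoupledInterval(
                        start=start, end=end, interval_R=R_whole,
                        mean_phase_diff=circular_mean(seg),
                    )
                )
        k = j + 1
    return intervals


def coupling_likelihood(intervals: list[CoupledInterval], total_time: float) -> float:
    """Summed coupled-interval length divided by the total recording length."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if not intervals:
        return 0.0
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError("coupled intervals must be disjoint")
    for iv in ivs:
        if iv.start < -1e-9 or iv.end > total_time + 1e-9:
            raise ValueError("interval outside the recording span")
    return float(sum(iv.length for iv in ivs) / total_time)


def analyze_pair(
    phi1: PhaseSeries,
    phi2: PhaseSeries,
    labels: tuple[str, str],
    total_time: float,
    window: float = R_WINDOW,
    step: float = 1.0,
    r_window_threshold: float = R_WINDOW_THRESHOLD,
    min_duration: float = MIN_DURATION,
    interval_R_threshold: float = INTERVAL_R_THRESHOLD,
) -> CouplingReport:
    """Gliding R, interval detection and likelihood for one channel pair."""
    r = gliding_r(phi1, phi2, window=window, step=step)
    diff = phi1.phi - phi2.phi
    intervals = detect_coupled_intervals(
        r, diff, phi1.rate,
        r_window_threshold=r_window_threshold,
        min_duration=min_duration,
        interval_R_threshold=interval_R_threshold,
    )
    return CouplingReport(
        pair=tuple(sorted(labels)),
        intervals=intervals,
        likelihood=coupling_likelihood(intervals, total_time),
        total_time=total_time,
        r_series=r,
    )


@dataclass
class ClassComparison:
    class_a: str
    class_b: str
    t: float
    p: float
    significant: bool


def compare_connection_classes(
    likelihoods: dict[str, list[float]], alpha: float = 0.05
) -> list[ClassComparison]:
    """Pairwise Welch two-sample t-tests between connection classes.

    ``likelihoods`` maps a connection class (e.g. ``"meso-meso"``) to its
    per-animal values.  Raw p-values are reported without
    multiple-comparison correction.
    """
    for cls, vals in likelihoods.items():
        if len(vals) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 values for a t-test")
    out = []
    for a, b in combinations(likelihoods, 2):
        res = stats.ttest_ind(likelihoods[a], likelihoods[b], equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # both samples constant and equal
            t, p = 0.0, 1.0
        out.append(ClassComparison(a, b, t, p, bool(p < alpha)))
    return out
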