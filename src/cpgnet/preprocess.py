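"""Spike2-style preprocessing: DC removal, rectification, smoothing, decimation.

Per channel, in order: subtract the mean, take the absolute value,
centered moving-average smoothing, anti-aliased decimation to the target
rate (200 Hz by default), then a final mean re-subtraction so the output
is zero-mean.  The final re-subtraction matters downstream: the analytic
signal of a zero-mean rhythm encircles the origin, which is what makes
Poincare-section onset detection well defined.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .recording import Recording

TARGET_RATE = 200.0  # Hz
DEFAULT_SMOOTH = 0.05  # s


def preprocess(
    raw: Recording, smooth_window: float = DEFAULT_SMOOTH, target_rate: float = TARGET_RATE
) -> Recording:
    """DC-remove, rectify, smooth and downsample a raw recording.

    ``smooth_window`` is the width (s) of the centered moving average;
    it must span at least one input sample.  ``target_rate`` may not
    exceed the input rate (upsampling not supported).
    """
    if raw.stage != "raw":
        raise ValueError("preprocess expects a raw recording")
    if target_rate > raw.rate:
        raise ValueError("upsampling not supported: target_rate exceeds recording rate")
    if smooth_window < 1.0 / raw.rate:
        raise ValueError("smooth_window shorter than one input sample")

    win = max(1, round(smooth_window * raw.rate))
    ratio = Fraction(raw.rate / target_rate).limit_denominator(1000)
    channels = {}
    for label, x in raw.channels.items():
        y = np.abs(x - x.mean())
        y = uniform_filter1d(y, size=win, mode="nearest")
        y = _decimate(y, ratio)
        channels[label] = y - y.mean()

    meta = dict(raw.meta)
    meta["preprocess"] = {"smooth_window": smooth_window, "source_rate": raw.rate}
    return Recording(rate=target_rate, channels=channels, t0=raw.t0, stage="preprocessed", meta=meta)


def _decimate(x: np.ndarray, ratio: Fraction) -> np.ndarray:
    """Anti-aliased downsampling by a rational factor.

    Integer factors use a zero-phase FIR low-pass at 0.8x the target
    Nyquist followed by subsampling (output length ceil(n/q)); other
    factors fall back to polyphase resampling.
    """
    if ratio == 1:
        return x.copy()
    if ratio.denominator == 1:
        q = ratio.numerator
        # cutoff 0.8 * (Nyquist of target) expressed on the input scale
        taps = signal.firwin(8 * q + 1, 0.8 / q)
        y = signal.filtfilt(taps, [1.0], x, padlen=min(3 * len(taps), len(x) - 1))
        return y[::q]
    return signal.resample_poly(x, ratio.denominator, ratio.numerator)
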