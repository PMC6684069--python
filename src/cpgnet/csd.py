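"""Welch-style empirical cross-spectral density estimation.

Averaged periodograms over half-overlapping Hann-tapered segments,
restricted to the analysis band (0.05-2 Hz by default, covering ~5 s
burst cycles and their harmonics).  One-sided density scaling matches
``scipy.signal.csd``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .recording import Recording

FMIN = 0.05  # Hz
FMAX = 2.0  # Hz
SEG_LEN = 20.0  # s


@dataclass
class CrossSpectrum:
    """Per-frequency Hermitian CSD matrix.

    ``S`` has shape (n_freqs, n_channels, n_channels) in units^2/Hz;
    ``n_segments_avg`` is the number of averaged segments (infinite for
    a closed-form model spectrum).
    """

    freqs: np.ndarray
    S: np.ndarray
    n_segments_avg: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.S = np.asarray(self.S, dtype=complex)
        if self.S.ndim != 3 or self.S.shape[1] != self.S.shape[2]:
            raise ValueError("S must have shape (n_freqs, n, n)")
        if len(self.freqs) != self.S.shape[0]:
            raise ValueError("freqs and S disagree on the number of frequencies")
        if not np.allclose(self.S, self.S.conj().transpose(0, 2, 1), atol=1e-10 * self._scale()):
            raise ValueError("S must be Hermitian at every frequency")
        diag = np.diagonal(self.S, axis1=1, axis2=2)
        if np.any(diag.real < -1e-12 * self._scale()) or np.any(np.abs(diag.imag) > 1e-10 * self._scale()):
            raise ValueError("diagonal of S must be real and non-negative")

    def _scale(self) -> float:
        return float(np.max(np.abs(self.S))) or 1.0

    @property
    def n_channels(self) -> int:
        return self.S.shape[1]

    def coherence(self) -> np.ndarray:
        """Magnitude-squared coherence |S_ij|^2 / (S_ii S_jj)."""
        diag = np.diagonal(self.S, axis1=1, axis2=2).real
        denom = diag[:, :, None] * diag[:, None, :]
        return np.abs(self.S) ** 2 / np.maximum(denom, 1e-300)

    def data_hash(self) -> str:
        """Stable fingerprint of the empirical data behind this spectrum."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.round(self.freqs, 12).tobytes())
        h.update(np.round(self.S, 12).tobytes())
        return h.hexdigest()[:16]


def empirical_csd(
    rec: Recording,
    fmin: float = FMIN,
    fmax: float = FMAX,
    seg_len: float = SEG_LEN,
) -> CrossSpectrum:
    """Averaged cross-periodogram of a preprocessed recording.

    Half-overlapping Hann-windowed segments of ``seg_len`` seconds, mean
    removed per segment; the returned grid is the rFFT grid intersected
    with [fmin, fmax].
    """
    if rec.duration < 2 * seg_len:
        raise ValueError(
            f"recording too short ({rec.duration:.0f} s) for seg_len {seg_len:.0f} s; "
            "need at least two segments"
        )
    x = rec.as_matrix()
    fs = rec.rate
    nper = round(seg_len * fs)
    step = nper // 2
    starts = range(0, x.shape[0] - nper + 1, step)
    w = hann(nper, sym=False)
    scale = 1.0 / (fs * (w**2).sum())
    freqs = np.fft.rfftfreq(nper, 1 / fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    n = x.shape[1]
    S = np.zeros((band.sum(), n, n), dtype=complex)
    K = 0
    for s0 in starts:
        seg = x[s0 : s0 + nper]
        seg = seg - seg.mean(axis=0)
        F = np.fft.rfft(w[:, None] * seg, axis=0)[band]
        S += F[:, :, None] * F[:, None, :].conj()
        K += 1
    S *= scale / K
    interior = (freqs[band] > 0) & (freqs[band] < fs / 2)
    S[interior] *= 2.0  # one-sided
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return CrossSpectrum(freqs=freqs[band], S=S, n_segments_avg=K, labels=rec.labels)
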