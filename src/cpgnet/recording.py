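"""Multichannel recording container and delimited-text I/O.

A :class:`Recording` holds uniformly sampled, labeled time series -- the
in-memory analogue of an extracellular nerve recording exported from an
acquisition system as a text table.  Channel labels encode the thoracic
segment and body side as ``<segment>_<side>``, e.g. ``meso_L``.

On disk a recording is a TSV file whose header row is
``time<TAB>label1<TAB>label2...`` with time in seconds, plus an optional
JSON sidecar (same path, ``.json`` suffix) carrying sampling rate, seed
and ground-truth provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEGMENTS = ("pro", "meso", "meta")
SIDES = ("L", "R")


class FormatError(ValueError):
    """Raised when an on-disk recording violates the expected layout."""


def parse_label(label: str) -> tuple[str, str]:
    """Split ``"meso_L"`` into ``("meso", "L")``, validating both parts."""
    try:
        seg, side = label.strip().split("_")
    except ValueError as exc:
        raise FormatError(f"channel label {label!r} is not '<segment>_<side>'") from exc
    if seg not in SEGMENTS or side not in SIDES:
        raise FormatError(
            f"channel label {label!r}: segment must be one of {SEGMENTS}, side one of {SIDES}"
        )
    return seg, side


@dataclass
class Recording:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    rate :
        Sampling rate in Hz.
    channels :
        Mapping label -> 1-D float array; all arrays equal length.
    t0 :
        Time of the first sample in seconds.
    stage :
        ``"raw"`` or ``"preprocessed"``.
    meta :
        Free-form provenance (seed, ground-truth coupling, ...).
    """

    rate: float
    channels: dict[str, np.ndarray]
    t0: float = 0.0
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.stage not in ("raw", "preprocessed"):
            raise ValueError(f"unknown stage {self.stage!r}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for label in self.channels:
            parse_label(label)

    @property
    def labels(self) -> list[str]:
        return list(self.channels)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Total duration in seconds (n samples at 1/rate spacing)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def as_matrix(self) -> np.ndarray:
        """Channels stacked as columns, shape (n_samples, n_channels)."""
        return np.column_stack([self.channels[k] for k in self.labels])


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as TSV (header ``time<TAB>label...``) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time": rec.times})
    for label in rec.labels:
        df[label] = rec.channels[label]
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    sidecar = {
        "rate": rec.rate,
        "t0": rec.t0,
        "stage": rec.stage,
        "labels": rec.labels,
        "meta": _jsonable(rec.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_recording(path: str | Path) -> Recording:
    """Read a TSV recording written by :func:`write_recording`.

    Raises :class:`FormatError` on a missing time column, ragged rows,
    non-monotone or non-uniform time.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows or malformed TSV ({exc})") from exc
    if df.columns[0] != "time":
        raise FormatError(f"{path}: first column must be 'time', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: no channel columns")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows (missing values)")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9 * max(abs(dt[0]), 1e-12)):
        raise FormatError(f"{path}: uniform sampling required, time steps vary")
    rate = 1.0 / dt[0]

    stage, meta = "raw", {}
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        stage = sidecar.get("stage", "raw")
        meta = sidecar.get("meta", {})
        rate = float(sidecar.get("rate", rate))

    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return Recording(rate=rate, channels=channels, t0=float(t[0]), stage=stage, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
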