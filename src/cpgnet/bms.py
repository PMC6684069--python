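"""Bayesian model selection and coupling-strength summaries.

Candidate architectures fitted to the same data are compared by their
Laplace log evidences.  Relative log evidence is reported against the
least probable model,

    log B_ji = log p(y | m = j) - log p(y | m = i),

and posterior model probabilities follow from equal model priors as the
softmax of the log evidences; for two models this reduces exactly to
p(m = i | y) = 1 / (1 + exp(-log B_ij)).

Strength summaries assume left-right symmetry -- mirror-image directed
connections between the same pair of CPGs are averaged into a single
connection value per class -- and offer the two normalisation
conventions used for reporting: dividing by the maximum class strength
(max -> 1) or by a named reference connection class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ClassComparison, compare_connection_classes
from .fitting import ModelFit
from .recording import parse_label

SEGMENT_ORDER = {"pro": 0, "meso": 1, "meta": 2}


@dataclass
class BMSResult:
    """Relative log evidences and posterior probabilities over a model space."""

    model_ids: list[str]
    log_evidence: np.ndarray
    relative_log_evidence: np.ndarray
    posterior_prob: np.ndarray
    winner: str

    def to_dict(self) -> dict:
        return {
            "model_ids": self.model_ids,
            "log_evidence": self.log_evidence.tolist(),
            "relative_log_evidence": self.relative_log_evidence.tolist(),
            "posterior_prob": self.posterior_prob.tolist(),
            "winner": self.winner,
        }


def bms(fits: list[ModelFit]) -> BMSResult:
    """Compare fitted models by Laplace evidence under equal model priors."""
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fitted models")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("all fits must be computed on identical data")
    ids = [f.architecture.id for f in fits]
    loge = np.array([f.log_evidence for f in fits])
    rel = loge - loge.min()
    ex = np.exp(loge - loge.max())
    post = ex / ex.sum()
    return BMSResult(
        model_ids=ids, log_evidence=loge, relative_log_evidence=rel,
        posterior_prob=post, winner=ids[int(np.argmax(loge))],
    )


def connection_class(label_a: str, label_b: str) -> str:
    """Symmetry class of a connection between two hemisegmental nodes.

    Within one segment: ``"meso-meso"``.  Between segments on the same
    side: ``"pro-meso"``.  Between segments on opposite sides (diagonal
    cross connection): ``"pro-meso-cross"``.
    """
    seg_a, side_a = parse_label(label_a)
    seg_b, side_b = parse_label(label_b)
    segs = sorted((seg_a, seg_b), key=SEGMENT_ORDER.__getitem__)
    if seg_a == seg_b:
        return f"{seg_a}-{seg_b}"
    base = f"{segs[0]}-{segs[1]}"
    return base if side_a == side_b else base + "-cross"


@dataclass
class StrengthSummary:
    """Per-connection-class coupling strengths over a set of fits."""

    per_fit: pd.DataFrame  # rows: class, columns: fit index, raw |strength|
    class_means: pd.Series  # normalized per-class means
    normalization: str
    comparisons: list[ClassComparison]

    def to_dict(self) -> dict:
        return {
            "normalization": self.normalization,
            "class_means": self.class_means.to_dict(),
            "per_fit": {c: row.tolist() for c, row in self.per_fit.iterrows()},
            "comparisons": [
                {"class_a": c.class_a, "class_b": c.class_b, "t": c.t, "p": c.p,
                 "significant": c.significant}
                for c in self.comparisons
            ],
        }


def summarize_strengths(
    fits: list[ModelFit],
    normalization: str = "max_to_1",
    reference_class: str | None = None,
    use_trial2: bool = False,
) -> StrengthSummary:
    """Symmetry-averaged strength table with the requested normalisation.

    Each fit contributes, per connection class, the mean absolute
    strength of its directed connections in that class (this averages
    both directions of a connection and its left-right mirror image).
    ``max_to_1`` divides the class means by their maximum;
    ``reference_connection`` divides by the mean of ``reference_class``.
    Class-pair Welch t-tests run on the raw per-fit values.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    arch_ids = {f.architecture.id for f in fits}
    if len(arch_ids) > 1:
        raise ValueError(f"fits mix architectures: {sorted(arch_ids)}")
    arch = fits[0].architecture
    classes = sorted(
        {connection_class(arch.labels[i], arch.labels[j]) for i, j in arch.edges()}
    )
    if not classes:
        raise ValueError("nothing to normalize: architecture has no connections")
    rows = {}
    for cls in classes:
        vals = []
        for f in fits:
            A = f.A_trial2 if use_trial2 else f.A_hat
            strengths = [
                abs(A[i, j])
                for i, j in arch.edges()
                if connection_class(arch.labels[i], arch.labels[j]) == cls
            ]
            vals.append(float(np.mean(strengths)))
        rows[cls] = vals
    per_fit = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=[f"fit{k}" for k in range(len(fits))])
    means = per_fit.mean(axis=1)
    if float(means.max()) == 0.0:
        raise ValueError("nothing to normalize: all strengths are zero")
    if normalization == "max_to_1":
        class_means = means / means.max()
    elif normalization == "reference_connection":
        if reference_class is None or reference_class not in means.index:
            raise ValueError("reference_connection normalization needs a valid reference_class")
        class_means = means / means[reference_class]
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    comparisons = []
    if len(fits) >= 2 and len(classes) >= 2:
        comparisons = compare_connection_classes({c: rows[c] for c in classes})
    return StrengthSummary(
        per_fit=per_fit, class_means=class_means,
        normalization=normalization, comparisons=comparisons,
    )
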