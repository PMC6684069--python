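"""Candidate coupling architectures for segmental CPG networks.

Each architecture is a directed adjacency mask over hemisegmental nodes
(one node per ganglion side, labels ``<segment>_<side>``).  Connections
fall into three edge classes:

* ``intra`` -- contralateral connections within one segment (L<->R),
* ``inter`` -- ipsilateral connections between segments (L<->L, R<->R),
* ``diag`` -- diagonal cross connections between segments (L<->R).

Two model spaces are predefined.  The two-segment space steps down from
fully connected to fully unconnected:

1. fully connected (all ordered pairs),
2. "eight-shaped": intrasegmental + ipsilateral intersegmental,
3. intrasegmental + diagonal cross,
4. intrasegmentally unconnected (ipsilateral + diagonal),
5. diagonal cross only,
6. intersegmentally unconnected (intrasegmental only),
7. fully unconnected.

The three-segment space builds on the eight-shaped winner of the
two-segment comparisons:

1. union of the two winning two-segment subnetworks,
2. (1) + diagonal cross connections between outer segments,
3. (1) + bidirectional ipsilateral outer-segment connections,
4. (1) + unidirectional ipsilateral feedback from the hindmost to the
   front segment.

Entry convention everywhere: ``mask[i, j]`` / ``A[i, j]`` is the influence
of node *j* on node *i*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import parse_label

TWO_SEGMENT_IDS = (1, 2, 3, 4, 5, 6, 7)
THREE_SEGMENT_IDS = (1, 2, 3, 4)

EDGE_CLASSES = ("intra", "inter", "diag")


def node_labels(segments: tuple[str, ...]) -> list[str]:
    return [f"{seg}_{side}" for seg in segments for side in ("L", "R")]


def edge_class(label_from: str, label_to: str) -> str:
    """Classify a directed edge by the segment/side relation of its endpoints."""
    seg_f, side_f = parse_label(label_from)
    seg_t, side_t = parse_label(label_to)
    if seg_f == seg_t:
        if side_f == side_t:
            raise ValueError("self connections carry no edge class")
        return "intra"
    return "inter" if side_f == side_t else "diag"


def _pairs(labels, cls_filter, adjacent_only=True):
    """All ordered pairs (i, j) meaning j -> i, filtered by edge class."""
    segs = []
    for lab in labels:
        seg = parse_label(lab)[0]
        if seg not in segs:
            segs.append(seg)
    order = {s: k for k, s in enumerate(segs)}
    out = []
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            if i == j:
                continue
            try:
                cls = edge_class(lj, li)
            except ValueError:
                continue
            if cls != cls_filter:
                continue
            si, sj = parse_label(li)[0], parse_label(lj)[0]
            if cls != "intra" and adjacent_only and abs(order[si] - order[sj]) != 1:
                continue
            out.append((i, j))
    return out


@dataclass
class ModelArchitecture:
    """Directed adjacency mask with a global sign constraint.

    ``mask_A[i, j]`` marks an allowed connection j -> i.  Self terms are
    node dynamics, never part of the mask.  ``mask_B`` marks connections
    allowed to change between experimental conditions (subset of
    ``mask_A``).
    """

    id: str
    labels: list[str]
    mask_A: np.ndarray
    sign: str = "excitatory"
    mask_B: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask_A = np.asarray(self.mask_A, dtype=bool)
        n = len(self.labels)
        if self.mask_A.shape != (n, n):
            raise ValueError("mask_A shape must match number of labels")
        if self.mask_A.diagonal().any():
            raise ValueError("diagonal of mask_A must be empty (self terms are node dynamics)")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"sign must be excitatory or inhibitory, got {self.sign!r}")
        if self.mask_B is not None:
            self.mask_B = np.asarray(self.mask_B, dtype=bool)
            if (self.mask_B & ~self.mask_A).any():
                raise ValueError("mask_B must be a subset of mask_A")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_connections(self) -> int:
        return int(self.mask_A.sum())

    @property
    def sign_value(self) -> float:
        return 1.0 if self.sign == "excitatory" else -1.0

    def edges(self) -> list[tuple[int, int]]:
        """Ordered (i, j) index pairs of allowed connections j -> i."""
        return [tuple(ij) for ij in np.argwhere(self.mask_A)]

    def edge_classes(self) -> list[str]:
        return [edge_class(self.labels[j], self.labels[i]) for i, j in self.edges()]


def two_segment_architecture(
    architecture_id: int,
    segments: tuple[str, str] = ("meso", "meta"),
    sign: str = "excitatory",
) -> ModelArchitecture:
    """Architecture from the 7-model two-segment space (4 nodes)."""
    if architecture_id not in TWO_SEGMENT_IDS:
        raise ValueError(
            f"unknown two-segment architecture id {architecture_id}; valid ids are 1-7"
        )
    labels = node_labels(segments)
    classes_by_id = {
        1: ("intra", "inter", "diag"),
        2: ("intra", "inter"),
        3: ("intra", "diag"),
        4: ("inter", "diag"),
        5: ("diag",),
        6: ("intra",),
        7: (),
    }
    mask = np.zeros((4, 4), dtype=bool)
    for cls in classes_by_id[architecture_id]:
        for i, j in _pairs(labels, cls):
            mask[i, j] = True
    return ModelArchitecture(
        id=f"2seg-{architecture_id}", labels=labels, mask_A=mask, sign=sign,
        meta={"space": "two_segment", "architecture_id": architecture_id},
    )


def three_segment_architecture(
    architecture_id: int,
    segments: tuple[str, str, str] = ("pro", "meso", "meta"),
    sign: str = "excitatory",
) -> ModelArchitecture:
    """Architecture from the 4-model three-segment space (6 nodes)."""
    if architecture_id not in THREE_SEGMENT_IDS:
        raise ValueError(
            f"unknown three-segment architecture id {architecture_id}; valid ids are 1-4"
        )
    labels = node_labels(segments)
    n = len(labels)
    mask = np.zeros((n, n), dtype=bool)
    # base: intrasegmental everywhere + ipsilateral between adjacent segments
    for cls in ("intra", "inter"):
        for i, j in _pairs(labels, cls, adjacent_only=True):
            mask[i, j] = True
    idx = {lab: k for k, lab in enumerate(labels)}
    first, _, last = segments
    if architecture_id == 2:  # diagonal cross between outer segments
        for sf, st in (("L", "R"), ("R", "L")):
            mask[idx[f"{first}_{st}"], idx[f"{last}_{sf}"]] = True
            mask[idx[f"{last}_{st}"], idx[f"{first}_{sf}"]] = True
    elif architecture_id == 3:  # bidirectional ipsilateral outer-segment
        for side in ("L", "R"):
            mask[idx[f"{first}_{side}"], idx[f"{last}_{side}"]] = True
            mask[idx[f"{last}_{side}"], idx[f"{first}_{side}"]] = True
    elif architecture_id == 4:  # unidirectional hind -> front feedback
        for side in ("L", "R"):
            mask[idx[f"{first}_{side}"], idx[f"{last}_{side}"]] = True
    return ModelArchitecture(
        id=f"3seg-{architecture_id}", labels=labels, mask_A=mask, sign=sign,
        meta={"space": "three_segment", "architecture_id": architecture_id},
    )


def architecture(architecture_id: int, n_segments: int, **kwargs) -> ModelArchitecture:
    """Dispatch on segment count (2 -> 7-model space, 3 -> 4-model space)."""
    if n_segments == 2:
        return two_segment_architecture(architecture_id, **kwargs)
    if n_segments == 3:
        return three_segment_architecture(architecture_id, **kwargs)
    raise ValueError(f"n_segments must be 2 or 3, got {n_segments}")
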