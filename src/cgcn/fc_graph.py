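"""Functional-connectivity matrices and k-nearest-neighbor connectivity graphs.

The convolutional neighborhood of the network is not Euclidean: each ROI
(node) is connected to the k other ROIs with which its time course is most
strongly correlated in the *group-average* functional-connectivity (FC)
matrix, computed from training records only.  This module provides the FC
computation (Pearson correlation over all frames of a record), group
averaging, and construction of the directed k-NN graph, plus the
random-graph control used to show that connectivity-defined neighborhoods
(and not graph convolution per se) carry the classification signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "FcMatrix",
    "KnnGraph",
    "zscore_record",
    "compute_fc",
    "group_fc",
    "build_knn_graph",
    "build_random_graph",
]


@dataclass
class RoiTimeSeries:
    """One subject-session recording: a frames x ROIs signal matrix plus metadata.

    Attributes
    ----------
    subject_id, session_id : str
        Identity of the recording.
    class_label : str or int
        Classification target (diagnostic group, or subject id for
        identification tasks).
    site_label : str
        Acquisition site; used by leave-one-site-out cross-validation.
    signals : ndarray, shape (T, N)
        ROI-mean BOLD-like time courses, frames as rows.
    """

    subject_id: str
    session_id: str
    class_label: object
    site_label: str
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D frames x ROIs matrix")
        t, n = self.signals.shape
        if t < 2 or n < 2:
            raise ValueError(f"need at least 2 frames and 2 ROIs, got {t}x{n}")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.signals.shape[0]

    @property
    def n_rois(self) -> int:
        return self.signals.shape[1]


@dataclass
class FcMatrix:
    """ROI x ROI Pearson-correlation matrix (individual or group-averaged)."""

    values: np.ndarray
    n_records_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("FC matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise ValueError("FC entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class KnnGraph:
    """Directed neighborhood structure: node i keeps edges to its k neighbors.

    ``neighbors[i]`` is the ordered list (strongest first for connectivity
    graphs) of the k out-neighbors of node i; no self-loops, no duplicates.
    """

    n_nodes: int
    k: int
    neighbors: np.ndarray
    edge_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=np.int64)
        if self.neighbors.shape != (self.n_nodes, self.k):
            raise ValueError("neighbors must have shape (n_nodes, k)")
        if not (1 <= self.k <= self.n_nodes - 1):
            raise ValueError(f"k={self.k} out of range for {self.n_nodes} nodes")
        rows = np.arange(self.n_nodes)[:, None]
        if np.any(self.neighbors == rows):
            raise ValueError("self-loops are not allowed")
        if np.any(self.neighbors < 0) or np.any(self.neighbors >= self.n_nodes):
            raise ValueError("neighbor index out of range")
        for i in range(self.n_nodes):
            if len(set(self.neighbors[i].tolist())) != self.k:
                raise ValueError(f"duplicate neighbors for node {i}")


def _constant_columns(x: np.ndarray) -> np.ndarray:
    """Columns whose spread is at floating-point noise level."""
    sd = x.std(axis=0, ddof=0)
    scale = np.maximum(1.0, np.abs(x.mean(axis=0)))
    return sd <= 1e-10 * scale


def zscore_record(record: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize each ROI column to mean 0, sd 1 over frames.

    Correlation is scale-free, so FC is unchanged; the network, however,
    needs inputs of comparable magnitude.  Statistics come from the record
    itself only, so normalization cannot leak information across records.
    """
    x = record.signals
    const = _constant_columns(x)
    if np.any(const):
        bad = int(np.flatnonzero(const)[0])
        raise ValueError(f"ROI column {bad} is constant; cannot z-score")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    return RoiTimeSeries(
        subject_id=record.subject_id,
        session_id=record.session_id,
        class_label=record.class_label,
        site_label=record.site_label,
        signals=z,
    )


def compute_fc(record: RoiTimeSeries) -> FcMatrix:
    """Pearson-correlation FC of one record over all of its frames."""
    x = record.signals
    const = _constant_columns(x)
    if np.any(const):
        bad = int(np.flatnonzero(const)[0])
        raise ValueError(f"ROI column {bad} is constant; correlation undefined")
    c = np.corrcoef(x, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return FcMatrix(values=c, n_records_averaged=1)


def group_fc(matrices: list[FcMatrix], fisher_z: bool = False) -> FcMatrix:
    """Entrywise mean of FC matrices (the group FC matrix).

    With ``fisher_z`` the mean is taken on arctanh-transformed values and
    mapped back; the default is a plain mean of the raw coefficients.
    """
    if not matrices:
        raise ValueError("group_fc requires at least one FC matrix")
    n = matrices[0].n_rois
    for m in matrices:
        if m.n_rois != n:
            raise ValueError(
                f"FC dimension mismatch: expected {n}, got {m.n_rois}"
            )
    stack = np.stack([m.values for m in matrices])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-12, 1 - 1e-12))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    mean = np.clip((mean + mean.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mean, 1.0)
    return FcMatrix(
        values=mean,
        n_records_averaged=sum(m.n_records_averaged for m in matrices),
    )


def build_knn_graph(fc: FcMatrix, k: int) -> KnnGraph:
    """Keep, for each node, the k neighbors with the largest signed correlation.

    Ranking uses the correlation coefficient itself (not its absolute
    value); the diagonal is excluded, and ties are broken toward the lower
    node index for cross-platform determinism.  Edges are directed, so the
    resulting graph need not be symmetric.
    """
    n = fc.n_rois
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    neighbors = np.empty((n, k), dtype=np.int64)
    values = np.empty((n, k), dtype=float)
    idx = np.arange(n)
    for i in range(n):
        row = fc.values[i]
        # lexsort: primary key -row (descending value), secondary key index
        order = np.lexsort((idx, -row))
        order = order[order != i][:k]
        neighbors[i] = order
        values[i] = row[order]
    return KnnGraph(n_nodes=n, k=k, neighbors=neighbors, edge_values=values)


def build_random_graph(n_nodes: int, k: int, seed: int) -> KnnGraph:
    """Random control graph: k distinct uniform neighbors per node, no self-loops."""
    if not (1 <= k <= n_nodes - 1):
        raise ValueError(f"k must be in [1, {n_nodes - 1}], got {k}")
    rng = np.random.default_rng(seed)
    neighbors = np.empty((n_nodes, k), dtype=np.int64)
    for i in range(n_nodes):
        candidates = np.concatenate([np.arange(i), np.arange(i + 1, n_nodes)])
        neighbors[i] = rng.choice(candidates, size=k, replace=False)
    return KnnGraph(n_nodes=n_nodes, k=k, neighbors=neighbors)
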