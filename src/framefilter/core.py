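"""Edge time series, functional connectivity, and co-fluctuation amplitude.

Functional connectivity (FC) between regions *i* and *j* is the Pearson
correlation

    r_ij = (1 / (T - 1)) * sum_t z_i(t) * z_j(t),

with ``z`` the column-z-scored (sample sd, denominator T-1) regional time
series.  Dropping the final average yields the edge time series (eTS)

    r_ij(t) = z_i(t) * z_j(t),

a frames x edges matrix of instantaneous co-fluctuations whose time mean
(divisor T-1) reproduces FC exactly.  The root-sum-square (RSS) of a frame's
edge values measures the global co-fluctuation amplitude at that moment;
high-RSS frames ("events") carry a disproportionate share of FC structure.

Edge vectorization is fixed package-wide: upper triangle, ``i < j``,
lexicographic in ``(i, j)``, 0-based -- the order of ``np.triu_indices``.
Frame indices are 0-based in ``[0, T)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionalTimeSeries", "ZScoredSeries", "EdgeTimeSeries", "RSSVector",
    "ConnectivityMatrix", "FrameSet", "zscore_series", "edge_time_series",
    "pearson_fc", "rss_amplitude", "component_from_frames",
    "frame_fc_similarity", "edge_index_pairs", "matrix_to_vec",
    "vec_to_matrix",
]


@dataclass
class RegionalTimeSeries:
    """Parcellated activity: frames T x regions N, one subject/run."""

    data: np.ndarray
    subject_id: str = "s0"
    run_id: str = "r0"
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D frames x nodes array")
        T, N = self.data.shape
        if T < 3:
            raise ValueError(f"need at least 3 frames, got {T}")
        if N < 2:
            raise ValueError(f"need at least 2 nodes, got {N}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.node_labels is None:
            self.node_labels = [f"node{i}" for i in range(N)]
        if len(self.node_labels) != N:
            raise ValueError("node_labels length does not match column count")
        if len(set(self.node_labels)) != N:
            raise ValueError("node_labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class ZScoredSeries:
    """Column-standardized series (mean 0, sample sd 1 per node)."""

    data: np.ndarray
    provenance: RegionalTimeSeries | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class EdgeTimeSeries:
    """Frames T x edges K co-fluctuation matrix, K = N(N-1)/2."""

    data: np.ndarray
    edge_index: list[tuple[int, int]]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]


@dataclass
class RSSVector:
    """Per-frame root-sum-square co-fluctuation amplitude (>= 0)."""

    values: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N connectivity; ``kind`` in {fc, fcc, agreement, agc}."""

    data: np.ndarray
    kind: str = "fc"
    frames_used: object = "all"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    def vec(self) -> np.ndarray:
        """Upper-triangle edge vector in the shared package ordering."""
        return matrix_to_vec(self.data)


@dataclass
class FrameSet:
    """Sorted unique 0-based frame indices into a series of length T."""

    indices: np.ndarray
    T: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.T):
            raise ValueError(f"frame indices out of range [0, {self.T})")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    @classmethod
    def full(cls, T: int) -> "FrameSet":
        return cls(np.arange(T), T)

    @property
    def is_full(self) -> bool:
        return len(self) == self.T


def edge_index_pairs(N: int) -> list[tuple[int, int]]:
    """Upper-triangle node pairs (i, j), i < j, lexicographic, 0-based."""
    iu, ju = np.triu_indices(N, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def matrix_to_vec(mat: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle in the shared edge ordering."""
    mat = np.asarray(mat)
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    return mat[iu, ju]


def vec_to_matrix(vec: np.ndarray, diag: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix from an upper-triangle edge vector."""
    vec = np.asarray(vec, dtype=float)
    K = vec.size
    N = int(round((1 + np.sqrt(1 + 8 * K)) / 2))
    if N * (N - 1) // 2 != K:
        raise ValueError(f"edge vector length {K} is not triangular")
    mat = np.full((N, N), diag, dtype=float)
    iu, ju = np.triu_indices(N, k=1)
    mat[iu, ju] = vec
    mat[ju, iu] = vec
    return mat


def zscore_series(ts: RegionalTimeSeries) -> ZScoredSeries:
    """Z-score each node's time series (mean 0, sample sd with T-1).

    Raises ``ValueError`` naming the offending node if any column is
    constant (zero sample variance).
    """
    data = ts.data
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.node_labels[i] for i in bad[:5])
        raise ValueError(f"constant node (zero variance): {names}")
    return ZScoredSeries(data=(data - mu) / sd, provenance=ts)


def edge_time_series(z: ZScoredSeries) -> EdgeTimeSeries:
    """Per-frame outer products z_i(t) * z_j(t) over all node pairs i < j."""
    iu, ju = np.triu_indices(z.n_nodes, k=1)
    data = z.data[:, iu] * z.data[:, ju]
    return EdgeTimeSeries(data=data, edge_index=list(zip(iu.tolist(), ju.tolist())))


def pearson_fc(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Full-scan functional connectivity (Pearson correlation matrix)."""
    z = zscore_series(ts)
    mat = (z.data.T @ z.data) / (z.n_frames - 1)
    np.fill_diagonal(mat, 1.0)
    mat = (mat + mat.T) / 2.0
    return ConnectivityMatrix(data=mat, kind="fc", frames_used="all")


def rss_amplitude(ets: EdgeTimeSeries) -> RSSVector:
    """RSS(t) = sqrt(sum over edges of r_ij(t)^2), one value per frame."""
    return RSSVector(values=np.sqrt(np.sum(ets.data**2, axis=1)))


def component_from_frames(ets: EdgeTimeSeries, frames: FrameSet) -> ConnectivityMatrix:
    """Connectivity component (FCc): mean co-fluctuation over selected frames.

    A proper subset of frames is averaged with the plain mean (divisor
    ``len(frames)``); the full frame set uses divisor ``T - 1`` so the
    result equals Pearson FC exactly.
    """
    if len(frames) == 0:
        raise ValueError("empty frame set")
    sel = ets.data[frames.indices]
    if frames.is_full:
        vec = sel.sum(axis=0) / (ets.n_frames - 1)
        diag = 1.0
    else:
        vec = sel.mean(axis=0)
        diag = 1.0
    mat = vec_to_matrix(vec, diag=diag)
    return ConnectivityMatrix(data=mat, kind="fcc", frames_used=frames)


def frame_fc_similarity(ets: EdgeTimeSeries, fc: ConnectivityMatrix) -> np.ndarray:
    """Per-frame Pearson correlation between each eTS frame and vectorized FC.

    Frames with zero variance across edges get similarity 0 with a warning
    rather than NaN, so downstream summaries stay defined.
    """
    fvec = fc.vec()
    if len(fvec) != ets.n_edges:
        raise ValueError("edge ordering mismatch between eTS and FC")
    X = ets.data - ets.data.mean(axis=1, keepdims=True)
    y = fvec - fvec.mean()
    xn = np.linalg.norm(X, axis=1)
    yn = np.linalg.norm(y)
    out = np.zeros(ets.n_frames)
    tol = 1e-10 * (np.abs(ets.data).max() + 1.0)
    ok = (xn > tol) & (yn > tol)
    if np.any(~ok):
        warnings.warn("zero-variance frame(s) in similarity; recorded as 0")
    out[ok] = (X[ok] @ y) / (xn[ok] * yn)
    return out
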