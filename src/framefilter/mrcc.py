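"""Multiresolution consensus clustering of behavior RSS-amplitude profiles.

Behaviors are compared by the Spearman similarity of their co-fluctuation
amplitude profiles (mean |brain-behavior correlation| per RSS decile) and
clustered by modularity maximization

    Q(gamma) = sum_{r != s} [S_rs - gamma * P_rs] * delta(sigma_r, sigma_s),

summed over ordered pairs with the constant Potts null P_rs = 1; negative
similarities participate directly.  A Louvain-style two-phase greedy search
(seeded sweep order, aggregation between phases) maximizes Q at each value
of a resolution sweep; the resulting partition ensemble becomes a
probabilistic co-classification matrix, which is reclustered iteratively
(minus a chance-level offset) until unanimous -- the consensus partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Partition", "CoClassification", "profile_similarity", "potts_modularity",
    "louvain", "gamma_sweep", "coclassification", "consensus",
]


@dataclass
class Partition:
    """Community labels (contiguous from 0) with the gamma and Q achieved."""

    labels: np.ndarray
    gamma: float = 0.0
    Q: float = 0.0

    def __post_init__(self) -> None:
        self.labels = _canonical(np.asarray(self.labels, dtype=int))

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class CoClassification:
    """Fraction of ensemble partitions co-assigning each behavior pair."""

    matrix: np.ndarray
    n_partitions: int


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities contiguously by first appearance."""
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def profile_similarity(profiles: np.ndarray) -> np.ndarray:
    """Spearman correlation between every pair of behavior profiles.

    ``profiles`` is behaviors B x bins (rows are RSS-decile correlation
    profiles).  A constant profile yields a zero row/column with a warning;
    the diagonal is 1.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need a 2-D profile matrix with at least 3 behaviors")
    B = P.shape[0]
    ranks = stats.rankdata(P, axis=1, method="average")
    Rc = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Rc, axis=1)
    const = norms == 0
    if const.any():
        warnings.warn("constant profile(s); similarity row recorded as 0")
    safe = np.where(const, 1.0, norms)
    S = (Rc @ Rc.T) / np.outer(safe, safe)
    S[const, :] = 0.0
    S[:, const] = 0.0
    np.fill_diagonal(S, 1.0)
    return S


def potts_modularity(S: np.ndarray, labels, gamma: float) -> float:
    """Q(gamma) over ordered node pairs r != s with constant Potts null."""
    S = np.asarray(S, dtype=float)
    labels = np.asarray(getattr(labels, "labels", labels), dtype=int)
    if S.shape[0] != S.shape[1] or labels.size != S.shape[0]:
        raise ValueError("similarity matrix and labels are inconsistent")
    Q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        block = S[np.ix_(idx, idx)]
        within = block.sum() - np.trace(block)
        n_c = idx.size
        Q += within - gamma * n_c * (n_c - 1)
    return float(Q)


def _local_move(W, node_sizes, gamma, rng):
    """One level of greedy local moving; returns (labels, improved)."""
    n = W.shape[0]
    labels = np.arange(n)
    comm_sizes = node_sizes.astype(float).copy()
    improved = False
    moved = True
    while moved:
        moved = False
        for u in rng.permutation(n):
            a = labels[u]
            # similarity mass from u to each community (u excluded from its own)
            links = np.bincount(labels, weights=W[u], minlength=n)
            size_u = node_sizes[u]
            # gain of staying counted with u removed from its community
            gain = 2.0 * (links - gamma * size_u * comm_sizes)
            gain[a] = 2.0 * (links[a] - gamma * size_u * (comm_sizes[a] - size_u))
            best = int(np.argmax(gain))
            if gain[best] > gain[a] + 1e-12:
                comm_sizes[a] -= size_u
                comm_sizes[best] += size_u
                labels[u] = best
                moved = True
                improved = True
    return labels, improved


def louvain(S: np.ndarray, gamma: float, seed: int | np.random.Generator = 0) -> Partition:
    """Two-phase greedy modularity maximization with the constant Potts null.

    Phase 1 sweeps nodes in seeded order, applying the best Q-improving
    community move; phase 2 aggregates communities into super-nodes
    (tracking original sizes for the gamma penalty) and repeats until no
    move improves.  Negative similarities are handled natively by the gain
    arithmetic.
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 behaviors")
    rng = np.random.default_rng(seed)

    W = S.copy()
    np.fill_diagonal(W, 0.0)
    sizes = np.ones(n)
    membership = np.arange(n)  # original node -> current super-node

    while True:
        labels, improved = _local_move(W, sizes, gamma, rng)
        labels = _canonical(labels)
        membership = labels[membership]
        n_comms = labels.max() + 1
        if not improved or n_comms == W.shape[0]:
            break
        # aggregate super-nodes into communities
        onehot = np.eye(n_comms)[labels]
        W = onehot.T @ W @ onehot
        np.fill_diagonal(W, 0.0)  # within-community mass re-enters via Q only
        # keep within-community similarity: store on diagonal is wrong for
        # gain arithmetic; fold it by tracking Q through potts_modularity at
        # the end instead
        sizes = onehot.T @ sizes

    part = Partition(labels=membership, gamma=float(gamma))
    part.Q = potts_modularity(S, part.labels, gamma)
    return part


def gamma_sweep(
    S: np.ndarray, gamma_grid, seed: int = 0
) -> list[Partition]:
    """One seeded Louvain partition per resolution value."""
    gamma_grid = np.atleast_1d(np.asarray(gamma_grid, dtype=float))
    if gamma_grid.size == 0:
        raise ValueError("empty gamma grid")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=gamma_grid.size)
    return [louvain(S, g, int(s)) for g, s in zip(gamma_grid, seeds)]


def coclassification(parts: list[Partition]) -> CoClassification:
    """Fraction of partitions assigning each pair to the same community."""
    if not parts:
        raise ValueError("need at least one partition")
    n = parts[0].labels.size
    M = np.zeros((n, n))
    for p in parts:
        lab = p.labels
        M += (lab[:, None] == lab[None, :]).astype(float)
    M /= len(parts)
    return CoClassification(matrix=M, n_partitions=len(parts))


def _chance_coassignment(parts: list[Partition]) -> float:
    """Expected pair co-assignment rate under random node permutations."""
    rates = []
    for p in parts:
        n = p.labels.size
        _, counts = np.unique(p.labels, return_counts=True)
        rates.append(np.sum(counts * (counts - 1)) / (n * (n - 1)))
    return float(np.mean(rates))


def consensus(
    cc: CoClassification,
    null_level: float | None = None,
    seed: int = 0,
    n_restarts: int = 32,
    max_rounds: int = 100,
    ensemble: list[Partition] | None = None,
) -> Partition:
    """Iteratively recluster the co-classification matrix until unanimous.

    Each round runs ``n_restarts`` seeded Louvain passes on
    ``cc - null_level`` (gamma 0: the chance offset is already subtracted);
    if they all agree the shared partition is returned, otherwise their
    co-classification matrix feeds the next round.  ``null_level`` defaults
    to the ensemble's chance co-assignment rate when the generating ensemble
    is supplied, else to the mean off-diagonal of ``cc``.
    """
    M = np.asarray(cc.matrix, dtype=float)
    if null_level is None:
        if ensemble is not None:
            null_level = _chance_coassignment(ensemble)
        else:
            off = M[~np.eye(M.shape[0], dtype=bool)]
            null_level = float(off.mean()) if off.size else 0.0
    rng = np.random.default_rng(seed)
    for _ in range(max_rounds):
        A = M - null_level
        np.fill_diagonal(A, 0.0)
        parts = [
            louvain(A, gamma=0.0, seed=int(s))
            for s in rng.integers(0, 2**31 - 1, size=n_restarts)
        ]
        first = parts[0].labels
        if all(np.array_equal(p.labels, first) for p in parts):
            out = Partition(labels=first)
            return out
        M = coclassification(parts).matrix
    raise RuntimeError(
        f"consensus did not converge within {max_rounds} rounds "
        f"(last ensemble had {len({tuple(p.labels) for p in parts})} distinct partitions)"
    )
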