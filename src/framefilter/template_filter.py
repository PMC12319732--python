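"""Template matching of bipartition frames and RSS amplitude binning.

A filtering template is a binary node vector.  Its similarity to each
frame's bipartition is the mutual information of the 2x2 label contingency,

    MI(M, M') = sum_m sum_m' P(m, m') log[ P(m, m') / (P(m) P(m')) ],

normalized as 2*MI / (H(M) + H(M')) so that a partition and its exact
inversion both score 1 against themselves -- MI sees community structure,
not raw activations.  The top fraction of frames by normalized MI (default
10%) is selected per run.  RSS decile binning sorts frames by co-fluctuation
amplitude into ten equal rank blocks (bin 1 = highest RSS), and random
frame bins provide the matched chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from framefilter.bipartition import BipartitionSeries
from framefilter.core import FrameSet, RSSVector

__all__ = [
    "Template", "nmi_binary", "match_scores", "match_frames",
    "rss_decile_bins", "random_frame_bins",
]


@dataclass
class Template:
    """Binary node-label vector used to filter frames."""

    labels: np.ndarray
    name: str = "template"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("template must be a 1-D vector")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("template entries must be 0/1")
        self.labels = self.labels.astype(np.int8)

    def __len__(self) -> int:
        return int(self.labels.size)

    def complement(self) -> "Template":
        return Template(labels=1 - self.labels, name=f"{self.name}~")


def _mi_from_counts(n11, n10, n01, n00, N):
    """MI and the two marginal entropies from 2x2 contingency counts.

    Vectorized over leading dimensions; natural log.  Zero cells contribute
    zero by the p log p -> 0 limit.
    """
    counts = np.stack(
        [np.asarray(c, dtype=float) for c in (n11, n10, n01, n00)], axis=-1
    )
    p = counts / N
    rows = p[..., 0] + p[..., 1]  # P(a = 1)
    cols = p[..., 0] + p[..., 2]  # P(b = 1)
    marg = np.stack(
        [rows * cols, rows * (1 - cols), (1 - rows) * cols, (1 - rows) * (1 - cols)],
        axis=-1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / np.where(marg > 0, marg, 1.0)), 0.0)
    mi = terms.sum(axis=-1)

    def _h(q):
        with np.errstate(divide="ignore", invalid="ignore"):
            return -(
                np.where(q > 0, q * np.log(q), 0.0)
                + np.where(q < 1, (1 - q) * np.log(1 - q), 0.0)
            )

    return mi, _h(rows), _h(cols)


def nmi_binary(a, b) -> float:
    """Normalized mutual information between two binary partitions.

    Normalization 2*MI/(H(a) + H(b)); symmetric, in [0, 1], invariant to
    complementation of either argument.  If either partition has zero
    entropy (all one label) the score is 0.
    """
    a = np.asarray(getattr(a, "labels", a)).astype(int)
    b = np.asarray(getattr(b, "labels", b)).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("partitions must be 1-D vectors of equal length")
    N = a.size
    if N < 2:
        raise ValueError("need at least 2 nodes")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = N - n11 - n10 - n01
    mi, ha, hb = _mi_from_counts(n11, n10, n01, n00, N)
    if ha == 0 or hb == 0:
        return 0.0
    return float(2.0 * mi / (ha + hb))


def match_scores(tpl: Template, bps: BipartitionSeries) -> np.ndarray:
    """Normalized MI between the template and every frame's bipartition."""
    if len(tpl) != bps.n_nodes:
        raise ValueError("template length does not match node count")
    N = bps.n_nodes
    a = tpl.labels.astype(float)
    B = bps.data.astype(float)
    n11 = B @ a
    n10 = B.sum(axis=1) - n11
    n01 = a.sum() - n11
    n00 = N - n11 - n10 - n01
    mi, hb, ha = _mi_from_counts(n11, n10, n01, n00, N)
    denom = ha + hb
    scores = np.zeros(bps.n_frames)
    ok = (ha > 0) & (hb > 0)
    scores[ok] = 2.0 * mi[ok] / denom[ok]
    return np.clip(scores, 0.0, 1.0)


def match_frames(tpl: Template, bps: BipartitionSeries, fraction: float = 0.10) -> FrameSet:
    """Select the round(fraction * T) frames with highest template NMI.

    Ties at the cutoff are broken toward earlier frame indices (stable
    sort), so selection is deterministic.  At least one frame is always
    selected; selection is per run.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    T = bps.n_frames
    n_sel = max(1, int(round(fraction * T)))
    scores = match_scores(tpl, bps)
    order = np.argsort(-scores, kind="stable")
    return FrameSet(indices=np.sort(order[:n_sel]), T=T)


def rss_decile_bins(rss: RSSVector) -> list[FrameSet]:
    """Partition frames into 10 RSS-rank blocks; bin 1 = highest amplitude.

    Frames are ranked by RSS descending (ties to the earlier index) and
    split into 10 contiguous rank blocks whose sizes differ by at most 1.
    """
    values = np.asarray(rss.values)
    T = values.size
    if T < 10:
        raise ValueError("need at least 10 frames for decile binning")
    order = np.argsort(-values, kind="stable")
    splits = np.array_split(order, 10)
    return [FrameSet(indices=np.sort(s), T=T) for s in splits]


def random_frame_bins(
    T: int, bin_size: int, n_bins: int, seed: int | np.random.Generator = 0
) -> list[FrameSet]:
    """Seeded uniform draws of ``bin_size`` distinct frames, ``n_bins`` times."""
    if bin_size > T:
        raise ValueError("bin_size cannot exceed T")
    rng = np.random.default_rng(seed)
    return [
        FrameSet(indices=np.sort(rng.choice(T, size=bin_size, replace=False)), T=T)
        for _ in range(n_bins)
    ]
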