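"""Bipartitions of regional activity and agreement (co-classification) components.

Thresholding the z-scored series at zero splits each frame's nodes into an
above-mean and a below-mean group -- a bipartition that discards amplitude
but retains the sign structure carrying most of the information in FC.  The
agreement matrix over a set of frames records, per node pair, the fraction
of frames in which both nodes fall in the same group.  A permutation null

    P_null = (1/l) * sum_k sum_s (|C_ks| / N) * ((|C_ks| - 1) / (N - 1))

(sum over the l selected frames k and each frame's two groups s) gives the
chance co-classification rate given the observed group sizes; subtracting
it yields the agreement component (AGc), a drop-in FC surrogate for
arbitrary frame subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from framefilter.core import FrameSet, ZScoredSeries, matrix_to_vec

__all__ = [
    "BipartitionSeries", "AgreementComponent", "binarize",
    "pnull_expected", "agreement_component", "subject_agreement",
]


@dataclass
class BipartitionSeries:
    """Binary T x N matrix: 1 where z > 0, else 0."""

    data: np.ndarray
    provenance: object = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("bipartition entries must be 0/1")
        self.data = self.data.astype(np.int8)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class AgreementComponent:
    """Agreement matrix over a frame subset, with its permutation null."""

    matrix: np.ndarray
    pnull: float
    frames_used: FrameSet
    corrected: bool = True

    def vec(self) -> np.ndarray:
        """Off-diagonal edge vector in the shared ordering (diagonal excluded)."""
        return matrix_to_vec(self.matrix)


def binarize(z: ZScoredSeries) -> BipartitionSeries:
    """Threshold the z-scored series at zero (z > 0 -> 1, else 0).

    Exact zeros map to 0 so the rule is total and deterministic.
    """
    return BipartitionSeries(data=(z.data > 0).astype(np.int8), provenance=z)


def pnull_expected(bps: BipartitionSeries, frames: FrameSet) -> float:
    """Expected chance co-classification rate over the selected frames."""
    if len(frames) == 0:
        raise ValueError("empty frame set")
    N = bps.n_nodes
    n1 = bps.data[frames.indices].sum(axis=1).astype(float)  # per-frame 1-group size
    n0 = N - n1
    per_frame = (n1 / N) * ((n1 - 1) / (N - 1)) + (n0 / N) * ((n0 - 1) / (N - 1))
    return float(per_frame.mean())


def agreement_component(
    bps: BipartitionSeries, frames: FrameSet, corrected: bool = True
) -> AgreementComponent:
    """Agreement component (AGc) from a subset of bipartitioned frames.

    Raw entry (i, j) is the fraction of selected frames in which nodes i and
    j carry equal labels; with ``corrected`` the scalar ``pnull_expected``
    is subtracted from every entry.
    """
    if len(frames) == 0:
        raise ValueError("empty frame set")
    B = bps.data[frames.indices].astype(float)
    l = B.shape[0]
    # same-label count = #frames both 1 + #frames both 0
    agree = (B.T @ B + (1.0 - B).T @ (1.0 - B)) / l
    np.fill_diagonal(agree, 1.0)
    pnull = pnull_expected(bps, frames)
    if corrected:
        agree = agree - pnull
    return AgreementComponent(
        matrix=agree, pnull=pnull, frames_used=frames, corrected=corrected
    )


def subject_agreement(
    run_bps: list[BipartitionSeries],
    run_frames: list[FrameSet],
    corrected: bool = True,
) -> np.ndarray:
    """Subject-level AGc edge vector: unweighted mean of per-run components.

    Agreement is computed per run from that run's selected frames, then
    averaged across runs; returns the off-diagonal edge vector.
    """
    if len(run_bps) != len(run_frames) or not run_bps:
        raise ValueError("need matching, nonempty run lists")
    vecs = [
        agreement_component(b, f, corrected=corrected).vec()
        for b, f in zip(run_bps, run_frames)
    ]
    return np.mean(vecs, axis=0)
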