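"""Circular-shift null models for frame-selection consistency.

Repeated optimizations select framesets per cross-validation; stacking them
as a raster gives per-frame selection counts.  The null rigidly rotates
each cross-validation's frameset by an independent uniform offset around
the circular time axis -- preserving set size, autocorrelation, and the
spacing between selected frames while randomizing position -- and the
observed per-frame count is compared against the null counts with the
conservative convention p = (1 + #{null >= observed}) / (1 + n_iter).
Overlap of significant frames across behaviors is tested the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from framefilter.core import FrameSet

__all__ = [
    "SelectionRaster", "SignificantFrames", "circshift_frameset",
    "selection_counts", "consistency_pvalues", "behavior_overlap",
    "framewise_property_summary",
]


@dataclass
class SelectionRaster:
    """Per-frame counts of how many cross-validations selected each frame."""

    counts: np.ndarray
    n_cv: int


@dataclass
class SignificantFrames:
    """Frames whose selection consistency beats the circshift null."""

    frames: FrameSet
    alpha: float
    pvals: np.ndarray


def circshift_frameset(frames: FrameSet, offset: int, T: int | None = None) -> FrameSet:
    """Rigidly rotate a frameset by ``offset`` modulo T (wrapping at edges)."""
    T = frames.T if T is None else T
    return FrameSet(indices=np.sort((frames.indices + offset) % T), T=T)


def selection_counts(framesets: list[FrameSet], T: int) -> SelectionRaster:
    counts = np.zeros(T, dtype=int)
    for fs in framesets:
        counts[fs.indices] += 1
    return SelectionRaster(counts=counts, n_cv=len(framesets))


def consistency_pvalues(
    framesets: list[FrameSet],
    T: int,
    n_iter: int = 10_000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> SignificantFrames:
    """Per-frame selection-consistency p-values against circshifted nulls.

    Each null iteration shifts every cross-validation's frameset by its own
    uniform random offset; p[t] = (1 + #{null count[t] >= observed[t]}) /
    (1 + n_iter), never exactly zero.
    """
    if len(framesets) < 2:
        raise ValueError("need at least 2 cross-validations")
    rng = np.random.default_rng(seed)
    observed = selection_counts(framesets, T).counts
    exceed = np.zeros(T, dtype=int)
    idx = [fs.indices for fs in framesets]
    for _ in range(n_iter):
        null_counts = np.zeros(T, dtype=int)
        offsets = rng.integers(0, T, size=len(idx))
        for ind, off in zip(idx, offsets):
            null_counts[(ind + off) % T] += 1
        exceed += null_counts >= observed
    pvals = (1.0 + exceed) / (1.0 + n_iter)
    sig = np.flatnonzero(pvals < alpha)
    return SignificantFrames(frames=FrameSet(indices=sig, T=T), alpha=alpha, pvals=pvals)


def behavior_overlap(
    sig_by_behavior: dict[str, SignificantFrames],
    T: int,
    n_iter: int = 10_000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Cross-behavior overlap of significant frames versus circshifted nulls.

    Counts, per frame, how many behaviors flagged it; the null shifts each
    behavior's significant set independently per iteration.  Returns the
    observed counts, p-values (same convention as consistency), and the
    frames overlapping more than chance.
    """
    if len(sig_by_behavior) < 2:
        raise ValueError("need at least 2 behaviors")
    rng = np.random.default_rng(seed)
    sets = [sf.frames.indices for sf in sig_by_behavior.values()]
    observed = np.zeros(T, dtype=int)
    for ind in sets:
        observed[ind] += 1
    exceed = np.zeros(T, dtype=int)
    for _ in range(n_iter):
        null_counts = np.zeros(T, dtype=int)
        offsets = rng.integers(0, T, size=len(sets))
        for ind, off in zip(sets, offsets):
            if ind.size:
                null_counts[(ind + off) % T] += 1
        exceed += null_counts >= observed
    pvals = (1.0 + exceed) / (1.0 + n_iter)
    sig = np.flatnonzero(pvals < alpha)
    return {
        "counts": observed,
        "pvals": pvals,
        "significant": FrameSet(indices=sig, T=T),
        "alpha": alpha,
    }


def framewise_property_summary(
    frames: FrameSet,
    rss: np.ndarray,
    fc_sim: np.ndarray | None = None,
    fd: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Mean framewise properties over a frameset, all frames, and a matched
    random frameset.

    Properties: RSS amplitude, similarity to full FC, and (if provided) a
    framewise-displacement-like nuisance column; FD is optional and absent
    for synthetic data.
    """
    rss = np.asarray(getattr(rss, "values", rss), dtype=float)
    T = frames.T
    if rss.size != T:
        raise ValueError("RSS length does not match frameset T")
    props = {"rss": rss}
    if fc_sim is not None:
        fc_sim = np.asarray(fc_sim, dtype=float)
        if fc_sim.size != T:
            raise ValueError("fc_sim length does not match frameset T")
        props["fc_similarity"] = fc_sim
    if fd is not None:
        fd = np.asarray(fd, dtype=float)
        if fd.size != T:
            raise ValueError("fd length does not match frameset T")
        props["fd"] = fd
    rng = np.random.default_rng(seed)
    rand = np.sort(rng.choice(T, size=len(frames), replace=False))
    out = {}
    for name, vec in props.items():
        out[name] = {
            "selected_mean": float(vec[frames.indices].mean()),
            "global_mean": float(vec.mean()),
            "random_mean": float(vec[rand].mean()),
        }
    return out
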