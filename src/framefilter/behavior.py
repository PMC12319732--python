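"""Brain-behavior maps: confound residualization, edgewise Spearman, costs.

A brain-behavior map relates one behavioral measure, residualized on
nuisance confounds (age, sex, BMI, head motion, intracranial volume in the
motivating application), to connectivity-component edges across subjects:
per edge, the Spearman correlation between that edge's value over subjects
and the behavior vector.  The scalar objective used by the template
optimizer is mean(|rho|) over all edges.  Transfer metrics compare a
training group's map with a held-out group's map built from the same
template -- the generalizability currency of the whole approach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BrainBehaviorMap", "MapSummary", "residualize", "edgewise_spearman",
    "cost_mean_abs", "map_transfer", "signed_edge_transfer", "map_kurtosis",
]


@dataclass
class BrainBehaviorMap:
    """Per-edge Spearman rho across subjects for one behavior."""

    rho: np.ndarray
    behavior_name: str = "behavior"
    n_subjects: int = 0


@dataclass
class MapSummary:
    mean_abs: float
    kurtosis: float
    pos_mask: np.ndarray
    neg_mask: np.ndarray


def residualize(scores: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """OLS residuals of ``scores`` on confound columns plus an intercept.

    Residualization is refit within each subject group it is applied to
    (train and test separately); never fit on one group and applied to
    another.  Raises on a rank-deficient confound design.
    """
    scores = np.asarray(scores, dtype=float)
    if confounds is None:
        return scores - scores.mean()
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    S = scores.shape[0]
    if C.shape[0] != S:
        raise ValueError("confound rows do not match score length")
    X = np.column_stack([np.ones(S), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        sds = C.std(axis=0)
        const = [str(i) for i in np.flatnonzero(sds == 0)]
        detail = f" (constant columns: {', '.join(const)})" if const else ""
        raise ValueError(f"rank-deficient confound design{detail}")
    if S <= X.shape[1]:
        raise ValueError("need more subjects than confounds + intercept")
    beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
    return scores - X @ beta


def _rank_columns(arr: np.ndarray) -> np.ndarray:
    return stats.rankdata(arr, axis=0, method="average")


def edgewise_spearman(
    components: np.ndarray, behavior: np.ndarray, behavior_name: str = "behavior"
) -> BrainBehaviorMap:
    """Spearman rho, per edge, between edge values and behavior across subjects.

    ``components`` is subjects S x edges K (each row a subject's component
    edge vector in the shared ordering).  Average ranks handle ties; an
    edge constant across subjects gets rho = 0 with a warning so downstream
    costs stay defined.
    """
    comp = np.asarray(components, dtype=float)
    beh = np.asarray(behavior, dtype=float)
    if comp.ndim != 2:
        raise ValueError("components must be subjects x edges")
    S = comp.shape[0]
    if beh.shape[0] != S:
        raise ValueError("subject count mismatch between components and behavior")
    if S < 4:
        raise ValueError("need at least 4 subjects")
    R = _rank_columns(comp)
    rb = stats.rankdata(beh, method="average")
    Rc = R - R.mean(axis=0)
    rbc = rb - rb.mean()
    num = Rc.T @ rbc
    den = np.linalg.norm(Rc, axis=0) * np.linalg.norm(rbc)
    rho = np.zeros(comp.shape[1])
    ok = den > 0
    if np.any(~ok):
        warnings.warn("constant edge(s) across subjects; rho recorded as 0")
    if np.linalg.norm(rbc) == 0:
        raise ValueError("behavior vector is constant")
    rho[ok] = num[ok] / den[ok]
    return BrainBehaviorMap(rho=np.clip(rho, -1, 1), behavior_name=behavior_name,
                            n_subjects=S)


def cost_mean_abs(bb: BrainBehaviorMap) -> float:
    """Objective D = mean(abs(rho)) over all edges."""
    return float(np.mean(np.abs(bb.rho)))


def map_transfer(train: BrainBehaviorMap, test: BrainBehaviorMap) -> float:
    """Spearman correlation between train and test maps (generalizability)."""
    a, b = np.asarray(train.rho), np.asarray(test.rho)
    if a.shape != b.shape:
        raise ValueError("maps must share edge count")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant map in transfer; recorded as 0")
        return 0.0
    return float(stats.spearmanr(a, b).statistic)


def signed_edge_transfer(
    train: BrainBehaviorMap, test: BrainBehaviorMap
) -> tuple[float, float]:
    """Mean test rho within the train map's positive and negative edge sets."""
    a, b = np.asarray(train.rho), np.asarray(test.rho)
    if a.shape != b.shape:
        raise ValueError("maps must share edge count")
    pos, neg = a > 0, a < 0
    out = []
    for mask, name in ((pos, "positive"), (neg, "negative")):
        if not mask.any():
            warnings.warn(f"empty {name} edge mask; transfer recorded as 0")
            out.append(0.0)
        else:
            out.append(float(b[mask].mean()))
    return out[0], out[1]


def map_kurtosis(bb: BrainBehaviorMap) -> float:
    """Sample excess kurtosis of the edge-correlation distribution."""
    rho = np.asarray(bb.rho)
    if rho.size < 4:
        raise ValueError("need at least 4 edges")
    if np.var(rho) == 0:
        raise ValueError("zero-variance map has undefined kurtosis")
    return float(stats.kurtosis(rho, fisher=True, bias=False))


def summarize_map(bb: BrainBehaviorMap) -> MapSummary:
    """Scalar summaries plus the signed edge masks of a map."""
    rho = np.asarray(bb.rho)
    return MapSummary(
        mean_abs=cost_mean_abs(bb),
        kurtosis=map_kurtosis(bb) if np.var(rho) > 0 else 0.0,
        pos_mask=rho > 0,
        neg_mask=rho < 0,
    )
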