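"""Simulated-annealing optimization of behavior-specific filtering templates.

The search space is the 2^N binary node templates; exhaustive evaluation is
infeasible, so a Metropolis-Hastings chain explores it.  Each iteration
mutates the current template by flipping 1, 2, or 3 uniformly chosen nodes
with probabilities 0.68, 0.27, and 0.04 (renormalized), filters the top
fraction of best-matching frames per run, rebuilds per-subject agreement
components, scores the edgewise brain-behavior map by the objective
D = mean(|rho|), and accepts the move if D improves or, otherwise, with
probability exp(-dD / Temp) under the geometric cooling schedule
Temp = T0 * Texp^h.  Cross-validation wraps the optimizer in repeated 80/20
subject splits with residualization refit inside each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from framefilter.behavior import (
    cost_mean_abs,
    edgewise_spearman,
    map_transfer,
    residualize,
    signed_edge_transfer,
)
from framefilter.bipartition import BipartitionSeries
from framefilter.core import FrameSet
from framefilter.template_filter import Template, _mi_from_counts

__all__ = [
    "CoolingSchedule", "OptimizationConfig", "OptimizationResult",
    "CrossValidationSplit", "TemplateEvaluator", "cooling_temperature",
    "propose_mutation", "accept_step", "optimize_template", "make_cv_split",
    "run_cross_validation",
]

# flip-count kernel: printed weights (0.68, 0.27, 0.04) sum to 0.99 and are
# renormalized to a proper categorical distribution
FLIP_PROBS = (0.68, 0.27, 0.04)


@dataclass
class CoolingSchedule:
    """Geometric cooling Temp(h) = T0 * Texp**h.

    Defaults put the starting temperature on the scale of typical early
    cost differences of the mean-|rho| objective (a few hundredths) and
    decay to a near-greedy regime within a thousand iterations.
    """

    T0: float = 0.05
    Texp: float = 0.996

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not 0 < self.Texp < 1:
            raise ValueError("Texp must lie in (0, 1)")


@dataclass
class OptimizationConfig:
    n_iter: int = 10_000
    fraction: float = 0.10
    seed: int = 0
    cooling: CoolingSchedule = field(default_factory=CoolingSchedule)
    flip_probs: tuple[float, ...] = FLIP_PROBS

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


@dataclass
class OptimizationResult:
    best_template: Template
    best_cost: float
    cost_trace: np.ndarray
    accept_trace: np.ndarray
    per_subject_frames: dict
    seed: int


@dataclass
class CrossValidationSplit:
    train_ids: list
    test_ids: list
    seed: int


def cooling_temperature(sched: CoolingSchedule, h: int) -> float:
    """Temperature after h iterations of geometric decay."""
    if h < 0:
        raise ValueError("iteration index must be >= 0")
    return sched.T0 * sched.Texp**h


def propose_mutation(
    tpl: Template, rng: np.random.Generator, flip_probs=FLIP_PROBS
) -> Template:
    """Flip k distinct uniformly chosen nodes, k ~ categorical over {1, 2, 3}.

    The stated weights are renormalized to sum 1.  Returns a new template;
    the input is left unmodified.
    """
    p = np.asarray(flip_probs, dtype=float)
    p = p / p.sum()
    k = int(rng.choice(np.arange(1, len(p) + 1), p=p))
    nodes = rng.choice(len(tpl), size=k, replace=False)
    labels = tpl.labels.copy()
    labels[nodes] = 1 - labels[nodes]
    return Template(labels=labels, name=tpl.name)


def accept_step(
    D_new: float, D_ref: float, temp: float, rng: np.random.Generator
) -> bool:
    """Metropolis acceptance: improvements always; worsenings with
    probability exp(-dD / Temp); a frozen system (temp = 0) never accepts a
    worse cost."""
    if D_new >= D_ref:
        return True
    if temp <= 0:
        return False
    return bool(np.exp(-(D_ref - D_new) / temp) > rng.uniform())


class TemplateEvaluator:
    """Evaluates a template's objective D on a fixed set of subjects.

    All runs are stacked once at construction so that each template costs
    one matrix-vector NMI pass, a batched top-fraction selection, and a
    batched agreement computation; frame-marginal entropies, which do not
    depend on the template, are precomputed.  Requires equal frame counts
    and run counts across subjects (the pipeline's normal shape).
    """

    def __init__(
        self,
        bps_by_subject: dict[str, list[BipartitionSeries]],
        behavior: np.ndarray,
        fraction: float = 0.10,
    ):
        self.subject_ids = list(bps_by_subject)
        self.behavior = np.asarray(behavior, dtype=float)
        if self.behavior.shape[0] != len(self.subject_ids):
            raise ValueError("behavior length does not match subject count")
        if np.all(self.behavior == self.behavior[0]):
            raise ValueError("behavior vector is constant")
        if len(self.subject_ids) < 4:
            raise ValueError("need at least 4 subjects")
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        self.fraction = fraction

        runs = [bps_by_subject[s] for s in self.subject_ids]
        n_runs = {len(r) for r in runs}
        shapes = {b.data.shape for r in runs for b in r}
        if len(n_runs) != 1 or len(shapes) != 1:
            raise ValueError(
                "all subjects must share the same run count and series shape"
            )
        self.runs_per_subject = n_runs.pop()
        self.T, self.n_nodes = shapes.pop()
        self.n_sel = max(1, int(round(self.fraction * self.T)))

        # stacked bipartitions: (total runs, T, N)
        self._B = np.stack(
            [b.data.astype(np.float64) for r in runs for b in r], axis=0
        )
        self._R = self._B.shape[0]
        flat = self._B.reshape(-1, self.n_nodes)
        self._flatB = flat
        self._rowsum = flat.sum(axis=1)  # per-frame 1-group size
        N = self.n_nodes
        q = self._rowsum / N
        with np.errstate(divide="ignore", invalid="ignore"):
            self._h_frames = -(
                np.where(q > 0, q * np.log(q), 0.0)
                + np.where(q < 1, (1 - q) * np.log(1 - q), 0.0)
            )
        self._iu, self._ju = np.triu_indices(N, k=1)

    def _scores(self, tpl: Template) -> np.ndarray:
        """Normalized MI of every frame against the template, (R, T)."""
        if len(tpl) != self.n_nodes:
            raise ValueError("template length does not match node count")
        N = self.n_nodes
        a = tpl.labels.astype(np.float64)
        a1 = a.sum()
        n11 = self._flatB @ a
        n10 = self._rowsum - n11
        n01 = a1 - n11
        n00 = N - n11 - n10 - n01
        mi, hb, ha = _mi_from_counts(n11, n10, n01, n00, N)
        denom = ha + self._h_frames
        scores = np.zeros_like(mi)
        ok = (self._h_frames > 0) & (ha > 0)
        scores[ok] = 2.0 * mi[ok] / denom[ok]
        return scores.reshape(self._R, self.T)

    def select_indices(self, tpl: Template) -> np.ndarray:
        """Sorted selected-frame indices per run, shape (R, n_sel).

        Ties at the cutoff break toward earlier frames (stable sort on
        descending score), matching ``match_frames``.
        """
        scores = self._scores(tpl)
        order = np.argsort(-scores, axis=1, kind="stable")
        return np.sort(order[:, : self.n_sel], axis=1)

    def subject_components(self, sel: np.ndarray) -> np.ndarray:
        """Subjects x edges matrix of run-averaged corrected AGc vectors."""
        N = self.n_nodes
        l = sel.shape[1]
        Bs = np.take_along_axis(self._B, sel[:, :, None], axis=1)  # (R, l, N)
        agree = (
            np.einsum("rli,rlj->rij", Bs, Bs)
            + np.einsum("rli,rlj->rij", 1.0 - Bs, 1.0 - Bs)
        ) / l
        n1 = Bs.sum(axis=2)
        n0 = N - n1
        pnull = (
            (n1 / N) * ((n1 - 1) / (N - 1)) + (n0 / N) * ((n0 - 1) / (N - 1))
        ).mean(axis=1)
        vecs = agree[:, self._iu, self._ju] - pnull[:, None]
        return vecs.reshape(len(self.subject_ids), self.runs_per_subject, -1).mean(axis=1)

    def frames_dict(self, sel: np.ndarray) -> dict:
        """Selected indices as subject -> list of FrameSets."""
        out = {}
        for i, s in enumerate(self.subject_ids):
            base = i * self.runs_per_subject
            out[s] = [
                FrameSet(indices=sel[base + r], T=self.T)
                for r in range(self.runs_per_subject)
            ]
        return out

    def select_frames(self, tpl: Template) -> dict:
        """Top-fraction best-matching frames per subject and run."""
        return self.frames_dict(self.select_indices(tpl))

    def evaluate(self, tpl: Template):
        """Return (cost D, selected indices (R, n_sel), brain-behavior map)."""
        sel = self.select_indices(tpl)
        comps = self.subject_components(sel)
        bb = edgewise_spearman(comps, self.behavior)
        return cost_mean_abs(bb), sel, bb


def optimize_template(
    bps_by_subject: dict[str, list[BipartitionSeries]],
    behavior: np.ndarray,
    cfg: OptimizationConfig,
) -> OptimizationResult:
    """Anneal a behavior-specific template on the given (training) subjects.

    Fully reproducible from ``cfg.seed``: the initial random template, every
    mutation, and every acceptance draw flow from one generator.  The chain
    compares each proposal against the last *accepted* cost; the global best
    is tracked separately and returned.
    """
    evaluator = TemplateEvaluator(bps_by_subject, behavior, cfg.fraction)
    rng = np.random.default_rng(cfg.seed)
    N = evaluator.n_nodes

    current = Template(labels=rng.integers(0, 2, size=N), name="optimized")
    cur_cost, cur_sel, _ = evaluator.evaluate(current)
    best, best_cost, best_sel = current, cur_cost, cur_sel

    cost_trace = np.empty(cfg.n_iter)
    accept_trace = np.zeros(cfg.n_iter, dtype=bool)
    cost_trace[0] = cur_cost
    accept_trace[0] = True

    for h in range(1, cfg.n_iter):
        cand = propose_mutation(current, rng, cfg.flip_probs)
        cand_cost, cand_sel, _ = evaluator.evaluate(cand)
        temp = cooling_temperature(cfg.cooling, h)
        if accept_step(cand_cost, cur_cost, temp, rng):
            current, cur_cost, cur_sel = cand, cand_cost, cand_sel
            accept_trace[h] = True
            if cand_cost > best_cost:
                best, best_cost, best_sel = cand, cand_cost, cand_sel
        cost_trace[h] = cur_cost

    return OptimizationResult(
        best_template=best,
        best_cost=best_cost,
        cost_trace=cost_trace,
        accept_trace=accept_trace,
        per_subject_frames=evaluator.frames_dict(best_sel),
        seed=cfg.seed,
    )


def make_cv_split(
    subject_ids, train_frac: float = 0.8, seed: int | np.random.Generator = 0
) -> CrossValidationSplit:
    """Seeded uniform 80/20-style partition; |train| = round(train_frac * S)."""
    ids = list(subject_ids)
    S = len(ids)
    if S < 5:
        raise ValueError("need at least 5 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(S)
    n_train = int(round(train_frac * S))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return CrossValidationSplit(train_ids=train, test_ids=test, seed=int(seed_val))


def _group_map(bps_by_subject, ids, behavior_by_subject, confounds_by_subject, tpl, fraction):
    """Map + cost for one subject group under a fixed template.

    Residualization is fit inside this group only -- no rows from any other
    group enter the statistics.
    """
    beh = np.array([behavior_by_subject[s] for s in ids], dtype=float)
    if confounds_by_subject is not None:
        C = np.vstack([confounds_by_subject[s] for s in ids])
        beh = residualize(beh, C)
    ev = TemplateEvaluator({s: bps_by_subject[s] for s in ids}, beh, fraction)
    cost, sel, bb = ev.evaluate(tpl)
    return cost, ev.frames_dict(sel), bb, beh


def run_cross_validation(
    bps_by_subject: dict[str, list[BipartitionSeries]],
    behavior_by_subject: dict[str, float],
    confounds_by_subject: dict[str, np.ndarray] | None = None,
    n_splits: int = 100,
    train_frac: float = 0.8,
    cfg: OptimizationConfig | None = None,
    include_full_fc_baseline: bool = True,
    full_fc_by_subject: dict[str, np.ndarray] | None = None,
) -> list[dict]:
    """Repeated train/test optimization with per-group residualization.

    For each split: residualize behavior within the training group, anneal a
    template on training subjects only, then apply the final template to the
    held-out subjects (their behavior residualized within the test group).
    Optionally computes full-connectivity baseline maps for the same splits
    (``full_fc_by_subject``: subject -> edge vector of the full-scan
    component, e.g. all-frames corrected AGc or Pearson FC).
    """
    if cfg is None:
        cfg = OptimizationConfig()
    results = []
    for k in range(n_splits):
        split_seed = cfg.seed + 7919 * k
        split = make_cv_split(bps_by_subject.keys(), train_frac, seed=split_seed)
        run_cfg = OptimizationConfig(
            n_iter=cfg.n_iter, fraction=cfg.fraction, seed=split_seed,
            cooling=cfg.cooling, flip_probs=cfg.flip_probs,
        )

        tr_beh = np.array([behavior_by_subject[s] for s in split.train_ids])
        if confounds_by_subject is not None:
            tr_beh = residualize(
                tr_beh, np.vstack([confounds_by_subject[s] for s in split.train_ids])
            )
        opt = optimize_template(
            {s: bps_by_subject[s] for s in split.train_ids}, tr_beh, run_cfg
        )
        tr_cost, _, tr_bb, _ = _group_map(
            bps_by_subject, split.train_ids, behavior_by_subject,
            confounds_by_subject, opt.best_template, cfg.fraction,
        )
        te_cost, te_frames, te_bb, _ = _group_map(
            bps_by_subject, split.test_ids, behavior_by_subject,
            confounds_by_subject, opt.best_template, cfg.fraction,
        )
        rec = {
            "split": split,
            "result": opt,
            "train_cost": tr_cost,
            "test_cost": te_cost,
            "train_map": tr_bb,
            "test_map": te_bb,
            "test_frames": te_frames,
            "transfer": map_transfer(tr_bb, te_bb),
            "signed_transfer": signed_edge_transfer(tr_bb, te_bb),
        }
        if include_full_fc_baseline and full_fc_by_subject is not None:
            rec["fc_transfer"], rec["fc_costs"] = _baseline_transfer(
                full_fc_by_subject, split, behavior_by_subject, confounds_by_subject
            )
        results.append(rec)
    return results


def _baseline_transfer(full_fc_by_subject, split, behavior_by_subject, confounds_by_subject):
    out = {}
    for name, ids in (("train", split.train_ids), ("test", split.test_ids)):
        beh = np.array([behavior_by_subject[s] for s in ids])
        if confounds_by_subject is not None:
            beh = residualize(beh, np.vstack([confounds_by_subject[s] for s in ids]))
        comp = np.vstack([full_fc_by_subject[s] for s in ids])
        out[name] = edgewise_spearman(comp, beh)
    costs = {k: cost_mean_abs(v) for k, v in out.items()}
    return map_transfer(out["train"], out["test"]), costs
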