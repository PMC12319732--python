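"""Metropolis-Hastings template optimization and cross-validation driver."""

import numpy as np
import pytest

from framefilter.anneal import (
    CoolingSchedule,
    OptimizationConfig,
    accept_step,
    cooling_temperature,
    make_cv_split,
    optimize_template,
    propose_mutation,
    run_cross_validation,
)
from framefilter.behavior import residualize
from framefilter.pipeline import cohort_bipartitions, cohort_full_agc
from framefilter.template_filter import Template


@pytest.fixture(scope="module")
def tiny_cohort(tiny_dataset):
    ds = tiny_dataset
    bps = cohort_bipartitions(ds.series)
    ids = ds.subject_ids
    beh = residualize(
        ds.behaviors.loc[ids, "coupled"].to_numpy(float),
        ds.confounds.loc[ids].to_numpy(float),
    )
    return bps, beh


class TestCooling:
    def test_geometric_decay_values(self):
        s = CoolingSchedule(T0=1.0, Texp=0.9)
        assert cooling_temperature(s, 0) == 1.0
        assert cooling_temperature(s, 1) == pytest.approx(0.9)

    def test_monotone_to_zero(self):
        s = CoolingSchedule(T0=0.5, Texp=0.99)
        temps = [cooling_temperature(s, h) for h in range(0, 2000, 100)]
        assert all(a > b for a, b in zip(temps, temps[1:]))
        assert temps[-1] < 1e-4 * temps[0]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CoolingSchedule(T0=0.0)
        with pytest.raises(ValueError):
            CoolingSchedule(Texp=1.0)


class TestMutation:
    def test_hamming_distance_in_1_2_3(self):
        rng = np.random.default_rng(0)
        tpl = Template(labels=rng.integers(0, 2, size=30))
        for _ in range(500):
            out = propose_mutation(tpl, rng)
            d = int(np.sum(out.labels != tpl.labels))
            assert d in (1, 2, 3)

    def test_input_unmodified(self):
        rng = np.random.default_rng(1)
        tpl = Template(labels=np.zeros(10, dtype=int))
        before = tpl.labels.copy()
        propose_mutation(tpl, rng)
        np.testing.assert_array_equal(tpl.labels, before)

    def test_flip_count_frequencies(self):
        # printed weights 0.68/0.27/0.04 renormalized by their 0.99 sum
        rng = np.random.default_rng(2)
        tpl = Template(labels=rng.integers(0, 2, size=50))
        counts = np.zeros(4)
        n = 100_000
        for _ in range(n):
            out = propose_mutation(tpl, rng)
            counts[int(np.sum(out.labels != tpl.labels))] += 1
        assert counts[1] / n == pytest.approx(0.68 / 0.99, abs=0.01)
        assert counts[2] / n == pytest.approx(0.27 / 0.99, abs=0.01)
        assert counts[3] / n == pytest.approx(0.04 / 0.99, abs=0.005)

    def test_same_seed_identical_proposal(self):
        tpl = Template(labels=np.arange(20) % 2)
        a = propose_mutation(tpl, np.random.default_rng(42))
        b = propose_mutation(tpl, np.random.default_rng(42))
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAcceptStep:
    def test_improvement_always_accepted(self):
        rng = np.random.default_rng(0)
        assert accept_step(0.5, 0.4, temp=0.0, rng=rng)
        assert accept_step(0.5, 0.4, temp=10.0, rng=rng)

    def test_worsening_rejected_when_frozen(self):
        rng = np.random.default_rng(0)
        assert not accept_step(0.3, 0.4, temp=0.0, rng=rng)

    def test_equal_cost_accepted(self):
        rng = np.random.default_rng(0)
        assert accept_step(0.4, 0.4, temp=0.0, rng=rng)

    def test_worsening_acceptance_rate_matches_boltzmann(self):
        rng = np.random.default_rng(3)
        temp, dD = 0.1, 0.05
        acc = sum(accept_step(0.0, dD, temp, rng) for _ in range(20_000)) / 20_000
        assert acc == pytest.approx(np.exp(-dD / temp), abs=0.02)


class TestOptimize:
    def test_single_iteration_returns_initial_template(self, tiny_cohort):
        bps, beh = tiny_cohort
        res = optimize_template(bps, beh, OptimizationConfig(n_iter=1, seed=4))
        assert res.cost_trace.shape == (1,)
        assert res.best_cost == res.cost_trace[0]

    def test_best_cost_never_below_initial(self, tiny_cohort):
        bps, beh = tiny_cohort
        for seed in (0, 1, 2):
            res = optimize_template(bps, beh, OptimizationConfig(n_iter=40, seed=seed))
            assert res.best_cost >= res.cost_trace[0]

    def test_running_maximum_non_decreasing(self, tiny_cohort):
        bps, beh = tiny_cohort
        res = optimize_template(bps, beh, OptimizationConfig(n_iter=60, seed=5))
        running = np.maximum.accumulate(res.cost_trace)
        assert np.all(np.diff(running) >= 0)
        assert res.best_cost == pytest.approx(running[-1])

    def test_frozen_chain_is_strict_hill_climb(self, tiny_cohort):
        bps, beh = tiny_cohort
        cfg = OptimizationConfig(
            n_iter=60, seed=6, cooling=CoolingSchedule(T0=1e-300, Texp=0.5)
        )
        res = optimize_template(bps, beh, cfg)
        accepted = res.cost_trace[res.accept_trace]
        assert np.all(np.diff(accepted) >= -1e-15)

    def test_same_seed_bit_identical(self, tiny_cohort):
        bps, beh = tiny_cohort
        cfg = OptimizationConfig(n_iter=30, seed=7)
        a = optimize_template(bps, beh, cfg)
        b = optimize_template(bps, beh, cfg)
        np.testing.assert_array_equal(a.best_template.labels, b.best_template.labels)
        np.testing.assert_array_equal(a.cost_trace, b.cost_trace)
        np.testing.assert_array_equal(a.accept_trace, b.accept_trace)
        for s in a.per_subject_frames:
            for fa, fb in zip(a.per_subject_frames[s], b.per_subject_frames[s]):
                np.testing.assert_array_equal(fa.indices, fb.indices)

    def test_constant_behavior_rejected_before_iterating(self, tiny_cohort):
        bps, _ = tiny_cohort
        with pytest.raises(ValueError):
            optimize_template(bps, np.ones(len(bps)), OptimizationConfig(n_iter=5))


class TestCrossValidation:
    def test_352_subjects_split_282_70(self):
        split = make_cv_split([f"s{i}" for i in range(352)], 0.8, seed=0)
        assert len(split.train_ids) == 282
        assert len(split.test_ids) == 70

    def test_split_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(10)]
        split = make_cv_split(ids, 0.5, seed=1)
        assert len(split.train_ids) == 5 and len(split.test_ids) == 5
        assert set(split.train_ids) | set(split.test_ids) == set(ids)
        assert not set(split.train_ids) & set(split.test_ids)

    def test_cv_deterministic_and_leak_free(self, tiny_dataset):
        ds = tiny_dataset
        bps = cohort_bipartitions(ds.series)
        beh = {s: float(ds.behaviors.loc[s, "coupled"]) for s in ds.subject_ids}
        conf = {s: ds.confounds.loc[s].to_numpy(float) for s in ds.subject_ids}
        fc = cohort_full_agc(bps)
        cfg = OptimizationConfig(n_iter=8, seed=9)
        kw = dict(n_splits=2, train_frac=0.6, cfg=cfg, full_fc_by_subject=fc)
        a = run_cross_validation(bps, beh, conf, **kw)
        b = run_cross_validation(bps, beh, conf, **kw)
        for ra, rb in zip(a, b):
            assert ra["transfer"] == rb["transfer"]
            np.testing.assert_array_equal(ra["test_map"].rho, rb["test_map"].rho)
            # the test map is built from test subjects only
            assert ra["test_map"].n_subjects == len(ra["split"].test_ids)
            assert not set(ra["split"].train_ids) & set(ra["split"].test_ids)
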