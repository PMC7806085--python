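"""Split protocols: disjointness, balance, seed isolation; small end-to-end
runs of the validation drivers."""

import numpy as np
import pytest

import palpaid as p
from palpaid.validation import pool_accuracy


@pytest.fixture(scope="module")
def small_cohort(desk_profile):
    return p.generate_cohort(3, desk_profile, rng=np.random.default_rng(21))


def _class_counts(ids, trials):
    present = sum(trials[i].tumor_present for i in ids)
    return present, len(ids) - present


class TestWithinPlan:
    def test_counts_and_balance(self, participant_trials):
        folds = p.within_participant_plan(participant_trials,
                                          np.random.default_rng(0))
        assert len(folds) == 4 and all(len(f) == 5 for f in folds)
        for fold in folds:
            for plan in fold:
                assert len(plan.test_ids) == 10
                assert _class_counts(plan.train_ids, participant_trials) == (10, 10)
                assert _class_counts(plan.calib_ids, participant_trials) == (5, 5)
                combined = set(plan.test_ids) | set(plan.train_ids) | set(plan.calib_ids)
                assert len(combined) == 40

    def test_folds_partition_all_trials(self, participant_trials):
        folds = p.within_participant_plan(participant_trials,
                                          np.random.default_rng(1))
        tests = [i for fold in folds for i in fold[0].test_ids]
        assert sorted(tests) == list(range(40))

    def test_fold_seed_isolated_from_split_seed(self, participant_trials):
        def plans(fold_seed, split_seed):
            return p.within_participant_plan(
                participant_trials, np.random.default_rng(split_seed),
                fold_rng=np.random.default_rng(fold_seed))

        a = plans(5, 1)
        b = plans(5, 2)
        assert [f[0].test_ids for f in a] == [f[0].test_ids for f in b]
        assert [pl.train_ids for f in a for pl in f] != \
            [pl.train_ids for f in b for pl in f]

    def test_unbalanced_input_rejected(self, participant_trials):
        with pytest.raises(ValueError, match="protocol requires"):
            p.within_participant_plan(participant_trials[:30],
                                      np.random.default_rng(0))

    @pytest.mark.parametrize("seed", range(8))
    def test_disjointness_over_seeds(self, participant_trials, seed):
        folds = p.within_participant_plan(participant_trials,
                                          np.random.default_rng(seed))
        for fold in folds:
            for plan in fold:
                assert not set(plan.test_ids) & set(plan.train_ids)
                assert not set(plan.test_ids) & set(plan.calib_ids)
                assert not set(plan.train_ids) & set(plan.calib_ids)


class TestAcrossPlan:
    def test_counts_per_quoted_arithmetic(self, small_cohort):
        plans = p.across_participant_plan(small_cohort,
                                          np.random.default_rng(0))
        n_others = len(small_cohort) - 1
        assert len(plans) == len(small_cohort)
        for held_out, fold_plans in plans:
            assert len(fold_plans) == 5
            for plan in fold_plans:
                assert len(plan.test_ids) == 40
                assert len(plan.train_ids) == 26 * n_others
                assert len(plan.calib_ids) == 14 * n_others
                # held-out participant never leaks into model construction
                assert all(pid != held_out for pid, _ in plan.train_ids)
                assert all(pid != held_out for pid, _ in plan.calib_ids)

    def test_every_contributor_gives_13_13_and_7_7(self, small_cohort):
        plans = p.across_participant_plan(small_cohort,
                                          np.random.default_rng(3))
        held_out, fold_plans = plans[0]
        for plan in fold_plans:
            for pid, trials in small_cohort.items():
                if pid == held_out:
                    continue
                train_p = sum(trials[i].tumor_present
                              for q, i in plan.train_ids if q == pid)
                train_a = sum(not trials[i].tumor_present
                              for q, i in plan.train_ids if q == pid)
                calib_p = sum(trials[i].tumor_present
                              for q, i in plan.calib_ids if q == pid)
                assert (train_p, train_a) == (13, 13)
                assert calib_p == 7

    def test_twelve_participant_arithmetic(self):
        # 11 contributors x 26 = 286 training, x 14 = 154 calibration trials
        assert 11 * 26 == 286 and 11 * 14 == 154


@pytest.fixture(scope="module")
def within_result(participant_trials):
    seg = p.WindowSegmenterMLP(epochs=25)
    return p.run_within_validation({"P01": participant_trials}, seg,
                                   seed=5)["P01"]


class TestRunValidation:
    def test_high_snr_within_participant_separates_classes(self, within_result):
        s = within_result.summary()
        assert s["acc_mean"] >= 0.9
        assert s["a_g_mean"] >= 0.95
        assert len(within_result.folds) == 4

    def test_fold_bookkeeping(self, within_result):
        for fold in within_result.folds:
            assert fold.n_test == 10
            assert len(fold.criteria) == 5
            assert 0.0 <= fold.c_th_mean <= 1.0
            assert 0.0 <= fold.a_g <= 1.0
        correct, total = pool_accuracy(within_result)
        assert total == 40 and 0 <= correct <= 40

    def test_rerun_with_same_seed_is_identical(self, participant_trials,
                                               within_result):
        seg = p.WindowSegmenterMLP(epochs=25)
        again = p.run_within_validation({"P01": participant_trials}, seg,
                                        seed=5)["P01"]
        np.testing.assert_array_equal(again.accuracies, within_result.accuracies)
        np.testing.assert_array_equal(again.areas, within_result.areas)
        np.testing.assert_allclose(again.criteria, within_result.criteria)


def test_compare_with_human_hook():
    rng = np.random.default_rng(0)
    model = rng.uniform(0.8, 1.0, size=12)
    human = model - rng.uniform(0.0, 0.1, size=12)
    out = p.compare_with_human(model, human)
    assert set(out) == {"shapiro_stat", "shapiro_p", "wilcoxon_stat",
                        "wilcoxon_p"}
    assert out["wilcoxon_p"] < 0.05  # model consistently above human here
    with pytest.raises(ValueError):
        p.compare_with_human([0.5], [0.5, 0.6])
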