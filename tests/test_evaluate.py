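"""Evaluation protocol: folds, voting, metrics, CV, hold-out, sweeps."""

import itertools

import numpy as np
import pytest

from mdfnet import (
    ConfigurationError, MetricsReport, ModelConfig, PreprocessConfig, TrainConfig,
    attention_summary, balanced_subject_folds, compute_metrics, majority_vote,
    mean_report, paired_t_test, run_cross_validation, run_repeated_holdout,
    sample_cohort_metadata, sweep_sampling_settings, train_model,
)
from oracles import auc_pair_count, majority_vote_direct, paired_t_direct

SMOKE_MODEL = ModelConfig(ttcn_channels=(4, 6, 4), cmix_channels=(4, 6, 4))
SMOKE_TRAIN = TrainConfig.scaled(epochs=3, lr_peak=1e-3, batch_size=64, rng_seed=0)


class TestBalancedFolds:
    def test_cohort_of_415_gives_83_per_fold(self):
        metas = sample_cohort_metadata(289, 126, rng_seed=1)
        folds = balanced_subject_folds(metas, k=5, n_trials=200, rng_seed=1)
        sizes = folds.balance_report.n_subjects.to_numpy()
        assert ((sizes >= 82) & (sizes <= 84)).all()
        assert sizes.sum() == 415

    def test_partition_property(self):
        metas = sample_cohort_metadata(20, 10, rng_seed=2)
        folds = balanced_subject_folds(metas, k=5, n_trials=50, rng_seed=2)
        assert sorted(folds.mapping) == sorted(m.subject_id for m in metas)
        assert set(folds.mapping.values()) == {1, 2, 3, 4, 5}

    def test_one_subject_per_fold_at_minimum(self):
        metas = sample_cohort_metadata(3, 2, rng_seed=3)
        folds = balanced_subject_folds(metas, k=5, n_trials=20, rng_seed=3)
        assert sorted(folds.mapping.values()) == [1, 2, 3, 4, 5]

    def test_chosen_split_beats_median_trial(self):
        metas = sample_cohort_metadata(40, 20, rng_seed=4)
        folds = balanced_subject_folds(metas, k=5, n_trials=200, rng_seed=4)
        assert folds.score <= np.median(folds.trial_scores)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            balanced_subject_folds(sample_cohort_metadata(2, 1, rng_seed=0), k=5)


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([0.9, 0.8, 0.2]).voted_label == 1
        assert majority_vote([0.1, 0.2, 0.8]).voted_label == 0

    def test_tie_breaks_on_mean_probability(self):
        d = majority_vote([0.9, 0.1])
        assert d.mean_probability == pytest.approx(0.5)
        assert d.voted_label == 1  # boundary goes to PD by convention
        assert majority_vote([0.8, 0.1]).voted_label == 0  # mean 0.45

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_matches_enumeration_oracle_on_grid(self):
        grid = np.round(np.arange(0.0, 1.01, 0.1), 1)
        for length in (1, 2, 3, 4):
            for probs in itertools.product(grid, repeat=length):
                assert majority_vote(list(probs)).voted_label == \
                    majority_vote_direct(list(probs)), probs


class TestMetrics:
    def test_pooled_confusion_counts(self):
        # 106 PD found / 20 missed; 13 of 289 HC misflagged
        y_true = [1] * 126 + [0] * 289
        y_pred = [1] * 106 + [0] * 20 + [1] * 13 + [0] * 276
        rep = compute_metrics(y_true, y_pred)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (106, 20, 13, 276)
        assert rep.rec == pytest.approx(106 / 126, abs=1e-9)
        assert rep.prec == pytest.approx(106 / 119, abs=1e-9)
        assert rep.acc == pytest.approx((106 + 276) / 415, abs=1e-9)

    def test_perfect_prediction(self):
        rep = compute_metrics([0, 1, 0, 1], [0, 1, 0, 1], scores=[0.1, 0.9, 0.2, 0.8])
        assert rep.acc == rep.prec == rep.rec == rep.f1 == rep.auc == 1.0

    def test_metric_identities(self, rng):
        y = rng.integers(0, 2, size=50)
        p = rng.integers(0, 2, size=50)
        rep = compute_metrics(y, p)
        n = rep.tp + rep.tn + rep.fp + rep.fn
        assert n == 50
        assert rep.acc == pytest.approx((rep.tp + rep.tn) / n)
        if rep.prec + rep.rec > 0:
            assert rep.f1 == pytest.approx(2 * rep.prec * rep.rec / (rep.prec + rep.rec))

    def test_single_class_auc_flagged_undefined(self):
        rep = compute_metrics([1, 1], [1, 0], scores=[0.9, 0.3])
        assert not rep.auc_defined and np.isnan(rep.auc)

    def test_fold_mean_reproduces_summary_row(self):
        accs = (95.1, 91.4, 87.8, 91.9, 95.2)
        reports = [MetricsReport(level="subject", tp=0, tn=0, fp=0, fn=0,
                                 acc=a, prec=0, rec=0, f1=0, auc=0) for a in accs]
        assert mean_report(reports)["acc"] == pytest.approx(92.28, abs=1e-9)

    @pytest.mark.parametrize("n", [6, 12, 20])
    def test_auc_matches_pair_counting(self, rng, n):
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        s = np.round(rng.random(n), 1)  # coarse grid forces ties
        rep = compute_metrics(y, (s >= 0.5).astype(int), scores=s)
        assert rep.auc == pytest.approx(auc_pair_count(y, s), abs=1e-9)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_guard(self):
        with pytest.warns(UserWarning):
            t, p = paired_t_test([2.0, 3.0, 4.0, 5.0, 6.0],
                                 [1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        t, p = paired_t_test(a, b)
        assert t == pytest.approx(paired_t_direct(a, b), abs=1e-9)
        assert 0 <= p <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def cv_result(small_segments, small_cohort):
    folds = balanced_subject_folds([r.meta for r in small_cohort], k=2,
                                   n_trials=50, rng_seed=0)
    return run_cross_validation(small_segments, folds, SMOKE_MODEL, SMOKE_TRAIN), folds


@pytest.fixture(scope="module")
def trained(small_segments):
    subjects = sorted({s.subject_id for s in small_segments})
    val = set(subjects[::3])
    tr = [s for s in small_segments if s.subject_id not in val]
    va = [s for s in small_segments if s.subject_id in val]
    return train_model(tr, va, ModelConfig(), SMOKE_TRAIN).model, va


class TestCrossValidation:
    def test_fold_reports_and_mean(self, cv_result):
        cv, _ = cv_result
        assert len(cv.fold_sample) == len(cv.fold_subject) == 2
        for key in ("acc", "f1", "auc"):
            assert cv.mean_subject[key] == pytest.approx(
                np.mean([getattr(r, key) for r in cv.fold_subject]), abs=1e-9)

    def test_pooled_confusion_covers_cohort(self, cv_result, small_cohort):
        cv, _ = cv_result
        assert cv.pooled_confusion.sum() == len(small_cohort)
        assert len(cv.decisions) == len(small_cohort)
        assert len({d.subject_id for d in cv.decisions}) == len(small_cohort)

    def test_summary_table_shape(self, cv_result):
        cv, _ = cv_result
        table = cv.summary_table("subject")
        assert list(table.fold) == [1, 2, "mean"]

    def test_incomplete_fold_cover_rejected(self, small_segments, small_cohort):
        folds = balanced_subject_folds([r.meta for r in small_cohort[:-2]], k=2,
                                       n_trials=10, rng_seed=0)
        with pytest.raises(ConfigurationError):
            run_cross_validation(small_segments, folds, SMOKE_MODEL, SMOKE_TRAIN)


class TestRepeatedHoldout:
    def test_smoke_aggregation(self, small_segments, small_cohort):
        res = run_repeated_holdout(small_segments, [r.meta for r in small_cohort],
                                   n_runs=2, model_cfg=SMOKE_MODEL,
                                   train_cfg=SMOKE_TRAIN, rng_seed=1)
        assert len(res.run_subject) == 2
        for k in ("acc", "f1"):
            sd = np.std([getattr(r, k) for r in res.run_subject], ddof=1)
            assert res.ci_halfwidth[k] == pytest.approx(1.96 * sd / np.sqrt(2), abs=1e-9)

    def test_bad_split_rejected(self, small_segments, small_cohort):
        with pytest.raises(ConfigurationError):
            run_repeated_holdout(small_segments, [r.meta for r in small_cohort],
                                 n_runs=1, split=(0.5, 0.2, 0.2))


def test_sweep_single_setting(small_cohort):
    folds = balanced_subject_folds([r.meta for r in small_cohort], k=2,
                                   n_trials=20, rng_seed=0)
    table = sweep_sampling_settings(small_cohort, folds, [(1.0, 20.0)],
                                    SMOKE_MODEL, SMOKE_TRAIN,
                                    PreprocessConfig(), rng_seed=0)
    assert len(table) == 1
    row = table.iloc[0]
    assert row.n_per_segment == 20
    for col in ("sample_acc", "subject_acc", "sample_auc", "subject_auc"):
        assert 0 <= row[col] <= 1


class TestAttentionSummary:
    def test_summary_lengths_match_feature_dims(self, trained):
        model, segs = trained
        summary = attention_summary(model, segs)
        assert summary.channel.shape == (32,)
        assert summary.freq.shape == (11,)
        assert summary.wavelet.shape == (26,)
        assert summary.missing_branches == ()

    def test_mean_of_simplex_vectors_stays_on_simplex(self, trained):
        model, segs = trained
        summary = attention_summary(model, segs)
        for vec in (summary.channel, summary.freq, summary.wavelet):
            assert (vec >= 0).all()
            assert vec.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_segment_summary_is_its_own_weights(self, trained):
        model, segs = trained
        one = attention_summary(model, segs[:1])
        from mdfnet import stack_domain_features
        feats, _, _ = stack_domain_features(segs[:1])
        _, attn = model.forward(feats)
        np.testing.assert_allclose(one.freq, attn["freq"][0], atol=1e-12)
        np.testing.assert_allclose(one.channel, attn["channel"][0], atol=1e-12)

    def test_disabled_branch_flagged(self, small_segments):
        model_t = ModelConfig(ttcn_channels=(4, 6, 4), cmix_channels=(4, 6, 4),
                              branches_enabled=("T", "F"))
        from mdfnet import MDFNet, FeatureShapes
        model = MDFNet(model_t, FeatureShapes(), rng_seed=0)
        summary = attention_summary(model, small_segments[:3])
        assert summary.wavelet is None
        assert summary.missing_branches == ("W",)

    def test_empty_segment_list_rejected(self, trained):
        with pytest.raises(ValueError):
            attention_summary(trained[0], [])


def test_voting_dominates_sample_accuracy_in_simulation(rng):
    """With i.i.d. per-segment accuracy p > 0.5, voting over segments can
    only help: subject-level accuracy >= sample-level accuracy."""
    p, n_subj, n_seg = 0.7, 60, 11
    correct = rng.random((n_subj, n_seg)) < p
    sample_acc = correct.mean()
    subject_acc = (correct.sum(axis=1) > n_seg / 2).mean()
    assert subject_acc >= sample_acc
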