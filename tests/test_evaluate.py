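"""Metrics, AUC, history reductions, LOOCV structure and statistics."""

import itertools

import numpy as np
import pytest
import scipy.stats

from acetoseg import evaluate
from acetoseg.errors import ValidationError
from acetoseg.evaluate import (
    ConfusionCounts,
    confusion,
    default_epoch_window,
    epoch_window_mean,
    fold_seed,
    loocv,
    metrics,
    min_loss_epoch,
    roc_auc,
    welch_t,
    wilcoxon_signed_rank,
)
from acetoseg.model import TrainingHistory, UNetConfig, dice_loss


def loop_confusion(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_prediction(self, rng):
        truth = (rng.random((8, 8)) > 0.6).astype(np.uint8)
        c = confusion(truth, truth)
        k = int(truth.sum())
        assert (c.tp, c.tn, c.fp, c.fn) == (k, 64 - k, 0, 0)

    def test_all_foreground_vs_all_background(self):
        c = confusion(np.ones((2, 2), np.uint8), np.zeros((2, 2), np.uint8))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 4, 0, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        truth = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == loop_confusion(pred, truth)

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            confusion(np.array([[0, 2]]), np.array([[0, 1]]))


class TestMetrics:
    def test_hand_computed_example(self):
        rec = metrics(ConfusionCounts(tp=50, fp=10, fn=10, tn=30))
        assert rec.accuracy == pytest.approx(0.8)
        assert rec.recall == pytest.approx(5 / 6)
        assert rec.precision == pytest.approx(5 / 6)
        assert rec.f1 == pytest.approx(5 / 6)

    def test_perfect_prediction_all_ones(self):
        rec = metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=20))
        assert (rec.accuracy, rec.recall, rec.precision, rec.f1) == (1, 1, 1, 1)

    def test_undefined_ratios_are_none(self):
        rec = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert rec.precision is None and rec.f1 is None
        assert rec.recall == 0.0
        rec = metrics(ConfusionCounts(tp=0, fp=2, fn=0, tn=5))
        assert rec.recall is None and rec.f1 is None

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @pytest.mark.parametrize("seed", range(4))
    def test_f1_equals_one_minus_dice_loss(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        truth = (rng.random((12, 12)) > 0.4).astype(np.uint8)
        rec = metrics(confusion(pred, truth))
        assert rec.f1 == pytest.approx(
            1.0 - dice_loss(pred.astype(float), truth.astype(float), smooth=0.0),
            abs=1e-12,
        )


def pairwise_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc(np.full(10, 0.5), np.arange(10) % 2) == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 400))
        scores = rng.integers(0, 7, n) / 6.0  # heavy ties
        labels = (rng.random(n) > 0.5).astype(np.uint8)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pairwise_auc(scores, labels)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(300)
        labels = (rng.random(300) > 0.4).astype(np.uint8)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([0.5, 0.6]), np.array([1, 1]))


def make_history(losses, f1=None):
    n = len(losses)
    h = TrainingHistory(
        train_loss=list(losses), val_loss=list(losses),
        accuracy=[0.9] * n, recall=[0.8] * n, precision=[0.7] * n,
        f1=list(f1) if f1 is not None else [0.75] * n,
    )
    return h


class TestHistoryReductions:
    def test_window_of_one_epoch_is_that_epoch(self):
        h = make_history([0.5, 0.4, 0.3], f1=[0.1, 0.2, 0.3])
        assert epoch_window_mean(h, (2, 2)).f1 == pytest.approx(0.2)

    def test_constant_history_unchanged(self):
        h = make_history([0.5] * 10)
        rec = epoch_window_mean(h, (1, 10))
        assert rec.f1 == pytest.approx(0.75) and rec.accuracy == pytest.approx(0.9)

    def test_nan_epochs_excluded_from_mean(self):
        h = make_history([0.5] * 4, f1=[0.5, np.nan, 0.7, np.nan])
        assert epoch_window_mean(h, (1, 4)).f1 == pytest.approx(0.6)

    def test_default_window_matches_500_epoch_convention(self):
        assert default_epoch_window(500) == (450, 500)
        assert default_epoch_window(40) == (36, 40)
        assert default_epoch_window(1) == (1, 1)

    def test_bad_window_rejected(self):
        with pytest.raises(ValidationError):
            epoch_window_mean(make_history([0.5]), (1, 2))

    def test_min_loss_strictly_decreasing_is_last(self):
        assert min_loss_epoch(make_history([0.5, 0.4, 0.3])) == 3

    def test_min_loss_tie_takes_earliest(self):
        assert min_loss_epoch(make_history([0.5, 0.2, 0.2])) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_min_loss_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        losses = rng.random(50).round(2)  # rounding forces occasional ties
        h = make_history(losses)
        best, arg = np.inf, None
        for i, v in enumerate(losses):
            if v < best:
                best, arg = v, i + 1
        assert min_loss_epoch(h) == arg


class TestWelch:
    def test_equal_samples_t_zero_p_one(self):
        a = [1.0, 2.0, 3.0]
        t, df, p = welch_t(a, a)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p < 1e-3

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 2, 12)
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_ref = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_ref = 2 * scipy.stats.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref)
        assert df == pytest.approx(df_ref)
        assert p == pytest.approx(p_ref)

    def test_invariant_under_common_shift(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        t1, _, p1 = welch_t(a, b)
        t2, _, p2 = welch_t(a + 100, b + 100)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            welch_t([1.0, 1.0], [2.0, 2.0])


def exhaustive_wilcoxon(d):
    """Enumerate all sign assignments of |d| to get the exact two-sided p
    for the observed min(R+, R-) statistic (midranks, no zeros)."""
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    w_obs = min(w_plus_obs, total - w_plus_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, total - w_plus) <= w_obs:
            count += 1
    return w_obs, count / 2 ** n


class TestWilcoxon:
    def test_all_same_sign_n6(self):
        a = np.array([2.0, 3, 4, 5, 6, 7])
        b = np.zeros(6)
        w, p = wilcoxon_signed_rank(a, b)
        assert w == 0.0
        assert p == pytest.approx(2 / 64)

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration_n8(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.3, 1, 8)
        b = rng.normal(0.0, 1, 8)
        w, p = wilcoxon_signed_rank(a, b)
        w_ref, p_ref = exhaustive_wilcoxon(a - b)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref)

    def test_invariant_under_common_shift(self, rng):
        a = rng.normal(0.5, 1, 10)
        b = rng.normal(0.0, 1, 10)
        w1, p1 = wilcoxon_signed_rank(a, b)
        w2, p2 = wilcoxon_signed_rank(a + 7, b + 7)
        assert w1 == w2 and p1 == pytest.approx(p2)


class TestLoocv:
    def test_three_cases_three_folds_of_two(self, tiny_cases):
        cases = tiny_cases[:3]
        cfg = UNetConfig(epochs=2, base_channels=2, in_channels=6)
        hists = loocv(cases, cfg, experiment_seed=1)
        assert len(hists) == 3
        assert all(h.n_train == 2 for h in hists)
        assert [h.case_id for h in hists] == [c.case_id for c in cases]

    def test_validation_folds_cover_dataset_without_repeats(self, tiny_cases):
        cfg = UNetConfig(epochs=1, base_channels=2)
        hists = loocv(tiny_cases[:4], cfg, experiment_seed=0)
        held_out = [h.case_id for h in hists]
        assert sorted(held_out) == sorted(c.case_id for c in tiny_cases[:4])

    def test_fewer_than_two_cases_rejected(self, tiny_cases):
        with pytest.raises(ValidationError):
            loocv(tiny_cases[:1], UNetConfig(epochs=1))

    def test_fold_seeds_distinct_and_stable(self):
        seeds = [fold_seed(3, i) for i in range(30)]
        assert len(set(seeds)) == 30
        assert seeds == [fold_seed(3, i) for i in range(30)]
        assert all(0 <= s < 2 ** 31 for s in seeds)


@pytest.fixture(scope="module")
def comparison(tiny_cases):
    cfg = UNetConfig(epochs=4, base_channels=2)
    return evaluate.compare_arms(tiny_cases[:3], cfg, n_experiments=2, base_seed=5)


class TestCompareArms:
    def test_bookkeeping_shapes(self, comparison):
        for arm in ("proposed", "control"):
            assert comparison.per_experiment[arm].shape == (2, 5)  # 4 metrics + auc
            assert comparison.per_case[arm].shape == (3, 5)
        assert set(comparison.records.columns) == {
            "experiment", "case", "arm", "metric", "value"
        }

    def test_summary_table_structure(self, comparison):
        s = comparison.summary()
        assert list(s.index) == ["accuracy", "recall", "precision", "f1", "auc"]
        assert {"proposed_mean", "control_mean", "proposed_sd", "control_sd"} <= set(
            s.columns
        )

    def test_deterministic_given_base_seed(self, tiny_cases, comparison):
        cfg = UNetConfig(epochs=4, base_channels=2)
        again = evaluate.compare_arms(
            tiny_cases[:3], cfg, n_experiments=2, base_seed=5
        )
        for arm in ("proposed", "control"):
            np.testing.assert_array_equal(
                comparison.per_experiment[arm].to_numpy(),
                again.per_experiment[arm].to_numpy(),
            )

    def test_identical_configurations_produce_identical_histories(self, tiny_cases):
        """Same seed + same channels -> the paired differences vanish."""
        cfg = UNetConfig(epochs=2, base_channels=2)
        h1 = loocv(tiny_cases[:3], cfg, experiment_seed=4)
        h2 = loocv(tiny_cases[:3], cfg, experiment_seed=4)
        for a, b in zip(h1, h2):
            assert a.train_loss == b.train_loss and a.f1 == b.f1

    def test_pixel_pooled_mode_runs(self, tiny_cases):
        cfg = UNetConfig(epochs=3, base_channels=2)
        comp = evaluate.compare_arms(
            tiny_cases[:3], cfg, n_experiments=1, base_seed=2,
            pooling="pixel_pooled",
        )
        for arm in ("proposed", "control"):
            assert comp.per_experiment[arm].notna().all().all()
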