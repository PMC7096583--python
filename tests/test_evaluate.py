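"""Confusion metrics, balanced draws, cross-validation and the chain-level
independent test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ionbind.core import LigandProfile
from ionbind.evaluate import (
    LeakageError,
    assert_disjoint,
    balance_draws,
    compute_metrics,
    crossval,
    independent_evaluate,
    independent_split,
    mean_result,
    metrics_from_predictions,
    repeated_crossval,
)
from ionbind.learn import GBMConfig
from ionbind.simulate import SimConfig, generate_corpus
from ionbind.windows import corpus_segments, split_by_label


def oracle_metrics(y_true, y_pred):
    """Per-sample counting reference for the confusion metrics."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(50, 0, 50, 0)
        assert (r.sn, r.sp, r.acc, r.mcc) == (100.0, 100.0, 100.0, 1.0)
        assert r.fpr == 0.0

    def test_chance_symmetry(self):
        r = compute_metrics(25, 25, 25, 25)
        assert r.acc == 50.0 and r.mcc == 0.0

    def test_worked_confusion_table(self):
        r = compute_metrics(80, 24, 76, 20)
        assert r.sn == pytest.approx(80.0)
        assert r.sp == pytest.approx(76.0)
        assert r.fpr == pytest.approx(24.0)
        assert r.acc == pytest.approx(78.0)
        assert r.mcc == pytest.approx(0.5604, abs=1e-4)

    def test_fpr_complements_sp(self):
        r = compute_metrics(10, 7, 13, 5)
        assert r.sp + r.fpr == pytest.approx(100.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 5, 5)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 5, 5, 0)  # no positives

    def test_zero_denominator_mcc_flagged(self):
        r = compute_metrics(0, 0, 50, 50)  # no predicted positives
        assert r.mcc == 0.0 and r.mcc_undefined

    def test_agrees_with_counting_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            if y_true.min() == y_true.max():
                continue
            tp, fp, tn, fn = oracle_metrics(y_true, y_pred)
            r = metrics_from_predictions(y_true, y_pred)
            assert (r.tp, r.fp, r.tn, r.fn) == (tp, fp, tn, fn)


@settings(derandomize=True, deadline=None, max_examples=300)
@given(
    tp=st.integers(0, 500), fn=st.integers(0, 500),
    tn=st.integers(0, 500), fp=st.integers(0, 500),
)
def test_balanced_set_accuracy_identity(tp, fn, tn, fp):
    """On a balanced evaluation set (equal positives and negatives),
    Acc = (Sn + Sp) / 2 exactly."""
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        return
    # rescale the negative side to match the positive side exactly
    r = compute_metrics(tp * n_neg, fp * n_pos, tn * n_pos, fn * n_neg)
    assert r.acc == pytest.approx((r.sn + r.sp) / 2, abs=1e-9)


class TestBalanceDraws:
    def _segments(self, n_pos, n_neg):
        chains = generate_corpus(
            SimConfig(n_chains=4, length_range=(40, 50), binding_fraction=0.2,
                      seed=13)
        )
        pos, neg = split_by_label(corpus_segments(chains, 7))
        return pos[:n_pos], neg[:n_neg]

    def test_draw_sizes(self):
        pos, neg = self._segments(10, 100)
        draws = balance_draws(pos, neg, n_draws=10, seed=0)
        assert len(draws) == 10
        for d in draws:
            assert len(d) == 20
            assert sum(s.label for s in d) == 10

    def test_draws_differ_but_seed_reproduces(self):
        pos, neg = self._segments(10, 100)
        a = balance_draws(pos, neg, n_draws=5, seed=4)
        b = balance_draws(pos, neg, n_draws=5, seed=4)
        assert a == b
        assert len({tuple(id(s) for s in d) for d in a}) > 1

    def test_equal_classes_draw_is_full_dataset(self):
        pos, neg = self._segments(8, 8)
        draws = balance_draws(pos, neg, n_draws=3, seed=0)
        for d in draws:
            assert sorted(id(s) for s in d) == sorted(id(s) for s in pos + neg)

    def test_fewer_negatives_than_positives_rejected(self):
        pos, neg = self._segments(10, 5)
        with pytest.raises(ValueError, match="balancing is unnecessary"):
            balance_draws(pos, neg)


class TestLeakageGuard:
    def test_overlap_raises(self):
        with pytest.raises(LeakageError):
            assert_disjoint({("c1", 3), ("c1", 4)}, {("c1", 4)})

    def test_disjoint_passes(self):
        assert_disjoint({("c1", 3)}, {("c2", 3)})


@pytest.fixture(scope="module")
def medium_corpus():
    chains = generate_corpus(
        SimConfig(n_chains=12, length_range=(60, 80), binding_fraction=0.1,
                  effect_size=2.0, motif=True, seed=17)
    )
    return chains


class TestCrossval:
    def test_fold_bookkeeping_and_guard(self, medium_corpus):
        profile = LigandProfile.default("Zn2+")
        pos, neg = split_by_label(corpus_segments(medium_corpus, 7))
        dataset = balance_draws(pos, neg, n_draws=1, seed=1)[0]
        cv = crossval(dataset, profile, GBMConfig.fast(seed=1), k=5, seed=1)
        assert len(cv.folds) == 5
        sizes = [f.tp + f.fp + f.tn + f.fn for f in cv.folds]
        assert max(sizes) - min(sizes) <= 2  # equal folds (both classes)
        assert sum(sizes) == len(dataset)
        assert all(f.provenance["leakage_guard"] for f in cv.folds)

    def test_single_class_dataset_rejected(self, medium_corpus):
        profile = LigandProfile.default("Zn2+")
        _, neg = split_by_label(corpus_segments(medium_corpus, 7))
        with pytest.raises(ValueError, match="both classes"):
            crossval(neg[:50], profile, GBMConfig.fast(), k=5, seed=0)

    def test_repeated_crossval_recovers_signal(self, medium_corpus):
        """On a motif-bearing corpus the pipeline must beat chance clearly."""
        profile = LigandProfile.default("Zn2+")
        pos, neg = split_by_label(corpus_segments(medium_corpus, 7))
        per_draw, overall = repeated_crossval(
            pos, neg, profile, GBMConfig.fast(seed=2), n_draws=2, k=5, seed=2
        )
        assert len(per_draw) == 2
        assert overall.acc > 75.0
        assert overall.mcc > 0.5


class TestIndependentSplit:
    def test_80_20_counts(self, medium_corpus):
        chains = medium_corpus
        train, test = independent_split(chains, 0.2, seed=0)
        assert len(test) == round(0.2 * len(chains))
        assert len(train) + len(test) == len(chains)

    def test_partition_at_chain_level(self, medium_corpus):
        train, test = independent_split(medium_corpus, 0.3, seed=1)
        train_ids = {c.chain_id for c in train}
        test_ids = {c.chain_id for c in test}
        assert not train_ids & test_ids
        assert train_ids | test_ids == {c.chain_id for c in medium_corpus}

    def test_half_up_rounding(self, medium_corpus):
        train, test = independent_split(medium_corpus[:5], 0.5, seed=0)
        assert (len(train), len(test)) == (2, 3)  # round-half-up

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, medium_corpus, fraction):
        with pytest.raises(ValueError):
            independent_split(medium_corpus, fraction)

    def test_too_few_chains_rejected(self, medium_corpus):
        with pytest.raises(ValueError):
            independent_split(medium_corpus[:1], 0.2)


class TestIndependentEvaluate:
    def test_natural_ratio_kept_and_signal_found(self, medium_corpus):
        profile = LigandProfile.default("Zn2+")
        train, test = independent_split(medium_corpus, 0.25, seed=3)
        per_draw, overall = independent_evaluate(
            train, test, profile, GBMConfig.fast(seed=3), n_draws=2, seed=3
        )
        n_test = sum(len(c) for c in test)
        n_test_pos = sum(sum(c.labels) for c in test)
        for r in per_draw:
            assert r.tp + r.fn == n_test_pos
            assert r.tp + r.fp + r.tn + r.fn == n_test
        assert n_test_pos < n_test - n_test_pos  # imbalanced test side
        assert overall.mcc > 0.0


def test_mean_result_averages_metrics():
    a = compute_metrics(50, 0, 50, 0)
    b = compute_metrics(25, 25, 25, 25)
    m = mean_result([a, b])
    assert m.acc == pytest.approx(75.0)
    assert m.mcc == pytest.approx(0.5)
    assert m.provenance["n_runs"] == 2


def test_draw_averaging_reduces_accuracy_variance():
    """Averaging over 10 balanced draws yields a steadier accuracy than a
    single draw, checked with a fixed RSA-threshold classifier so the effect
    is purely the draw sampling."""
    chains = generate_corpus(
        SimConfig(n_chains=10, length_range=(60, 80), binding_fraction=0.08,
                  seed=19)
    )
    pos, neg = split_by_label(corpus_segments(chains, 7))

    def acc_of(dataset):
        y_true = np.array([s.label for s in dataset])
        y_pred = np.array([1 if s.center.rsa < 0.25 else 0 for s in dataset])
        return (y_true == y_pred).mean()

    single, averaged = [], []
    for rep in range(20):
        draws = balance_draws(pos, neg, n_draws=10, seed=100 + rep)
        accs = [acc_of(d) for d in draws]
        single.append(accs[0])
        averaged.append(np.mean(accs))
    assert np.var(averaged) < np.var(single)
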