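"""Evaluation protocol: confusion metrics, balanced undersampling with
repeated draws, stratified k-fold cross-validation, and the chain-level
independent test.

Metrics (percentages except MCC):

    Sn  = TP / (TP + FN) * 100        sensitivity
    Sp  = TN / (TN + FP) * 100        specificity
    FPR = FP / (TN + FP) * 100        false positive rate
    Acc = (TP + TN) / total * 100     accuracy
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Because non-binding segments vastly outnumber binding ones, training sets
are balanced by undersampling: all positives plus an equal-sized random
negative sample, drawn 10 times by default, with results averaged over the
draws.  Within each cross-validation fold the position-weight matrices are
refit from that fold's training segments only — a structural guard asserts
that no test segment ever enters matrix construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .channels import encode_segments
from .core import AnnotatedChain, LigandProfile
from .learn import FittedGBM, GBMConfig, predict, train_gbm
from .pwsm import fit_all_pairs, score_matrix
from .windows import Segment, corpus_segments, split_by_label


class LeakageError(RuntimeError):
    """Raised when test segments would leak into training-side fitting."""


def assert_disjoint(train_ids: set, test_ids: set) -> None:
    overlap = train_ids & test_ids
    if overlap:
        raise LeakageError(
            f"{len(overlap)} segment(s) appear in both training and test sides"
        )


@dataclass
class EvalResult:
    """Confusion counts plus the five derived metrics for one run.

    Counts are floats so that fold/draw averages can be represented; a
    single run has integer counts.  ``mcc_undefined`` flags a zero MCC
    denominator (MCC reported as 0 by convention).
    """

    tp: float
    fp: float
    tn: float
    fn: float
    sn: float
    sp: float
    fpr: float
    acc: float
    mcc: float
    mcc_undefined: bool = False
    provenance: dict = field(default_factory=dict)


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalResult:
    """Metrics from a confusion table; requires both classes present."""
    for name, v in (("TP", tp), ("FP", fp), ("TN", tn), ("FN", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fn == 0:
        raise ValueError("no positive samples: Sn undefined")
    if tn + fp == 0:
        raise ValueError("no negative samples: Sp/FPR undefined")
    total = tp + fp + tn + fn
    sn = tp / (tp + fn) * 100.0
    sp = tn / (tn + fp) * 100.0
    fpr = fp / (tn + fp) * 100.0
    acc = (tp + tn) / total * 100.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, undefined = 0.0, True
    else:
        mcc, undefined = (tp * tn - fp * fn) / math.sqrt(denom), False
    return EvalResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sn=sn, sp=sp, fpr=fpr, acc=acc, mcc=mcc, mcc_undefined=undefined,
    )


def metrics_from_predictions(y_true, y_pred) -> EvalResult:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return compute_metrics(tp, fp, tn, fn)


def mean_result(results: list[EvalResult], **provenance) -> EvalResult:
    """Average metrics (and counts) over folds or draws."""
    if not results:
        raise ValueError("no results to average")
    def avg(attr):
        return float(np.mean([getattr(r, attr) for r in results]))
    return EvalResult(
        tp=avg("tp"), fp=avg("fp"), tn=avg("tn"), fn=avg("fn"),
        sn=avg("sn"), sp=avg("sp"), fpr=avg("fpr"), acc=avg("acc"), mcc=avg("mcc"),
        mcc_undefined=any(r.mcc_undefined for r in results),
        provenance={"n_runs": len(results), **provenance},
    )


def balance_draws(
    pos_segments: list[Segment],
    neg_segments: list[Segment],
    n_draws: int = 10,
    seed: int = 0,
) -> list[list[Segment]]:
    """Repeatedly undersample negatives to the positive count.

    Each draw is all positives plus a without-replacement negative sample of
    equal size; draws use independent seeded sub-streams.
    """
    n_pos, n_neg = len(pos_segments), len(neg_segments)
    if n_pos == 0:
        raise ValueError("no positive segments to balance against")
    if n_neg < n_pos:
        raise ValueError(
            f"fewer negatives ({n_neg}) than positives ({n_pos}); "
            "balancing is unnecessary — use the dataset as is"
        )
    children = np.random.SeedSequence(seed).spawn(n_draws)
    draws = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.choice(n_neg, size=n_pos, replace=False)
        draws.append(list(pos_segments) + [neg_segments[i] for i in idx])
    return draws


def _sub_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


def _fit_and_eval(
    train_segments: list[Segment],
    test_segments: list[Segment],
    profile: LigandProfile,
    model_config: GBMConfig,
    background: str = "pooled",
) -> tuple[EvalResult, FittedGBM]:
    """Fit PWSMs + GBM on training segments only; evaluate on test segments."""
    train_ids = {(s.chain_id, s.center_pos) for s in train_segments}
    test_ids = {(s.chain_id, s.center_pos) for s in test_segments}
    assert_disjoint(train_ids, test_ids)

    pos, neg = split_by_label(train_segments)
    enc_pos = encode_segments(pos, profile)
    enc_neg = encode_segments(neg, profile)
    pairs = fit_all_pairs(enc_pos, enc_neg, profile, background=background)

    X_train = score_matrix(enc_pos + enc_neg, pairs)
    y_train = np.array([1] * len(pos) + [0] * len(neg))
    model = train_gbm(X_train, y_train, model_config)

    X_test = score_matrix(encode_segments(test_segments, profile), pairs)
    y_test = np.array([s.label for s in test_segments])
    y_pred, _ = predict(model, X_test)
    result = metrics_from_predictions(y_test, y_pred)
    result.provenance["leakage_guard"] = True
    return result, model


@dataclass
class CrossvalResult:
    folds: list[EvalResult]
    mean: EvalResult


def crossval(
    segments: list[Segment],
    profile: LigandProfile,
    model_config: GBMConfig | None = None,
    k: int = 5,
    seed: int = 0,
    background: str = "pooled",
) -> CrossvalResult:
    """Stratified k-fold cross-validation of one (balanced) dataset.

    Fold sizes differ by at most one; PWSMs and the classifier are refit
    inside every fold from the training folds only.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    model_config = model_config or GBMConfig.fast(seed=seed)
    labels = np.array([s.label for s in segments])
    if labels.min() == labels.max():
        raise ValueError("cross-validation needs both classes present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    seed_seq = np.random.SeedSequence(seed)
    fold_results = []
    for fold_seed, (train_idx, test_idx) in zip(
        seed_seq.spawn(k), skf.split(np.zeros(len(segments)), labels)
    ):
        cfg = GBMConfig(
            n_trees=model_config.n_trees,
            min_node=model_config.min_node,
            depth=model_config.depth,
            shrinkage=model_config.shrinkage,
            seed=_sub_seed(fold_seed),
        )
        result, _ = _fit_and_eval(
            [segments[i] for i in train_idx],
            [segments[i] for i in test_idx],
            profile, cfg, background,
        )
        fold_results.append(result)
    return CrossvalResult(
        folds=fold_results,
        mean=mean_result(fold_results, protocol=f"{k}-fold CV", stratified=True),
    )


def repeated_crossval(
    pos_segments: list[Segment],
    neg_segments: list[Segment],
    profile: LigandProfile,
    model_config: GBMConfig | None = None,
    n_draws: int = 10,
    k: int = 5,
    seed: int = 0,
    background: str = "pooled",
) -> tuple[list[CrossvalResult], EvalResult]:
    """k-fold CV on each of ``n_draws`` balanced undersampling draws; the
    overall result averages the per-draw means."""
    draws = balance_draws(pos_segments, neg_segments, n_draws=n_draws, seed=seed)
    per_draw = []
    for d, dataset in enumerate(draws):
        per_draw.append(
            crossval(dataset, profile, model_config, k=k, seed=seed + 1000 * (d + 1),
                     background=background)
        )
    overall = mean_result(
        [r.mean for r in per_draw], protocol=f"{n_draws} draws x {k}-fold CV"
    )
    return per_draw, overall


def independent_split(
    chains: list[AnnotatedChain], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[AnnotatedChain], list[AnnotatedChain]]:
    """Chain-level train/test partition; no chain contributes segments to
    both sides.  Test size = round-half-up(fraction * n), clamped to
    [1, n-1]."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if len(chains) < 2:
        raise ValueError("need at least 2 chains to split")
    n = len(chains)
    n_test = min(max(int(math.floor(test_fraction * n + 0.5)), 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [c for i, c in enumerate(chains) if i not in test_idx]
    test = [c for i, c in enumerate(chains) if i in test_idx]
    return train, test


def independent_evaluate(
    train_chains: list[AnnotatedChain],
    test_chains: list[AnnotatedChain],
    profile: LigandProfile,
    model_config: GBMConfig | None = None,
    n_draws: int = 10,
    seed: int = 0,
    background: str = "pooled",
) -> tuple[list[EvalResult], EvalResult]:
    """Train on balanced draws from the training chains; evaluate on the
    full, imbalanced segment set of the held-out chains.

    The test side keeps its natural class ratio, so MCC is the indicator to
    watch.  Metrics are averaged over the draws.
    """
    model_config = model_config or GBMConfig.fast(seed=seed)
    L = profile.window_length
    train_pos, train_neg = split_by_label(corpus_segments(train_chains, L))
    test_segments = corpus_segments(test_chains, L)
    if not any(s.label == 1 for s in test_segments):
        raise ValueError("independent test set has no positive segments")
    draws = balance_draws(train_pos, train_neg, n_draws=n_draws, seed=seed)
    per_draw = []
    for d, dataset in enumerate(draws):
        cfg = GBMConfig(
            n_trees=model_config.n_trees,
            min_node=model_config.min_node,
            depth=model_config.depth,
            shrinkage=model_config.shrinkage,
            seed=seed + 7919 * (d + 1),
        )
        result, _ = _fit_and_eval(dataset, test_segments, profile, cfg, background)
        per_draw.append(result)
    overall = mean_result(per_draw, protocol=f"independent test, {n_draws} draws")
    return per_draw, overall
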