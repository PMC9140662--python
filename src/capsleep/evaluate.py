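"""Performance metrics and experiment harnesses.

Accuracy / sensitivity / specificity from confusion counts, ROC AUC,
left-tailed Wilcoxon rank-sum comparison, subject-level split plans
(random sub-sampling validation and leave-one-subject-out), and learning
curves over training-set fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SplitPlan:
    """Per-repeat (train subject ids, eval subject ids) assignments."""

    mode: str
    assignments: list
    seed: int

    def __post_init__(self):
        for train, evaluation in self.assignments:
            if set(train) & set(evaluation):
                raise ValueError("train and eval subjects must be disjoint")


def confusion(predicted, truth) -> ConfusionCounts:
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError("length mismatch")
    return ConfusionCounts(
        tp=int(np.sum(predicted & truth)),
        tn=int(np.sum(~predicted & ~truth)),
        fp=int(np.sum(predicted & ~truth)),
        fn=int(np.sum(~predicted & truth)),
    )


def acc_sen_spe(c: ConfusionCounts):
    """Accuracy, sensitivity, specificity as fractions."""
    if c.n == 0:
        raise ZeroDivisionError("accuracy undefined: no evaluated epochs")
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive epochs")
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative epochs")
    acc = (c.tp + c.tn) / c.n
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.tn + c.fp)
    return acc, sen, spe


def auc(scores, truth) -> float:
    """ROC AUC by threshold-sweep trapezoid.

    Equals the Mann-Whitney pairwise concordance
    P(score_pos > score_neg) + 0.5 * P(tie).
    """
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=np.float64)))


def wilcoxon_left(sample_a, sample_b) -> float:
    """Left-tailed Wilcoxon rank-sum p-value (H1: a shifted below b).

    Exact null distribution when the combined sample is small and tie-free;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    combined = np.concatenate([a, b])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_WILCOXON_MAX_N and not ties) \
        else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="less", method=method)
    return float(result.pvalue)


def make_splits(subjects, mode: str, repeats: int = 10, seed: int = 0,
                n_train: int | None = None) -> SplitPlan:
    """Subject-level split plan.

    RSV: per repeat, a seeded random split into ``n_train`` training
    subjects (default: the 10/9 proportion of a 19-subject cohort) and the
    rest for evaluation. LOO: each subject is the evaluation set exactly
    once per cycle; ``repeats`` cycles.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    assignments = []
    if mode == "RSV":
        if n_train is None:
            n_train = int(round(len(subjects) * 10 / 19))
        n_train = max(1, min(n_train, len(subjects) - 1))
        for _ in range(repeats):
            order = rng.permutation(len(subjects))
            train = [subjects[i] for i in order[:n_train]]
            evaluation = [subjects[i] for i in order[n_train:]]
            assignments.append((train, evaluation))
    elif mode == "LOO":
        for _ in range(repeats):
            for held_out in subjects:
                train = [s for s in subjects if s != held_out]
                assignments.append((train, [held_out]))
    else:
        raise ValueError("mode must be 'RSV' or 'LOO'")
    return SplitPlan(mode=mode, assignments=assignments, seed=seed)


def learning_curve(pipeline_runner, subjects, fractions, seed: int = 0) -> dict:
    """Mean validation AUC per training-set fraction.

    ``pipeline_runner(train_subjects)`` must return a validation AUC; the
    subject subsets are nested (larger fractions extend smaller ones).
    """
    subjects = list(subjects)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    out = {}
    for frac in fractions:
        if not (0 < frac <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        k = int(round(frac * len(subjects)))
        if k == 0:
            raise ValueError(f"fraction {frac} yields zero subjects")
        subset = [subjects[i] for i in order[:k]]
        out[frac] = float(pipeline_runner(subset))
    return out
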