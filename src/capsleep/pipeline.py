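"""End-to-end orchestration: signal -> labels -> classifier -> CAP report.

Stage order: preprocessing (decimation to 100 Hz + standardization), feature
creation + mRMR ranking for the feature-based presets, segmentation
(epochs / overlapping windows / time-step sequences), parallel A-phase and
NREM classification, post-processing correction, FSM CAP scoring, and
CAP-rate estimation, with subject-disjoint train/validation splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import cap_scoring, classifiers, evaluate, features, mrmr, preprocess, synthetic
from .classifiers import LstmSpec, TrainConfig
from .preprocess import SequenceSpec
from .types import LabelStream, SignalRecord

logger = logging.getLogger(__name__)

PRESETS = ("ffnn", "cnn-afc", "lstm-afc", "lstm-features")


@dataclass
class RunConfig:
    """Everything needed to replay a pipeline run bit-identically."""

    preset: str = "ffnn"
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_features: int | None = None     # top-k mRMR features (feature presets)
    n_train_subjects: int | None = None
    mrmr_bins: int = 10
    nrem_smooth_s: int = 31           # median window over predicted NREM
    seed: int = 0

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")


def prepare_record(record: SignalRecord) -> SignalRecord:
    """Decimate to 100 Hz and standardize."""
    return preprocess.standardize(preprocess.decimate(record))


@dataclass
class _SubjectData:
    record: SignalRecord
    labels: LabelStream          # ground truth on the epoch grid
    truth: synthetic.GroundTruth
    feature_table = None


def _feature_design(subjects, train_ids, config: RunConfig):
    """mRMR-ranked, train-standardized feature matrices per subject."""
    for s in subjects:
        if s.feature_table is None:
            s.feature_table = features.feature_matrix(s.record)
    train_x = np.concatenate(
        [subjects[i].feature_table.to_numpy() for i in train_ids])
    train_y = np.concatenate([subjects[i].labels.a_phase for i in train_ids])
    table = subjects[train_ids[0]].feature_table
    import pandas as pd
    ranking = mrmr.rank_features(
        pd.DataFrame(train_x, columns=table.columns), train_y,
        n_bins=config.mrmr_bins)
    k = config.n_features or (14 if config.preset == "ffnn" else 12)
    selected = ranking.ordering[:k]
    cols = [list(table.columns).index(c) for c in selected]
    mean = train_x[:, cols].mean(axis=0)
    sd = train_x[:, cols].std(axis=0)
    sd[sd == 0] = 1.0

    def design(s):
        return (s.feature_table.to_numpy()[:, cols] - mean) / sd

    return design, ranking, selected


def _build_inputs(subjects, train_ids, config: RunConfig):
    """Per-subject model inputs for the chosen preset.

    Returns (design(subject) -> X, spec_a, spec_nrem, extras).
    """
    extras = {}
    if config.preset in ("ffnn", "lstm-features"):
        design_feat, ranking, selected = _feature_design(
            subjects, train_ids, config)
        extras["mrmr_ordering"] = ranking.ordering
        extras["selected_features"] = selected
        k = len(selected)
        if config.preset == "ffnn":
            spec_a = classifiers.preset("ffnn", n_features=k)
            spec_nrem = classifiers.preset("ffnn", n_features=k)
            design = design_feat
        else:
            spec_a = classifiers.preset("lstm-features", n_features=k)
            spec_nrem = classifiers.preset("lstm-nrem", n_features=k)
            seq = SequenceSpec(spec_a.time_steps)

            def design(s):
                return preprocess.build_sequences(design_feat(s), seq)
    elif config.preset == "cnn-afc":
        spec_a = classifiers.preset("cnn-afc")
        spec_nrem = classifiers.preset("cnn-nrem")

        def design(s):
            return preprocess.build_windows(s.record, spec_a.window)
    elif config.preset == "lstm-afc":
        spec_a = classifiers.preset("lstm-afc")
        spec_nrem = LstmSpec(n_inputs=100, hidden_units=300, time_steps=25,
                             dense_option="half")
        seq = SequenceSpec(spec_a.time_steps)

        def design(s):
            return preprocess.build_sequences(
                preprocess.segment_epochs(s.record), seq)
    else:  # pragma: no cover
        raise ValueError(config.preset)
    return design, spec_a, spec_nrem, extras


def run_pipeline(config: RunConfig, records_truths=None,
                 return_models: bool = False):
    """Train the preset's A-phase and NREM classifiers and score CAP.

    ``records_truths`` optionally supplies (SignalRecord, GroundTruth)
    pairs; by default a synthetic cohort from ``config.synthetic`` is used.
    Returns a JSON-serializable report with A-phase, NREM, CAP-cycle, and
    CAP-rate sections.
    """
    if records_truths is None:
        records_truths = synthetic.generate_cohort(config.synthetic)
    subjects = []
    for record, truth in records_truths:
        prepared = prepare_record(record)
        n_epochs = prepared.n_samples // preprocess.EPOCH_SAMPLES
        labels = synthetic.truth_to_labels(truth, n_epochs)
        s = _SubjectData(record=prepared, labels=labels, truth=truth)
        subjects.append(s)

    n_sub = len(subjects)
    plan = evaluate.make_splits(list(range(n_sub)), "RSV", repeats=1,
                                seed=config.seed,
                                n_train=config.n_train_subjects)
    train_ids, eval_ids = plan.assignments[0]

    design, spec_a, spec_nrem, extras = _build_inputs(
        subjects, train_ids, config)

    x_train = np.concatenate([design(subjects[i]) for i in train_ids])
    x_val = np.concatenate([design(subjects[i]) for i in eval_ids])
    ya_train = np.concatenate([subjects[i].labels.a_phase for i in train_ids])
    ya_val = np.concatenate([subjects[i].labels.a_phase for i in eval_ids])
    yn_train = np.concatenate([subjects[i].labels.nrem for i in train_ids])
    yn_val = np.concatenate([subjects[i].labels.nrem for i in eval_ids])

    # keep a sensible number of optimizer steps per epoch at desk scale:
    # the default batch of 1024 is sized for full-night cohorts
    train_cfg = replace(config.train, batch_size=min(
        config.train.batch_size, max(32, len(x_train) // 16)))

    model_a = classifiers.build_model(spec_a, seed=config.seed)
    hist_a = classifiers.train(model_a, (x_train, ya_train), (x_val, ya_val),
                               train_cfg)
    model_n = classifiers.build_model(spec_nrem, seed=config.seed + 1)
    hist_n = classifiers.train(model_n, (x_train, yn_train), (x_val, yn_val),
                               train_cfg)

    scores_a = model_a.predict_proba(x_val)
    scores_n = model_n.predict_proba(x_val)
    report = {
        "preset": config.preset,
        "subjects": {"train": train_ids, "eval": eval_ids},
        "a_phase": _task_metrics(scores_a, ya_val),
        "nrem": _task_metrics(scores_n, yn_val),
        "history": {"a_phase": hist_a, "nrem": hist_n},
    }
    report.update({k: v for k, v in extras.items()})

    # per-subject CAP scoring on every subject
    per_subject = []
    cap_confusion = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for i, s in enumerate(subjects):
        x = design(s)
        pred_a = classifiers.predict_labels(model_a.predict_proba(x))
        pred_n = classifiers.predict_labels(model_n.predict_proba(x))
        entry = score_subject(pred_a, pred_n, s.truth, len(s.labels.a_phase),
                              nrem_smooth_s=config.nrem_smooth_s)
        entry["subject"] = i
        entry["role"] = "train" if i in train_ids else "eval"
        cap_truth = _truth_cap_labels(s.truth, len(s.labels.a_phase))
        c = evaluate.confusion(entry.pop("cap_labels"), cap_truth)
        for key in cap_confusion:
            cap_confusion[key] += getattr(c, key)
        per_subject.append(entry)

    c = evaluate.ConfusionCounts(**cap_confusion)
    acc, sen, spe = acc_sen_spe_safe(c)
    eval_errors = [abs(e["cap_rate_pct_error"]) for e in per_subject
                   if e["cap_rate_pct_error"] is not None]
    report["cap_cycles"] = {"acc": acc, "sen": sen, "spe": spe}
    report["cap_rate"] = {
        "per_subject": per_subject,
        "median_pct_error": float(np.median(eval_errors)) if eval_errors else None,
    }
    if return_models:
        models = {"a_phase": (model_a, spec_a), "nrem": (model_n, spec_nrem)}
        return report, models
    return report


def _task_metrics(scores, truth) -> dict:
    pred = classifiers.predict_labels(scores)
    c = evaluate.confusion(pred, truth)
    acc, sen, spe = acc_sen_spe_safe(c)
    return {"auc": evaluate.auc(scores, truth), "acc": acc, "sen": sen,
            "spe": spe}


def acc_sen_spe_safe(c):
    """Metrics tuple with None where a denominator vanishes."""
    try:
        return evaluate.acc_sen_spe(c)
    except ZeroDivisionError:
        acc = (c.tp + c.tn) / c.n if c.n else None
        sen = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
        spe = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
        return acc, sen, spe


def _truth_cap_labels(truth, n_epochs):
    labels = np.zeros(n_epochs, dtype=bool)
    for onset, dur in truth.cap_intervals:
        labels[int(onset): int(onset + dur)] = True
    return labels


def score_subject(pred_a, pred_n, truth, n_epochs,
                  nrem_smooth_s: int = 31) -> dict:
    """Post-process one subject's predictions and compare CAP rates.

    The predicted NREM stream is majority-smoothed over ``nrem_smooth_s``
    seconds before CAP scoring: sleep macrostructure changes on the scale
    of the clinical 30 s staging epoch, so per-second stage flickers are
    noise as far as the B-phase content rule is concerned.
    """
    pred_n = np.asarray(pred_n).astype(bool)
    if nrem_smooth_s > 1:
        from scipy.ndimage import median_filter
        pred_n = median_filter(pred_n.astype(np.int8),
                               size=nrem_smooth_s).astype(bool)
    corrected = cap_scoring.correct_isolated(pred_a)
    masked = cap_scoring.apply_nrem_mask(corrected, pred_n)
    entry = {}
    if pred_n.sum() == 0:
        logger.warning("no predicted NREM epochs; CAP rate set to 0")
        entry["cap_rate_predicted"] = 0.0
        entry["cap_labels"] = np.zeros(n_epochs, dtype=bool)
    else:
        result = cap_scoring.score_cap(masked, pred_n)
        entry["cap_rate_predicted"] = result.cap_rate
        entry["cap_labels"] = result.cap_labels
    reference = synthetic.ground_truth_cap_rate(truth, n_epochs)
    entry["cap_rate_reference"] = reference
    if reference > 0:
        err, pct = cap_scoring.cap_rate_metrics(
            entry["cap_rate_predicted"], reference)
        entry["cap_rate_error"] = err
        entry["cap_rate_pct_error"] = pct
    else:
        entry["cap_rate_error"] = entry["cap_rate_predicted"] - reference
        entry["cap_rate_pct_error"] = None
    return entry
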