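"""Data splitting, training loops, vote metrics, ablations and statistics.

Protocols implemented here:

* unlabeled pretraining data are split 85:15 into train/validation by whole
  recordings;
* target-task recordings are split 70:15:15 along recording time, and a
  segment survives only if its whole ω-second span lies inside one split's
  window (border-straddling segments, an artifact of Δω < ω, are dropped);
* the two classes are balanced by pairing recordings rank-to-rank on segment
  count and keeping the first n = min(pair) segments of each;
* training uses AdamW with a reduce-on-plateau schedule: LR × 0.3 after 10
  stale epochs, stop when a third reduction would be needed;
* metrics are reported per segment and per subject, the latter by majority
  vote (ties broken by the higher mean subject-level probability);
* model comparisons use a paired t test on segment probabilities, a
  random-intercept mixed model grouping by subject, and a paired t test on
  per-subject correct-segment fractions, all Bonferroni-corrected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import nn
from .nn import Tensor
from .model import CHANNEL_ORDER, E4mer, ModelConfig, segments_to_batch, transfer
from .preprocess import Segment
from .pretext import (
    MaskSpec,
    TRANSFORM_KINDS,
    apply_transform,
    sample_mask,
)

__all__ = [
    "LABEL_TO_INT",
    "SplitAssignment",
    "SchedulerState",
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "ComparisonResult",
    "AblationResult",
    "split_unlabeled",
    "time_split_target",
    "balance_classes",
    "scheduler_step",
    "train",
    "predict_segments",
    "evaluate",
    "pearson_corr",
    "compare_models",
    "ablate",
]

LABEL_TO_INT = {"euthymia": 0, "acute": 1}


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Split membership for segments and the per-recording time boundaries."""

    segment_split: list[str | None]  # "train" / "val" / "test" / None (dropped)
    boundaries: dict[str, tuple[float, float]]  # recording -> (t_train_end, t_val_end)

    def segments(self, segments: list[Segment], split: str) -> list[Segment]:
        return [s for s, sp in zip(segments, self.segment_split) if sp == split]


def split_unlabeled(
    recording_ids: list[str], ratio: tuple[float, float] = (0.85, 0.15), seed: int = 0,
) -> dict[str, str]:
    """Assign whole recordings to pretraining train/validation sets.

    The validation set gets ``round(ratio[1] * n)`` recordings (at least one);
    assignment is a seeded shuffle, so it is reproducible.
    """
    n = len(recording_ids)
    if n < 2:
        raise ValueError("need at least 2 recordings to split")
    if not math.isclose(sum(ratio), 1.0):
        raise ValueError("split ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    n_val = max(1, int(round(ratio[1] * n)))
    val_ids = {recording_ids[i] for i in order[:n_val]}
    return {rid: ("val" if rid in val_ids else "train") for rid in recording_ids}


def time_split_target(
    segments: list[Segment],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    durations: dict[str, float] | None = None,
) -> SplitAssignment:
    """Cut each recording's timeline at 70%/85% and confine segments to splits.

    A segment belongs to a split only if its whole [start, start + ω) span
    lies inside that split's window; segments straddling a border are dropped
    (split ``None``).  ``durations`` gives each recording's length in seconds;
    when omitted, the largest segment end per recording is used.
    """
    if not math.isclose(sum(ratios), 1.0):
        raise ValueError("split ratios must sum to 1")
    if durations is None:
        durations = {}
        for s in segments:
            end = s.start_offset + s.omega
            durations[s.session_id] = max(durations.get(s.session_id, 0), end)

    boundaries = {
        rid: (ratios[0] * dur, (ratios[0] + ratios[1]) * dur)
        for rid, dur in durations.items()
    }
    assignment: list[str | None] = []
    for s in segments:
        b1, b2 = boundaries[s.session_id]
        start, end = s.start_offset, s.start_offset + s.omega
        if end <= b1:
            assignment.append("train")
        elif start >= b1 and end <= b2:
            assignment.append("val")
        elif start >= b2:
            assignment.append("test")
        else:
            assignment.append(None)
    return SplitAssignment(segment_split=assignment, boundaries=boundaries)


def balance_classes(
    recordings_by_class: dict[str, list[list[Segment]]],
) -> dict[str, list[Segment]]:
    """Equalize segment counts across the two classes by rank pairing.

    Recordings of each class are sorted by segment count and paired
    rank-to-rank (which minimizes the total absolute pairwise difference);
    within each pair both recordings keep their first n = min(pair) segments
    in temporal order.
    """
    if len(recordings_by_class) != 2:
        raise ValueError("expected exactly two classes")
    (label_a, recs_a), (label_b, recs_b) = recordings_by_class.items()
    if len(recs_a) != len(recs_b):
        raise ValueError("classes must have equal numbers of recordings")
    sorted_a = sorted(recs_a, key=len, reverse=True)
    sorted_b = sorted(recs_b, key=len, reverse=True)
    kept: dict[str, list[Segment]] = {label_a: [], label_b: []}
    for ra, rb in zip(sorted_a, sorted_b):
        n = min(len(ra), len(rb))
        for label, rec in ((label_a, ra), (label_b, rb)):
            ordered = sorted(rec, key=lambda s: s.start_offset)
            kept[label].extend(ordered[:n])
    return kept


# ---------------------------------------------------------------------------
# scheduler
# ---------------------------------------------------------------------------

@dataclass
class SchedulerState:
    current_lr: float
    best_val: float = math.inf
    epochs_since_improve: int = 0
    n_reductions: int = 0


def scheduler_step(
    state: SchedulerState,
    val_metric: float,
    factor: float = 0.3,
    patience: int = 10,
    max_reductions: int = 2,
) -> tuple[SchedulerState, str]:
    """Reduce-on-plateau step; one call per epoch.

    Improvement resets the staleness counter.  After ``patience`` stale
    epochs the learning rate is multiplied by ``factor``; when a reduction
    beyond ``max_reductions`` would be required, training terminates.
    Returns the updated state and an action in {"continue", "reduce", "stop"}.
    """
    if val_metric < state.best_val:
        state.best_val = val_metric
        state.epochs_since_improve = 0
        return state, "continue"
    state.epochs_since_improve += 1
    if state.epochs_since_improve < patience:
        return state, "continue"
    if state.n_reductions >= max_reductions:
        return state, "stop"
    state.current_lr *= factor
    state.n_reductions += 1
    state.epochs_since_improve = 0
    return state, "reduce"


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    task: str = "classify"  # "classify" | "mp" | "tp"
    lr: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 256
    max_epochs: int = 300
    patience: int = 10
    lr_factor: float = 0.3
    max_reductions: int = 2
    mask_spec: MaskSpec = field(default_factory=MaskSpec)
    seed: int = 0


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_val: float
    history: list[dict]


def _segment_targets(segments: list[Segment]) -> np.ndarray:
    try:
        return np.array([LABEL_TO_INT[s.label] for s in segments])
    except KeyError as exc:
        raise ValueError("classification requires labeled segments") from exc


def _classify_loss(model: E4mer, segments: list[Segment], _rng) -> Tensor:
    batch = segments_to_batch(segments)
    logits = model.classify_logits(model.representations(batch))
    return nn.cross_entropy(logits, _segment_targets(segments))


def _mp_loss(model: E4mer, segments: list[Segment], rng: np.random.Generator,
             spec: MaskSpec) -> Tensor:
    originals = segments_to_batch(segments)
    corrupted = {}
    masks = {}
    for name in CHANNEL_ORDER:
        arr = originals[name]
        fs = segments[0].fs[name]
        m = np.stack([sample_mask(arr.shape[1], spec, rng, fs=fs) for _ in segments])
        corrupted[name] = np.where(m, 0.0, arr)
        masks[name] = m
    total = sum(int(m.sum()) for m in masks.values())
    if total == 0:
        raise ValueError("empty mask; cannot compute masked RMSE")
    recon = model.reconstruct(model.representations(corrupted))
    sse = None
    for name in CHANNEL_ORDER:
        diff = (recon[name] - Tensor(originals[name])) * Tensor(masks[name].astype(float))
        term = (diff ** 2.0).sum()
        sse = term if sse is None else sse + term
    return (sse * (1.0 / total)) ** 0.5


def _tp_loss(model: E4mer, segments: list[Segment], rng: np.random.Generator) -> Tensor:
    n_kinds = len(TRANSFORM_KINDS)
    transformed = {name: [] for name in CHANNEL_ORDER}
    targets = np.empty((len(segments), len(CHANNEL_ORDER)), dtype=int)
    for i, seg in enumerate(segments):
        kinds = rng.integers(0, n_kinds, size=len(CHANNEL_ORDER))
        targets[i] = kinds
        for c, name in enumerate(CHANNEL_ORDER):
            transformed[name].append(
                apply_transform(seg.channels[name], TRANSFORM_KINDS[kinds[c]], None, rng)
            )
    batch = {name: np.stack(vals) for name, vals in transformed.items()}
    logits = model.predict_transforms(model.representations(batch))
    return nn.cross_entropy(logits, targets)


def _task_loss(model: E4mer, segments: list[Segment], rng, cfg: TrainConfig) -> Tensor:
    if cfg.task == "classify":
        return _classify_loss(model, segments, rng)
    if cfg.task == "mp":
        return _mp_loss(model, segments, rng, cfg.mask_spec)
    if cfg.task == "tp":
        return _tp_loss(model, segments, rng)
    raise ValueError(f"unknown task {cfg.task!r}")


def train(
    model: E4mer,
    train_segments: list[Segment],
    val_segments: list[Segment],
    cfg: TrainConfig,
) -> TrainResult:
    """Seeded training loop with plateau scheduling and best-checkpoint return.

    The validation loss uses a fixed seed for its pretext randomness (masks /
    transform draws), so epochs are compared on the same corruption and the
    plateau detector sees model progress rather than sampling noise.
    """
    if not train_segments:
        raise ValueError("empty training set")
    opt = nn.AdamW(model.trainable_parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = SchedulerState(current_lr=cfg.lr)
    rng = np.random.default_rng([cfg.seed, 17])
    history: list[dict] = []
    best_state = model.state_dict()
    best_val = math.inf

    for epoch in range(cfg.max_epochs):
        model.set_mode(True)
        order = rng.permutation(len(train_segments))
        epoch_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_segments[i] for i in order[lo:lo + cfg.batch_size]]
            model.zero_grad()
            loss = _task_loss(model, batch, rng, cfg)
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        model.set_mode(False)
        val_rng = np.random.default_rng([cfg.seed, 23])
        val_losses = []
        for lo in range(0, len(val_segments), cfg.batch_size):
            batch = val_segments[lo:lo + cfg.batch_size]
            val_losses.append(float(_task_loss(model, batch, val_rng, cfg).data))
        val_loss = float(np.mean(val_losses)) if val_losses else float(np.mean(epoch_losses))

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        sched, action = scheduler_step(
            sched, val_loss, factor=cfg.lr_factor,
            patience=cfg.patience, max_reductions=cfg.max_reductions,
        )
        opt.lr = sched.current_lr
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "lr": sched.current_lr,
            "action": action,
        })
        if action == "stop":
            break
    model.load_state_dict(best_state)
    return TrainResult(best_state=best_state, best_val=best_val, history=history)


def predict_segments(model: E4mer, segments: list[Segment], batch_size: int = 64) -> np.ndarray:
    """Probability of the acute class for each segment, in input order."""
    model.set_mode(False)
    probs = []
    for lo in range(0, len(segments), batch_size):
        batch = segments_to_batch(segments[lo:lo + batch_size])
        p = model.classify(model.representations(batch)).data
        probs.append(p[:, LABEL_TO_INT["acute"]])
    return np.concatenate(probs) if probs else np.empty(0)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    acc_segment: float
    acc_subject: float
    segment_metrics: dict[str, float]
    subject_metrics: dict[str, float]
    per_subject: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "acc_segment": self.acc_segment,
            "acc_subject": self.acc_subject,
            "segment_metrics": self.segment_metrics,
            "subject_metrics": self.subject_metrics,
            "per_subject": self.per_subject,
        }


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, y_prob: np.ndarray) -> dict[str, float]:
    from sklearn.metrics import (
        f1_score, precision_score, recall_score, roc_auc_score,
    )
    out = {
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }
    out["auroc"] = (
        float(roc_auc_score(y_true, y_prob)) if len(np.unique(y_true)) > 1 else math.nan
    )
    return out


def evaluate(
    probs: np.ndarray, labels: np.ndarray, subject_ids: list[str],
) -> EvalReport:
    """Segment- and subject-level metrics from per-segment acute probabilities.

    A subject's prediction is the majority vote over their segments (ties go
    to the class favored by the mean probability); the subject-level
    probability is the mean of the subject's segment probabilities.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) != len(labels) or len(probs) != len(subject_ids):
        raise ValueError("probs, labels and subject_ids must align")
    preds = (probs > 0.5).astype(int)
    acc_segment = float(np.mean(preds == labels))

    per_subject: dict[str, dict] = {}
    for subject in dict.fromkeys(subject_ids):
        idx = [i for i, s in enumerate(subject_ids) if s == subject]
        if not idx:
            raise ValueError(f"subject {subject} has zero segments")
        y = labels[idx]
        if len(set(y.tolist())) > 1:
            raise ValueError(f"subject {subject} carries mixed ground-truth labels")
        votes_acute = int(preds[idx].sum())
        n = len(idx)
        mean_prob = float(probs[idx].mean())
        if votes_acute * 2 == n:
            pred_subject = int(mean_prob > 0.5)  # tie-break on mean probability
        else:
            pred_subject = int(votes_acute * 2 > n)
        per_subject[subject] = {
            "n_segments": n,
            "label": int(y[0]),
            "pred": pred_subject,
            "mean_prob": mean_prob,
            "frac_correct": float(np.mean(preds[idx] == y)),
        }

    subj_true = np.array([d["label"] for d in per_subject.values()])
    subj_pred = np.array([d["pred"] for d in per_subject.values()])
    subj_prob = np.array([d["mean_prob"] for d in per_subject.values()])
    acc_subject = float(np.mean(subj_pred == subj_true))
    return EvalReport(
        acc_segment=acc_segment,
        acc_subject=acc_subject,
        segment_metrics=_binary_metrics(labels, preds, probs),
        subject_metrics=_binary_metrics(subj_true, subj_pred, subj_prob),
        per_subject=per_subject,
    )


def pearson_corr(x, y) -> float:
    """Product-moment correlation; requires n ≥ 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# model comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    mean_diff_segment: float
    p_t_segment: float
    p_lme: float
    lme_intercept: float
    lme_ci: tuple[float, float]
    mean_diff_subject: float
    p_t_subject: float
    n_tests: int
    degenerate: bool = False

    @property
    def corrected(self) -> dict[str, float]:
        bonf = lambda p: float(min(1.0, p * self.n_tests)) if not math.isnan(p) else p
        return {
            "p_t_segment": bonf(self.p_t_segment),
            "p_lme": bonf(self.p_lme),
            "p_t_subject": bonf(self.p_t_subject),
        }


def compare_models(
    correct_probs_a: np.ndarray,
    correct_probs_b: np.ndarray,
    subject_ids: list[str],
    n_tests: int = 19,
) -> ComparisonResult:
    """Compare two classifiers on paired correct-class probabilities.

    Three tests: (i) a two-tailed paired t test on segment-level probability
    differences; (ii) a random-intercept linear mixed model of the difference
    with subject grouping, testing a zero fixed intercept; (iii) a two-tailed
    paired t test on per-subject correct-segment fractions.  Bonferroni
    correction uses ``n_tests`` (the published analysis counted 19).
    """
    a = np.asarray(correct_probs_a, dtype=float)
    b = np.asarray(correct_probs_b, dtype=float)
    if a.shape != b.shape or len(a) != len(subject_ids):
        raise ValueError("inputs must be paired and aligned with subject_ids")
    d = a - b
    degenerate = bool(np.std(d) == 0)

    if degenerate:
        mean = float(np.mean(d))
        p_seg = 1.0 if mean == 0.0 else math.nan
        p_lme = p_seg
        lme_intercept, lme_ci = mean, (mean, mean)
    else:
        p_seg = float(sps.ttest_rel(a, b).pvalue)
        import statsmodels.api as sm

        groups = np.asarray(subject_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lme = sm.MixedLM(d, np.ones((len(d), 1)), groups=groups).fit(reml=True)
        lme_intercept = float(lme.params[0])
        p_lme = float(lme.pvalues[0])
        se = float(lme.bse[0])
        lme_ci = (lme_intercept - 1.96 * se, lme_intercept + 1.96 * se)

    # per-subject fractions of correctly classified segments
    subjects = list(dict.fromkeys(subject_ids))
    sid = np.asarray(subject_ids)
    frac_a = np.array([np.mean(a[sid == s] > 0.5) for s in subjects])
    frac_b = np.array([np.mean(b[sid == s] > 0.5) for s in subjects])
    fd = frac_a - frac_b
    if np.std(fd) == 0:
        p_subj = 1.0 if float(np.mean(fd)) == 0.0 else math.nan
    else:
        p_subj = float(sps.ttest_rel(frac_a, frac_b).pvalue)

    return ComparisonResult(
        mean_diff_segment=float(np.mean(d)),
        p_t_segment=p_seg,
        p_lme=p_lme,
        lme_intercept=lme_intercept,
        lme_ci=lme_ci,
        mean_diff_subject=float(np.mean(fd)),
        p_t_subject=p_subj,
        n_tests=n_tests,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    condition: str
    acc_segment: float
    acc_subject: float
    delta_acc_segment: float
    delta_acc_subject: float
    report: EvalReport
    comparison: ComparisonResult | None = None


def _select_ablated(
    unlabeled: list[tuple[str, str, list[Segment]]],
    mode: tuple,
    seed: int,
) -> list[tuple[str, str, list[Segment]]]:
    kind = mode[0]
    if kind == "downsample":
        ratio = float(mode[1])
        if not 0.0 <= ratio <= 1.0:
            raise ValueError("downsampling ratio must lie in [0, 1]")
        if ratio == 0.0:
            return []
        rng = np.random.default_rng([seed, 29])
        by_dataset: dict[str, list] = {}
        for item in unlabeled:
            by_dataset.setdefault(item[0], []).append(item)
        kept = []
        for dataset in sorted(by_dataset):
            recs = by_dataset[dataset]
            n_keep = max(1, int(round(ratio * len(recs))))  # keep >=1 per dataset
            idx = rng.permutation(len(recs))[:n_keep]
            kept.extend(recs[i] for i in sorted(idx))
        return kept
    if kind == "leave_one_out":
        dataset_id = mode[1]
        known = {item[0] for item in unlabeled}
        if dataset_id not in known:
            raise ValueError(f"unknown dataset id {dataset_id!r}")
        return [item for item in unlabeled if item[0] != dataset_id]
    raise ValueError(f"unknown ablation mode {kind!r}")


def ablate(
    unlabeled: list[tuple[str, str, list[Segment]]],
    mode: tuple,
    target: dict[str, list[Segment]],
    model_cfg: ModelConfig,
    pretrain_cfg: TrainConfig,
    finetune_cfg: TrainConfig,
    reference: EvalReport,
    reference_probs: np.ndarray | None = None,
    seed: int = 0,
) -> AblationResult:
    """Retrain the MP-pretrained, fine-tuned pipeline on an ablated collection.

    ``unlabeled`` holds (dataset_id, recording_id, segments) triples.  The
    pretraining set is the ablated unlabeled collection plus the target
    training set (pretraining on the target training set costs nothing in
    annotation); pretext validation uses the target validation set.  The
    result reports the change in segment/subject accuracy against the
    reference (full-collection) run, which shares the same initialization
    seed so the data effect is isolated.
    """
    kept = _select_ablated(unlabeled, mode, seed)
    pretrain_segments = [s for _, _, segs in kept for s in segs] + list(target["train"])

    cfg = ModelConfig(**{**model_cfg.__dict__})
    cfg.seed = seed
    encoder = E4mer(cfg)
    pre_cfg = TrainConfig(**{**pretrain_cfg.__dict__, "task": "mp", "seed": seed})
    train(encoder, pretrain_segments, target["val"], pre_cfg)

    clf = transfer(encoder, mode="FT", head_seed=seed + 1)
    fit_cfg = TrainConfig(**{**finetune_cfg.__dict__, "task": "classify", "seed": seed})
    train(clf, target["train"], target["val"], fit_cfg)

    probs = predict_segments(clf, target["test"])
    labels = _segment_targets(target["test"])
    subject_ids = [s.subject_id for s in target["test"]]
    report = evaluate(probs, labels, subject_ids)

    comparison = None
    if reference_probs is not None:
        correct_here = np.where(labels == 1, probs, 1.0 - probs)
        correct_ref = np.where(labels == 1, reference_probs, 1.0 - reference_probs)
        comparison = compare_models(correct_here, correct_ref, subject_ids)

    condition = f"{mode[0]}={mode[1]}"
    return AblationResult(
        condition=condition,
        acc_segment=report.acc_segment,
        acc_subject=report.acc_subject,
        delta_acc_segment=report.acc_segment - reference.acc_segment,
        delta_acc_subject=report.acc_subject - reference.acc_subject,
        report=report,
        comparison=comparison,
    )
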