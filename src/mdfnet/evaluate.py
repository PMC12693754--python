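"""Subject-independent evaluation protocol.

Balanced subject-level k-fold assignment (repeated seeded random splits
scored lexicographically on PD/HC balance, then age balance, then sex
balance), per-subject majority voting with a mean-probability tie-break,
confusion-matrix metrics (accuracy, precision, recall, F1) plus rank-based
AUC with PD as the positive class, paired t-tests across folds, repeated
hold-out validation, sampling-setting sweeps, and attention-weight summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from .model import MDFNet, ModelConfig
from .preprocess import PreprocessConfig, Segment, run_pipeline
from .synth import ConfigurationError, RawRecording, SubjectMeta
from .train import TrainConfig, TrainResult, train_model, _predict_in_batches
from .transforms import WaveletConfig, stack_domain_features

__all__ = [
    "FoldAssignment",
    "SubjectDecision",
    "MetricsReport",
    "AttentionSummary",
    "balanced_subject_folds",
    "majority_vote",
    "compute_metrics",
    "mean_report",
    "preprocess_cohort",
    "run_cross_validation",
    "run_repeated_holdout",
    "paired_t_test",
    "evaluate_split",
    "sweep_sampling_settings",
    "attention_summary",
    "CVResult",
    "HoldoutResult",
]

logger = logging.getLogger("mdfnet.evaluate")

# lexicographic-like priority weights: class balance >> age balance >> sex balance
_BALANCE_WEIGHTS = (1e4, 1e2, 1.0)


# --------------------------------------------------------------------------- #
# fold assignment
# --------------------------------------------------------------------------- #
@dataclass
class FoldAssignment:
    mapping: dict[str, int]  # subject_id -> fold in 1..k
    balance_report: pd.DataFrame
    score: float
    trial_scores: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return max(self.mapping.values())

    def subjects_in_fold(self, fold: int) -> list[str]:
        return [sid for sid, f in self.mapping.items() if f == fold]


def _balance_score(fold_ids: np.ndarray, labels: np.ndarray, ages: np.ndarray,
                   male: np.ndarray, k: int) -> float:
    pd_counts = np.array([np.sum((fold_ids == f) & (labels == 1)) for f in range(k)])
    mean_ages = np.array([ages[fold_ids == f].mean() for f in range(k)])
    male_props = np.array([male[fold_ids == f].mean() for f in range(k)])
    w1, w2, w3 = _BALANCE_WEIGHTS
    return float(w1 * (pd_counts.max() - pd_counts.min())
                 + w2 * mean_ages.std() + w3 * male_props.std())


def balanced_subject_folds(subjects: list[SubjectMeta], k: int = 5,
                           n_trials: int = 1000, rng_seed: int = 0) -> FoldAssignment:
    """Best of `n_trials` class-stratified random partitions into k folds."""
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if len(subjects) < k:
        raise ConfigurationError(f"{len(subjects)} subjects cannot fill {k} folds")
    ids = np.array([s.subject_id for s in subjects], dtype=object)
    labels = np.array([1 if s.label == "PD" else 0 for s in subjects])
    ages = np.array([s.age for s in subjects])
    male = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])

    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xF01D]))
    idx_by_class = [np.flatnonzero(labels == c) for c in (0, 1)]
    best: tuple[float, np.ndarray] | None = None
    scores = np.empty(n_trials)
    for t in range(n_trials):
        fold_ids = np.empty(len(subjects), dtype=int)
        offset = 0
        for cls_idx in idx_by_class:
            perm = rng.permutation(cls_idx)
            # round-robin deal keeps per-fold class counts within +-1; the
            # running offset keeps overall fold sizes within +-1 as well
            fold_ids[perm] = (offset + np.arange(perm.size)) % k
            offset += perm.size
        s = _balance_score(fold_ids, labels, ages, male, k)
        scores[t] = s
        if best is None or s < best[0]:
            best = (s, fold_ids.copy())
    score, fold_ids = best
    mapping = {sid: int(f) + 1 for sid, f in zip(ids, fold_ids)}
    rows = []
    for f in range(k):
        in_f = fold_ids == f
        hc, pdm = in_f & (labels == 0), in_f & (labels == 1)
        rows.append({
            "fold": f + 1,
            "n_subjects": int(in_f.sum()),
            "n_hc": int(hc.sum()),
            "n_pd": int(pdm.sum()),
            "mean_age": float(ages[in_f].mean()),
            "mean_age_hc": float(ages[hc].mean()) if hc.any() else np.nan,
            "mean_age_pd": float(ages[pdm].mean()) if pdm.any() else np.nan,
            "male_prop": float(male[in_f].mean()),
        })
    return FoldAssignment(mapping=mapping, balance_report=pd.DataFrame(rows),
                          score=score, trial_scores=scores)


# --------------------------------------------------------------------------- #
# voting and metrics
# --------------------------------------------------------------------------- #
@dataclass
class SubjectDecision:
    subject_id: str
    true_label: int  # 0 = HC, 1 = PD
    voted_label: int
    mean_probability: float  # PD-class probability averaged over segments
    n_segments: int


def majority_vote(segment_probs, threshold: float = 0.5,
                  subject_id: str = "", true_label: int = -1) -> SubjectDecision:
    """Vote per-segment thresholded labels; break exact ties by mean probability.

    A segment counts as PD when its probability is >= threshold; on a tied
    vote the subject is called PD iff the mean probability is >= 0.5 (the
    boundary goes to PD by convention).
    """
    probs = np.asarray(list(segment_probs), dtype=float)
    if probs.size == 0:
        raise ValueError("majority_vote requires at least one segment probability")
    votes_pd = int(np.sum(probs >= threshold))
    votes_hc = probs.size - votes_pd
    mean_p = float(probs.mean())
    if votes_pd > votes_hc:
        label = 1
    elif votes_pd < votes_hc:
        label = 0
    else:
        label = 1 if mean_p >= 0.5 else 0
    return SubjectDecision(subject_id=subject_id, true_label=true_label,
                           voted_label=label, mean_probability=mean_p,
                           n_segments=probs.size)


@dataclass
class MetricsReport:
    level: str  # 'sample' or 'subject'
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    prec: float
    rec: float
    f1: float
    auc: float  # nan when undefined
    auc_defined: bool = True

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int,
                    auc: float = np.nan, level: str = "sample") -> "MetricsReport":
        n = tp + tn + fp + fn
        acc = (tp + tn) / n if n else np.nan
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return cls(level=level, tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, prec=prec,
                   rec=rec, f1=f1, auc=auc, auc_defined=np.isfinite(auc))

    def as_dict(self) -> dict:
        return {"acc": self.acc, "prec": self.prec, "rec": self.rec,
                "f1": self.f1, "auc": self.auc}


def compute_metrics(y_true, y_pred, scores=None, level: str = "sample") -> MetricsReport:
    """Confusion counts + accuracy/precision/recall/F1 and rank-based AUC.

    PD (label 1) is the positive class.  AUC uses `scores` (probabilities)
    and is flagged undefined when only one class is present.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    auc = np.nan
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    elif scores is not None:
        logger.warning("AUC undefined: only one class present at %s level", level)
    return MetricsReport.from_counts(tp, tn, fp, fn, auc=auc, level=level)


def mean_report(reports: list[MetricsReport]) -> dict[str, float]:
    """Arithmetic mean of the metric columns across fold reports."""
    keys = ("acc", "prec", "rec", "f1", "auc")
    return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}


def paired_t_test(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-fold metric values."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t_test needs two equal-length vectors (n >= 2)")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences: |t| unbounded")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sstats.ttest_rel(a, b)
    return float(t), float(p)


# --------------------------------------------------------------------------- #
# end-to-end protocols
# --------------------------------------------------------------------------- #
def preprocess_cohort(
    recordings: list[RawRecording],
    cfg: PreprocessConfig = PreprocessConfig(),
    rng_seed: int = 0,
) -> tuple[list[Segment], pd.DataFrame]:
    """Run the full preprocessing pipeline over a cohort."""
    segments: list[Segment] = []
    reports = []
    for i, rec in enumerate(recordings):
        segs, rep = run_pipeline(rec, cfg, rng_seed=int(rng_seed) + i)
        segments.extend(segs)
        reports.append(rep)
    return segments, pd.DataFrame(reports)


def _split_segments(segments: list[Segment], subject_ids: set[str]) -> list[Segment]:
    return [s for s in segments if s.subject_id in subject_ids]


def evaluate_split(model: MDFNet, segments: list[Segment],
                   wavelet_cfg: WaveletConfig = WaveletConfig(),
                   batch_size: int = 512,
                   ) -> tuple[MetricsReport, MetricsReport, list[SubjectDecision]]:
    """Sample- and subject-level metrics for one held-out segment set."""
    feats, y, sids = stack_domain_features(segments, wavelet_cfg)
    probs = _predict_in_batches(model, feats, batch_size)
    preds = (probs >= 0.5).astype(int)
    sample_rep = compute_metrics(y, preds, scores=probs, level="sample")
    decisions = []
    for sid in pd.unique(sids):
        mask = sids == sid
        decisions.append(majority_vote(probs[mask], subject_id=str(sid),
                                       true_label=int(y[mask][0])))
    s_true = np.array([d.true_label for d in decisions])
    s_pred = np.array([d.voted_label for d in decisions])
    s_score = np.array([d.mean_probability for d in decisions])
    subject_rep = compute_metrics(s_true, s_pred, scores=s_score, level="subject")
    return sample_rep, subject_rep, decisions


@dataclass
class CVResult:
    fold_sample: list[MetricsReport]
    fold_subject: list[MetricsReport]
    mean_sample: dict[str, float]
    mean_subject: dict[str, float]
    pooled_confusion: np.ndarray  # subject-level 2x2, rows = true (HC, PD)
    decisions: list[SubjectDecision]
    train_results: list[TrainResult] = field(default_factory=list, repr=False)

    def summary_table(self, level: str = "subject") -> pd.DataFrame:
        reps = self.fold_subject if level == "subject" else self.fold_sample
        rows = [{"fold": i + 1, **r.as_dict()} for i, r in enumerate(reps)]
        mean = self.mean_subject if level == "subject" else self.mean_sample
        rows.append({"fold": "mean", **mean})
        return pd.DataFrame(rows)


def run_cross_validation(
    segments: list[Segment],
    folds: FoldAssignment,
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    wavelet_cfg: WaveletConfig = WaveletConfig(),
) -> CVResult:
    """Train k models, each validated on its held-out subject fold."""
    seg_subjects = {s.subject_id for s in segments}
    fold_subjects = set(folds.mapping)
    if not seg_subjects <= fold_subjects:
        raise ConfigurationError("fold assignment does not cover all segment subjects")
    fold_sample, fold_subject, all_decisions, train_results = [], [], [], []
    for f in range(1, folds.k + 1):
        val_ids = set(folds.subjects_in_fold(f)) & seg_subjects
        train_ids = seg_subjects - val_ids
        tr = train_model(_split_segments(segments, train_ids),
                         _split_segments(segments, val_ids),
                         model_cfg, train_cfg, wavelet_cfg)
        sample_rep, subject_rep, decisions = evaluate_split(
            tr.model, _split_segments(segments, val_ids), wavelet_cfg,
            train_cfg.batch_size)
        fold_sample.append(sample_rep)
        fold_subject.append(subject_rep)
        all_decisions.extend(decisions)
        train_results.append(tr)
        logger.info("fold %d: sample acc %.3f, subject acc %.3f",
                    f, sample_rep.acc, subject_rep.acc)
    pooled = np.zeros((2, 2), dtype=int)
    for d in all_decisions:
        pooled[d.true_label, d.voted_label] += 1
    return CVResult(fold_sample=fold_sample, fold_subject=fold_subject,
                    mean_sample=mean_report(fold_sample),
                    mean_subject=mean_report(fold_subject),
                    pooled_confusion=pooled, decisions=all_decisions,
                    train_results=train_results)


@dataclass
class HoldoutResult:
    run_subject: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    ci_halfwidth: dict[str, float]  # 1.96 * sd / sqrt(n_runs), normal approx


def run_repeated_holdout(
    segments: list[Segment],
    subjects: list[SubjectMeta],
    n_runs: int = 10,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    wavelet_cfg: WaveletConfig = WaveletConfig(),
    rng_seed: int = 0,
) -> HoldoutResult:
    """n_runs random subject-disjoint 60/20/20 splits; mean +- 95% CI."""
    if not np.isclose(sum(split), 1.0):
        raise ConfigurationError(f"split fractions must sum to 1, got {split}")
    ids = np.array([s.subject_id for s in subjects], dtype=object)
    labels = np.array([1 if s.label == "PD" else 0 for s in subjects])
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x801D]))
    reports = []
    for run in range(n_runs):
        train_ids, val_ids, test_ids = set(), set(), set()
        for cls in (0, 1):  # stratified per class
            cls_ids = rng.permutation(ids[labels == cls])
            n = cls_ids.size
            n_tr = int(round(split[0] * n))
            n_va = int(round(split[1] * n))
            train_ids |= set(cls_ids[:n_tr])
            val_ids |= set(cls_ids[n_tr:n_tr + n_va])
            test_ids |= set(cls_ids[n_tr + n_va:])
        if not (train_ids and val_ids and test_ids):
            raise ConfigurationError("cohort too small for a 60/20/20 subject split")
        tr = train_model(_split_segments(segments, train_ids),
                         _split_segments(segments, val_ids),
                         model_cfg, train_cfg, wavelet_cfg)
        _, subject_rep, _ = evaluate_split(
            tr.model, _split_segments(segments, test_ids), wavelet_cfg,
            train_cfg.batch_size)
        reports.append(subject_rep)
        logger.info("holdout run %d: subject acc %.3f", run + 1, subject_rep.acc)
    keys = ("acc", "prec", "rec", "f1", "auc")
    vals = {k: np.array([getattr(r, k) for r in reports]) for k in keys}
    return HoldoutResult(
        run_subject=reports,
        mean={k: float(v.mean()) for k, v in vals.items()},
        sd={k: float(v.std(ddof=1)) if n_runs > 1 else 0.0 for k, v in vals.items()},
        ci_halfwidth={k: float(1.96 * v.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1
                      else 0.0 for k, v in vals.items()},
    )


def sweep_sampling_settings(
    recordings: list[RawRecording],
    folds: FoldAssignment,
    settings: list[tuple[float, float]],
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    base_cfg: PreprocessConfig = PreprocessConfig(),
    wavelet_cfg: WaveletConfig = WaveletConfig(),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Re-run preprocessing + CV for each (window_s, target_rate) setting."""
    rows = []
    for window_s, rate in settings:
        cfg = PreprocessConfig(
            band_low=base_cfg.band_low, band_high=base_cfg.band_high,
            ica_components=base_cfg.ica_components,
            reject_percentile=base_cfg.reject_percentile,
            target_rate=rate, window_s=window_s,
        )
        segments, _ = preprocess_cohort(recordings, cfg, rng_seed=rng_seed)
        cv = run_cross_validation(segments, folds, model_cfg, train_cfg, wavelet_cfg)
        n_per_segment = int(round(window_s * rate))
        rows.append({
            "window_s": window_s, "rate_hz": rate, "n_per_segment": n_per_segment,
            **{f"sample_{k}": v for k, v in cv.mean_sample.items()},
            **{f"subject_{k}": v for k, v in cv.mean_subject.items()},
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# attention analysis
# --------------------------------------------------------------------------- #
@dataclass
class AttentionSummary:
    channel: np.ndarray | None  # [32]
    freq: np.ndarray | None     # [F]
    wavelet: np.ndarray | None  # [W]
    missing_branches: tuple[str, ...] = ()


def attention_summary(model: MDFNet, segments: list[Segment],
                      wavelet_cfg: WaveletConfig = WaveletConfig(),
                      batch_size: int = 512) -> AttentionSummary:
    """Element-wise mean of per-segment attention vectors over a segment set."""
    if not segments:
        raise ValueError("attention_summary requires at least one segment")
    feats, _, _ = stack_domain_features(segments, wavelet_cfg)
    sums: dict[str, np.ndarray] = {}
    n = len(segments)
    for lo in range(0, n, batch_size):
        chunk = {k: v[lo:lo + batch_size] for k, v in feats.items()}
        _, attn = model.forward(chunk, training=False)
        for key, val in attn.items():
            sums[key] = sums.get(key, 0.0) + val.sum(axis=0)
    means = {k: v / n for k, v in sums.items()}
    missing = tuple(b for b in ("T", "F", "W")
                    if b not in model.config.branches_enabled)
    if missing:
        logger.warning("branches %s disabled: corresponding summaries absent", missing)
    return AttentionSummary(
        channel=means.get("channel"),
        freq=means.get("freq"),
        wavelet=means.get("wavelet"),
        missing_branches=missing,
    )
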