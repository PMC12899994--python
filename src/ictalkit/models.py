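"""Classifier suite, LOSO harness, and isotonic probability calibration.

The six model configurations mirror a gradient-boosted/bagged ensemble
protocol: three boosted configs ("xgboost", "lightgbm", "catboost" — realized
here with scikit-learn's gradient-boosting estimators carrying the same
stated hyperparameters: 200 rounds, learning rate 0.1, depth 6 / 31 leaves,
subsampling 0.8, the respective regularization terms), two bagged forests
(100 trees, sqrt features, min_samples_split 10, min_samples_leaf 5,
balanced class weights) and a logistic baseline (C=1, lbfgs, 1000 iters).
Boosted configs weight positives by min(neg/pos, 100) (the capped
scale_pos_weight rule); every model sits behind a StandardScaler.

``LosoExperiment`` is the model-facing surface: built from a FeatureMatrix,
``fit()`` runs the leave-one-subject-out protocol (per-fold cleaning,
collinearity pruning, 20:1 undersampling, fitting, isotonic calibration on a
20 % stratified split) and returns a ``LosoResults`` carrying per-fold
scores, metrics, event-level reports and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import events as ev
from .features import FeatureMatrix
from .harmonize import (
    CleanStats,
    apply_clean,
    balance_classes,
    clean_matrix,
    collinearity_filter,
)
from .io import SeizureInterval

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "build_model",
    "make_sample_weight",
    "fit_calibrator",
    "run_loso",
    "fit_single_fold",
    "FoldResult",
    "LosoExperiment",
    "LosoResults",
]

MODEL_NAMES = ["xgboost", "lightgbm", "catboost", "extra_trees", "random_forest", "logistic"]
BOOSTED = {"xgboost", "lightgbm", "catboost"}
SCALE_POS_WEIGHT_CAP = 100.0

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    # 200 trees, lr 0.1, max_depth 6, subsample 0.8, colsample 0.8, min_child_weight 5
    "xgboost": dict(n_estimators=200, learning_rate=0.1, max_depth=6,
                    subsample=0.8, max_features=0.8, min_samples_leaf=5),
    # 200 estimators, lr 0.1, num_leaves 31, lambda 0.1
    "lightgbm": dict(max_iter=200, learning_rate=0.1, max_leaf_nodes=31,
                     l2_regularization=0.1),
    # 200 iterations, lr 0.1, depth 6, L2 3.0
    "catboost": dict(max_iter=200, learning_rate=0.1, max_depth=6,
                     max_leaf_nodes=None, l2_regularization=3.0),
    "extra_trees": dict(n_estimators=100, max_features="sqrt",
                        min_samples_split=10, min_samples_leaf=5,
                        class_weight="balanced"),
    "random_forest": dict(n_estimators=100, max_features="sqrt",
                          min_samples_split=10, min_samples_leaf=5,
                          class_weight="balanced"),
    "logistic": dict(C=1.0, solver="lbfgs", max_iter=1000, class_weight="balanced"),
}


@dataclass
class ModelSpec:
    """Named classifier configuration with frozen hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; known: {MODEL_NAMES}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.name])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    @classmethod
    def default(cls, name: str, seed: int = 42) -> "ModelSpec":
        return cls(name=name, seed=seed)


def build_model(spec: ModelSpec) -> Pipeline:
    """Fresh (StandardScaler -> classifier) pipeline for a spec."""
    hp = spec.hyperparameters
    if spec.name == "xgboost":
        clf = GradientBoostingClassifier(random_state=spec.seed, **hp)
    elif spec.name in ("lightgbm", "catboost"):
        clf = HistGradientBoostingClassifier(random_state=spec.seed, **hp)
    elif spec.name == "extra_trees":
        clf = ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **hp)
    elif spec.name == "random_forest":
        clf = RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    elif spec.name == "logistic":
        clf = LogisticRegression(random_state=spec.seed, **hp)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.name)
    return Pipeline([("scaler", StandardScaler()), ("clf", clf)])


def make_sample_weight(y: np.ndarray, spec: ModelSpec) -> np.ndarray | None:
    """Positive-class weighting for the boosted configs (capped at 100)."""
    if spec.name not in BOOSTED:
        return None
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        return None
    ratio = n_neg / n_pos
    if spec.name in ("xgboost", "lightgbm"):
        ratio = min(ratio, SCALE_POS_WEIGHT_CAP)
    w = np.ones(y.size)
    w[y == 1] = ratio
    return w


class _IdentityCalibrator:
    def predict(self, scores: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(scores, dtype=np.float64), 0.0, 1.0)


def fit_calibrator(raw_scores: np.ndarray, labels: np.ndarray):
    """Isotonic score->probability map; identity (with warning) if one class."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class calibration split; using identity map")
        return _IdentityCalibrator()
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(np.asarray(raw_scores, dtype=np.float64), labels)
    return iso


# ---------------------------------------------------------------------------
# LOSO harness
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    model_name: str
    held_out_subject: str
    raw_scores: np.ndarray
    calibrated_probs: np.ndarray
    labels: np.ndarray
    sessions: np.ndarray
    start_times_s: np.ndarray
    kept_features: list[str]
    clean_stats: CleanStats
    pipeline: Pipeline
    calibrator: object
    segment_metrics: dict[str, float]
    window_s: float = 5.0
    hop_s: float = 2.5
    calibration_scores: np.ndarray | None = None  # raw scores on the 20% split
    calibration_labels: np.ndarray | None = None


def _fold_seed(global_seed: int, subject: str) -> int:
    return int((global_seed * 100003 + zlib.crc32(subject.encode())) % (2 ** 31))


def _segment_metrics(y: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> dict:
    pred = (probs >= threshold).astype(int)
    out = {
        "accuracy": accuracy_score(y, pred),
        "precision": precision_score(y, pred, zero_division=0),
        "recall": recall_score(y, pred, zero_division=0),
        "f1": f1_score(y, pred, zero_division=0),
    }
    out["auc"] = roc_auc_score(y, probs) if len(np.unique(y)) == 2 else np.nan
    return {k: float(v) for k, v in out.items()}


def _prepare_fold(fm: FeatureMatrix, subject: str, seed: int,
                  collinearity_threshold: float, sample_cap: int,
                  max_ratio: float, calibration_frac: float):
    """Training-side preparation shared by all model specs in one fold."""
    fseed = _fold_seed(seed, subject)
    train = fm.subset_rows(fm.groups != subject)
    test = fm.subset_rows(fm.groups == subject)
    if train.labels.sum() == 0:
        raise ValueError(f"no positive training segments for fold {subject}")
    train_clean, stats = clean_matrix(train)
    test_clean = apply_clean(test, stats)
    train_filt, kept = collinearity_filter(
        train_clean, threshold=collinearity_threshold,
        sample_cap=sample_cap, seed=fseed,
    )
    test_filt = test_clean.select_features(kept)
    bal_idx = balance_classes(train_filt.labels, max_ratio=max_ratio, seed=fseed)
    Xb = train_filt.X.to_numpy(dtype=np.float64)[bal_idx]
    yb = train_filt.labels[bal_idx].astype(int)
    X_fit, X_cal, y_fit, y_cal = train_test_split(
        Xb, yb, test_size=calibration_frac, stratify=yb, random_state=fseed % (2 ** 31),
    )
    return fseed, stats, kept, test_filt, test, X_fit, y_fit, X_cal, y_cal


def run_loso(fm: FeatureMatrix, specs: list[ModelSpec], seed: int = 42,
             collinearity_threshold: float = 0.95, sample_cap: int = 20000,
             max_ratio: float = 20.0, calibration_frac: float = 0.2,
             ) -> dict[str, list[FoldResult]]:
    """Leave-one-subject-out protocol over every subject in ``fm``.

    Each fold refits cleaning, collinearity pruning, balancing, scaling and
    calibration on the training subjects only; the held-out subject is only
    ever scored.
    """
    subjects = list(dict.fromkeys(fm.groups))  # stable order
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    results: dict[str, list[FoldResult]] = {spec.name: [] for spec in specs}
    for subject in subjects:
        prepared = _prepare_fold(
            fm, subject, seed, collinearity_threshold, sample_cap,
            max_ratio, calibration_frac,
        )
        for spec in specs:
            fr = _fit_prepared_fold(prepared, spec, subject, fm.window_s)
            results[spec.name].append(fr)
            logger.info("fold %s / %s: AUC %.4f", subject, spec.name,
                        fr.segment_metrics["auc"])
    return results


def _fit_prepared_fold(prepared, spec: ModelSpec, subject: str,
                       window_s: float) -> FoldResult:
    (fseed, stats, kept, test_filt, test, X_fit, y_fit, X_cal, y_cal) = prepared
    X_test = test_filt.X.to_numpy(dtype=np.float64)
    pipe = build_model(spec)
    w = make_sample_weight(y_fit, spec)
    if w is not None:
        pipe.fit(X_fit, y_fit, clf__sample_weight=w)
    else:
        pipe.fit(X_fit, y_fit)
    raw_cal = pipe.predict_proba(X_cal)[:, 1]
    calibrator = fit_calibrator(raw_cal, y_cal)
    raw_test = pipe.predict_proba(X_test)[:, 1]
    cal_test = np.asarray(calibrator.predict(raw_test), dtype=np.float64)
    metrics = _segment_metrics(test.labels.astype(int), cal_test)
    return FoldResult(
        model_name=spec.name,
        held_out_subject=subject,
        raw_scores=raw_test,
        calibrated_probs=cal_test,
        labels=test.labels.astype(int),
        sessions=test.sessions,
        start_times_s=test.start_times_s,
        kept_features=kept,
        clean_stats=stats,
        pipeline=pipe,
        calibrator=calibrator,
        segment_metrics=metrics,
        window_s=window_s,
        calibration_scores=raw_cal,
        calibration_labels=np.asarray(y_cal),
    )


def fit_single_fold(fm: FeatureMatrix, spec: ModelSpec, subject: str,
                    seed: int = 42, collinearity_threshold: float = 0.95,
                    sample_cap: int = 20000, max_ratio: float = 20.0,
                    calibration_frac: float = 0.2) -> FoldResult:
    """One LOSO fold (training universe = every other subject in ``fm``)."""
    prepared = _prepare_fold(fm, subject, seed, collinearity_threshold,
                             sample_cap, max_ratio, calibration_frac)
    return _fit_prepared_fold(prepared, spec, subject, fm.window_s)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class LosoExperiment:
    """Leave-one-subject-out seizure-detection experiment.

    Parameters
    ----------
    fm : FeatureMatrix
        Feature rows of the seizure-positive subjects.
    specs : list of ModelSpec, optional
        Classifier configurations (default: the "xgboost" config).
    intervals : list of SeizureInterval, optional
        Ground-truth seizure intervals for the sessions in ``fm``; required
        for event-level reports on the results object.
    seed : int
        Global seed; per-fold streams are derived from it.
    """

    def __init__(self, fm: FeatureMatrix, specs: list[ModelSpec] | None = None,
                 intervals: list[SeizureInterval] | None = None, seed: int = 42,
                 collinearity_threshold: float = 0.95, sample_cap: int = 20000,
                 max_ratio: float = 20.0, calibration_frac: float = 0.2,
                 smoothing_window: int = 5, threshold: float = 0.5,
                 min_event_len: int = 3):
        self.fm = fm
        self.specs = specs or [ModelSpec.default("xgboost", seed=seed)]
        self.intervals = intervals or []
        self.seed = seed
        self.collinearity_threshold = collinearity_threshold
        self.sample_cap = sample_cap
        self.max_ratio = max_ratio
        self.calibration_frac = calibration_frac
        self.smoothing_window = smoothing_window
        self.threshold = threshold
        self.min_event_len = min_event_len

    def fit(self) -> "LosoResults":
        folds = run_loso(
            self.fm, self.specs, seed=self.seed,
            collinearity_threshold=self.collinearity_threshold,
            sample_cap=self.sample_cap, max_ratio=self.max_ratio,
            calibration_frac=self.calibration_frac,
        )
        return LosoResults(self, folds)


class LosoResults:
    """Per-fold scores, metrics and event-level reports of a LOSO run."""

    def __init__(self, experiment: LosoExperiment,
                 folds: dict[str, list[FoldResult]]):
        self.experiment = experiment
        self.folds = folds

    # -- segment level ------------------------------------------------------

    def segment_table(self) -> pd.DataFrame:
        rows = []
        for name, frs in self.folds.items():
            for fr in frs:
                rows.append({"model": name, "subject": fr.held_out_subject,
                             **fr.segment_metrics})
        return pd.DataFrame(rows)

    # -- event level --------------------------------------------------------

    def _fold_decisions(self, fr: FoldResult):
        """Per-session smoothed decisions and events for one fold."""
        exp = self.experiment
        out = []
        for session in dict.fromkeys(fr.sessions):
            m = fr.sessions == session
            order = np.argsort(fr.start_times_s[m], kind="stable")
            probs = fr.calibrated_probs[m][order]
            labels = fr.labels[m][order]
            starts = fr.start_times_s[m][order]
            smoothed = ev.smooth_probabilities(probs, exp.smoothing_window)
            series = ev.extract_events(
                (smoothed >= exp.threshold).astype(int),
                min_len=exp.min_event_len, start_times_s=starts,
                window_s=fr.window_s, hop_s=fr.hop_s,
            )
            out.append((session, series, labels, probs, starts))
        return out

    def event_report(self, fr: FoldResult,
                     intervals: list[SeizureInterval] | None = None
                     ) -> ev.MetricsReport:
        """Aggregate event metrics over the held-out subject's sessions."""
        intervals = self.experiment.intervals if intervals is None else intervals
        detected = n_true = n_pred = matched_pred = 0
        tp = fp = tn = 0
        false_events = 0
        hours = 0.0
        all_labels, all_probs = [], []
        for session, series, labels, probs, starts in self._fold_decisions(fr):
            truth = [iv for iv in intervals if iv.session_id == session]
            n_true += len(truth)
            detected += sum(
                any(e.overlaps(iv.onset_s, iv.offset_s) for e in series.events)
                for iv in truth
            )
            n_pred += len(series.events)
            matched_pred += sum(
                any(e.overlaps(iv.onset_s, iv.offset_s) for iv in truth)
                for e in series.events
            )
            d = series.decisions
            tp += int(((d == 1) & (labels == 1)).sum())
            fp += int(((d == 1) & (labels == 0)).sum())
            tn += int(((d == 0) & (labels == 0)).sum())
            false_events += n_false_events(series, truth)
            hours += (starts[-1] + fr.window_s) / 3600.0 if starts.size else 0.0
            all_labels.append(labels)
            all_probs.append(probs)
        rep = ev.MetricsReport(n_true_events=n_true, n_pred_events=n_pred,
                               n_detected=detected)
        rep.event_sensitivity = detected / n_true if n_true else None
        rep.specificity = tn / (tn + fp) if (tn + fp) else None
        rep.precision = tp / (tp + fp) if (tp + fp) else None
        rep.event_precision = matched_pred / n_pred if n_pred else None
        if rep.event_precision is not None and rep.event_sensitivity is not None:
            p, r = rep.event_precision, rep.event_sensitivity
            rep.event_f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        rep.fa_per_24h = false_events * 24.0 / hours if hours > 0 else None
        y = np.concatenate(all_labels)
        p_ = np.concatenate(all_probs)
        if len(np.unique(y)) == 2:
            rep.auc = float(roc_auc_score(y, p_))
        return rep

    def event_table(self, intervals: list[SeizureInterval] | None = None
                    ) -> pd.DataFrame:
        rows = []
        for name, frs in self.folds.items():
            for fr in frs:
                rep = self.event_report(fr, intervals)
                rows.append({
                    "model": name, "subject": fr.held_out_subject,
                    "event_sensitivity": rep.event_sensitivity,
                    "specificity": rep.specificity,
                    "fa_per_24h": rep.fa_per_24h,
                    "auc": rep.auc,
                    "n_true_events": rep.n_true_events,
                    "n_detected": rep.n_detected,
                })
        return pd.DataFrame(rows)

    def frontier(self, intervals: list[SeizureInterval] | None = None
                 ) -> pd.DataFrame:
        """Zero-false-alarm frontier over models, per held-out patient."""
        table = self.event_table(intervals)
        per_patient: dict[str, dict[str, tuple[float, float]]] = {}
        for _, row in table.iterrows():
            per_patient.setdefault(row["subject"], {})[row["model"]] = (
                row["fa_per_24h"], row["event_sensitivity"],
            )
        return ev.zero_fa_frontier(per_patient)

    # -- seizure-free deployment -------------------------------------------

    def false_alarms_on(self, free_fm: FeatureMatrix) -> pd.DataFrame:
        """Deploy each fold's model on seizure-free subjects; FA/24 h per fold."""
        exp = self.experiment
        rows = []
        for name, frs in self.folds.items():
            for fr in frs:
                clean = apply_clean(free_fm, fr.clean_stats).select_features(
                    fr.kept_features
                )
                X = clean.X.to_numpy(dtype=np.float64)
                probs = np.asarray(
                    fr.calibrator.predict(fr.pipeline.predict_proba(X)[:, 1]),
                    dtype=np.float64,
                )
                false_events = 0
                hours = 0.0
                for session in dict.fromkeys(clean.sessions):
                    m = clean.sessions == session
                    order = np.argsort(clean.start_times_s[m], kind="stable")
                    smoothed = ev.smooth_probabilities(
                        probs[m][order], exp.smoothing_window
                    )
                    series = ev.extract_events(
                        (smoothed >= exp.threshold).astype(int),
                        min_len=exp.min_event_len,
                        start_times_s=clean.start_times_s[m][order],
                        window_s=fr.window_s, hop_s=fr.hop_s,
                    )
                    false_events += len(series.events)
                    starts = clean.start_times_s[m][order]
                    hours += (starts[-1] + fr.window_s) / 3600.0
                rows.append({"model": name, "fold": fr.held_out_subject,
                             "false_events": false_events,
                             "monitored_hours": hours,
                             "fa_per_24h": false_events * 24.0 / hours})
        return pd.DataFrame(rows)

    # -- presentation -------------------------------------------------------

    def summary(self, intervals: list[SeizureInterval] | None = None) -> str:
        seg = self.segment_table().groupby("model").mean(numeric_only=True)
        lines = ["LOSO seizure-detection results",
                 "=" * 64,
                 f"{'model':<14}{'AUC':>8}{'recall':>9}{'precision':>11}{'F1':>8}"]
        for model, row in seg.iterrows():
            lines.append(
                f"{model:<14}{row['auc']:>8.4f}{row['recall']:>9.4f}"
                f"{row['precision']:>11.4f}{row['f1']:>8.4f}"
            )
        if self.experiment.intervals or intervals:
            evt = self.event_table(intervals).groupby("model").mean(numeric_only=True)
            lines += ["", f"{'model':<14}{'event sens':>11}{'FA/24h':>9}"]
            for model, row in evt.iterrows():
                lines.append(
                    f"{model:<14}{row['event_sensitivity']:>11.4f}"
                    f"{row['fa_per_24h']:>9.4f}"
                )
        lines.append("=" * 64)
        return "\n".join(lines)


def n_false_events(series: ev.EventSeries, truth: list[SeizureInterval]) -> int:
    return sum(
        not any(e.overlaps(iv.onset_s, iv.offset_s) for iv in truth)
        for e in series.events
    )
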