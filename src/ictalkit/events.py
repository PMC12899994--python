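"""Event-level decisions and clinical metrics.

Per-segment calibrated probabilities are median-smoothed, thresholded at
0.5 and grouped into events (runs of at least three consecutive positive
segments).  A true seizure counts as detected when at least one predicted
event overlaps it in time; event sensitivity is detected/true events.
Specificity and precision are segment-level counts; the event F1 combines
event-level precision (predicted events overlapping truth / predicted
events) with event sensitivity.  False alarms are predicted events with no
overlap with any true seizure, normalized to a 24 h monitoring period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.metrics import roc_auc_score

from .io import SeizureInterval

__all__ = [
    "Event",
    "EventSeries",
    "MetricsReport",
    "smooth_probabilities",
    "extract_events",
    "score_events",
    "fa_per_24h",
    "zero_fa_frontier",
]


@dataclass(frozen=True)
class Event:
    start_idx: int
    end_idx: int          # inclusive
    start_s: float
    end_s: float          # half-open end time
    matched: bool = False

    def overlaps(self, onset_s: float, offset_s: float) -> bool:
        return self.start_s < offset_s and self.end_s > onset_s


@dataclass
class EventSeries:
    """Thresholded decision sequence of one session, grouped into events."""

    decisions: np.ndarray
    events: list[Event]
    window_s: float = 5.0
    hop_s: float = 2.5
    start_times_s: np.ndarray | None = None


@dataclass
class MetricsReport:
    event_sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    event_f1: float | None = None
    event_precision: float | None = None
    fa_per_24h: float | None = None
    auc: float | None = None
    ece: float | None = None
    brier: float | None = None
    n_true_events: int = 0
    n_pred_events: int = 0
    n_detected: int = 0
    undefined: list[str] = field(default_factory=list)


def smooth_probabilities(probs: np.ndarray, window: int = 5) -> np.ndarray:
    """Running median with edge reflection (odd window, 3-11)."""
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    if not 3 <= window <= 11:
        raise ValueError("median window must lie in [3, 11]")
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size == 0:
        return probs
    # edge reflection duplicates the boundary sample; an isolated spike at
    # the very first/last position can therefore survive (documented)
    return median_filter(probs, size=window, mode="reflect")


def extract_events(decisions: np.ndarray, min_len: int = 3,
                   start_times_s: np.ndarray | None = None,
                   window_s: float = 5.0, hop_s: float = 2.5) -> EventSeries:
    """Maximal runs of 1s with length >= min_len become events."""
    decisions = np.asarray(decisions).astype(np.int8)
    if start_times_s is None:
        start_times_s = np.arange(decisions.size) * hop_s
    events: list[Event] = []
    i = 0
    n = decisions.size
    while i < n:
        if decisions[i] == 1:
            j = i
            while j + 1 < n and decisions[j + 1] == 1:
                j += 1
            if j - i + 1 >= min_len:
                events.append(Event(
                    start_idx=i, end_idx=j,
                    start_s=float(start_times_s[i]),
                    end_s=float(start_times_s[j] + window_s),
                ))
            i = j + 1
        else:
            i += 1
    return EventSeries(decisions=decisions, events=events, window_s=window_s,
                       hop_s=hop_s, start_times_s=np.asarray(start_times_s))


def score_events(pred: EventSeries, truth: list[SeizureInterval],
                 segment_labels: np.ndarray,
                 probs: np.ndarray | None = None) -> MetricsReport:
    """Event- and segment-level metrics for one aligned timeline."""
    labels = np.asarray(segment_labels)
    decisions = pred.decisions
    if decisions.size != labels.size:
        raise ValueError("decision and label timelines differ in length")

    detected = sum(
        any(ev.overlaps(iv.onset_s, iv.offset_s) for ev in pred.events)
        for iv in truth
    )
    matched_pred = sum(
        any(ev.overlaps(iv.onset_s, iv.offset_s) for iv in truth)
        for ev in pred.events
    )

    tp = int(((decisions == 1) & (labels == 1)).sum())
    fp = int(((decisions == 1) & (labels == 0)).sum())
    tn = int(((decisions == 0) & (labels == 0)).sum())

    rep = MetricsReport(n_true_events=len(truth), n_pred_events=len(pred.events),
                        n_detected=int(detected))
    if truth:
        rep.event_sensitivity = detected / len(truth)
    else:
        rep.undefined.append("event_sensitivity")
    if tn + fp > 0:
        rep.specificity = tn / (tn + fp)
    else:
        rep.undefined.append("specificity")
    if tp + fp > 0:
        rep.precision = tp / (tp + fp)
    else:
        rep.undefined.append("precision")
    if pred.events:
        rep.event_precision = matched_pred / len(pred.events)
    else:
        rep.undefined.append("event_precision")
    if rep.event_precision is not None and rep.event_sensitivity is not None:
        p, r = rep.event_precision, rep.event_sensitivity
        rep.event_f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    else:
        rep.undefined.append("event_f1")
    if probs is not None and len(np.unique(labels)) == 2:
        rep.auc = float(roc_auc_score(labels, probs))
    return rep


def fa_per_24h(pred: EventSeries, monitored_hours: float,
               truth: list[SeizureInterval] | None = None) -> float:
    """False-alarm events per 24 h: predicted events with no true overlap."""
    if not monitored_hours > 0:
        raise ValueError("monitored_hours must be positive")
    truth = truth or []
    false_events = sum(
        not any(ev.overlaps(iv.onset_s, iv.offset_s) for iv in truth)
        for ev in pred.events
    )
    return false_events * 24.0 / monitored_hours


def zero_fa_frontier(per_patient: dict[str, dict[str, tuple[float, float]]]
                     ) -> pd.DataFrame:
    """Per patient, the model with highest sensitivity among those at FA = 0.

    ``per_patient[patient][model] = (fa_per_24h, event_sensitivity)``.
    Patients where no model attains FA = 0 are flagged ``attained=False``.
    The frontier mean is the mean sensitivity over attained patients; it is
    attached as ``DataFrame.attrs['frontier_mean_sensitivity']``.
    """
    rows = []
    for patient, table in per_patient.items():
        zero_fa = {m: sens for m, (fa, sens) in table.items() if fa == 0.0}
        if zero_fa:
            best = max(sorted(zero_fa), key=lambda m: zero_fa[m])
            rows.append({"patient": patient, "model": best,
                         "sensitivity": zero_fa[best], "attained": True})
        else:
            rows.append({"patient": patient, "model": None,
                         "sensitivity": np.nan, "attained": False})
    df = pd.DataFrame(rows)
    attained = df[df["attained"]]
    df.attrs["frontier_mean_sensitivity"] = (
        float(attained["sensitivity"].mean()) if len(attained) else float("nan")
    )
    return df
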