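"""Multi-domain EEG feature bank.

Per channel and 5 s window the bank computes 32 descriptors:

* time domain (13): mean, variance, skewness, kurtosis, line length,
  zero-crossing rate, Hjorth activity/mobility/complexity, RMS, IQR,
  peak-to-peak, mean Teager-Kaiser energy;
* spectral (17): absolute and relative delta/theta/alpha/beta/gamma band
  powers (Welch, 256-sample Hann segments, 50 % overlap), theta/alpha,
  beta/alpha and (beta+gamma)/(alpha+theta) ratios, spectral entropy,
  median frequency, 95 % spectral edge, 1/f slope (log-log OLS, 1-40 Hz);
* nonlinear (2): sample entropy (m=2, r=0.2*SD, Chebyshev distance,
  self-matches excluded) and permutation entropy (order 4, delay 1,
  normalized to [0, 1]).

Cross-channel summaries add the maximum RMS over channels, per-band
hemispheric lateralization indices (odd 10-20 indices = left, even = right,
midline excluded; bipolar channels assigned by their first electrode), and
mean absolute relative-power asymmetry between adjacent bands.

``build_feature_matrix`` exposes a vectorized batch path; the single-window
functions (``time_domain_features`` etc.) are the reference semantics and the
batch path is tested against them.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .preprocess import SegmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "time_domain_features",
    "spectral_features",
    "nonlinear_features",
    "cross_channel_features",
    "build_feature_matrix",
    "TIME_FEATURE_NAMES",
    "SPECTRAL_FEATURE_NAMES",
    "NONLINEAR_FEATURE_NAMES",
    "channel_side",
]

DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class FeatureConfig:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    welch_nperseg: int = 256
    welch_overlap: float = 0.5
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    permen_order: int = 4
    permen_delay: int = 1
    slope_range_hz: tuple[float, float] = (1.0, 40.0)
    total_range_hz: tuple[float, float] = (0.5, 40.0)
    include_overlap_frac: bool = False  # label-leakage replication switch

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (0.5 - 1e-9 <= lo < hi <= 40.0 + 1e-9):
                raise ValueError(f"band {name} edges must increase within [0.5, 40]")


TIME_FEATURE_NAMES = [
    "mean", "variance", "skew", "kurtosis", "line_length", "zcr",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "rms", "iqr", "ptp", "tkeo",
]

_BAND_ORDER = ["delta", "theta", "alpha", "beta", "gamma"]
SPECTRAL_FEATURE_NAMES = (
    [f"abs_{b}" for b in _BAND_ORDER]
    + [f"rel_{b}" for b in _BAND_ORDER]
    + ["theta_alpha_ratio", "beta_alpha_ratio", "fast_slow_ratio",
       "spectral_entropy", "median_freq", "sef95", "one_over_f_slope"]
)
NONLINEAR_FEATURE_NAMES = ["sampen", "permen"]
PER_CHANNEL_FEATURES = TIME_FEATURE_NAMES + SPECTRAL_FEATURE_NAMES + NONLINEAR_FEATURE_NAMES


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------


def _batch_time_domain(x: np.ndarray) -> dict[str, np.ndarray]:
    """x: [..., n] -> dict of arrays with the leading shape."""
    n = x.shape[-1]
    mean = x.mean(axis=-1)
    var = x.var(axis=-1)
    # biased moment estimators; both defined as 0 for constant signals
    centered = x - mean[..., None]
    m2 = var
    m3 = (centered ** 3).mean(axis=-1)
    m4 = (centered ** 4).mean(axis=-1)
    ok = m2 > 0
    skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
    kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2 - 3.0, 0.0)
    dx = np.diff(x, axis=-1)
    ddx = np.diff(dx, axis=-1)
    line_length = np.abs(dx).sum(axis=-1)
    s = np.sign(x)
    zcr = (s[..., :-1] * s[..., 1:] < 0).sum(axis=-1) / (n - 1)
    var_dx = dx.var(axis=-1)
    var_ddx = ddx.var(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.where(var > 0, np.sqrt(var_dx / np.where(var > 0, var, 1.0)), 0.0)
        mob_dx = np.where(var_dx > 0, np.sqrt(var_ddx / np.where(var_dx > 0, var_dx, 1.0)), 0.0)
        complexity = np.where(mobility > 0, mob_dx / np.where(mobility > 0, mobility, 1.0), 0.0)
    rms = np.sqrt(np.mean(x ** 2, axis=-1))
    q75, q25 = np.percentile(x, [75, 25], axis=-1)
    iqr = q75 - q25
    ptp = x.max(axis=-1) - x.min(axis=-1)
    tkeo = (x[..., 1:-1] ** 2 - x[..., :-2] * x[..., 2:]).mean(axis=-1)
    return {
        "mean": mean, "variance": var, "skew": skew, "kurtosis": kurt,
        "line_length": line_length, "zcr": zcr,
        "hjorth_activity": var, "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "rms": rms, "iqr": iqr, "ptp": ptp, "tkeo": tkeo,
    }


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """Time-domain descriptors of a single-channel window (|x| >= 3)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("x must be 1-D with at least 3 samples")
    vals = _batch_time_domain(x[None, :])
    return {k: float(v[0]) for k, v in vals.items()}


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------


def _welch_psd(x: np.ndarray, fs: float, cfg: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(cfg.welch_nperseg, x.shape[-1])
    noverlap = int(nperseg * cfg.welch_overlap)
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, axis=-1)
    return freqs, psd


def _batch_spectral(x: np.ndarray, fs: float, cfg: FeatureConfig) -> dict[str, np.ndarray]:
    freqs, psd = _welch_psd(x, fs, cfg)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    eps = 1e-300

    out: dict[str, np.ndarray] = {}
    band_abs: dict[str, np.ndarray] = {}
    for name in _BAND_ORDER:
        lo, hi = cfg.bands[name]
        mask = (freqs >= lo) & (freqs < hi)
        band_abs[name] = psd[..., mask].sum(axis=-1) * df
        out[f"abs_{name}"] = band_abs[name]
    total = sum(band_abs.values())
    nz = total > 0
    for name in _BAND_ORDER:
        rel = np.zeros_like(total)
        np.divide(band_abs[name], total, out=rel, where=nz)
        out[f"rel_{name}"] = rel

    def _ratio(num, den):
        r = np.zeros_like(total)
        np.divide(num, den + eps, out=r, where=den > 0)
        return r

    out["theta_alpha_ratio"] = _ratio(band_abs["theta"], band_abs["alpha"])
    out["beta_alpha_ratio"] = _ratio(band_abs["beta"], band_abs["alpha"])
    out["fast_slow_ratio"] = _ratio(band_abs["beta"] + band_abs["gamma"],
                                    band_abs["alpha"] + band_abs["theta"])

    lo, hi = cfg.total_range_hz
    mask = (freqs >= lo) & (freqs <= hi)
    p = psd[..., mask]
    ptot = p.sum(axis=-1, keepdims=True)
    ok = ptot[..., 0] > 0
    pn = np.divide(p, ptot, out=np.zeros_like(p), where=ptot > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(pn * np.log(pn, out=np.zeros_like(pn), where=pn > 0)).sum(axis=-1)
    n_bins = int(mask.sum())
    out["spectral_entropy"] = np.where(ok, ent / np.log(n_bins), 0.0)

    cum = np.cumsum(p, axis=-1)
    fband = freqs[mask]

    def _edge(q: float) -> np.ndarray:
        target = q * cum[..., -1:]
        idx = (cum >= target - 1e-300).argmax(axis=-1)
        return np.where(ok, fband[idx], 0.0)

    out["median_freq"] = _edge(0.5)
    out["sef95"] = _edge(0.95)

    slo, shi = cfg.slope_range_hz
    smask = (freqs >= slo) & (freqs <= shi)
    fs_log = np.log10(freqs[smask])
    ps = psd[..., smask]
    ps_ok = (ps > 0).all(axis=-1)
    logp = np.log10(np.where(ps > 0, ps, 1.0))
    fm = fs_log - fs_log.mean()
    denom = (fm ** 2).sum()
    slope = (logp * fm).sum(axis=-1) / denom
    out["one_over_f_slope"] = np.where(ps_ok, slope, 0.0)
    return out


def spectral_features(x: np.ndarray, cfg: FeatureConfig | None = None,
                      fs: float = 256.0) -> dict[str, float]:
    """Welch-based spectral descriptors of a single-channel window."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=np.float64)
    return {k: float(v[0]) for k, v in _batch_spectral(x[None, :], fs, cfg).items()}


# ---------------------------------------------------------------------------
# nonlinear
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sampen_counts(x: np.ndarray, r: float) -> tuple[int, int]:
    """Template match counts (B: length m=2, A: length 3), self-matches excluded."""
    n = x.shape[0]
    B = 0
    A = 0
    for i in range(n - 2):
        for j in range(i + 1, n - 2):
            d0 = abs(x[i] - x[j])
            if d0 >= r:
                continue
            d1 = abs(x[i + 1] - x[j + 1])
            if d1 >= r:
                continue
            B += 1
            if abs(x[i + 2] - x[j + 2]) < r:
                A += 1
    return A, B


def _sample_entropy(x: np.ndarray, r_factor: float) -> float:
    n = x.shape[0]
    sd = x.std()
    if sd == 0:
        return 0.0  # constant signal: perfectly regular
    r = r_factor * sd
    A, B = _sampen_counts(np.ascontiguousarray(x, dtype=np.float64), r)
    n_pairs = (n - 2) * (n - 3) // 2
    cap = np.log(max(n_pairs, 1))
    if B == 0 or A == 0:
        logger.warning("sample entropy: zero template matches, capped at log(pairs)")
        return float(cap)
    return float(min(-np.log(A / B), cap))


def _batch_permutation_entropy(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    """x: [rows, n] -> normalized permutation entropy per row."""
    rows, n = x.shape
    span = (order - 1) * delay
    windows = sliding_window_view(x, span + 1, axis=-1)[..., ::delay]
    codes = np.argsort(windows, axis=-1, kind="stable")
    weights = (np.ones(order, dtype=np.int64) * order) ** np.arange(order)
    flat = (codes * weights).sum(axis=-1)  # injective code per permutation
    n_codes = order ** order
    ent = np.empty(rows)
    n_win = flat.shape[-1]
    for i in range(rows):
        counts = np.bincount(flat[i], minlength=n_codes)
        p = counts[counts > 0] / n_win
        ent[i] = -(p * np.log(p)).sum()
    k = 1.0
    for i in range(2, order + 1):
        k *= i
    return ent / np.log(k)


def nonlinear_features(x: np.ndarray, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Sample entropy and permutation entropy of a single-channel window."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    return {
        "sampen": _sample_entropy(x, cfg.sampen_r_factor),
        "permen": float(
            _batch_permutation_entropy(x[None, :], cfg.permen_order, cfg.permen_delay)[0]
        ),
    }


# ---------------------------------------------------------------------------
# cross-channel summaries
# ---------------------------------------------------------------------------

_ELECTRODE_DIGITS = re.compile(r"(\d+)$")


def channel_side(label: str) -> str:
    """'left' / 'right' / 'midline' from the first electrode of a montage label."""
    first = label.split("-")[0].strip().upper()
    if first.endswith("Z"):
        return "midline"
    m = _ELECTRODE_DIGITS.search(first)
    if m is None:
        return "midline"
    return "left" if int(m.group(1)) % 2 == 1 else "right"


_ADJACENT_BANDS = [("delta", "theta"), ("theta", "alpha"),
                   ("alpha", "beta"), ("beta", "gamma")]


def cross_channel_features(per_channel: dict[str, dict[str, float | np.ndarray]],
                           channel_labels: list[str],
                           epsilon: float = 1e-12) -> dict[str, float | np.ndarray]:
    """Global summaries over per-channel feature maps (scalar or batched)."""
    if len(channel_labels) < 2:
        raise ValueError("need at least 2 channels")
    out: dict[str, float | np.ndarray] = {}
    out["global_max_rms"] = np.maximum.reduce(
        [np.asarray(per_channel[ch]["rms"]) for ch in channel_labels]
    )
    left = [ch for ch in channel_labels if channel_side(ch) == "left"]
    right = [ch for ch in channel_labels if channel_side(ch) == "right"]
    if left and right:
        for band in _BAND_ORDER:
            L = sum(np.asarray(per_channel[ch][f"abs_{band}"]) for ch in left)
            R = sum(np.asarray(per_channel[ch][f"abs_{band}"]) for ch in right)
            out[f"lateralization_{band}"] = (L - R) / (L + R + epsilon)
    else:
        logger.warning("no lateralizable channels; lateralization features omitted")
    for b1, b2 in _ADJACENT_BANDS:
        diffs = [
            np.abs(np.asarray(per_channel[ch][f"rel_{b1}"])
                   - np.asarray(per_channel[ch][f"rel_{b2}"]))
            for ch in channel_labels
        ]
        out[f"asym_{b1}_{b2}"] = sum(diffs) / len(diffs)
    return out


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """One row per segment; named columns ``{CHANNEL}__{feature}`` + globals."""

    X: pd.DataFrame
    labels: np.ndarray
    groups: np.ndarray          # subject per row
    sessions: np.ndarray
    start_times_s: np.ndarray
    overlap_frac: np.ndarray    # meta, not a model input by default
    window_s: float = 5.0

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        n = len(self.X)
        for name in ("labels", "groups", "sessions", "start_times_s", "overlap_frac"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != row count")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_segments(self) -> int:
        return len(self.X)

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(mask)
        return FeatureMatrix(
            X=self.X.iloc[idx].reset_index(drop=True) if idx.dtype != bool
            else self.X.loc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            groups=self.groups[idx],
            sessions=self.sessions[idx],
            start_times_s=self.start_times_s[idx],
            overlap_frac=self.overlap_frac[idx],
            window_s=self.window_s,
        )

    def select_features(self, names: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[names].copy(), labels=self.labels, groups=self.groups,
            sessions=self.sessions, start_times_s=self.start_times_s,
            overlap_frac=self.overlap_frac, window_s=self.window_s,
        )

    def save(self, path: str | Path) -> None:
        """Columnar table + sidecar JSON schema."""
        path = Path(path)
        table = self.X.copy()
        table["label"] = self.labels
        table["subject"] = self.groups
        table["session"] = self.sessions
        table["start_s"] = self.start_times_s
        table["overlap_frac"] = self.overlap_frac
        table.to_csv(path, index=False)
        schema = {
            "feature_names": self.feature_names,
            "meta_columns": ["label", "subject", "session", "start_s", "overlap_frac"],
            "window_s": self.window_s,
        }
        path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))


def _batch_sampen(rows: np.ndarray, r_factor: float) -> np.ndarray:
    out = np.empty(rows.shape[0])
    for i in range(rows.shape[0]):
        out[i] = _sample_entropy(rows[i], r_factor)
    return out


def build_feature_matrix(segs: SegmentSet, cfg: FeatureConfig | None = None,
                         chunk_size: int = 64) -> FeatureMatrix:
    """Compute the full named feature matrix for a SegmentSet."""
    cfg = cfg or FeatureConfig()
    if segs.n_segments == 0:
        raise ValueError("SegmentSet is empty")
    n_seg, n_ch, _ = segs.segments.shape
    labels = segs.channel_labels
    per_channel: dict[str, dict[str, np.ndarray]] = {
        ch: {} for ch in labels
    }
    feats_per_ch = {name: np.empty((n_seg, n_ch)) for name in PER_CHANNEL_FEATURES}

    for start in range(0, n_seg, chunk_size):
        stop = min(start + chunk_size, n_seg)
        block = segs.segments[start:stop]  # [b, ch, n]
        td = _batch_time_domain(block)
        spec = _batch_spectral(block, segs.fs_hz, cfg)
        for name, arr in {**td, **spec}.items():
            feats_per_ch[name][start:stop] = arr
        b, c, n = block.shape
        rows = block.reshape(b * c, n)
        feats_per_ch["permen"][start:stop] = _batch_permutation_entropy(
            rows, cfg.permen_order, cfg.permen_delay
        ).reshape(b, c)
        feats_per_ch["sampen"][start:stop] = _batch_sampen(
            rows, cfg.sampen_r_factor
        ).reshape(b, c)

    for ci, ch in enumerate(labels):
        for name in PER_CHANNEL_FEATURES:
            per_channel[ch][name] = feats_per_ch[name][:, ci]

    columns: dict[str, np.ndarray] = {}
    for ch in labels:
        for name in PER_CHANNEL_FEATURES:
            columns[f"{ch}__{name}"] = per_channel[ch][name]
    if n_ch >= 2:
        for name, arr in cross_channel_features(per_channel, labels).items():
            columns[name] = np.asarray(arr)
    if cfg.include_overlap_frac:
        columns["overlap_frac"] = segs.overlap_frac.copy()

    X = pd.DataFrame(columns)
    return FeatureMatrix(
        X=X,
        labels=np.asarray(segs.labels, dtype=np.int8),
        groups=np.asarray(segs.subject_ids),
        sessions=np.asarray(segs.session_ids),
        start_times_s=np.asarray(segs.start_times_s, dtype=np.float64),
        overlap_frac=np.asarray(segs.overlap_frac, dtype=np.float64),
        window_s=segs.window_s,
    )
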