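"""Feature-matrix cleaning, collinearity pruning, class balancing, PCA check.

All fitting statistics (medians, winsorization bounds, correlation-based
keep lists, undersampling indices) are computed on training rows only and
re-applied to held-out rows, so the LOSO harness can stay leakage-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CleanStats",
    "clean_matrix",
    "apply_clean",
    "collinearity_filter",
    "balance_classes",
    "pca_check",
]

Z_TRIGGER = 5.0           # |z| threshold that triggers winsorization
PCTL = (0.1, 99.9)        # two-sided clipping percentiles


@dataclass
class CleanStats:
    """Column statistics frozen on a training matrix."""

    columns: list[str]
    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def _fit_stats(X: pd.DataFrame) -> CleanStats:
    vals = X.to_numpy(dtype=np.float64)
    finite = np.isfinite(vals)
    med = np.zeros(vals.shape[1])
    lo = np.zeros(vals.shape[1])
    hi = np.zeros(vals.shape[1])
    mean = np.zeros(vals.shape[1])
    sd = np.zeros(vals.shape[1])
    for j in range(vals.shape[1]):
        col = vals[finite[:, j], j]
        if col.size == 0:
            logger.warning("column %s is all non-finite; zero-filled", X.columns[j])
            continue
        med[j] = np.median(col)
        lo[j], hi[j] = np.percentile(col, PCTL)
        mean[j] = col.mean()
        sd[j] = col.std()
    return CleanStats(list(X.columns), med, mean, sd, lo, hi)


def apply_clean(fm: FeatureMatrix, stats: CleanStats) -> FeatureMatrix:
    """Apply frozen cleaning statistics: impute, winsorize, cast, zero-fill.

    Columns expected by ``stats`` but missing from ``fm`` are zero-filled to
    keep dimensionality consistent across folds.
    """
    vals = np.zeros((fm.n_segments, len(stats.columns)), dtype=np.float64)
    present = {c: i for i, c in enumerate(fm.X.columns)}
    src = fm.X.to_numpy(dtype=np.float64)
    for j, col in enumerate(stats.columns):
        if col not in present:
            logger.warning("missing feature %s zero-filled", col)
            continue
        v = src[:, present[col]].copy()
        bad = ~np.isfinite(v)
        v[bad] = stats.median[j]
        if stats.sd[j] > 0:
            z_hi = stats.mean[j] + Z_TRIGGER * stats.sd[j]
            z_lo = stats.mean[j] - Z_TRIGGER * stats.sd[j]
            v[v > z_hi] = stats.hi[j]
            v[v < z_lo] = stats.lo[j]
        vals[:, j] = v
    X = pd.DataFrame(vals.astype(np.float32), columns=stats.columns)
    return FeatureMatrix(
        X=X, labels=fm.labels, groups=fm.groups, sessions=fm.sessions,
        start_times_s=fm.start_times_s, overlap_frac=fm.overlap_frac,
        window_s=fm.window_s,
    )


def clean_matrix(fm: FeatureMatrix) -> tuple[FeatureMatrix, CleanStats]:
    """Impute non-finite entries with column medians, winsorize |z|>5 values
    to the 0.1/99.9 percentiles, cast to single precision."""
    stats = _fit_stats(fm.X)
    return apply_clean(fm, stats), stats


def collinearity_filter(fm: FeatureMatrix, threshold: float = 0.95,
                        sample_cap: int = 20000, seed: int = 42,
                        ) -> tuple[FeatureMatrix, list[str]]:
    """Greedy Pearson |r| pruning: scan columns in canonical order and drop
    any column correlated at |r| >= threshold with an earlier kept column.

    Correlations are computed on at most ``sample_cap`` seeded random rows;
    zero-variance columns have undefined r (treated as 0) and are kept.
    """
    if fm.n_segments < 2:
        raise ValueError("need at least 2 rows")
    rng = np.random.default_rng(seed)
    n = fm.n_segments
    if n > sample_cap:
        rows = np.sort(rng.choice(n, size=sample_cap, replace=False))
        vals = fm.X.to_numpy(dtype=np.float64)[rows]
    else:
        vals = fm.X.to_numpy(dtype=np.float64)
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[:, sd == 0] = 0.0
    corr[sd == 0, :] = 0.0

    kept_idx: list[int] = []
    for j in range(vals.shape[1]):
        if all(abs(corr[j, k]) < threshold for k in kept_idx):
            kept_idx.append(j)
    kept = [fm.X.columns[j] for j in kept_idx]
    return fm.select_features(kept), kept


def balance_classes(labels: np.ndarray, max_ratio: float = 20.0,
                    seed: int = 42) -> np.ndarray:
    """Keep all positives; undersample negatives to <= max_ratio x positives.

    Returns sorted row indices.  Raises if there are no positives.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0:
        raise ValueError("no positive segments; fold unusable")
    cap = int(max_ratio * pos.size)
    if neg.size > cap:
        rng = np.random.default_rng(seed)
        neg = rng.choice(neg, size=cap, replace=False)
    return np.sort(np.concatenate([pos, neg]))


def pca_check(fm: FeatureMatrix, n_rows: int = 50000, seed: int = 42) -> np.ndarray:
    """Two leading explained-variance ratios on standardized features
    (diagnostic only, balanced subsample up to n_rows)."""
    rng = np.random.default_rng(seed)
    n = fm.n_segments
    idx = np.arange(n)
    if n > n_rows:
        idx = np.sort(rng.choice(n, size=n_rows, replace=False))
    X = fm.X.to_numpy(dtype=np.float64)[idx]
    X = StandardScaler().fit_transform(X)
    k = min(2, min(X.shape) - 1) if min(X.shape) > 1 else 1
    pca = PCA(n_components=k, random_state=seed)
    pca.fit(X)
    return pca.explained_variance_ratio_
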