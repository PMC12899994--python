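"""Statistical evaluation: FA-rate equivalence tests, bootstrap CIs, paired
nonparametric tests, calibration quality, and permutation nulls for ranking
consistency.

The one-sided FA/24h test checks H0: mean FA >= limit against the clinical
bound (default 0.5/day); with zero sample variance a textbook t statistic is
undefined, so the degenerate rule applies: p = 0 when the mean is below the
limit, 1 otherwise (this reproduces the all-zero-FA columns a pipeline with
strictly zero false alarms produces).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as spstats

__all__ = [
    "equivalence_fa_test",
    "bootstrap_ci",
    "paired_tests",
    "calibration_quality",
    "permutation_consistency_null",
]


def equivalence_fa_test(fa_values: np.ndarray, limit: float = 0.5
                        ) -> tuple[float, float]:
    """One-sided t-test of mean FA/24h below ``limit``; returns (t, p)."""
    fa = np.asarray(fa_values, dtype=np.float64)
    n = fa.size
    if n < 2:
        raise ValueError("need at least 2 folds")
    mean = fa.mean()
    s = fa.std(ddof=1)
    if s <= 1e-12 * max(1.0, abs(mean)):
        # degenerate: all folds identical
        return (-np.inf if mean < limit else np.inf,
                0.0 if mean < limit else 1.0)
    t = (mean - limit) / (s / np.sqrt(n))
    p = float(spstats.t.cdf(t, df=n - 1))
    return float(t), p


def bootstrap_ci(values: np.ndarray, B: int = 5000, level: float = 0.95,
                 seed: int = 42) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for the mean."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("need at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def paired_tests(a: np.ndarray, b: np.ndarray) -> dict[str, float | None]:
    """Two-sided Wilcoxon signed-rank (zero differences dropped, exact for
    small n) and Mann-Whitney U p-values."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("Wilcoxon requires equal-length pairs")
    out: dict[str, float | None] = {}
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        out["wilcoxon_stat"] = None
        out["wilcoxon_p"] = None
        out["wilcoxon_undefined"] = True
    else:
        method = "exact" if nz.size <= 25 and len(np.unique(np.abs(nz))) == nz.size \
            else "auto"
        res = spstats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                               method=method)
        out["wilcoxon_stat"] = float(res.statistic)
        out["wilcoxon_p"] = float(res.pvalue)
        out["wilcoxon_undefined"] = False
    mw = spstats.mannwhitneyu(a, b, alternative="two-sided")
    out["mannwhitney_stat"] = float(mw.statistic)
    out["mannwhitney_p"] = float(mw.pvalue)
    return out


def calibration_quality(probs: np.ndarray, labels: np.ndarray, bins: int = 10
                        ) -> tuple[float, float, list[tuple[float, float]]]:
    """(ECE, Brier, reliability curve) with equal-width decile bins.

    ECE = sum_b (n_b/N) |acc_b - conf_b| over non-empty bins; the curve is a
    list of (mean predicted probability, fraction positive) per bin.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(probs, edges[1:-1], right=False), 0, bins - 1)
    ece = 0.0
    curve: list[tuple[float, float]] = []
    n = probs.size
    for b in range(bins):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        conf = probs[mask].mean()
        acc = labels[mask].mean()
        ece += (nb / n) * abs(acc - conf)
        curve.append((float(conf), float(acc)))
    brier = float(np.mean((probs - labels) ** 2))
    return float(ece), brier, curve


def _mean_pairwise_jaccard(sets: list[set]) -> float:
    vals = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            u = len(sets[i] | sets[j])
            vals.append(len(sets[i] & sets[j]) / u if u else 0.0)
    return float(np.mean(vals))


def permutation_consistency_null(rankings: list[list[str]], n_perm: int = 1000,
                                 seed: int = 42,
                                 universe: list[str] | None = None
                                 ) -> tuple[float, float]:
    """Permutation test of cross-fold ranking agreement.

    Observed statistic: mean pairwise Jaccard over the given top-k sets.
    Null: feature identities are relabelled by a random permutation of the
    universe independently per ranking.  Returns (observed, p) with the
    add-one estimator p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings")
    if universe is None:
        universe = sorted({f for r in rankings for f in r})
    rng = np.random.default_rng(seed)
    observed = _mean_pairwise_jaccard([set(r) for r in rankings])
    uni = np.asarray(universe, dtype=object)
    count = 0
    for _ in range(n_perm):
        null_sets = []
        for r in rankings:
            perm = rng.permutation(len(uni))
            mapping = {uni[i]: uni[perm[i]] for i in range(len(uni))}
            null_sets.append({mapping[f] for f in r})
        if _mean_pairwise_jaccard(null_sets) >= observed - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, float(p)
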