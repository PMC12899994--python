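"""Attribution analyses: SHAP global importance, LIME-style local
surrogates, SHAP-LIME consistency, channel topography, feature ablation
and cross-fold stability tables.

Global importance of feature j is the mean absolute SHAP contribution
I_j = (1/N) sum_i |phi_ij|; attributions come from the exact tree-path
TreeSHAP engine in ``_treeshap``.  The LIME surrogate is self-contained:
seeded Gaussian perturbations around the sample, proximity-weighted ridge
regression on standardized coordinates, features ranked by |coefficient|.

Two overlap statistics are reported for SHAP-vs-LIME agreement: the
asymmetric consistency |S∩L|/|L| and the Jaccard index |S∩L|/|S∪L|; the
Jaccard index is the default headline statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from ._treeshap import TreeShapExplainer
from .features import FeatureMatrix
from .models import ModelSpec, run_loso

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionSet",
    "RankedFeatureSet",
    "shap_attributions",
    "shap_global",
    "lime_local",
    "explanation_consistency",
    "channel_topography",
    "feature_ablation",
    "stability_table",
]


@dataclass
class AttributionSet:
    """Per-sample, per-feature attribution values."""

    method: str                      # "shap" or "lime"
    values: np.ndarray               # [n_samples, n_features]
    feature_names: list[str]
    base_value: float | None = None  # shap only

    def global_importance(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


@dataclass
class RankedFeatureSet:
    """Feature names ordered by non-increasing score."""

    names: list[str]
    scores: np.ndarray
    signed_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.names[:k]

    @property
    def k(self) -> int:
        return len(self.names)


def _rank(names: list[str], scores: np.ndarray,
          signed: np.ndarray | None = None) -> RankedFeatureSet:
    order = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
    return RankedFeatureSet(
        names=[names[j] for j in order],
        scores=scores[order],
        signed_scores=None if signed is None else signed[order],
    )


def shap_attributions(model, X, feature_names: list[str] | None = None
                      ) -> AttributionSet:
    """Exact TreeSHAP values for every row of X (DataFrame or array)."""
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=np.float64)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    explainer = TreeShapExplainer(model)
    phi = explainer.shap_values(X)
    return AttributionSet("shap", phi, list(feature_names),
                          base_value=float(explainer.base_value))


def shap_global(model, X, feature_names: list[str] | None = None
                ) -> RankedFeatureSet:
    """Mean-|SHAP| global ranking (ties broken by feature name)."""
    att = shap_attributions(model, X, feature_names)
    return _rank(att.feature_names, att.global_importance())


def lime_local(model, x: np.ndarray, background_mean: np.ndarray,
               background_sd: np.ndarray, n_perturb: int = 1000,
               kernel_width: float | None = None, k: int = 10,
               seed: int = 0, feature_names: list[str] | None = None
               ) -> RankedFeatureSet:
    """Local linear surrogate around one sample.

    Gaussian perturbations (SD = training-fold feature SD; zero-variance
    features are not perturbed) are scored by the model, weighted by an RBF
    proximity kernel on standardized distance, and fit with a ridge
    surrogate; the top-k features by |weight| are returned.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float64).ravel()
    sd = np.asarray(background_sd, dtype=np.float64).copy()
    p = x.size
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    perturbable = sd > 0
    noise = np.zeros((n_perturb, p))
    noise[:, perturbable] = rng.standard_normal((n_perturb, perturbable.sum()))
    Xp = x[None, :] + noise * np.where(perturbable, sd, 0.0)
    Xp[0] = x  # include the sample itself
    probs = model.predict_proba(Xp)[:, 1]

    Z = np.zeros_like(Xp)
    Z[:, perturbable] = (Xp[:, perturbable] - x[perturbable]) / sd[perturbable]
    dist = np.linalg.norm(Z, axis=1)
    kw = kernel_width if kernel_width is not None else 0.75 * np.sqrt(p)
    weights = np.exp(-(dist ** 2) / kw ** 2)

    ridge = Ridge(alpha=1.0)
    ridge.fit(Z, probs, sample_weight=weights)
    coef = ridge.coef_
    ranked = _rank(feature_names, np.abs(coef), signed=coef)
    return RankedFeatureSet(
        names=ranked.names[:k], scores=ranked.scores[:k],
        signed_scores=ranked.signed_scores[:k],
    )


def explanation_consistency(f_shap: RankedFeatureSet | list[str],
                            f_lime: RankedFeatureSet | list[str],
                            ) -> tuple[float, float]:
    """(asymmetric consistency |S∩L|/|L|, Jaccard |S∩L|/|S∪L|)."""
    S = set(f_shap.names if isinstance(f_shap, RankedFeatureSet) else f_shap)
    L = set(f_lime.names if isinstance(f_lime, RankedFeatureSet) else f_lime)
    if not S or not L:
        raise ValueError("both feature sets must be non-empty")
    inter = len(S & L)
    return inter / len(L), inter / len(S | L)


def channel_topography(ranked: RankedFeatureSet,
                       channel_labels: list[str]) -> dict[str, float]:
    """Per-channel summed importance, min-max normalized to [0, 1].

    Only names of the form ``{CHANNEL}__{feature}`` contribute; a constant
    score vector normalizes to all ones (degenerate case).
    """
    totals = {ch: 0.0 for ch in channel_labels}
    for name, score in zip(ranked.names, ranked.scores):
        if "__" not in name:
            continue
        ch = name.split("__", 1)[0]
        if ch in totals:
            totals[ch] += float(score)
    vals = np.array([totals[ch] for ch in channel_labels])
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-15:
        return {ch: 1.0 for ch in channel_labels}
    return {ch: float((v - lo) / (hi - lo)) for ch, v in zip(channel_labels, vals)}


def feature_ablation(fm: FeatureMatrix, rankings: dict[str, list[str]],
                     ks: tuple[int, ...] = (5, 10, 15, 20, 25, 30),
                     specs: list[ModelSpec] | None = None, seed: int = 42,
                     **loso_kwargs) -> pd.DataFrame:
    """Re-run LOSO restricted to top-k features per ranking; collect AUC.

    Returns a table with one row per (ranking, k, model, held-out subject).
    Requesting k beyond the ranking length caps k with a warning.
    """
    specs = specs or [ModelSpec.default("xgboost", seed=seed)]
    rows = []
    for rank_name, ordered in rankings.items():
        available = [f for f in ordered if f in fm.X.columns]
        for k in ks:
            kk = min(k, len(available))
            if kk < k:
                warnings.warn(f"ranking {rank_name}: k={k} capped to {kk}")
            sub = fm.select_features(available[:kk])
            folds = run_loso(sub, specs, seed=seed, **loso_kwargs)
            for model_name, frs in folds.items():
                for fr in frs:
                    rows.append({
                        "ranking": rank_name, "k": k, "model": model_name,
                        "subject": fr.held_out_subject,
                        "auc": fr.segment_metrics["auc"],
                    })
    return pd.DataFrame(rows)


def stability_table(per_fold_rankings: dict[tuple[str, str], RankedFeatureSet],
                    k: int = 20) -> pd.DataFrame:
    """Selection counts of top-k features across (fold, model) rankings.

    ``per_fold_rankings`` maps (held-out subject, model name) to a ranking.
    ``count`` is the number of (fold, model) combinations where the feature
    enters the top-k; ``coverage_pct`` the percentage of subjects in whose
    fold it appears (any model).
    """
    if len({subj for subj, _ in per_fold_rankings}) < 2:
        raise ValueError("need rankings from at least 2 folds")
    counts: dict[str, int] = {}
    subj_cover: dict[str, set[str]] = {}
    subjects = sorted({subj for subj, _ in per_fold_rankings})
    for (subj, _model), ranked in per_fold_rankings.items():
        for name in ranked.top(k):
            counts[name] = counts.get(name, 0) + 1
            subj_cover.setdefault(name, set()).add(subj)
    rows = [
        {
            "feature": name,
            "count": counts[name],
            "coverage_pct": 100.0 * len(subj_cover[name]) / len(subjects),
        }
        for name in counts
    ]
    df = pd.DataFrame(rows).sort_values(
        ["count", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    return df
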