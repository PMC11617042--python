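"""Differential-abundance screening and covariate-adjusted association.

Two complementary screens mirror common practice in murine microbiome
studies:

* an effect-size screen in the LEfSe spirit — a rank test gates each
  feature, and passing features get a log10-scale score computed from the
  between-group difference of mean relative abundance (counts per
  million); features whose score strictly exceeds a threshold (1.5 by
  default) are flagged as differential;
* a MaAsLin2-style covariate-adjusted linear model — per-feature OLS of
  log relative abundance on the group indicator plus one numeric
  covariate (e.g. body weight), with a two-sided t test on the group
  coefficient and Benjamini-Hochberg adjustment across features.

The effect-size screen is deterministic by default; an optional
bootstrapped one-dimensional LDA mode averages the score over seeded
resamples for closer fidelity to the bootstrapped-LDA heritage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tabio import AbundanceTable, StudyMetadata, align

__all__ = [
    "mann_whitney",
    "effect_score",
    "covariate_adjusted_association",
    "bh_adjust",
    "differential_features",
    "DifferentialResult",
]

EXACT_MW_POOLED_N = 10  # exact enumeration below this pooled size (tie-free)


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration over rank splits when the pooled sample size is at
    most 10 and there are no ties; tie-corrected normal approximation
    (without continuity correction) otherwise.  Returns (U of the first
    sample, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # all values tied: zero-variance normal approximation
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= EXACT_MW_POOLED_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialResult:
    """Per-feature screening table.

    ``table`` columns: feature, direction (enriched group), p, q, score,
    flagged, coef, coef_p, coef_q.  ``flagged`` marks features passing
    both the rank-test gate (p < alpha) and the score threshold.
    """

    table: pd.DataFrame
    alpha: float
    threshold: float
    groups: tuple[str, str]

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "feature"].tolist()


def _group_matrices(table: AbundanceTable, metadata: StudyMetadata):
    table, metadata = align(table, metadata)
    level_a, level_b = metadata.group_levels
    cpm = table.relative_abundance(scale=1e6)
    in_a = np.array([str(metadata.group[s]) == level_a for s in table.sample_ids])
    return table, metadata, cpm, in_a, (level_a, level_b)


def effect_score(
    table: AbundanceTable,
    metadata: StudyMetadata,
    alpha: float = 0.05,
    threshold: float = 1.5,
    n_bootstrap: int = 0,
    subsample_fraction: float = 2 / 3,
    seed: int | None = None,
) -> DifferentialResult:
    """Rank-gated log10 effect-size screen on the CPM scale.

    For each feature, a two-sided Mann-Whitney test compares the two
    groups; features with p < ``alpha`` receive
    score = log10(|mean_A - mean_B| + 1) on CPM means, with the
    direction of enrichment.  With ``n_bootstrap`` > 0 the score is the
    mean over seeded subsample replicates (one-dimensional LDA on a
    single feature reduces to the difference of group means).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    table, metadata, cpm, in_a, (level_a, level_b) = _group_matrices(table, metadata)
    rng = np.random.default_rng(seed)
    rows = []
    for i, feat in enumerate(table.feature_ids):
        va, vb = cpm[i, in_a], cpm[i, ~in_a]
        _, p = mann_whitney(va, vb)
        if n_bootstrap > 0:
            diffs = []
            for _ in range(n_bootstrap):
                sa = rng.choice(va, size=max(2, int(np.ceil(va.size * subsample_fraction))), replace=False)
                sb = rng.choice(vb, size=max(2, int(np.ceil(vb.size * subsample_fraction))), replace=False)
                diffs.append(abs(sa.mean() - sb.mean()))
            effect = float(np.mean(diffs))
        else:
            effect = abs(float(va.mean() - vb.mean()))
        score = float(np.log10(effect + 1.0))
        direction = level_a if va.mean() > vb.mean() else level_b
        rows.append({"feature": feat, "direction": direction, "p": p, "score": score})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["flagged"] = (df["p"] < alpha) & (df["score"] > threshold)
    return DifferentialResult(df, alpha, threshold, (level_a, level_b))


def covariate_adjusted_association(
    table: AbundanceTable,
    metadata: StudyMetadata,
    covariate: str | None = None,
) -> pd.DataFrame:
    """Per-feature OLS of log relative abundance on group + covariate.

    Relative abundance (TSS) is log-transformed after adding a
    per-feature pseudocount equal to half the feature's smallest nonzero
    relative abundance.  Returns a frame with feature, coef (group
    effect, second level vs first), coef_p, coef_q.
    """
    table, metadata, cpm, in_a, (level_a, level_b) = _group_matrices(table, metadata)
    rel = cpm / 1e6
    n = table.n_samples
    group_ind = (~in_a).astype(float)  # 1 = second level
    cols = [np.ones(n), group_ind]
    if covariate is not None:
        if covariate not in metadata.covariates.columns:
            raise KeyError(f"covariate {covariate!r} not in metadata")
        cov = metadata.covariates[covariate].to_numpy(dtype=float)
        if np.ptp(cov) == 0:
            warnings.warn(f"covariate {covariate!r} is constant; dropped from the model")
        else:
            cols.append(cov)
    X = np.column_stack(cols)
    dof = n - X.shape[1]
    if dof < 1:
        raise ValueError("not enough samples for the linear model")
    xtx_inv = np.linalg.inv(X.T @ X)
    rows = []
    for i, feat in enumerate(table.feature_ids):
        x = rel[i]
        nonzero = x[x > 0]
        if nonzero.size == 0 or np.ptp(x) == 0:
            rows.append({"feature": feat, "coef": 0.0, "coef_p": 1.0})
            continue
        y = np.log(x + nonzero.min() / 2.0)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(max(sigma2, 0.0) * xtx_inv[1, 1])
        if se == 0:
            p = 0.0 if beta[1] != 0 else 1.0
        else:
            t = beta[1] / se
            p = float(2 * stats.t.sf(abs(t), dof))
        rows.append({"feature": feat, "coef": float(beta[1]), "coef_p": p})
    df = pd.DataFrame(rows)
    df["coef_q"] = bh_adjust(df["coef_p"].to_numpy())
    return df


def differential_features(
    table: AbundanceTable,
    metadata: StudyMetadata,
    alpha: float = 0.05,
    threshold: float = 1.5,
    covariate: str | None = None,
    seed: int | None = None,
) -> DifferentialResult:
    """Full screen: effect-size scoring joined with the covariate-adjusted model."""
    res = effect_score(table, metadata, alpha=alpha, threshold=threshold, seed=seed)
    assoc = covariate_adjusted_association(table, metadata, covariate=covariate)
    res.table = res.table.merge(assoc, on="feature", how="left")
    return res
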