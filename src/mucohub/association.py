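"""Rank correlation of taxa with host phenotypes or pathway abundances.

Spearman's rho with mid-ranks for ties; p-values from the
t-distribution approximation (exact permutation enumeration available
for very small n).  Taxa enter as relative abundance (CPM) — Spearman is
rank-based, so any monotone per-sample normalization yields the same
rho.  Benjamini-Hochberg adjustment runs across all cells of an
association table.
"""

from __future__ import annotations

from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .tabio import AbundanceTable, StudyMetadata, align

__all__ = ["spearman", "associate"]

EXACT_SPEARMAN_MAX_N = 8


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks; p comes from
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df, with p = 0 by convention
    at rho = +/-1.  A constant input yields (0.0, 1.0).  With
    ``exact=True`` and n <= 8, p is the exact permutation tail
    probability of |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 4:
        raise ValueError("need equal-length vectors with at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > EXACT_SPEARMAN_MAX_N:
            raise ValueError(f"exact permutation p limited to n <= {EXACT_SPEARMAN_MAX_N}")
        count = total = 0
        for perm in _permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0 - 1e-12:  # perfect monotone agreement up to float error
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def associate(
    table: AbundanceTable,
    metadata_or_variables,
    taxa_subset: list[str] | None = None,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """All-pairs Spearman between taxa and phenotype/pathway variables.

    ``metadata_or_variables`` is either StudyMetadata (phenotype columns)
    or a second AbundanceTable (e.g. pathway abundances).  Returns a
    long-format frame (taxon, variable, rho, p, q, significant) with BH
    adjustment across every cell; ``significant`` is raw p < 0.05.
    """
    if isinstance(metadata_or_variables, StudyMetadata):
        table, metadata = align(table, metadata_or_variables)
        var_df = metadata.phenotypes
    elif isinstance(metadata_or_variables, AbundanceTable):
        other = metadata_or_variables.subset_samples(list(table.sample_ids))
        var_df = pd.DataFrame(
            other.relative_abundance().T, index=other.sample_ids, columns=other.feature_ids
        )
    else:
        var_df = pd.DataFrame(metadata_or_variables).loc[list(table.sample_ids)]
    if taxa_subset is None:
        taxa_subset = list(table.feature_ids)
    if variables is None:
        variables = list(var_df.columns)
    unknown_taxa = [t for t in taxa_subset if t not in set(table.feature_ids)]
    if unknown_taxa:
        raise KeyError(f"unknown taxa: {unknown_taxa}")
    unknown_vars = [v for v in variables if v not in set(var_df.columns)]
    if unknown_vars:
        raise KeyError(f"unknown variables: {unknown_vars}")
    cpm = table.relative_abundance()
    feat_index = {f: i for i, f in enumerate(table.feature_ids)}
    rows = []
    for taxon in taxa_subset:
        abund = cpm[feat_index[taxon]]
        for var in variables:
            rho, p = spearman(abund, var_df[var].to_numpy(dtype=float))
            rows.append({"taxon": taxon, "variable": var, "rho": rho, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p"] < 0.05
    return df
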