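"""Correlations, genotype x index biplot decomposition, and selection-set
comparison.

The biplot layer is the standard GGE-style construction: column-standardize
the genotype x index matrix, take its SVD, report per-axis variance shares
and symmetrically scaled genotype/index coordinates.  Selection sets are
compared by exhaustive Venn-region counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correlate",
    "BiplotDecomposition",
    "index_biplot",
    "SelectionComparison",
    "compare_selections",
]


def correlate(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided t-based p-values.

    Returns (r, p) DataFrames.  Constant columns have undefined correlations;
    their entries are masked with NaN and a warning is issued.
    """
    if len(table) < 3:
        raise ValueError("correlation requires at least 3 genotypes")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns masked: {constant}")
    r = table.corr(method="pearson")
    n = len(table)
    rv = r.to_numpy(copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    pm = pd.DataFrame(p, index=r.index, columns=r.columns)
    np.fill_diagonal(pm.values, 0.0)
    for c in constant:
        r.loc[c, :] = r.loc[:, c] = np.nan
        pm.loc[c, :] = pm.loc[:, c] = np.nan
    return r, pm


@dataclass
class BiplotDecomposition:
    axis_variance_pct: np.ndarray     # per axis, sums to 100
    genotype_coords: pd.DataFrame     # axes 1-2, symmetric scaling
    index_coords: pd.DataFrame
    singular_values: np.ndarray


def index_biplot(dti: pd.DataFrame) -> BiplotDecomposition:
    """SVD of the column-standardized genotype x index matrix.

    Axis variance share = squared singular value over the total; genotype and
    index coordinates use the symmetric partition of the singular values
    (both sides scaled by sqrt(singular value)).  Rank-deficient matrices
    simply carry zero trailing variance.
    """
    if dti.shape[0] < 3 or dti.shape[1] < 3:
        raise ValueError("biplot requires >= 3 genotypes and >= 3 indices")
    sd = dti.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant index column: cannot standardize")
    z = (dti - dti.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    total = float(np.sum(s ** 2))
    var_pct = 100.0 * s ** 2 / total if total > 0 else np.zeros_like(s)
    k = min(2, len(s))
    scale = np.sqrt(s[:k])
    axes = [f"axis{i + 1}" for i in range(k)]
    geno = pd.DataFrame(u[:, :k] * scale, index=dti.index, columns=axes)
    idx = pd.DataFrame(vt[:k].T * scale, index=dti.columns, columns=axes)
    return BiplotDecomposition(axis_variance_pct=var_pct,
                               genotype_coords=geno, index_coords=idx,
                               singular_values=s)


@dataclass
class SelectionComparison:
    regions: dict[frozenset, int]     # exact-membership Venn region counts
    consensus: list
    union_size: int

    def region(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)


def compare_selections(sets: dict[str, list | set]) -> SelectionComparison:
    """Venn-region counts and the consensus of named selection sets.

    For k sets, every one of the 2^k - 1 exact-membership regions is counted
    (an item is in the region of exactly the sets that contain it); the
    counts sum to the size of the union, and the consensus is the
    intersection of all sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 selection sets")
    names = list(sets)
    as_sets = {k: set(v) for k, v in sets.items()}
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = 0
    universe = set().union(*as_sets.values())
    for item in universe:
        members = frozenset(k for k in names if item in as_sets[k])
        regions[members] += 1
    consensus = sorted(set.intersection(*as_sets.values()))
    return SelectionComparison(regions=regions, consensus=consensus,
                               union_size=len(universe))
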