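"""Drought-tolerance indices and rank-sum screening.

From per-genotype mean yields under stress (Ys) and non-stress (Yp):

    SI  = 1 - ybar_s / ybar_p          (trial-level stress intensity)
    STI = Ys * Yp / ybar_p**2          GMP = sqrt(Ys * Yp)
    MP  = (Ys + Yp) / 2                HM  = 2 * Ys * Yp / (Ys + Yp)
    TOL = Yp - Ys                      SSI = (1 - Ys/Yp) / SI
    YSI = Ys / Yp                      YI  = Ys / ybar_s

STI, GMP, MP and HM reward joint performance; TOL and SSI measure the yield
penalty of stress (large = susceptible); YSI and YI measure relative stress
performance.  Genotypes are ranked on Ys, Yp and the eight indices (rank 1 =
most drought-tolerant, so TOL and SSI rank ascending while all others rank
descending), and screened by the rank sum RS = R + SDR where R is the mean
rank and SDR the sample standard deviation of ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StressContext",
    "compute_indices",
    "rank_indices",
    "rank_sum",
    "select_by_rank_sum",
    "round_half_up",
    "INDEX_COLUMNS",
    "ASCENDING_INDICES",
]

#: rank-matrix column order (as conventionally tabulated)
INDEX_COLUMNS = ("Ys", "Yp", "STI", "GMP", "MP", "TOL", "HM", "YSI", "YI", "SSI")

#: indices where a *small* value marks the tolerant genotype
ASCENDING_INDICES = frozenset({"TOL", "SSI"})


@dataclass
class StressContext:
    ybar_s: float
    ybar_p: float

    @property
    def si(self) -> float:
        """Stress intensity, 1 - ybar_s/ybar_p."""
        return 1.0 - self.ybar_s / self.ybar_p


def compute_indices(ys: pd.Series, yp: pd.Series,
                    context: StressContext | None = None
                    ) -> tuple[pd.DataFrame, StressContext]:
    """Eight drought-tolerance indices from stress / non-stress yields.

    ``ys`` and ``yp`` are indexed by genotype; trial means default to the
    means of the supplied genotypes but can be overridden via ``context``
    (e.g. when screening a subset).  Non-positive yields are excluded with a
    warning; zero stress intensity leaves SSI undefined and raises.
    """
    ys, yp = ys.align(yp, join="inner")
    if len(ys) == 0:
        raise ValueError("no common genotypes between regimes")
    bad = (ys <= 0) | (yp <= 0) | ys.isna() | yp.isna()
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} genotypes with non-positive "
                      "or missing yields")
        ys, yp = ys[~bad], yp[~bad]
    if context is None:
        context = StressContext(ybar_s=float(ys.mean()), ybar_p=float(yp.mean()))
    if context.ybar_p <= 0 or context.ybar_s <= 0:
        raise ValueError("trial mean yields must be positive")
    si = context.si
    if si == 0.0:
        raise ValueError("stress intensity is zero: SSI undefined")

    tab = pd.DataFrame({
        "Ys": ys,
        "Yp": yp,
        "STI": ys * yp / context.ybar_p ** 2,
        "GMP": np.sqrt(ys * yp),
        "MP": (ys + yp) / 2.0,
        "HM": 2.0 * ys * yp / (ys + yp),
        "TOL": yp - ys,
        "SSI": (1.0 - ys / yp) / si,
        "YSI": ys / yp,
        "YI": ys / context.ybar_s,
    })
    tab.index.name = "genotype"
    return tab[list(INDEX_COLUMNS)], context


def rank_indices(dti: pd.DataFrame) -> pd.DataFrame:
    """Per-index tolerance ranks (1 = most tolerant), average ranks for ties.

    Yield and yield-combining indices rank descending (largest value = rank
    1); TOL and SSI rank ascending, since a small yield penalty marks the
    tolerant genotype.
    """
    if len(dti) < 2:
        raise ValueError("ranking requires at least 2 genotypes")
    ranks = {}
    for col in dti.columns:
        vals = dti[col]
        if vals.nunique() == 1:
            warnings.warn(f"index {col!r} is constant; all ranks tied")
        ranks[col] = vals.rank(ascending=col in ASCENDING_INDICES,
                               method="average")
    return pd.DataFrame(ranks, index=dti.index)


def rank_sum(ranks: pd.DataFrame) -> pd.DataFrame:
    """Rank mean R, rank standard deviation SDR (n-1) and RS = R + SDR."""
    if ranks.shape[1] < 2:
        raise ValueError("rank sum requires at least 2 indices")
    if ranks.isna().any().any():
        raise ValueError("rank matrix must be complete")
    out = pd.DataFrame({
        "R": ranks.mean(axis=1),
        "SDR": ranks.std(axis=1, ddof=1),
    })
    out["RS"] = out["R"] + out["SDR"]
    return out


def round_half_up(x: float) -> int:
    """round(0.5) -> 1: the documented selection-size rounding rule."""
    return int(np.floor(x + 0.5))


def select_by_rank_sum(summary: pd.DataFrame, intensity: float = 0.20
                       ) -> list[str]:
    """The round(g * intensity) genotypes with smallest RS.

    Ties are broken by smaller rank mean R, then by genotype label.
    """
    if not (0.0 < intensity <= 1.0):
        raise ValueError("selection intensity must be in (0, 1]")
    k = round_half_up(len(summary) * intensity)
    if k == 0:
        raise ValueError("selection intensity yields an empty selection")
    ordered = summary.reset_index().sort_values(
        ["RS", "R", summary.index.name or "index"]
    )
    return ordered.iloc[:k, 0].tolist()
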