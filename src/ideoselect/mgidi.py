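"""Multi-trait genotype-ideotype distance index (MGIDI).

The pipeline is: (1) linearly rescale each trait over genotypes to [0, 100]
so that 100 is always the desirable end (sense "increase" maps the column
maximum to 100, sense "decrease" maps the minimum to 100); the ideotype is
the all-100 row.  (2) Exploratory factor analysis on the correlation matrix
of the rescaled table: eigendecomposition, retain factors with eigenvalue
> 1, loadings = eigenvectors scaled by sqrt(eigenvalue), varimax rotation.
(3) Factor scores F = Z R^-1 A for the standardized genotypes and for the
ideotype (standardized with the genotype column statistics).  (4) MGIDI is
the Euclidean distance of each genotype's scores to the ideotype scores;
genotypes with the smallest distance are selected.  Per-factor squared
distances give the contribution shares w_ij = D2_ij / sum_j D2_ij, whose
smallest entries mark a genotype's strengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorModel",
    "MGIDIResult",
    "rescale",
    "factor_analysis",
    "varimax",
    "mgidi_distance",
    "select_by_mgidi",
    "selection_gains",
    "contributions",
    "run_mgidi",
    "DEFAULT_SENSES",
]

#: desirable direction per trait for the soybean screen: earliness and low
#: lodging are wanted, everything else should increase
DEFAULT_SENSES = {"D50F": "decrease", "D95M": "decrease", "LS": "decrease"}


def rescale(blues: pd.DataFrame, senses: dict[str, str] | None = None
            ) -> pd.DataFrame:
    """Rescale each trait linearly to [0, 100] with 100 = desirable.

    ``senses`` maps trait name to "increase" or "decrease"; unlisted traits
    default to "increase".  Constant columns are undefined under the rescale
    and raise.
    """
    senses = senses or {}
    out = {}
    for col in blues.columns:
        theta = blues[col].astype(float)
        lo, hi = float(theta.min()), float(theta.max())
        if hi == lo:
            raise ValueError(f"trait {col!r} is constant: rescale undefined")
        sense = senses.get(col, "increase")
        if sense not in ("increase", "decrease"):
            raise ValueError(f"unknown sense {sense!r} for trait {col!r}")
        if sense == "increase":
            out[col] = 100.0 * (theta - lo) / (hi - lo)
        else:
            out[col] = 100.0 * (hi - theta) / (hi - lo)
    return pd.DataFrame(out, index=blues.index)


def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
            ) -> np.ndarray:
    """Varimax rotation (orthogonal, unnormalized) of a loading matrix."""
    p, f = loadings.shape
    if f < 2:
        return loadings.copy()
    rot = np.eye(f)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam ** 3 - lam @ np.diag((lam ** 2).sum(axis=0)) / p))
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return loadings @ rot


@dataclass
class FactorModel:
    corr: pd.DataFrame              # p x p trait correlation matrix
    eigenvalues: np.ndarray
    loadings: pd.DataFrame          # p x f, varimax-rotated
    communality: pd.Series
    uniqueness: pd.Series
    z: pd.DataFrame                 # g x p standardized rescaled means
    scores: pd.DataFrame            # g x f genotype factor scores
    ideotype_scores: pd.Series      # f scores of the all-100 ideotype

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def factor_analysis(rx: pd.DataFrame, ridge: float = 1e-8) -> FactorModel:
    """Exploratory factor analysis of the rescaled genotype x trait table.

    Factors come from the eigendecomposition of the trait correlation matrix;
    those with eigenvalue > 1 are retained (at least one is always kept).
    Scores follow F = Z R^-1 A with A the rotated loadings, computed for the
    genotypes and for the all-100 ideotype standardized by the genotype
    column means and standard deviations.  A 1e-8 ridge stabilizes R^-1 when
    the correlation matrix is near-singular.
    """
    g, p = rx.shape
    mu = rx.mean(axis=0)
    sd = rx.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant trait column: factor analysis undefined")
    z = (rx - mu) / sd
    corr = z.corr()
    evals, evecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    f = int(np.sum(evals > 1.0))
    if f == 0:
        warnings.warn("no eigenvalue exceeds 1; retaining a single factor")
        f = 1
    raw = evecs[:, :f] * np.sqrt(np.clip(evals[:f], 0.0, None))
    rot = varimax(raw)
    # orient each factor so its largest-magnitude loading is positive
    for j in range(rot.shape[1]):
        if rot[np.argmax(np.abs(rot[:, j])), j] < 0:
            rot[:, j] = -rot[:, j]
    loadings = pd.DataFrame(rot, index=rx.columns,
                            columns=[f"FA{j + 1}" for j in range(f)])
    communality = (loadings ** 2).sum(axis=1)
    uniqueness = 1.0 - communality

    rmat = corr.to_numpy()
    if np.linalg.cond(rmat) > 1e8:  # near-singular: regularize the inverse
        rmat = rmat + ridge * np.eye(p)
    r_inv = np.linalg.inv(rmat)
    weight = r_inv @ rot                       # p x f score coefficients
    scores = pd.DataFrame(z.to_numpy() @ weight, index=rx.index,
                          columns=loadings.columns)
    z_ideo = (100.0 - mu) / sd
    ideo = pd.Series(z_ideo.to_numpy() @ weight, index=loadings.columns)
    return FactorModel(corr=corr, eigenvalues=evals, loadings=loadings,
                       communality=communality, uniqueness=uniqueness,
                       z=z, scores=scores, ideotype_scores=ideo)


@dataclass
class MGIDIResult:
    model: FactorModel
    distance: pd.Series             # MGIDI per genotype
    d2_by_factor: pd.DataFrame      # g x f squared per-factor distances

    def ranking(self) -> pd.Series:
        return self.distance.rank(method="first")


def mgidi_distance(model: FactorModel) -> MGIDIResult:
    """Euclidean distance of genotype factor scores to the ideotype scores."""
    diff = model.scores - model.ideotype_scores
    d2 = diff ** 2
    dist = np.sqrt(d2.sum(axis=1))
    dist.name = "MGIDI"
    return MGIDIResult(model=model, distance=dist, d2_by_factor=d2)


def select_by_mgidi(result: MGIDIResult, intensity: float = 0.20) -> list[str]:
    """round(g * intensity) genotypes nearest the ideotype, label tie-break."""
    if not (0.0 < intensity <= 1.0):
        raise ValueError("selection intensity must be in (0, 1]")
    from .drought_indices import round_half_up
    k = round_half_up(len(result.distance) * intensity)
    if k == 0:
        raise ValueError("selection intensity yields an empty selection")
    ordered = result.distance.reset_index()
    ordered.columns = ["genotype", "MGIDI"]
    ordered = ordered.sort_values(["MGIDI", "genotype"])
    return ordered["genotype"].iloc[:k].tolist()


def selection_gains(blues: pd.DataFrame, selected: list[str],
                    senses: dict[str, str] | None = None,
                    h2: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-trait selection differential of the selected subset, percent.

    SD% = 100 * (mean_selected - mean_all) / mean_all.  A gain is flagged
    desirable when its sign matches the trait's sense.  If entry-mean
    heritabilities are supplied, the heritability-weighted predicted gain
    SD% * H2 is reported alongside.
    """
    if len(selected) == 0:
        raise ValueError("selection is empty")
    senses = senses or {}
    mean_all = blues.mean(axis=0)
    if (mean_all == 0).any():
        raise ValueError("zero overall trait mean: SD% undefined")
    mean_sel = blues.loc[selected].mean(axis=0)
    sd_pct = 100.0 * (mean_sel - mean_all) / mean_all
    sense = pd.Series({t: senses.get(t, "increase") for t in blues.columns})
    desirable = (sd_pct >= 0) == (sense == "increase")
    out = pd.DataFrame({
        "mean_all": mean_all, "mean_selected": mean_sel,
        "SD_pct": sd_pct, "sense": sense, "desirable": desirable,
    })
    if h2 is not None:
        out["SDxH2_pct"] = sd_pct * pd.Series(h2).reindex(blues.columns)
    out.index.name = "trait"
    return out


def contributions(result: MGIDIResult) -> pd.DataFrame:
    """Share of each factor in a genotype's MGIDI: w_ij = D2_ij / sum D2_ij.

    Rows sum to one.  Small shares are strengths (the genotype is close to
    the ideotype on that factor).  A genotype exactly at the ideotype has no
    defined shares; it gets a uniform row and a warning.
    """
    tot = result.d2_by_factor.sum(axis=1)
    omega = result.d2_by_factor.div(tot, axis=0)
    zero = tot == 0.0
    if zero.any():
        warnings.warn("genotype(s) at the ideotype: uniform contributions")
        omega.loc[zero] = 1.0 / result.d2_by_factor.shape[1]
    return omega


def run_mgidi(blues: pd.DataFrame, senses: dict[str, str] | None = None,
              intensity: float = 0.20, h2: dict[str, float] | None = None):
    """Full MGIDI pass: rescale, factor analysis, distances, selection, gains.

    Returns (MGIDIResult, selected labels, gains table, contributions table).
    """
    if senses is None:
        senses = {t: DEFAULT_SENSES.get(t, "increase") for t in blues.columns}
    rx = rescale(blues, senses)
    model = factor_analysis(rx)
    result = mgidi_distance(model)
    selected = select_by_mgidi(result, intensity)
    gains = selection_gains(blues, selected, senses, h2=h2)
    omega = contributions(result)
    return result, selected, gains, omega
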