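"""Synthetic alpha-lattice multi-environment trial generator.

Generates plot-level phenotype records under the additive mixed model

    y = mu(regime) + env + rep(env) + block(rep) + g + ge + e

with Gaussian random effects, so that every downstream stage (variance
components, heritability, drought indices, MGIDI) can be exercised against
known ground truth.  Genotype effects may be correlated across traits and
across water regimes; all other effects are independent.

The default configuration (:func:`soybean_screen_config`) emulates a soybean
drought-screening trial: 150 accessions, two water regimes (water-stressed WS
and well-watered WW) each observed in two years, three replicates laid out as
an alpha lattice of ten incomplete blocks of fifteen plots, and nine traits
whose regime-level means, residual CVs and broad-sense heritabilities sit at
realistic field-trial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimResult",
    "simulate_met",
    "soybean_screen_config",
    "implied_h2",
]

REGIMES = ("WS", "WW")

#: canonical trait order for the soybean screening configuration
SOYBEAN_TRAITS = ("D50F", "D95M", "FB", "PH", "NPP", "NSPP", "LS", "HSW", "GY")


def _per_regime(value, regimes) -> dict:
    """Expand a scalar to a {regime: value} map; pass dicts through."""
    if isinstance(value, dict):
        return {r: float(value[r]) for r in regimes}
    return {r: float(value) for r in regimes}


@dataclass
class TraitSpec:
    """Per-trait generative parameters.

    Every variance field accepts either a single float (shared by both
    regimes) or a ``{regime: value}`` mapping.  ``grand_mean`` is the
    non-stress (WW) mean when given as a scalar; the WS mean is then
    ``stress_reduction * grand_mean``.
    """

    name: str
    grand_mean: float | dict
    sigma2_g: float | dict
    sigma2_ge: float | dict
    sigma2_e: float | dict
    sigma2_rep: float | dict = 0.0
    sigma2_block: float | dict = 0.0
    sigma2_env: float | dict = 0.0
    stress_reduction: float = 1.0
    bounds: tuple[float, float] | None = None

    def __post_init__(self):
        if not (0.0 < self.stress_reduction <= 1.0):
            raise ValueError(f"{self.name}: stress_reduction must be in (0, 1]")
        for fld in ("sigma2_g", "sigma2_ge", "sigma2_e", "sigma2_rep",
                    "sigma2_block", "sigma2_env"):
            v = getattr(self, fld)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{self.name}: {fld} must be non-negative")

    def means(self, regimes=REGIMES) -> dict:
        if isinstance(self.grand_mean, dict):
            return {r: float(self.grand_mean[r]) for r in regimes}
        m = {r: float(self.grand_mean) for r in regimes}
        if "WS" in m:
            m["WS"] *= self.stress_reduction
        return m

    def variances(self, which: str, regimes=REGIMES) -> dict:
        return _per_regime(getattr(self, which), regimes)


@dataclass
class SimConfig:
    """Full specification of a simulated multi-environment trial."""

    n_genotypes: int
    environments: list[tuple[str, str]]  # (label, regime)
    n_reps: int
    n_blocks: int
    traits: list[TraitSpec]
    seed: int = 0
    #: correlation of a trait's genotype effects across the two regimes
    rho_regime: float = 0.0
    #: optional trait x trait correlation matrix for genotype effects,
    #: ordered as ``traits``
    trait_corr: np.ndarray | None = None

    def __post_init__(self):
        if self.n_genotypes < 1 or self.n_reps < 1 or self.n_blocks < 1:
            raise ValueError("all design counts must be >= 1")
        if not self.traits:
            raise ValueError("trait list must not be empty")
        if not self.environments:
            raise ValueError("environment list must not be empty")
        if self.n_genotypes % self.n_blocks != 0:
            raise ValueError(
                "n_genotypes must be divisible by n_blocks "
                f"({self.n_genotypes} % {self.n_blocks} != 0)")
        for _, regime in self.environments:
            if regime not in REGIMES:
                raise ValueError(f"unknown regime {regime!r}")
        if not (-1.0 <= self.rho_regime <= 1.0):
            raise ValueError("rho_regime must be a correlation")

    @property
    def regimes(self) -> tuple[str, ...]:
        seen = []
        for _, r in self.environments:
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    @property
    def genotype_labels(self) -> list[str]:
        width = max(3, len(str(self.n_genotypes)))
        return [f"SY{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass
class SimResult:
    """Simulated trial plus the ground truth that generated it."""

    trials: pd.DataFrame  # long format: genotype, environment, regime, rep, block, trait, value
    config: SimConfig
    genotype_effects: pd.DataFrame  # genotype x (trait, regime)
    ge_effects: pd.DataFrame  # (genotype, environment) x trait
    env_effects: pd.DataFrame  # environment x trait

    def true_h2(self, trait: str, regime: str) -> float:
        spec = next(t for t in self.config.traits if t.name == trait)
        n_env = sum(1 for _, r in self.config.environments if r == regime)
        return implied_h2(
            spec.variances("sigma2_g")[regime],
            spec.variances("sigma2_ge")[regime],
            spec.variances("sigma2_e")[regime],
            n_env, self.config.n_reps)


def implied_h2(sigma2_g: float, sigma2_ge: float, sigma2_e: float,
               n_env: int, n_rep: int) -> float:
    """Broad-sense heritability implied by true variance components.

    H2 = s2g / (s2g + s2ge/nEnv + s2e/(nEnv*nRep)) on an entry-mean basis.
    """
    denom = sigma2_g + sigma2_ge / n_env + sigma2_e / (n_env * n_rep)
    return 0.0 if denom == 0 else sigma2_g / denom


def _block_of(genotype_index: int, rep_index: int, n_genotypes: int,
              n_blocks: int) -> int:
    """Cyclic incomplete-block assignment, rotated between replicates.

    Statistical balance, not field-plan optimality, is the goal: each
    replicate partitions the genotypes into ``n_blocks`` equal blocks, and the
    partition is shifted by one block size per replicate so block membership
    is not identical across replicates.
    """
    block_size = n_genotypes // n_blocks
    return ((genotype_index + rep_index * block_size) % n_genotypes) // block_size


def simulate_met(config: SimConfig) -> SimResult:
    """Simulate a multi-environment trial under the additive mixed model.

    Returns the plot-level table together with the sampled genotype,
    genotype-by-environment and environment effects so parameter-recovery
    tests are a single call.  Fixing ``config.seed`` makes the output
    deterministic.
    """
    rng = np.random.default_rng(config.seed)
    g, labels = config.n_genotypes, config.genotype_labels
    env_labels = [e for e, _ in config.environments]
    regime_of = dict(config.environments)
    regimes = config.regimes
    traits = config.traits
    p = len(traits)

    # genotype effects: standardized draws with optional trait x trait and
    # regime x regime correlation (Kronecker structure), scaled per regime
    n_reg = len(regimes)
    if config.trait_corr is not None:
        ct = np.asarray(config.trait_corr, dtype=float)
        if ct.shape != (p, p):
            raise ValueError("trait_corr shape must match number of traits")
    else:
        ct = np.eye(p)
    cr = np.full((n_reg, n_reg), config.rho_regime)
    np.fill_diagonal(cr, 1.0)
    cov = np.kron(ct, cr)
    # tiny jitter guards Cholesky on exactly-singular correlation inputs
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    z = rng.standard_normal((g, p * n_reg)) @ chol.T

    geno_cols = {}
    for j, spec in enumerate(traits):
        sg = spec.variances("sigma2_g", regimes)
        for k, r in enumerate(regimes):
            geno_cols[(spec.name, r)] = z[:, j * n_reg + k] * np.sqrt(sg[r])
    genotype_effects = pd.DataFrame(geno_cols, index=pd.Index(labels, name="genotype"))

    env_eff = {
        spec.name: {
            e: rng.normal(0.0, np.sqrt(spec.variances("sigma2_env", regimes)[regime_of[e]]))
            for e in env_labels
        }
        for spec in traits
    }
    ge_eff = {
        spec.name: {
            (i, e): rng.normal(
                0.0, np.sqrt(spec.variances("sigma2_ge", regimes)[regime_of[e]]))
            for e in env_labels for i in range(g)
        }
        for spec in traits
    }

    records = []
    for spec in traits:
        means = spec.means(regimes)
        s_rep = spec.variances("sigma2_rep", regimes)
        s_blk = spec.variances("sigma2_block", regimes)
        s_e = spec.variances("sigma2_e", regimes)
        for e in env_labels:
            regime = regime_of[e]
            for k in range(config.n_reps):
                rep_dev = rng.normal(0.0, np.sqrt(s_rep[regime]))
                blk_dev = rng.normal(0.0, np.sqrt(s_blk[regime]), size=config.n_blocks)
                noise = rng.normal(0.0, np.sqrt(s_e[regime]), size=g)
                for i in range(g):
                    b = _block_of(i, k, g, config.n_blocks)
                    val = (means[regime]
                           + env_eff[spec.name][e]
                           + rep_dev + blk_dev[b]
                           + genotype_effects.loc[labels[i], (spec.name, regime)]
                           + ge_eff[spec.name][(i, e)]
                           + noise[i])
                    if spec.bounds is not None:
                        val = min(max(val, spec.bounds[0]), spec.bounds[1])
                    records.append((labels[i], e, regime, k + 1, b + 1,
                                    spec.name, val))

    trials = pd.DataFrame(
        records,
        columns=["genotype", "environment", "regime", "rep", "block", "trait", "value"],
    )
    ge_df = pd.DataFrame(
        {t: pd.Series({(labels[i], e): v for (i, e), v in eff.items()})
         for t, eff in ge_eff.items()})
    ge_df.index.names = ["genotype", "environment"]
    env_df = pd.DataFrame(env_eff)
    env_df.index.name = "environment"
    return SimResult(trials=trials, config=config,
                     genotype_effects=genotype_effects,
                     ge_effects=ge_df, env_effects=env_df)


# ---------------------------------------------------------------------------
# soybean screening configuration

# regime-level (mean, CV%, H2%) per trait: the generator back-solves variance
# components so the implied residual CV and entry-mean heritability hit these.
_SOY_TARGETS = {
    #            WS                       WW
    "D50F": ((44.0, 3.74, 77.45), (43.0, 6.92, 81.67)),
    "D95M": ((109.0, 2.58, 38.45), (105.0, 3.12, 72.51)),
    "FB":   ((34.38, 36.24, 74.20), (121.52, 33.37, 77.71)),
    "PH":   ((62.11, 12.98, 71.99), (71.04, 17.75, 66.46)),
    "NPP":  ((114.7, 29.46, 57.54), (129.0, 30.24, 54.70)),
    "NSPP": ((2.31, 7.78, 30.24), (2.59, 9.76, 67.98)),
    "LS":   ((2.2, 36.53, 86.56), (2.33, 44.89, 78.93)),
    "HSW":  ((12.12, 5.01, 28.56), (14.07, 9.82, 76.30)),
    "GY":   ((859.49, 21.52, 42.97), (2324.26, 30.67, 21.56)),
}

# genotype-effect correlations among traits (symmetric, unlisted pairs 0);
# magnitudes follow reported phenotypic correlations in drought screens:
# phenology traits cluster, maturity trades off against seed weight and yield,
# canopy traits co-vary.
_SOY_TRAIT_CORR = {
    ("D50F", "D95M"): 0.61,
    ("D50F", "HSW"): -0.30,
    ("D95M", "HSW"): -0.38,
    ("D95M", "GY"): -0.28,
    ("GY", "HSW"): 0.25,
    ("GY", "NPP"): 0.21,
    ("PH", "FB"): 0.50,
    ("PH", "LS"): 0.30,
    ("FB", "LS"): 0.40,
    ("NPP", "NSPP"): 0.20,
}


def _soy_corr_matrix() -> np.ndarray:
    p = len(SOYBEAN_TRAITS)
    idx = {t: i for i, t in enumerate(SOYBEAN_TRAITS)}
    c = np.eye(p)
    for (a, b), r in _SOY_TRAIT_CORR.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    # guard positive-definiteness (eigenvalue floor)
    w, v = np.linalg.eigh(c)
    if w.min() < 1e-6:
        w = np.clip(w, 1e-6, None)
        c = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def _components_from_targets(mean: float, cv_pct: float, h2_pct: float,
                             n_env: int = 2, n_rep: int = 3) -> dict:
    """Back-solve variance components from (mean, CV%, H2%).

    The residual variance comes from the CV; the GxE variance is set to half
    the residual variance (a typical MET ratio); the genotypic variance then
    follows from the entry-mean heritability identity.
    """
    s2e = (cv_pct / 100.0 * mean) ** 2
    s2ge = 0.5 * s2e
    h2 = h2_pct / 100.0
    s2g = h2 / (1.0 - h2) * (s2ge / n_env + s2e / (n_env * n_rep))
    return {"sigma2_e": s2e, "sigma2_ge": s2ge, "sigma2_g": s2g,
            "sigma2_rep": 0.1 * s2e, "sigma2_block": 0.1 * s2e,
            "sigma2_env": 0.25 * s2e}


def soybean_screen_config(seed: int = 0) -> SimConfig:
    """Soybean drought-screening configuration.

    150 accessions x {WS, WW} x 2 years x 3 replicates, alpha lattice with 10
    incomplete blocks of 15 plots, 9 traits.  Per-regime trait means, residual
    CVs and entry-mean heritabilities are set to values typical of tropical
    soybean MET screens (e.g. mean grain yield 859.49 kg/ha under stress vs
    2324.26 kg/ha well-watered, a 63% stress-induced reduction); lodging score
    is bounded to its 1-5 scale.
    """
    traits = []
    for name in SOYBEAN_TRAITS:
        (m_ws, cv_ws, h2_ws), (m_ww, cv_ww, h2_ww) = _SOY_TARGETS[name]
        c_ws = _components_from_targets(m_ws, cv_ws, h2_ws)
        c_ww = _components_from_targets(m_ww, cv_ww, h2_ww)
        traits.append(TraitSpec(
            name=name,
            grand_mean={"WS": m_ws, "WW": m_ww},
            sigma2_g={"WS": c_ws["sigma2_g"], "WW": c_ww["sigma2_g"]},
            sigma2_ge={"WS": c_ws["sigma2_ge"], "WW": c_ww["sigma2_ge"]},
            sigma2_e={"WS": c_ws["sigma2_e"], "WW": c_ww["sigma2_e"]},
            sigma2_rep={"WS": c_ws["sigma2_rep"], "WW": c_ww["sigma2_rep"]},
            sigma2_block={"WS": c_ws["sigma2_block"], "WW": c_ww["sigma2_block"]},
            sigma2_env={"WS": c_ws["sigma2_env"], "WW": c_ww["sigma2_env"]},
            stress_reduction=m_ws / m_ww if name == "GY" else 1.0,
            bounds=(1.0, 5.0) if name == "LS" else None,
        ))
    return SimConfig(
        n_genotypes=150,
        environments=[("WS_23", "WS"), ("WS_24", "WS"),
                      ("WW_23", "WW"), ("WW_24", "WW")],
        n_reps=3,
        n_blocks=10,
        traits=traits,
        seed=seed,
        rho_regime=0.4,
        trait_corr=_soy_corr_matrix(),
    )
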