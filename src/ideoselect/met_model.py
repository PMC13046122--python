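"""Mixed-model analysis of multi-environment trials.

Per trait and water regime the plot-level model is

    y = mu + env + rep(env) + block(rep) + genotype + genotype:env + e

fitted twice: with genotype random (EM-REML variance components, broad-sense
heritability, CV) and with genotype fixed (generalized-least-squares adjusted
means, BLUEs).  A sequential-sums-of-squares ANOVA table with
expected-mean-squares F denominators accompanies the fits.

Heritability is on an entry-mean basis,

    H2 = s2g / (s2g + s2ge/nEnv + s2e/(nEnv*nRep)),

classified low (<30%), moderate (30-60%) or high (>60%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "fit_variance_components",
    "ems_components",
    "heritability",
    "anova",
    "blues",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    sigma2_env: float = 0.0
    sigma2_rep: float = 0.0
    sigma2_block: float = 0.0
    n_env: int = 1
    n_rep: int = 1
    grand_mean: float = float("nan")
    converged: bool = True
    n_iter: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sigma2_g", "sigma2_ge", "sigma2_e",
                 "sigma2_env", "sigma2_rep", "sigma2_block")}


@dataclass
class HeritabilityEstimate:
    h2: float           # proportion in [0, 1]
    category: str       # low / moderate / high
    cv_pct: float       # residual CV, percent of the grand mean

    @property
    def h2_pct(self) -> float:
        return 100.0 * self.h2


def _subset(trials: pd.DataFrame, trait: str, regime: str | None) -> pd.DataFrame:
    d = trials[trials["trait"] == trait]
    if regime is not None:
        d = d[d["regime"] == regime]
    if d.empty:
        raise ValueError(f"no records for trait={trait!r}, regime={regime!r}")
    return d


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    z = np.zeros((codes.size, n_levels))
    z[np.arange(codes.size), codes] = 1.0
    return z


def _design(d: pd.DataFrame, genotype_fixed: bool):
    """Build fixed/random design matrices for one trait-regime subset."""
    y = d["value"].to_numpy(dtype=float)
    gen = pd.Categorical(d["genotype"])
    env = pd.Categorical(d["environment"])
    rep = pd.Categorical(d["environment"].astype(str) + "/" + d["rep"].astype(str))
    blk = pd.Categorical(rep.astype(str) + "/" + d["block"].astype(str))
    n_env = len(env.categories)

    random_terms: list[tuple[str, np.ndarray]] = []
    if n_env > 1:
        random_terms.append(("env", _indicator(env.codes, n_env)))
    if len(rep.categories) > n_env:
        random_terms.append(("rep", _indicator(rep.codes, len(rep.categories))))
    if len(blk.categories) > len(rep.categories):
        random_terms.append(("block", _indicator(blk.codes, len(blk.categories))))
    zg = _indicator(gen.codes, len(gen.categories))
    if genotype_fixed:
        x = zg
    else:
        x = np.ones((len(d), 1))
        random_terms.append(("g", zg))
    if n_env > 1:
        ge = pd.Categorical(d["genotype"].astype(str) + "/" + d["environment"].astype(str))
        random_terms.append(("ge", _indicator(ge.codes, len(ge.categories))))
    return y, x, random_terms, gen, n_env, len(rep.categories) // max(n_env, 1)


def _em_reml(y, x, random_terms, init, tol=1e-8, max_iter=500):
    """EM-REML via Henderson's mixed-model equations.

    ``random_terms`` is a list of (name, Z) pairs; ``init`` maps name to a
    starting variance (plus ``"e"`` for the residual).  Components are kept
    non-negative throughout; estimates that collapse numerically to zero stay
    there (the boundary is absorbing for EM) and are truncated on output.
    """
    n, p = x.shape
    names = [nm for nm, _ in random_terms]
    w = np.hstack([x] + [z for _, z in random_terms])
    wtw = w.T @ w
    wty = w.T @ y
    yty = float(y @ y)
    q = [z.shape[1] for _, z in random_terms]
    offs = np.cumsum([p] + q)
    rank_x = np.linalg.matrix_rank(x) if p > 1 else 1

    s2 = {nm: max(float(init.get(nm, 1.0)), 1e-12) for nm in names}
    s2e = max(float(init.get("e", 1.0)), 1e-12)
    scale = max(float(np.var(y)), 1e-300)

    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        m = wtw.copy()
        for k, nm in enumerate(names):
            lam = s2e / max(s2[nm], 1e-12 * scale)
            idx = slice(offs[k], offs[k] + q[k])
            m[idx, idx] += lam * np.eye(q[k])
        try:
            cf = linalg.cho_factor(m, check_finite=False)
            sol = linalg.cho_solve(cf, wty, check_finite=False)
            minv = linalg.cho_solve(cf, np.eye(m.shape[0]), check_finite=False)
        except linalg.LinAlgError:
            minv = np.linalg.pinv(m)
            sol = minv @ wty
        new = {}
        for k, nm in enumerate(names):
            idx = slice(offs[k], offs[k] + q[k])
            u = sol[idx]
            new[nm] = (float(u @ u) + s2e * float(np.trace(minv[idx, idx]))) / q[k]
        s2e_new = max((yty - float(sol @ wty)) / (n - rank_x), 0.0)
        delta = max(
            [abs(new[nm] - s2[nm]) / max(s2[nm], 1e-8 * scale) for nm in names]
            + [abs(s2e_new - s2e) / max(s2e, 1e-8 * scale)])
        s2, s2e = new, max(s2e_new, 1e-300)
        if delta < tol:
            converged = True
            break
    s2 = {nm: (0.0 if v < 1e-8 * scale else v) for nm, v in s2.items()}
    return s2, s2e, converged, it


def ems_components(trials: pd.DataFrame, trait: str, regime: str | None = None
                   ) -> VarianceComponents:
    """Method-of-moments components from balanced expected mean squares.

    Classical ANOVA estimators for the balanced crossed genotype x environment
    design with replicates (incomplete blocks, if any, are ignored: their
    variance folds into the residual/replicate strata).  On fully balanced
    block-free data these coincide with REML whenever all solutions are
    non-negative.
    """
    d = _subset(trials, trait, regime)
    piv = d.pivot_table(index="genotype", columns=["environment", "rep"],
                        values="value")
    if piv.isna().any().any():
        raise ValueError("EMS estimator requires balanced data")
    arr = piv.to_numpy()
    g = arr.shape[0]
    envs = piv.columns.get_level_values(0).unique()
    e = len(envs)
    r = arr.shape[1] // e
    cell = np.stack([piv[env].to_numpy().mean(axis=1) for env in envs], axis=1)  # g x e
    gbar = arr.mean(axis=1)
    ebar = np.array([piv[env].to_numpy().mean() for env in envs])
    repbar = np.array([piv[env].to_numpy().mean(axis=0) for env in envs])  # e x r
    grand = arr.mean()

    ms_g = e * r * np.sum((gbar - grand) ** 2) / (g - 1)
    if e > 1:
        inter = cell - gbar[:, None] - ebar[None, :] + grand
        ms_ge = r * np.sum(inter ** 2) / ((g - 1) * (e - 1))
        ms_env = g * r * np.sum((ebar - grand) ** 2) / (e - 1)
    else:
        ms_ge = ms_env = 0.0
    if r > 1:
        ms_rep = g * np.sum((repbar - ebar[:, None]) ** 2) / (e * (r - 1))
    else:
        ms_rep = 0.0
    ss_tot = np.sum((arr - grand) ** 2)
    ss_model = (ms_g * (g - 1) + ms_ge * (g - 1) * (e - 1)
                + ms_env * (e - 1) + ms_rep * e * (r - 1))
    df_e = g * e * r - 1 - (g - 1) - (e - 1) * g - e * (r - 1)
    mse = (ss_tot - ss_model) / df_e if df_e > 0 else 0.0

    s2e = max(mse, 0.0)
    s2ge = max((ms_ge - mse) / r, 0.0) if e > 1 else 0.0
    s2g = max((ms_g - (ms_ge if e > 1 else mse)) / (e * r), 0.0)
    s2rep = max((ms_rep - mse) / g, 0.0) if r > 1 else 0.0
    s2env = max((ms_env - ms_rep - ms_ge + mse) / (g * r), 0.0) if e > 1 else 0.0
    return VarianceComponents(
        sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e, sigma2_env=s2env,
        sigma2_rep=s2rep, sigma2_block=0.0, n_env=e, n_rep=r,
        grand_mean=float(grand))


def fit_variance_components(trials: pd.DataFrame, trait: str,
                            regime: str | None = None, *,
                            tol: float = 1e-8, max_iter: int = 500,
                            init: dict | str = "ems") -> VarianceComponents:
    """EM-REML variance components for one trait within one water regime.

    The EM iteration runs on the mixed-model equations with all design terms
    random; it is initialized from the balanced method-of-moments solution
    (EMS), to which it is identical on balanced block-free data.  Negative
    solutions are truncated to zero.  With a single environment the GxE
    component is undefined and reported as zero with a warning.
    """
    d = _subset(trials, trait, regime)
    y = d["value"].to_numpy(dtype=float)
    if d["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    grand = float(y.mean())
    n_env = d["environment"].nunique()
    n_rep = int(d.groupby("environment")["rep"].nunique().max())

    if np.ptp(y) == 0.0:
        if n_env == 1:
            warnings.warn("single environment: sigma2_ge not estimable, set to 0")
        return VarianceComponents(0, 0, 0, 0, 0, 0, n_env=n_env, n_rep=n_rep,
                                  grand_mean=grand)
    if n_env == 1:
        warnings.warn("single environment: sigma2_ge not estimable, set to 0")

    if init == "ems":
        try:
            ems = ems_components(trials, trait, regime)
            if ems.sigma2_e <= 1e-10 * np.var(y):
                # noise-free balanced data: the EMS decomposition is exact and
                # the EM iteration is degenerate (unpenalized random effects)
                ems.grand_mean = grand
                return ems
            init = {"g": ems.sigma2_g, "ge": ems.sigma2_ge, "e": ems.sigma2_e,
                    "env": ems.sigma2_env, "rep": ems.sigma2_rep,
                    "block": 0.1 * ems.sigma2_e}
        except ValueError:
            init = "equal"
    if init == "equal":
        v = float(np.var(y, ddof=1))
        init = {k: v / 6 for k in ("g", "ge", "e", "env", "rep", "block")}
    init = {k: max(v, 1e-6 * np.var(y)) for k, v in init.items()}

    _, x, random_terms, _, _, _ = _design(d, genotype_fixed=False)
    s2, s2e, converged, it = _em_reml(y, x, random_terms, init,
                                      tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn(f"EM-REML did not reach tolerance in {max_iter} iterations")
    return VarianceComponents(
        sigma2_g=s2.get("g", 0.0), sigma2_ge=s2.get("ge", 0.0), sigma2_e=s2e,
        sigma2_env=s2.get("env", 0.0), sigma2_rep=s2.get("rep", 0.0),
        sigma2_block=s2.get("block", 0.0), n_env=n_env, n_rep=n_rep,
        grand_mean=grand, converged=converged, n_iter=it)


def heritability(vc: VarianceComponents) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability, CV and the 30/60% classification."""
    denom = (vc.sigma2_g + vc.sigma2_ge / vc.n_env
             + vc.sigma2_e / (vc.n_env * vc.n_rep))
    if denom == 0.0:
        warnings.warn("all variance components are zero; H2 reported as 0")
        h2 = 0.0
    else:
        h2 = vc.sigma2_g / denom
    pct = 100.0 * h2
    category = "low" if pct < 30.0 else ("moderate" if pct <= 60.0 else "high")
    cv = (100.0 * np.sqrt(vc.sigma2_e) / vc.grand_mean
          if np.isfinite(vc.grand_mean) and vc.grand_mean != 0 else float("nan"))
    return HeritabilityEstimate(h2=h2, category=category, cv_pct=float(cv))


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova(trials: pd.DataFrame, trait: str, regime: str | None = None
          ) -> pd.DataFrame:
    """Sequential ANOVA for one trait-regime: Env, Rep(Env), Gen, Env x Gen.

    Mean squares come from sequential sums of squares in that order; F for
    genotype is tested against the GxE mean square and GxE against the
    residual, following the expected mean squares of the random-effects
    layout.  Env is tested against Rep(Env).  Incomplete-block variation is
    left in the residual stratum.
    """
    d = _subset(trials, trait, regime)
    y = d["value"].to_numpy(dtype=float)
    n = len(d)
    gen = pd.Categorical(d["genotype"])
    env = pd.Categorical(d["environment"])
    rep = pd.Categorical(d["environment"].astype(str) + "/" + d["rep"].astype(str))
    n_env, g = len(env.categories), len(gen.categories)

    # sequential projections onto nested column spaces
    def proj_ss(cols):
        x = np.hstack(cols)
        q, _ = np.linalg.qr(x)
        fitted = q @ (q.T @ y)
        return float(fitted @ fitted), np.linalg.matrix_rank(x)

    ones = np.ones((n, 1))
    blocks = [ones]
    rows = []
    prev_ss, prev_rank = proj_ss(blocks)
    terms = []
    if n_env > 1:
        terms.append(("Env", _indicator(env.codes, n_env)))
    if len(rep.categories) > n_env:
        terms.append(("Rep(Env)", _indicator(rep.codes, len(rep.categories))))
    terms.append(("Gen", _indicator(gen.codes, g)))
    if n_env > 1:
        ge = pd.Categorical(d["genotype"].astype(str) + "/" + d["environment"].astype(str))
        terms.append(("Env x Gen", _indicator(ge.codes, len(ge.categories))))
    for name, z in terms:
        blocks.append(z)
        ss, rank = proj_ss(blocks)
        rows.append((name, rank - prev_rank, ss - prev_ss))
        prev_ss, prev_rank = ss, rank
    ss_res = float(y @ y) - prev_ss
    df_res = n - prev_rank
    rows.append(("Residual", df_res, ss_res))

    tab = pd.DataFrame(rows, columns=["source", "df", "ss"]).set_index("source")
    tab["ms"] = tab["ss"] / tab["df"].replace(0, np.nan)
    ms_res = tab.loc["Residual", "ms"]

    denom_of = {"Gen": "Env x Gen" if n_env > 1 else "Residual",
                "Env x Gen": "Residual",
                "Env": "Rep(Env)" if "Rep(Env)" in tab.index else "Residual",
                "Rep(Env)": "Residual"}
    fvals, pvals, sig = {}, {}, {}
    for src in tab.index:
        if src == "Residual":
            continue
        dsrc = denom_of.get(src, "Residual")
        ms_d, df_d = tab.loc[dsrc, "ms"], tab.loc[dsrc, "df"]
        ms_n, df_n = tab.loc[src, "ms"], tab.loc[src, "df"]
        if ms_d and ms_d > 0 and df_d > 0:
            f = ms_n / ms_d
            fvals[src] = f
            pvals[src] = float(stats.f.sf(f, df_n, df_d))
            sig[src] = _stars(pvals[src])
    tab["F"] = pd.Series(fvals)
    tab["p"] = pd.Series(pvals)
    tab["sig"] = pd.Series(sig)
    return tab.reset_index()


def blues(trials: pd.DataFrame, trait: str, regime: str | None = None,
          vc: VarianceComponents | None = None) -> pd.Series:
    """Genotype adjusted means (BLUEs) for one trait within one regime.

    Genotype enters as a fixed effect; environment, replicate, block and GxE
    enter as random effects with the (estimated or supplied) variance
    components, and the adjusted means come from the generalized-least-squares
    solve of the mixed-model equations.  On balanced noise-free data this
    reduces to the plain genotype mean.
    """
    d = _subset(trials, trait, regime)
    if vc is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = fit_variance_components(trials, trait, regime)
    y, x, random_terms, gen, _, _ = _design(d, genotype_fixed=True)
    counts = d.groupby("genotype").size()
    missing = counts[counts == 0]
    if len(missing):
        warnings.warn(f"genotypes never observed: {list(missing.index)}")

    s2_map = {"env": vc.sigma2_env, "rep": vc.sigma2_rep,
              "block": vc.sigma2_block, "ge": vc.sigma2_ge}
    s2e = vc.sigma2_e
    active = [(nm, z) for nm, z in random_terms if s2_map.get(nm, 0.0) > 0]
    n, p = x.shape
    if not active or s2e == 0.0:
        if s2e == 0.0 and active:
            # noise-free: random effects are perfectly absorbed by OLS on the
            # full design; plain genotype means remain unbiased and exact here
            pass
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    else:
        w = np.hstack([x] + [z for _, z in active])
        m = w.T @ w
        off = p
        for nm, z in active:
            q = z.shape[1]
            m[off:off + q, off:off + q] += (s2e / s2_map[nm]) * np.eye(q)
            off += q
        sol = np.linalg.solve(m, w.T @ y)
        beta = sol[:p]
    return pd.Series(beta, index=pd.Index(gen.categories, name="genotype"),
                     name=trait)


def blue_table(trials: pd.DataFrame, regime: str,
               traits: list[str] | None = None) -> pd.DataFrame:
    """Genotype x trait table of BLUEs for one regime."""
    if traits is None:
        traits = list(trials["trait"].unique())
    return pd.DataFrame({t: blues(trials, t, regime) for t in traits})
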