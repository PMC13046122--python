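import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from ideoselect import mgidi as mg


def _toy_blues(seed=0, g=6, p=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(10, 90, size=(g, p)),
                        index=[f"g{i}" for i in range(g)],
                        columns=[f"t{j}" for j in range(p)])


# ------------------------------------------------------------------ rescale

def test_rescale_endpoints_and_midpoint():
    blues = pd.DataFrame({"t": [40.0, 50.0, 60.0]}, index=list("abc"))
    rx = mg.rescale(blues, {"t": "increase"})
    assert list(rx["t"]) == [0.0, 50.0, 100.0]
    rx_dec = mg.rescale(blues, {"t": "decrease"})
    assert list(rx_dec["t"]) == [100.0, 50.0, 0.0]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(a=hst.floats(0.1, 20.0), b=hst.floats(-50.0, 50.0),
       seed=hst.integers(0, 100))
def test_rescale_affine_invariance(a, b, seed):
    blues = _toy_blues(seed)
    senses = {"t0": "increase", "t1": "decrease", "t2": "increase"}
    rx1 = mg.rescale(blues, senses)
    rx2 = mg.rescale(a * blues + b, senses)
    assert np.allclose(rx1, rx2, atol=1e-6)


def test_rescale_constant_column_raises():
    blues = pd.DataFrame({"t": [5.0, 5.0]}, index=list("ab"))
    with pytest.raises(ValueError, match="constant"):
        mg.rescale(blues)


def test_rescale_unknown_sense_raises():
    blues = pd.DataFrame({"t": [1.0, 2.0]}, index=list("ab"))
    with pytest.raises(ValueError, match="sense"):
        mg.rescale(blues, {"t": "sideways"})


# ---------------------------------------------------------- factor analysis

def test_varimax_is_orthogonal_rotation():
    rng = np.random.default_rng(1)
    load = rng.normal(size=(6, 3))
    rot = mg.varimax(load)
    # communalities (row norms) are preserved by any orthogonal rotation
    assert np.allclose((rot ** 2).sum(axis=1), (load ** 2).sum(axis=1))


def test_two_identical_traits_give_one_factor():
    base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
    rx = pd.DataFrame({"a": base, "b": base * 2 + 1},
                      index=[f"g{i}" for i in range(5)])
    rx = mg.rescale(rx)
    with np.errstate(all="ignore"):
        model = mg.factor_analysis(rx)
    assert model.n_factors == 1
    assert model.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)
    assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)


def test_independent_traits_eigenvalues_near_one():
    rng = np.random.default_rng(3)
    rx = pd.DataFrame(rng.uniform(0, 100, size=(4000, 5)),
                      columns=list("abcde"))
    model = mg.factor_analysis(rx)
    assert np.allclose(model.eigenvalues, 1.0, atol=0.1)
    assert model.n_factors == int(np.sum(model.eigenvalues > 1.0))


def test_communality_plus_uniqueness_is_one():
    model = mg.factor_analysis(mg.rescale(_toy_blues(4, g=30, p=5)))
    assert np.allclose(model.communality + model.uniqueness, 1.0, atol=1e-12)
    assert ((model.communality >= -1e-12) & (model.communality <= 1 + 1e-9)).all()


def test_no_eigenvalue_above_one_keeps_single_factor():
    # a single trait has the lone eigenvalue exactly 1: boundary "> 1" is
    # exclusive, so the fallback retains one factor with a warning
    rx = pd.DataFrame({"a": [0.0, 25.0, 75.0, 100.0]})
    with pytest.warns(UserWarning, match="eigenvalue"):
        model = mg.factor_analysis(rx)
    assert model.n_factors == 1


# --------------------------------------------------------- distances / MGIDI

def _oracle_mgidi(blues: pd.DataFrame, senses: dict) -> pd.Series:
    """Literal unrotated transcription of the rescale -> factor scores ->
    ideotype distance chain, kept independent of the implementation."""
    theta = blues.to_numpy(dtype=float)
    g, p = theta.shape
    rx = np.empty_like(theta)
    for j, col in enumerate(blues.columns):
        eta_o, phi_o = theta[:, j].max(), theta[:, j].min()
        if senses.get(col, "increase") == "increase":
            eta_n, phi_n = 100.0, 0.0
        else:
            eta_n, phi_n = 0.0, 100.0
        rx[:, j] = (eta_n - phi_n) / (eta_o - phi_o) * (theta[:, j] - eta_o) + eta_n
    mu, sd = rx.mean(axis=0), rx.std(axis=0, ddof=1)
    z = (rx - mu) / sd
    r = np.corrcoef(z, rowvar=False)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    f = max(int((evals > 1).sum()), 1)
    a = evecs[:, :f] * np.sqrt(evals[:f])
    w = np.linalg.solve(r, a)
    scores = z @ w
    ideo = ((100.0 - mu) / sd) @ w
    return pd.Series(np.sqrt(((scores - ideo) ** 2).sum(axis=1)),
                     index=blues.index)


@pytest.mark.parametrize("seed,g,p", [(0, 5, 3), (1, 6, 3), (2, 6, 2), (3, 4, 3)])
def test_distance_matches_bruteforce_oracle(seed, g, p):
    """Varimax is an orthogonal rotation of the score space, so distances to
    the identically-rotated ideotype must equal the unrotated transcription."""
    blues = _toy_blues(seed, g, p)
    senses = {c: ("decrease" if j % 2 else "increase")
              for j, c in enumerate(blues.columns)}
    res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues, senses)))
    oracle = _oracle_mgidi(blues, senses)
    assert np.allclose(res.distance, oracle, atol=1e-10)


def test_ideotype_equal_genotype_has_zero_distance():
    blues = pd.DataFrame({"t0": [9.0, 5.0, 1.0], "t1": [2.0, 5.0, 9.0]},
                         index=["best", "mid", "worst"])
    senses = {"t0": "increase", "t1": "decrease"}
    res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues, senses)))
    assert res.distance["best"] == pytest.approx(0.0, abs=1e-10)
    assert res.distance["worst"] > res.distance["mid"] > 0


def test_distance_permutation_equivariance():
    blues = _toy_blues(7, g=8, p=3)
    res1 = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues)))
    perm = blues.iloc[::-1]
    res2 = mg.mgidi_distance(mg.factor_analysis(mg.rescale(perm)))
    assert np.allclose(res1.distance.sort_index(), res2.distance.sort_index(),
                       atol=1e-9)


def test_trait_column_order_does_not_change_distances():
    blues = _toy_blues(9, g=10, p=4)
    res1 = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues)))
    shuffled = blues[list(blues.columns[::-1])]
    res2 = mg.mgidi_distance(mg.factor_analysis(mg.rescale(shuffled)))
    assert np.allclose(res1.distance, res2.distance, atol=1e-9)


def test_duplicate_trait_column_keeps_ideotype_at_zero():
    blues = pd.DataFrame({"t0": [9.0, 5.0, 1.0, 3.0], "t1": [8.0, 2.0, 1.0, 6.0]},
                         index=["best", "a", "b", "c"])
    blues["t0_dup"] = blues["t0"]
    with np.errstate(all="ignore"):
        res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues)))
    assert res.distance["best"] == pytest.approx(0.0, abs=1e-6)


def test_rotation_invariance_of_distances():
    blues = _toy_blues(11, g=12, p=4)
    res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues)))
    f = res.model.n_factors
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(f, f)))
    rotated = res.model.scores.to_numpy() @ q
    ideo = res.model.ideotype_scores.to_numpy() @ q
    dist = np.sqrt(((rotated - ideo) ** 2).sum(axis=1))
    assert np.allclose(dist, res.distance, atol=1e-10)


# ---------------------------------------------------------------- selection

def test_select_by_mgidi_sizes():
    blues = _toy_blues(5, g=25, p=3)
    res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues)))
    assert len(mg.select_by_mgidi(res, 0.20)) == 5
    assert len(mg.select_by_mgidi(res, 1.0)) == 25
    sel = mg.select_by_mgidi(res, 0.20)
    cut = res.distance.sort_values().iloc[4]
    assert all(res.distance[s] <= cut for s in sel)
    with pytest.raises(ValueError):
        mg.select_by_mgidi(res, 0.0)


# -------------------------------------------------------------------- gains

def test_gains_zero_when_everything_selected():
    blues = _toy_blues(6, g=8, p=3)
    gains = mg.selection_gains(blues, list(blues.index))
    assert np.allclose(gains["SD_pct"], 0.0, atol=1e-12)


def test_gains_ten_percent_toy():
    blues = pd.DataFrame({"t": [110.0, 110.0, 90.0, 90.0]},
                         index=list("abcd"))
    gains = mg.selection_gains(blues, ["a", "b"], {"t": "increase"})
    assert gains.loc["t", "SD_pct"] == pytest.approx(10.0)
    assert bool(gains.loc["t", "desirable"])
    down = mg.selection_gains(blues, ["c", "d"], {"t": "decrease"})
    assert down.loc["t", "SD_pct"] == pytest.approx(-10.0)
    assert bool(down.loc["t", "desirable"])


def test_gains_heritability_weighting():
    blues = pd.DataFrame({"t": [110.0, 90.0]}, index=list("ab"))
    gains = mg.selection_gains(blues, ["a"], h2={"t": 0.5})
    assert gains.loc["t", "SDxH2_pct"] == pytest.approx(
        gains.loc["t", "SD_pct"] * 0.5)


def test_gains_empty_selection_raises():
    with pytest.raises(ValueError):
        mg.selection_gains(_toy_blues(), [])


# ------------------------------------------------------------ contributions

def test_contributions_normalize_and_toy_values():
    blues = _toy_blues(13, g=10, p=4)
    res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(blues)))
    omega = mg.contributions(res)
    assert np.allclose(omega.sum(axis=1), 1.0, atol=1e-12)
    # direct arithmetic: D2 = (1, 3) => omega = (0.25, 0.75)
    toy = mg.MGIDIResult(
        model=res.model,
        distance=pd.Series([2.0], index=["g"]),
        d2_by_factor=pd.DataFrame([[1.0, 3.0]], index=["g"],
                                  columns=["FA1", "FA2"]))
    assert list(mg.contributions(toy).loc["g"]) == [0.25, 0.75]


def test_contributions_single_factor_is_one():
    base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
    rx = pd.DataFrame({"a": base, "b": base},
                      index=[f"g{i}" for i in range(5)])
    with np.errstate(all="ignore"):
        res = mg.mgidi_distance(mg.factor_analysis(mg.rescale(rx)))
    assert res.model.n_factors == 1
    omega = mg.contributions(res)
    assert np.allclose(omega, 1.0)


def test_contributions_at_ideotype_warn_uniform():
    res = mg.MGIDIResult(
        model=None,
        distance=pd.Series([0.0], index=["g"]),
        d2_by_factor=pd.DataFrame([[0.0, 0.0]], index=["g"],
                                  columns=["FA1", "FA2"]))
    with pytest.warns(UserWarning, match="ideotype"):
        omega = mg.contributions(res)
    assert list(omega.loc["g"]) == [0.5, 0.5]


# --------------------------------------------------- full-scale structural

def test_mgidi_on_trial_scale_data(trial_pipeline):
    """Nine correlated traits on 150 genotypes: a handful of factors is
    retained and the selection differential aggregates reproduce a direct
    recomputation from the adjusted means."""
    results, _ = trial_pipeline
    res, sel, gains, omega = results["mgidi"]["WS"]
    assert 3 <= res.model.n_factors <= 5
    assert np.allclose(res.model.communality + res.model.uniqueness, 1.0)
    assert len(sel) == 30
    # cumulative gain over increase-sense traits == direct recomputation
    blues = results["blues"]["WS"]
    senses = results["senses"]
    inc = [t for t in blues.columns if senses[t] == "increase"]
    direct = sum(100.0 * (blues[t].loc[sel].mean() - blues[t].mean())
                 / blues[t].mean() for t in inc)
    assert gains.loc[inc, "SD_pct"].sum() == pytest.approx(direct, abs=1e-9)
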