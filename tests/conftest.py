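import pytest

from ideoselect import synthetic_trials as st


def small_trial_config(seed: int = 5) -> st.SimConfig:
    """A 40-genotype, 2-regime x 2-env, 2-rep, 4-trait trial: big enough for
    every pipeline stage, small enough to fit many times in a test run."""
    def trait(name, m_ws, m_ww, cv, h2, bounds=None):
        c_ws = st._components_from_targets(m_ws, cv, h2, n_env=2, n_rep=2)
        c_ww = st._components_from_targets(m_ww, cv, h2, n_env=2, n_rep=2)
        return st.TraitSpec(
            name=name, grand_mean={"WS": m_ws, "WW": m_ww},
            sigma2_g={"WS": c_ws["sigma2_g"], "WW": c_ww["sigma2_g"]},
            sigma2_ge={"WS": c_ws["sigma2_ge"], "WW": c_ww["sigma2_ge"]},
            sigma2_e={"WS": c_ws["sigma2_e"], "WW": c_ww["sigma2_e"]},
            sigma2_rep={"WS": c_ws["sigma2_rep"], "WW": c_ww["sigma2_rep"]},
            sigma2_env={"WS": c_ws["sigma2_env"], "WW": c_ww["sigma2_env"]},
            bounds=bounds)
    return st.SimConfig(
        n_genotypes=40,
        environments=[("WS_1", "WS"), ("WS_2", "WS"),
                      ("WW_1", "WW"), ("WW_2", "WW")],
        n_reps=2, n_blocks=4,
        traits=[trait("GY", 860.0, 2320.0, 20.0, 50.0),
                trait("D50F", 44.0, 43.0, 4.0, 78.0),
                trait("HSW", 12.0, 14.0, 6.0, 40.0),
                trait("PH", 62.0, 71.0, 13.0, 70.0)],
        seed=seed, rho_regime=0.4)


@pytest.fixture()
def small_config():
    return small_trial_config()


@pytest.fixture(scope="session")
def trial_pipeline(tmp_path_factory):
    """One full soybean-scale pipeline run (150 genotypes, 9 traits, 4
    environments), shared across tests: returns (results dict, output dir)."""
    from ideoselect import cli_io
    out = tmp_path_factory.mktemp("pipeline")
    cfg = cli_io.PipelineConfig(out_dir=str(out), seed=1)
    results = cli_io.run_pipeline(cfg)
    return results, out


@pytest.fixture(scope="session")
def recovery_sim():
    """Balanced block-free 300-genotype trial with known components
    (s2g=4, s2ge=2, s2e=6 => entry-mean H2 = 2/3), plus its REML fit."""
    from ideoselect import met_model as mm
    spec = st.TraitSpec(name="T", grand_mean=100.0, sigma2_g=4.0,
                        sigma2_ge=2.0, sigma2_e=6.0, sigma2_rep=0.5,
                        sigma2_env=1.0)
    cfg = st.SimConfig(n_genotypes=300,
                       environments=[("E1", "WS"), ("E2", "WS")],
                       n_reps=3, n_blocks=1, traits=[spec], seed=42)
    sim = st.simulate_met(cfg)
    vc = mm.fit_variance_components(sim.trials, "T", "WS")
    return sim, vc
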