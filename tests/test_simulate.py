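"""Generator contracts: reproducibility, degenerate regimes, recovery."""

import numpy as np
import pandas as pd
import pytest

from vaxdyn import (
    CovariateTransitionModel,
    SimulationConfig,
    estimate_transitions,
    simulate_error_model_population,
    simulate_panel,
)
from vaxdyn.simulate import DEFAULT_TRANSITIONS


def test_same_seed_gives_identical_output():
    a, ta = simulate_panel(SimulationConfig(n_respondents=150, seed=9, misreport_rate=0.1))
    b, tb = simulate_panel(SimulationConfig(n_respondents=150, seed=9, misreport_rate=0.1))
    pd.testing.assert_frame_equal(a.data, b.data)
    pd.testing.assert_frame_equal(ta, tb)
    assert a.digest() == b.digest()


def test_different_seed_differs():
    a, _ = simulate_panel(SimulationConfig(n_respondents=150, seed=9))
    b, _ = simulate_panel(SimulationConfig(n_respondents=150, seed=10))
    assert a.digest() != b.digest()


def test_mu_zero_identity_chain_is_constant():
    eye = np.eye(5)
    cfg = SimulationConfig(
        n_respondents=100, misreport_rate=0.0,
        transition_model={"voluntary": eye, "mandated": eye},
        uptake_probability=0.0, partial_uptake_probability=0.0, seed=1,
    )
    panel, truth = simulate_panel(cfg)
    traj = panel.trajectories("voluntary")
    assert (traj.nunique(axis=1) == 1).all()
    # observed equals latent everywhere when mu = 0
    merged = panel.data.merge(truth, on=["id", "wave"])
    assert (merged["vol_likert"].astype(int) == merged["true_vol"]).all()


def test_mu_one_observed_marginal_is_uniform():
    cfg = SimulationConfig(
        n_respondents=4000, misreport_rate=1.0,
        uptake_probability=0.0, partial_uptake_probability=0.0, seed=2,
    )
    panel, _ = simulate_panel(cfg)
    counts = panel.data["vol_likert"].value_counts().sort_index().to_numpy()
    n = counts.sum()
    p = 0.2
    se = np.sqrt(p * (1 - p) * n)
    assert (np.abs(counts - n * p) < 4 * se).all()


def test_transition_recovery_from_known_matrix():
    """Empirical wave-to-wave frequencies sit within 3 SEs of the true P."""
    P = DEFAULT_TRANSITIONS["voluntary"]
    cfg = SimulationConfig(
        n_respondents=20_000, misreport_rate=0.0,
        uptake_probability=0.0, partial_uptake_probability=0.0, seed=5,
    )
    panel, _ = simulate_panel(cfg)
    est = estimate_transitions(panel, "voluntary", 1, 2)
    row_n = est.counts.sum(axis=1)
    se = np.sqrt(P * (1 - P) / row_n[:, None])
    assert (np.abs(est.P - P) <= 3 * se + 1e-12).all()


def test_uptake_only_among_willing_and_levels_missing():
    cfg = SimulationConfig(n_respondents=2018, seed=4)
    panel, truth = simulate_panel(cfg)
    w3 = panel.wave(3).set_index("id")
    twice = w3[w3["vax_status"] == "twice"]
    assert len(twice) > 0
    assert twice["vol_likert"].isna().all() and twice["man_likert"].isna().all()
    t3 = truth[truth["wave"] == 3].set_index("id")
    assert (t3.loc[twice.index, "true_vol"] >= 3).all()
    # roughly uptake_probability x willing-share of the panel
    frac = len(twice) / panel.n_respondents
    assert 0.03 < frac < 0.12


def test_covariate_tilt_shifts_transitions_toward_willing():
    base = DEFAULT_TRANSITIONS["voluntary"]
    tm = CovariateTransitionModel(base, coefs={"trust_institutions": 1.0})
    cfg = SimulationConfig(
        n_respondents=4000, seed=6,
        transition_model={"voluntary": tm, "mandated": DEFAULT_TRANSITIONS["mandated"]},
        uptake_probability=0.0, partial_uptake_probability=0.0,
    )
    panel, truth = simulate_panel(cfg)
    t = truth.pivot(index="id", columns="wave", values="true_vol")
    trust = panel.wave(1).set_index("id")["trust_institutions"]
    high = trust[trust > 0.5].index
    low = trust[trust < -0.5].index
    # among those starting opposed, high-trust respondents end up more willing
    opposed_w1 = t.index[t[1] <= 1]
    up_high = (t.loc[opposed_w1.intersection(high), 3] >= 3).mean()
    up_low = (t.loc[opposed_w1.intersection(low), 3] >= 3).mean()
    assert up_high > up_low + 0.1


def test_shared_misreport_flag_couples_regimes():
    cfg = SimulationConfig(
        n_respondents=500, misreport_rate=0.4,
        misreport_shared_across_regimes=True, seed=8,
    )
    _, truth = simulate_panel(cfg)
    assert (truth["misreport_vol"] == truth["misreport_man"]).all()
    cfg2 = SimulationConfig(n_respondents=500, misreport_rate=0.4, seed=8)
    _, truth2 = simulate_panel(cfg2)
    assert (truth2["misreport_vol"] != truth2["misreport_man"]).any()


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(misreport_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(initial_distribution={"voluntary": np.array([0.5, 0.5, 0.5, 0, 0]),
                                               "mandated": np.array([0.2] * 5)})
    with pytest.raises(ValueError):
        SimulationConfig(transition_model={"voluntary": np.ones((5, 5)),
                                           "mandated": DEFAULT_TRANSITIONS["mandated"]})


def test_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(n_respondents=123, misreport_rate=0.2, seed=77)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back.n_respondents == 123
    assert back.misreport_rate == 0.2
    assert back.seed == 77
    np.testing.assert_allclose(
        np.asarray(back.transition_model["voluntary"]),
        np.asarray(cfg.transition_model["voluntary"]),
    )


# -- misreport population ---------------------------------------------------


def test_error_population_all_opposed_no_noise():
    obs, truly = simulate_error_model_population(x=1.0, mu=0.0, n=200, W=3, seed=1)
    assert truly.all() and obs.all()


def test_error_population_no_noise_consistent_equals_cross_section():
    obs, _ = simulate_error_model_population(x=0.2, mu=0.0, n=100_000, W=3, seed=2)
    cons = obs.all(axis=1).mean()
    cross = obs.mean()
    se = np.sqrt(0.2 * 0.8 / 100_000)
    assert abs(cons - 0.2) < 3 * se
    assert abs(cross - 0.2) < 3 * se
    assert cons == pytest.approx(cross)  # identical columns when mu=0


def test_error_population_observed_share_converges():
    """Cross-section opposed share -> x(1-0.6mu) + (1-x)0.4mu."""
    x, mu, n = 0.3, 0.5, 200_000
    obs, _ = simulate_error_model_population(x, mu, n=n, W=2, seed=3)
    expected = x * (1 - 0.6 * mu) + (1 - x) * 0.4 * mu
    se = np.sqrt(expected * (1 - expected) / (n * 2))
    assert abs(obs.mean() - expected) < 3 * se
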