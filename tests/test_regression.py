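"""Standardization, Tjur's R2, binary fits and nested-model comparison."""

import numpy as np
import pandas as pd
import pytest

from vaxdyn import (
    BinaryAttitudeModel,
    ModelSpec,
    compare_models,
    fit_binary_model,
    standardize,
    tjur_r2,
)
from vaxdyn.regression import build_design, compute_outcome

from conftest import make_panel, trajectory_panel


# -- standardize ------------------------------------------------------------


def test_standardize_small_column_sample_sd():
    out, rec = standardize(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
    np.testing.assert_allclose(out["v"], [-1.0, 0.0, 1.0])  # sample SD = 1
    assert rec.loc["v", "mean"] == 2.0
    assert rec.loc["v", "sd"] == 1.0


def test_standardize_is_idempotent(rng):
    frame = pd.DataFrame({"v": rng.normal(3, 2, 1000)})
    once, _ = standardize(frame)
    twice, _ = standardize(once)
    np.testing.assert_allclose(once["v"], twice["v"], atol=1e-12)
    assert abs(once["v"].mean()) < 1e-12
    assert once["v"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardize_zero_variance_names_column():
    with pytest.raises(ValueError, match="flat"):
        standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))


def test_standardize_inverse_transform(rng):
    frame = pd.DataFrame({"v": rng.normal(-5, 7, 50)})
    out, rec = standardize(frame)
    back = out["v"] * rec.loc["v", "sd"] + rec.loc["v", "mean"]
    np.testing.assert_allclose(back, frame["v"], atol=1e-12)


# -- Tjur's R2 --------------------------------------------------------------


def test_tjur_worked_example():
    """Group predicted means 0.18 (ones) and 0.03 (zeros) give exactly 0.15."""
    p = np.array([0.18, 0.18, 0.03, 0.03, 0.03])
    y = np.array([1, 1, 0, 0, 0])
    assert tjur_r2(p, y) == pytest.approx(0.15, abs=1e-15)


def test_tjur_perfect_and_constant_predictions():
    y = np.array([1, 0, 1, 0])
    assert tjur_r2(y.astype(float), y) == 1.0
    assert tjur_r2(np.full(4, 0.5), y) == 0.0


def test_tjur_single_class_errors():
    with pytest.raises(ValueError):
        tjur_r2(np.array([0.5, 0.5]), np.array([1, 1]))


def test_tjur_equals_r2_for_linear_probability_model(rng):
    """Coefficient of discrimination == fraction of variance explained (OLS)."""
    import statsmodels.api as sm

    n = 2000
    X = rng.normal(size=(n, 3))
    y = (X @ [0.8, -0.5, 0.2] + rng.normal(size=n) > 0).astype(float)
    res = sm.OLS(y, sm.add_constant(X)).fit()
    assert tjur_r2(res.fittedvalues, y) == pytest.approx(res.rsquared, abs=1e-10)


# -- outcomes and design ----------------------------------------------------


def _belief_panel(rng, n=800, beta=1.5, socio_beta=0.0):
    """Panel whose consistent opposition follows a logit in one belief."""
    trust = rng.normal(size=n)
    female = rng.random(n) < 0.5
    eta = -1.5 - beta * trust + socio_beta * female
    p = 1 / (1 + np.exp(-eta))
    opposed = rng.random(n) < p
    rows = []
    covs = {}
    for i in range(n):
        lv = 0 if opposed[i] else 4
        covs[f"p{i}"] = {
            "trust": trust[i],
            "gender": "female" if female[i] else "male",
        }
        for w in (1, 2, 3):
            rows.append((f"p{i}", w, lv, lv))
    return make_panel(rows, covariates=covs), beta


def test_compute_outcome_consistent_opposition():
    panel = trajectory_panel([[0, 1, 0], [0, 4, 0], [3, 3, 3]])
    y = compute_outcome(panel, ModelSpec(outcome="consistently_opposed"))
    assert y.to_dict() == {"p0": 1, "p1": 0, "p2": 0}


def test_compute_outcome_switching_risk_set():
    panel = trajectory_panel([[0, 0, 3], [1, 1, 1], [3, 0, 4], [4, 4, 4]])
    y = compute_outcome(
        panel, ModelSpec(outcome="moved_opposed_to_willing", from_wave=2, to_wave=3)
    )
    # risk set: opposed at wave 2 -> p0, p1, p2
    assert y.to_dict() == {"p0": 1, "p1": 0, "p2": 1}


def test_design_standardizes_numerics_and_codes_categoricals(rng):
    panel, _ = _belief_panel(rng, n=200)
    X, y = build_design(panel, ModelSpec(sociodemographics=["gender"], beliefs=["trust"]))
    assert "const" in X.columns
    assert abs(X["trust"].mean()) < 1e-10
    assert X["trust"].std(ddof=1) == pytest.approx(1.0)
    assert any(c.startswith("gender_") for c in X.columns)


def test_predictor_sets_must_be_disjoint():
    with pytest.raises(ValueError, match="overlap"):
        ModelSpec(sociodemographics=["age"], beliefs=["age"])


# -- fits -------------------------------------------------------------------


def test_logit_coefficient_recovery(rng):
    """Known standardized logit coefficient recovered within 3 SEs."""
    panel, beta = _belief_panel(rng, n=10_000, beta=1.2)
    rep = fit_binary_model(panel, ModelSpec(beliefs=["trust"]))
    est = rep.coefficients.loc["trust"]
    # trust ~ N(0,1): standardized coefficient ~= -beta
    assert abs(est["coef"] - (-beta)) < 3 * est["se"]
    assert est["ci_low"] < -beta < est["ci_high"]
    assert rep.pseudo_r2 is not None and 0 < rep.pseudo_r2 < 1


def test_null_simulation_coverage(rng):
    """With no true effect, ~95% of replicates cover 0 (>= 90% asserted)."""
    cover = 0
    reps = 40
    for _ in range(reps):
        panel, _ = _belief_panel(rng, n=400, beta=0.0)
        rep = fit_binary_model(panel, ModelSpec(beliefs=["trust"]))
        lo, hi = rep.coefficients.loc["trust", ["ci_low", "ci_high"]]
        cover += lo <= 0 <= hi
    assert cover / reps >= 0.9


def test_degenerate_outcome_errors():
    panel = trajectory_panel([[0, 0, 0], [1, 1, 1]])
    with pytest.raises(ValueError, match="degenerate"):
        fit_binary_model(panel, ModelSpec())


def test_linear_probability_model_reports_no_pseudo_r2(rng):
    panel, _ = _belief_panel(rng, n=500)
    rep = fit_binary_model(
        panel, ModelSpec(beliefs=["trust"], estimator="linear_probability")
    )
    assert rep.pseudo_r2 is None
    # LPM identity: Tjur R2 == R2 of the fit
    resid = rep.outcome.to_numpy() - rep.fitted.to_numpy()
    ss_res = (resid ** 2).sum()
    y = rep.outcome.to_numpy().astype(float)
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert rep.tjur_r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)


def test_sklearn_wrapper_api(rng):
    panel, _ = _belief_panel(rng, n=300)
    model = BinaryAttitudeModel(beliefs=("trust",))
    model.set_params(estimator="linear_probability").fit(panel)
    assert model.tjur_r2_ > 0.1
    assert "trust" in model.params_.index


# -- nested comparison ------------------------------------------------------


def test_belief_driven_outcome_full_model_dominates(rng):
    panel, _ = _belief_panel(rng, n=3000, beta=1.5, socio_beta=0.0)
    cmp = compare_models(
        panel, "consistently_opposed", "voluntary",
        sociodemographics=["gender"], beliefs=["trust"],
    )
    assert cmp.sociodemographic_only.tjur_r2 < 0.02
    assert cmp.full.tjur_r2 > cmp.sociodemographic_only.tjur_r2 + 0.1
    assert cmp.delta_tjur_r2 == pytest.approx(
        cmp.full.tjur_r2 - cmp.sociodemographic_only.tjur_r2
    )
    assert cmp.full.n == cmp.sociodemographic_only.n == cmp.n


def test_sociodemographic_outcome_models_agree(rng):
    panel, _ = _belief_panel(rng, n=3000, beta=0.0, socio_beta=1.5)
    cmp = compare_models(
        panel, "consistently_opposed", "voluntary",
        sociodemographics=["gender"], beliefs=["trust"],
    )
    assert abs(cmp.delta_tjur_r2) < 0.02


def test_pure_noise_outcome_both_near_zero(rng):
    panel, _ = _belief_panel(rng, n=3000, beta=0.0, socio_beta=0.0)
    cmp = compare_models(
        panel, "consistently_opposed", "voluntary",
        sociodemographics=["gender"], beliefs=["trust"],
    )
    assert cmp.full.tjur_r2 < 0.02
    assert cmp.sociodemographic_only.tjur_r2 < 0.02


def test_belief_changes_enter_design(default_panel):
    panel, _ = default_panel
    spec = ModelSpec(
        outcome="moved_opposed_to_willing",
        beliefs=["trust_institutions"],
        include_belief_changes=True,
        belief_wave=2,
    )
    X, y = build_design(panel, spec)
    assert "trust_institutions_change" in X.columns
    assert y.isin([0, 1]).all()
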