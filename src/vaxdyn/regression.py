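"""Binary attitude models: logit / linear-probability fits with Tjur's R2.

Two outcomes are supported: being consistently opposed across all waves, and
moving out of opposition (opposed at one wave, willing at the next). Numeric
predictors are standardized (mean 0, SD 1, sample SD) so coefficients are
comparable; categorical predictors enter as treatment-coded indicators.

Tjur's R2 — the coefficient of discrimination — is the difference in mean
predicted probability between observed positives and negatives. For a
linear-probability model fit by least squares with an intercept it equals
the regression's fraction of variance explained exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .classify import _category_frame
from .panel import PanelTable

OUTCOMES = ("consistently_opposed", "moved_opposed_to_willing")


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect separation) or the fit diverged."""


def standardize(frame: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale numeric columns to mean 0, SD 1 (sample SD by default).

    Returns the scaled frame and a scaling record (mean/sd per column)
    sufficient to invert the transform. Zero-variance columns raise, naming
    the column.
    """
    out = frame.copy()
    rec = {}
    for col in frame.columns:
        v = frame[col].astype(float)
        sd = v.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        m = v.mean()
        out[col] = (v - m) / sd
        rec[col] = {"mean": m, "sd": sd}
    return out, pd.DataFrame(rec).T


def tjur_r2(predicted: np.ndarray, outcome: np.ndarray) -> float:
    """Coefficient of discrimination: mean(p | y=1) - mean(p | y=0)."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome)
    if set(np.unique(y)) - {0, 1, True, False}:
        raise ValueError("outcome must be binary 0/1")
    y = y.astype(bool)
    if y.all() or (~y).all():
        raise ValueError("outcome has a single class; Tjur's R2 undefined")
    return float(p[y].mean() - p[~y].mean())


@dataclass
class ModelSpec:
    """What to fit: outcome, regime, predictor sets, estimator.

    ``sociodemographics`` and ``beliefs`` are disjoint covariate-name lists;
    belief names may refer to per-wave columns, in which case the level at
    ``belief_wave`` and (optionally) the change to the following wave are
    used as predictors.
    """

    outcome: str = "consistently_opposed"
    regime: str = "voluntary"
    sociodemographics: list = field(default_factory=list)
    beliefs: list = field(default_factory=list)
    estimator: str = "logit"
    belief_wave: int = 2
    include_belief_changes: bool = False
    from_wave: int = 2  # for the switching outcome: opposed here ...
    to_wave: int = 3    # ... willing here

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.estimator not in ("logit", "linear_probability"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        overlap = set(self.sociodemographics) & set(self.beliefs)
        if overlap:
            raise ValueError(f"predictor sets overlap: {sorted(overlap)}")


@dataclass
class RegressionReport:
    """Fit summary: standardized coefficients, CIs, fit statistics."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # columns: coef, se, ci_low, ci_high
    tjur_r2: float
    pseudo_r2: float | None  # McFadden, logit only
    n: int
    converged: bool
    fitted: pd.Series  # predicted probabilities, indexed by respondent id
    outcome: pd.Series


def compute_outcome(panel: PanelTable, spec: ModelSpec) -> pd.Series:
    """Binary outcome per respondent (NA where not computable/not in risk set)."""
    cats = _category_frame(panel, spec.regime, vaccinated_policy="as_willing")
    if spec.outcome == "consistently_opposed":
        complete = cats.dropna()
        y = (complete == "opposed").all(axis=1).astype(int)
    else:  # moved_opposed_to_willing: risk set = opposed at from_wave
        a, b = f"w{spec.from_wave}", f"w{spec.to_wave}"
        pair = cats[[a, b]].dropna()
        risk = pair[pair[a] == "opposed"]
        if len(risk) == 0:
            raise ValueError(f"nobody opposed at wave {spec.from_wave}")
        y = (risk[b] == "willing").astype(int)
    return y


def build_design(panel: PanelTable, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (standardized numerics, indicator-coded categoricals) and outcome.

    List-wise deletion over the outcome and every predictor; the returned
    design carries an intercept column.
    """
    y = compute_outcome(panel, spec)
    cov = panel.covariates()

    pieces = []
    for name in spec.sociodemographics + spec.beliefs:
        per_wave = _per_wave_values(panel, name)
        if per_wave is not None and name in spec.beliefs:
            col = per_wave[spec.belief_wave].rename(name)
            pieces.append(col)
            if spec.include_belief_changes and spec.belief_wave + 1 in per_wave:
                delta = per_wave[spec.belief_wave + 1] - per_wave[spec.belief_wave]
                pieces.append(delta.rename(f"{name}_change"))
        elif name in cov.columns:
            pieces.append(cov[name])
        else:
            raise ValueError(f"predictor {name!r} not found among covariates")
    X = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=cov.index)

    frame = X.join(y.rename("_y"), how="inner").dropna()
    if len(frame) == 0:
        raise ValueError("no complete cases after list-wise deletion")
    y = frame.pop("_y").astype(int)

    numeric = frame.select_dtypes(include=[np.number]).columns.tolist()
    categorical = [c for c in frame.columns if c not in numeric]
    parts = []
    if numeric:
        scaled, _ = standardize(frame[numeric])
        parts.append(scaled)
    if categorical:
        parts.append(
            pd.get_dummies(frame[categorical], drop_first=True, dtype=float)
        )
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=frame.index)
    X.insert(0, "const", 1.0)
    return X, y


def _per_wave_values(panel: PanelTable, name: str) -> dict[int, pd.Series] | None:
    """If a covariate varies across waves, return {wave: per-id Series}."""
    if name not in panel.data.columns:
        return None
    wide = panel.data.pivot(index="id", columns="wave", values=name)
    if wide.nunique(axis=1, dropna=True).max() <= 1:
        return None
    return {int(w): wide[w] for w in wide.columns}


class BinaryAttitudeModel(BaseEstimator):
    """Sklearn-style wrapper: logit / LPM on a panel-defined binary outcome.

    Parameters mirror :class:`ModelSpec`. After ``fit(panel)`` the report is
    in ``report_``, coefficients in ``params_`` and Tjur's R2 in ``tjur_r2_``.
    """

    def __init__(
        self,
        outcome: str = "consistently_opposed",
        regime: str = "voluntary",
        sociodemographics: tuple = (),
        beliefs: tuple = (),
        estimator: str = "logit",
        belief_wave: int = 2,
        include_belief_changes: bool = False,
        from_wave: int = 2,
        to_wave: int = 3,
    ):
        self.outcome = outcome
        self.regime = regime
        self.sociodemographics = sociodemographics
        self.beliefs = beliefs
        self.estimator = estimator
        self.belief_wave = belief_wave
        self.include_belief_changes = include_belief_changes
        self.from_wave = from_wave
        self.to_wave = to_wave

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            outcome=self.outcome,
            regime=self.regime,
            sociodemographics=list(self.sociodemographics),
            beliefs=list(self.beliefs),
            estimator=self.estimator,
            belief_wave=self.belief_wave,
            include_belief_changes=self.include_belief_changes,
            from_wave=self.from_wave,
            to_wave=self.to_wave,
        )

    def fit(self, panel: PanelTable, y=None) -> "BinaryAttitudeModel":
        spec = self._spec()
        X, yy = build_design(panel, spec)
        self.report_ = _fit(X, yy, spec)
        self.params_ = self.report_.coefficients["coef"]
        self.tjur_r2_ = self.report_.tjur_r2
        return self

    def predict_proba_frame(self) -> pd.Series:
        return self.report_.fitted


def _fit(X: pd.DataFrame, y: pd.Series, spec: ModelSpec) -> RegressionReport:
    if y.nunique() < 2:
        raise ValueError("outcome is degenerate (single class)")
    if spec.estimator == "logit":
        model = sm.Logit(y.to_numpy(), X.to_numpy())
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(f"logit fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise SeparationError("logit did not converge (possible separation)")
        if np.abs(res.params).max() > 50:
            raise SeparationError("implausibly large coefficients: perfect separation")
        fitted = res.predict(X.to_numpy())
        pseudo = float(res.prsquared)
        converged = True
    else:
        res = sm.OLS(y.to_numpy().astype(float), X.to_numpy()).fit()
        fitted = res.fittedvalues
        pseudo = None
        converged = True

    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    coef = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=X.columns,
    )
    return RegressionReport(
        spec=spec,
        coefficients=coef,
        tjur_r2=tjur_r2(fitted, y.to_numpy()),
        pseudo_r2=pseudo,
        n=len(y),
        converged=converged,
        fitted=pd.Series(fitted, index=y.index),
        outcome=y,
    )


def fit_binary_model(panel: PanelTable, spec: ModelSpec) -> RegressionReport:
    """Function wrapper over :class:`BinaryAttitudeModel`."""
    X, y = build_design(panel, spec)
    return _fit(X, y, spec)


@dataclass
class ModelComparison:
    """Full (beliefs + sociodemographics) vs sociodemographics-only fits."""

    full: RegressionReport
    sociodemographic_only: RegressionReport
    delta_tjur_r2: float
    n: int


def compare_models(
    panel: PanelTable,
    outcome: str,
    regime: str,
    sociodemographics: list,
    beliefs: list,
    estimator: str = "logit",
    **spec_kwargs,
) -> ModelComparison:
    """Relative explanatory power of beliefs beyond sociodemographics.

    Both models are estimated on the *identical* sample: list-wise deletion
    over the union of all predictors, enforced before either fit.
    """
    full_spec = ModelSpec(
        outcome=outcome, regime=regime, sociodemographics=sociodemographics,
        beliefs=beliefs, estimator=estimator, **spec_kwargs,
    )
    X_full, y = build_design(panel, full_spec)

    socio_spec = ModelSpec(
        outcome=outcome, regime=regime, sociodemographics=sociodemographics,
        beliefs=[], estimator=estimator, **spec_kwargs,
    )
    X_socio_all, y_socio = build_design(panel, socio_spec)
    # restrict the nested model to the full model's estimation sample
    common = X_full.index.intersection(X_socio_all.index)
    if not X_full.index.equals(X_socio_all.index):
        X_socio = X_socio_all.loc[common]
        y_socio = y_socio.loc[common]
        X_full = X_full.loc[common]
        y = y.loc[common]
    else:
        X_socio = X_socio_all
    if not y.equals(y_socio):
        raise ValueError("estimation samples diverge between nested models")

    full = _fit(X_full, y, full_spec)
    socio = _fit(X_socio, y, socio_spec)
    return ModelComparison(
        full=full,
        sociodemographic_only=socio,
        delta_tjur_r2=full.tjur_r2 - socio.tjur_r2,
        n=len(y),
    )
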