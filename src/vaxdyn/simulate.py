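"""Synthetic three-wave attitude panels with known ground truth.

The generator emulates the structure the downstream analyses assume: each
respondent carries a latent Likert attitude per regime that evolves between
waves as a Markov chain (optionally covariate-dependent through a
multinomial-logit shift), the *observed* response equals the latent one with
probability 1 - mu and is uniform over the five levels with probability mu,
and latently willing respondents may be vaccinated twice by the final wave —
in which case their attitude responses are missing, as in the survey.

Ground truth (latent levels, misreport flags) is returned alongside the
observable panel so parameter-recovery tests can compare against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel import PanelTable

LEVELS = np.arange(5)

# Default initial Likert distributions. Voluntary: ~20% opposed (levels 0-1),
# ~13% undecided, ~67% willing; mandated: ~29% opposed — the opposition levels
# of a first-wave cross-section of the kind the analyses target.
DEFAULT_INITIAL = {
    "voluntary": np.array([0.12, 0.08, 0.13, 0.17, 0.50]),
    "mandated": np.array([0.20, 0.09, 0.16, 0.15, 0.40]),
}

# Default transition matrices. Voluntary opposition is transient (large
# upward flow out of levels 0-1); mandated opposition is sticky.
DEFAULT_TRANSITIONS = {
    "voluntary": np.array(
        [
            [0.35, 0.15, 0.15, 0.15, 0.20],
            [0.10, 0.20, 0.25, 0.25, 0.20],
            [0.06, 0.10, 0.34, 0.30, 0.20],
            [0.02, 0.04, 0.12, 0.42, 0.40],
            [0.01, 0.02, 0.05, 0.12, 0.80],
        ]
    ),
    "mandated": np.array(
        [
            [0.60, 0.15, 0.10, 0.08, 0.07],
            [0.25, 0.30, 0.20, 0.15, 0.10],
            [0.12, 0.15, 0.38, 0.20, 0.15],
            [0.05, 0.08, 0.17, 0.40, 0.30],
            [0.02, 0.04, 0.09, 0.15, 0.70],
        ]
    ),
}


@dataclass
class CovariateSpec:
    """One covariate: name, kind ('categorical'|'numeric') and parameters.

    Categorical params: ``levels`` (labels) and ``probs``. Numeric params:
    ``mean``, ``sd`` and optional ``lo``/``hi`` clipping; ``per_wave=True``
    makes the value evolve as a random walk with step sd ``walk_sd``.
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    per_wave: bool = False
    walk_sd: float = 0.3


def default_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("age", "numeric", {"mean": 53.0, "sd": 14.0, "lo": 18, "hi": 95}),
        CovariateSpec("gender", "categorical",
                      {"levels": ["female", "male"], "probs": [0.47, 0.53]}),
        CovariateSpec("region", "categorical",
                      {"levels": ["West", "East"], "probs": [0.79, 0.21]}),
        CovariateSpec("education", "categorical",
                      {"levels": ["low", "mid", "high"], "probs": [0.30, 0.45, 0.25]}),
        CovariateSpec("trust_institutions", "numeric", {"mean": 0.0, "sd": 1.0},
                      per_wave=True),
        CovariateSpec("vaccine_effectiveness", "numeric", {"mean": 0.0, "sd": 1.0},
                      per_wave=True),
    ]


@dataclass
class CovariateTransitionModel:
    """Multinomial-logit tilt of a baseline transition matrix.

    Destination logits for a respondent in origin state i are
    ``log P0[i, j] + s_j * sum_c beta_c * z_c`` where ``s_j = (j - 2) / 2``
    scores destinations from -1 (level 0) to +1 (level 4): a positive
    coefficient on a covariate pushes that respondent's transitions toward
    willingness.
    """

    baseline: np.ndarray
    coefs: dict = field(default_factory=dict)

    def rows(self, origin: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
        """Per-respondent transition rows, shape (n, 5)."""
        P0 = np.asarray(self.baseline, dtype=float)
        tilt = np.zeros(len(origin))
        for name, beta in self.coefs.items():
            tilt = tilt + beta * covariates[name].to_numpy(dtype=float)
        scores = (LEVELS - 2) / 2.0
        with np.errstate(divide="ignore"):
            logit = np.log(P0[origin])  # -inf where baseline mass is 0
        logit = logit + tilt[:, None] * scores[None, :]
        logit -= logit.max(axis=1, keepdims=True)
        w = np.exp(logit)
        return w / w.sum(axis=1, keepdims=True)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic panel.

    Defaults emulate a ~2,018-respondent three-wave panel: voluntary
    opposition transient and drifting down, mandated opposition sticky, no
    misreport contamination (``misreport_rate=0``) and wave-3 double
    vaccination among ~9% of the latently willing, yielding ~6-7% of the
    panel vaccinated twice.
    """

    n_respondents: int = 2018
    n_waves: int = 3
    initial_distribution: dict = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_INITIAL.items()}
    )
    transition_model: dict = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_TRANSITIONS.items()}
    )
    misreport_rate: float = 0.0
    misreport_shared_across_regimes: bool = False
    covariate_spec: list = field(default_factory=default_covariates)
    uptake_probability: float = 0.09
    partial_uptake_probability: float = 0.05
    coupling_strength: float = 0.0
    regime_offset: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.misreport_rate <= 1:
            raise ValueError(f"misreport_rate {self.misreport_rate} outside [0,1]")
        for reg, v in self.initial_distribution.items():
            v = np.asarray(v, dtype=float)
            if abs(v.sum() - 1) > 1e-12 or (v < 0).any():
                raise ValueError(f"initial distribution for {reg} is not a probability vector")
            self.initial_distribution[reg] = v
        for reg, tm in self.transition_model.items():
            if isinstance(tm, CovariateTransitionModel):
                mat = np.asarray(tm.baseline, dtype=float)
            else:
                mat = np.asarray(tm, dtype=float)
                self.transition_model[reg] = mat
            if mat.shape != (5, 5) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"transition matrix for {reg} is not 5x5 row-stochastic")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariate_spec" in raw:
            raw["covariate_spec"] = [CovariateSpec(**c) for c in raw["covariate_spec"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["initial_distribution"] = {
            k: [float(x) for x in v] for k, v in self.initial_distribution.items()
        }
        raw["transition_model"] = {
            k: np.asarray(v.baseline if isinstance(v, CovariateTransitionModel) else v)
            .tolist()
            for k, v in self.transition_model.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _draw_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    """n draws from a discrete distribution via inverse CDF (vectorized)."""
    cum = np.cumsum(probs)
    u = rng.random(n)
    return np.searchsorted(cum, u, side="right").clip(0, len(probs) - 1)


def _draw_rows(rng, rows: np.ndarray) -> np.ndarray:
    """One draw per row of a stack of probability vectors."""
    cum = np.cumsum(rows, axis=1)
    u = rng.random(len(rows))
    return (u[:, None] > cum).sum(axis=1).clip(0, rows.shape[1] - 1)


def simulate_panel(config: SimulationConfig) -> tuple[PanelTable, pd.DataFrame]:
    """Generate an observable panel plus its ground truth.

    Returns
    -------
    panel : PanelTable
        Long-format observable data (missing attitudes where the respondent
        was vaccinated twice or hit the missingness process).
    truth : pandas.DataFrame
        One row per respondent x wave: latent levels and misreport flags per
        regime. Never fed to the analyses — used only to verify recovery.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, W = cfg.n_respondents, cfg.n_waves
    ids = np.array([f"r{i:05d}" for i in range(n)])

    # covariates: sociodemographics fixed, per-wave beliefs random-walk
    cov_static: dict[str, np.ndarray] = {}
    cov_wave: dict[str, np.ndarray] = {}  # name -> (n, W)
    for spec in cfg.covariate_spec:
        if spec.kind == "categorical":
            idx = _draw_categorical(rng, np.asarray(spec.params["probs"], float), n)
            cov_static[spec.name] = np.asarray(spec.params["levels"], object)[idx]
        elif spec.kind == "numeric":
            v = rng.normal(spec.params.get("mean", 0.0), spec.params.get("sd", 1.0), n)
            if "lo" in spec.params or "hi" in spec.params:
                v = np.clip(v, spec.params.get("lo", -np.inf), spec.params.get("hi", np.inf))
            if spec.per_wave:
                path = np.empty((n, W))
                path[:, 0] = v
                for w in range(1, W):
                    path[:, w] = path[:, w - 1] + rng.normal(0, spec.walk_sd, n)
                cov_wave[spec.name] = path
            else:
                cov_static[spec.name] = v
        else:
            raise ValueError(f"unknown covariate kind {spec.kind!r}")

    # latent chains
    latent = {}
    for reg in ("voluntary", "mandated"):
        latent[reg] = np.empty((n, W), dtype=int)
    latent["voluntary"][:, 0] = _draw_categorical(rng, cfg.initial_distribution["voluntary"], n)
    man0 = _draw_categorical(rng, cfg.initial_distribution["mandated"], n)
    if cfg.coupling_strength > 0:
        # with prob rho the mandated start tracks the voluntary one shifted down
        coupled = rng.random(n) < cfg.coupling_strength
        shifted = np.clip(latent["voluntary"][:, 0] - cfg.regime_offset, 0, 4)
        man0 = np.where(coupled, shifted, man0)
    latent["mandated"][:, 0] = man0

    for reg in ("voluntary", "mandated"):
        tm = cfg.transition_model[reg]
        for w in range(1, W):
            origin = latent[reg][:, w - 1]
            if isinstance(tm, CovariateTransitionModel):
                covs = dict(cov_static)
                for k, v in cov_wave.items():
                    covs[k] = v[:, w - 1]
                rows = tm.rows(origin, pd.DataFrame(covs))
            else:
                rows = np.asarray(tm)[origin]
            latent[reg][:, w] = _draw_rows(rng, rows)

    # misreport contamination
    observed = {reg: latent[reg].copy() for reg in latent}
    flags = {}
    if cfg.misreport_shared_across_regimes:
        shared = rng.random((n, W)) < cfg.misreport_rate
        flags = {"voluntary": shared, "mandated": shared.copy()}
    else:
        flags = {reg: rng.random((n, W)) < cfg.misreport_rate for reg in ("voluntary", "mandated")}
    for reg in ("voluntary", "mandated"):
        noise = rng.integers(0, 5, size=(n, W))
        observed[reg] = np.where(flags[reg], noise, observed[reg])

    # vaccination uptake at the final wave among the latently willing
    willing_final = latent["voluntary"][:, W - 1] >= 3
    u = rng.random(n)
    twice = willing_final & (u < cfg.uptake_probability)
    once = willing_final & ~twice & (u < cfg.uptake_probability + cfg.partial_uptake_probability)
    vax = np.full((n, W), "unvaccinated", dtype=object)
    vax[twice, W - 1] = "twice"
    vax[once, W - 1] = "once"

    # independent item missingness, if any
    miss = {
        reg: rng.random((n, W)) < cfg.missing_rate for reg in ("voluntary", "mandated")
    }

    rows = []
    for w in range(W):
        rec = {
            "id": ids,
            "wave": np.full(n, w + 1),
            "vol_likert": observed["voluntary"][:, w].astype(float),
            "man_likert": observed["mandated"][:, w].astype(float),
            "vax_status": vax[:, w],
        }
        for reg, col in (("voluntary", "vol_likert"), ("mandated", "man_likert")):
            gone = miss[reg][:, w] | (vax[:, w] == "twice")
            rec[col] = np.where(gone, np.nan, rec[col])
        for k, v in cov_static.items():
            rec[k] = v
        for k, v in cov_wave.items():
            rec[k] = v[:, w]
        rows.append(pd.DataFrame(rec))
    long = pd.concat(rows, ignore_index=True).sort_values(["id", "wave"]).reset_index(drop=True)
    for col in ("vol_likert", "man_likert"):
        long[col] = long[col].astype("Float64").astype("Int64")

    truth_rows = []
    for w in range(W):
        truth_rows.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "wave": np.full(n, w + 1),
                    "true_vol": latent["voluntary"][:, w],
                    "true_man": latent["mandated"][:, w],
                    "misreport_vol": flags["voluntary"][:, w],
                    "misreport_man": flags["mandated"][:, w],
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True).sort_values(["id", "wave"]).reset_index(drop=True)

    panel = PanelTable(
        long,
        wave_count=W,
        metadata={"seed": cfg.seed, "generator": "vaxdyn.simulate", "n": n},
    )
    return panel, truth


def simulate_error_model_population(
    x: float,
    mu: float,
    n: int,
    W: int = 3,
    seed: int | None = None,
    p_opp: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw observed opposition indicators under the misreport model.

    A fraction ``x`` of respondents is truly (invariantly) opposed. Per wave,
    the truly opposed record opposition with probability ``1 - (1-p_opp) mu``
    and everyone else with probability ``p_opp mu``, independently across
    waves.

    Returns
    -------
    observed : bool array, shape (n, W)
        Observed opposed indicators.
    truly_opposed : bool array, shape (n,)
    """
    if not (0 <= x <= 1 and 0 <= mu <= 1):
        raise ValueError("x and mu must lie in [0,1]")
    rng = np.random.default_rng(seed)
    truly = rng.random(n) < x
    p = np.where(truly, 1 - (1 - p_opp) * mu, p_opp * mu)
    observed = rng.random((n, W)) < p[:, None]
    return observed, truly
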