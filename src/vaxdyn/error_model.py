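"""Random-misreport mixture model for consistent opposition.

Suppose a fraction x of respondents is invariantly opposed and, with
probability mu, any respondent answers by picking one of the K Likert items
uniformly at random. With an opposed response set of m items (levels {0,1} of
5 by default), a misreporting respondent lands in the opposed set with
probability m/K. A truly opposed respondent therefore records opposition with
probability 1 - (1 - m/K) mu per wave, and anyone else with probability
(m/K) mu. Matching the model to two observed moments — the share consistently
opposed over W waves (c) and the mean single-wave opposed share (a) —

    x (1 - p_not mu)^W + (1 - x) (p_opp mu)^W = c
    x (1 - p_not mu)   + (1 - x)  p_opp mu    = a

with p_opp = m/K, p_not = 1 - m/K, pins down (x, mu) on the unit square.
Because the hypothetical attributes *all* attitude change to noise, the
solved x is an upper bound on the true hard core of consistent opposition.

The solver eliminates x through the linear (cross-section) equation,

    x(mu) = (a - p_opp mu) / (1 - mu),        mu < 1,

scans the residual of the consistency equation over a dense mu grid, and
refines every sign change by bracketed root finding. All admissible roots are
reported; when several exist the smallest-mu root is primary (it attributes
the least response error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .classify import consistency_shares
from .panel import PanelTable


@dataclass(frozen=True)
class ErrorModelSpec:
    """Structural constants of the misreport model.

    K Likert categories, an opposed response set of m of them, W waves.
    Defaults (5, 2, 3) give the opposed-hit probabilities p_opp = 0.4 and
    p_not = 0.6 of the standard setting.
    """

    K: int = 5
    m: int = 2
    W: int = 3

    def __post_init__(self):
        if not (1 <= self.m < self.K):
            raise ValueError(f"need 1 <= m < K, got m={self.m}, K={self.K}")
        if self.W < 1:
            raise ValueError("need at least one wave")

    @property
    def p_opp(self) -> float:
        return self.m / self.K

    @property
    def p_not(self) -> float:
        return 1.0 - self.m / self.K


@dataclass
class ErrorModelSolution:
    """Solved (x, mu) with diagnostics.

    ``x`` is the invariant (hard-core) opposed fraction — an upper bound, since
    the model charges every attitude change to response error. ``mu`` is the
    random-response rate. ``roots`` lists every admissible (x, mu) pair found;
    ``unique`` flags whether there was exactly one.
    """

    x: float
    mu: float
    residual_consistent: float
    residual_cross_section: float
    roots: list = field(default_factory=list)
    unique: bool = True
    spec: ErrorModelSpec = field(default_factory=ErrorModelSpec)
    upper_bound_note: str = (
        "x is an upper bound on consistent opposition: the model attributes "
        "all observed attitude change to random response error"
    )

    def __post_init__(self):
        assert 0 <= self.x <= 1 and 0 <= self.mu <= 1


def forward_consistent_share(x: float, mu: float, spec: ErrorModelSpec = ErrorModelSpec()) -> float:
    """P(respond opposed in all W waves) under the misreport model."""
    _check_unit("x", x), _check_unit("mu", mu)
    return x * (1 - spec.p_not * mu) ** spec.W + (1 - x) * (spec.p_opp * mu) ** spec.W


def forward_cross_section_share(x: float, mu: float, spec: ErrorModelSpec = ErrorModelSpec()) -> float:
    """P(respond opposed in a single wave) under the misreport model."""
    _check_unit("x", x), _check_unit("mu", mu)
    return x * (1 - spec.p_not * mu) + (1 - x) * spec.p_opp * mu


def _check_unit(name, v):
    if not 0 <= v <= 1:
        raise ValueError(f"{name}={v} outside [0,1]")


class MisreportErrorModel(BaseEstimator):
    """Moment-matching estimator of (x, mu) from opposition shares.

    Parameters
    ----------
    K, m, W : int
        Likert categories, opposed-set size, number of waves.
    grid_size : int
        Points of the mu scan on [0, 1); every sign change of the consistency
        residual is refined by Brent's method.
    tol : float
        Residual tolerance a refined root must meet.

    Attributes (after fit)
    ----------------------
    x_, mu_ : float
        Primary solution (smallest admissible mu).
    solution_ : ErrorModelSolution
        Full diagnostics including all roots.

    Fit either from a panel (``fit(panel)``: the shares are computed with the
    classify machinery) or directly from observed shares
    (``fit_shares(c, a)``).
    """

    def __init__(self, K: int = 5, m: int = 2, W: int = 3,
                 grid_size: int = 100_000, tol: float = 1e-12):
        self.K = K
        self.m = m
        self.W = W
        self.grid_size = grid_size
        self.tol = tol

    @property
    def _spec(self) -> ErrorModelSpec:
        return ErrorModelSpec(K=self.K, m=self.m, W=self.W)

    def fit(self, panel: PanelTable, y=None, regime: str = "voluntary") -> "MisreportErrorModel":
        shares = consistency_shares(panel, regime)
        return self.fit_shares(
            shares.shares["consistently_opposed"], shares.mean_opposed
        )

    def fit_shares(self, consistent: float, cross_section: float) -> "MisreportErrorModel":
        self.solution_ = solve_error_model(consistent, cross_section, self._spec,
                                           grid_size=self.grid_size, tol=self.tol)
        self.x_ = self.solution_.x
        self.mu_ = self.solution_.mu
        return self


def solve_error_model(
    consistent: float,
    cross_section: float,
    spec: ErrorModelSpec = ErrorModelSpec(),
    grid_size: int = 100_000,
    tol: float = 1e-12,
) -> ErrorModelSolution:
    """Solve the two-moment system for (x, mu).

    Parameters
    ----------
    consistent : float
        Observed share opposed in every one of the W waves (c).
    cross_section : float
        Observed mean single-wave opposed share (a). Must satisfy
        ``consistent <= cross_section`` — consistency over several waves
        cannot exceed a single wave's share.

    Raises
    ------
    ValueError
        If no admissible root exists; the message carries the residual range
        scanned so the failure is diagnosable.
    """
    c, a = float(consistent), float(cross_section)
    if not (0 < c < 1) or not (0 < a < 1):
        raise ValueError(f"shares must lie in (0,1); got c={c}, a={a}")
    if c > a + 1e-12:
        raise ValueError(
            f"consistent share {c} exceeds cross-section share {a}; "
            "impossible under any (x, mu)"
        )
    p_o, p_n, W = spec.p_opp, spec.p_not, spec.W

    def x_of(mu):
        # from the linear equation: a = x(1 - p_n mu) + (1-x) p_o mu
        return (a - p_o * mu) / (1.0 - mu)

    def resid(mu):
        x = x_of(mu)
        return x * (1 - p_n * mu) ** W + (1 - x) * (p_o * mu) ** W - c

    mus = np.linspace(0.0, 1.0 - 1e-9, grid_size)
    vals = resid(mus)  # vectorized: x_of/resid are pure numpy expressions

    roots: list[tuple[float, float]] = []
    sign = np.sign(vals)
    crossings = np.where(sign[:-1] * sign[1:] <= 0)[0]
    for i in crossings:
        lo, hi = mus[i], mus[i + 1]
        if vals[i] == 0.0:
            mu_r = float(lo)
        else:
            try:
                mu_r = float(brentq(resid, lo, hi, xtol=1e-15, rtol=8.9e-16))
            except ValueError:
                continue
        x_r = float(x_of(mu_r))
        if -1e-12 <= x_r <= 1 + 1e-12 and abs(resid(mu_r)) < max(tol, 1e-10):
            x_r = min(max(x_r, 0.0), 1.0)
            if not any(abs(mu_r - m0) < 1e-9 for _, m0 in roots):
                roots.append((x_r, mu_r))

    if not roots:
        raise ValueError(
            "no admissible (x, mu) root: residual of the consistency equation "
            f"spans [{vals.min():.3g}, {vals.max():.3g}] over mu in [0,1) "
            f"with x restricted to [0,1] (c={c}, a={a}, spec={spec})"
        )

    roots.sort(key=lambda r: r[1])  # primary root = smallest mu
    x, mu = roots[0]
    return ErrorModelSolution(
        x=x,
        mu=mu,
        residual_consistent=abs(forward_consistent_share(x, mu, spec) - c),
        residual_cross_section=abs(forward_cross_section_share(x, mu, spec) - a),
        roots=roots,
        unique=len(roots) == 1,
        spec=spec,
    )
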