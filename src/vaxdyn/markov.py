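"""Attitude dynamics as a discrete-time Markov chain.

Transition matrices are estimated from paired adjacent waves by maximum
likelihood (row-wise relative frequencies). The stationary distribution pi —
the long-run equilibrium with pi P = pi, where outflow from every state is
exactly offset by inflow — is obtained by solving the linear system, with
power iteration available as an independent cross-check. Projections iterate
an initial distribution forward, the "what if these transition rates were
sustained" thought experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classify import CATEGORIES, _CAT_OF_LEVEL
from .panel import PanelTable, level_column

LIKERT_STATES = (0, 1, 2, 3, 4)

_STATE_SPACES = {
    "likert5": list(LIKERT_STATES),
    "collapsed3": list(CATEGORIES),
}


class ReducibleChainError(ValueError):
    """The chain has multiple closed communicating classes; pi is not unique."""


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix with its underlying counts.

    ``imputed_rows`` lists origin states that were never observed; per the
    default policy those rows are imputed as self-loops and flagged.
    """

    states: list
    P: np.ndarray
    counts: np.ndarray
    source_waves: tuple[int, int]
    imputed_rows: list = field(default_factory=list)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.counts = np.asarray(self.counts)
        k = len(self.states)
        if self.P.shape != (k, k):
            raise ValueError(f"P shape {self.P.shape} != ({k},{k})")
        if (self.P < -1e-15).any() or (self.P > 1 + 1e-15).any():
            raise ValueError("transition probabilities outside [0,1]")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.states, columns=self.states)


@dataclass
class StationaryDistribution:
    """Stationary vector with its fixed-point residual ``max|pi P - pi|``."""

    states: list
    pi: np.ndarray
    residual: float
    method: str

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        assert (self.pi >= -1e-12).all() and abs(self.pi.sum() - 1) < 1e-9

    def to_series(self) -> pd.Series:
        return pd.Series(self.pi, index=self.states)


class MarkovTransitionEstimator(BaseEstimator):
    """Estimate attitude transitions between two waves of a panel.

    Parameters
    ----------
    regime : {'voluntary', 'mandated'}
    from_wave, to_wave : int
        The paired waves (adjacent in the standard analysis).
    state_space : {'likert5', 'collapsed3'}
        Five Likert levels (default) or the opposed/undecided/willing collapse.
    alpha : float
        Laplace pseudocount added to every cell (0 = plain ML, the default).
    empty_row_policy : {'self_loop', 'uniform'}
        How to fill rows whose origin state was never observed; filled rows
        are flagged in ``transition_matrix_.imputed_rows``.

    Attributes
    ----------
    transition_matrix_ : TransitionMatrix
    stationary_ : StationaryDistribution
        Lazily computed on first access via `stationary_distribution`.
    """

    def __init__(
        self,
        regime: str = "voluntary",
        from_wave: int = 1,
        to_wave: int = 2,
        state_space: str = "likert5",
        alpha: float = 0.0,
        empty_row_policy: str = "self_loop",
    ):
        self.regime = regime
        self.from_wave = from_wave
        self.to_wave = to_wave
        self.state_space = state_space
        self.alpha = alpha
        self.empty_row_policy = empty_row_policy

    def fit(self, panel: PanelTable, y=None) -> "MarkovTransitionEstimator":
        if self.state_space not in _STATE_SPACES:
            raise ValueError(f"unknown state space {self.state_space!r}")
        states = _STATE_SPACES[self.state_space]
        k = len(states)
        traj = panel.trajectories(self.regime)
        a, b = f"w{self.from_wave}", f"w{self.to_wave}"
        if a not in traj.columns or b not in traj.columns:
            raise ValueError(f"waves {(self.from_wave, self.to_wave)} not in panel")
        pair = traj[[a, b]].dropna().astype(int)
        if len(pair) == 0:
            raise ValueError("no paired observations between these waves")
        src = pair[a].to_numpy()
        dst = pair[b].to_numpy()
        if self.state_space == "collapsed3":
            cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
            src = np.array([cat_idx[c] for c in _CAT_OF_LEVEL[src]])
            dst = np.array([cat_idx[c] for c in _CAT_OF_LEVEL[dst]])
        counts = np.zeros((k, k), dtype=int)
        np.add.at(counts, (src, dst), 1)

        work = counts.astype(float) + self.alpha
        row_tot = work.sum(axis=1)
        P = np.zeros((k, k))
        imputed = []
        for i in range(k):
            if row_tot[i] > 0:
                P[i] = work[i] / row_tot[i]
            else:
                imputed.append(states[i])
                if self.empty_row_policy == "self_loop":
                    P[i, i] = 1.0
                elif self.empty_row_policy == "uniform":
                    P[i] = 1.0 / k
                else:
                    raise ValueError(f"unknown policy {self.empty_row_policy!r}")
        self.transition_matrix_ = TransitionMatrix(
            states=list(states),
            P=P,
            counts=counts,
            source_waves=(self.from_wave, self.to_wave),
            imputed_rows=imputed,
        )
        return self

    @property
    def stationary_(self) -> StationaryDistribution:
        return stationary_distribution(self.transition_matrix_)


def estimate_transitions(
    panel: PanelTable,
    regime: str,
    from_wave: int,
    to_wave: int,
    state_space: str = "likert5",
    **kwargs,
) -> TransitionMatrix:
    """Function wrapper over :class:`MarkovTransitionEstimator`."""
    est = MarkovTransitionEstimator(
        regime=regime,
        from_wave=from_wave,
        to_wave=to_wave,
        state_space=state_space,
        **kwargs,
    )
    return est.fit(panel).transition_matrix_


# ---------------------------------------------------------------------------
# stationary distribution


def _closed_classes(P: np.ndarray) -> list[list[int]]:
    """Closed (recurrent) communicating classes of the chain's digraph."""
    g = nx.DiGraph()
    k = P.shape[0]
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(k):
            if P[i, j] > 0:
                g.add_edge(i, j)
    cond = nx.condensation(g)
    closed = []
    for node, members in cond.nodes(data="members"):
        if cond.out_degree(node) == 0:
            closed.append(sorted(members))
    return closed


def stationary_distribution(
    P: TransitionMatrix | np.ndarray,
    method: str = "linear",
    tol: float = 1e-10,
    max_iter: int = 10**6,
) -> StationaryDistribution:
    """Unique stationary vector of a row-stochastic matrix.

    ``method='linear'`` replaces one balance equation by the normalisation
    constraint and solves the resulting system; ``method='power'`` iterates
    ``pi <- pi P`` to the fixed point and serves as an independent check.
    A chain with more than one closed communicating class has no unique
    stationary vector; that raises :class:`ReducibleChainError` naming the
    classes.
    """
    if isinstance(P, TransitionMatrix):
        states, mat = P.states, P.P
    else:
        mat = np.asarray(P, dtype=float)
        states = list(range(mat.shape[0]))
    k = mat.shape[0]
    if mat.shape != (k, k) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be square and row-stochastic")

    closed = _closed_classes(mat)
    if len(closed) > 1:
        named = [[states[i] for i in cls] for cls in closed]
        raise ReducibleChainError(
            f"chain is reducible: {len(closed)} closed classes {named}; "
            "every mixture of their stationary vectors is stationary"
        )

    if method == "linear":
        # (P^T - I) pi = 0 with one row replaced by sum(pi) = 1
        A = mat.T - np.eye(k)
        A[-1, :] = 1.0
        b = np.zeros(k)
        b[-1] = 1.0
        pi = np.linalg.solve(A, b)
    elif method == "power":
        pi = np.full(k, 1.0 / k)
        for _ in range(max_iter):
            nxt = pi @ mat
            if np.abs(nxt - pi).max() < tol / 10:
                pi = nxt
                break
            pi = nxt
        else:
            raise RuntimeError("power iteration did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")

    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = float(np.abs(pi @ mat - pi).max())
    if residual > max(tol, 1e-10):
        raise RuntimeError(f"stationary residual {residual:g} exceeds tolerance")
    return StationaryDistribution(states=list(states), pi=pi, residual=residual, method=method)


def project(initial, P: TransitionMatrix | np.ndarray, n_steps: int) -> np.ndarray:
    """Iterate a distribution forward: row ``k`` is ``initial @ P**k``.

    Returns an ``(n_steps+1, k)`` array whose first row is the initial
    distribution; for an irreducible aperiodic chain the rows converge to the
    stationary distribution.
    """
    mat = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    v = np.asarray(initial, dtype=float)
    if v.shape != (mat.shape[0],):
        raise ValueError(f"initial shape {v.shape} does not match P {mat.shape}")
    if abs(v.sum() - 1) > 1e-9 or (v < -1e-12).any():
        raise ValueError("initial must be a probability vector")
    out = np.empty((n_steps + 1, mat.shape[0]))
    out[0] = v
    for t in range(1, n_steps + 1):
        out[t] = out[t - 1] @ mat
    return out


def bootstrap_stationary(
    panel: PanelTable,
    regime: str,
    from_wave: int,
    to_wave: int,
    state_space: str = "likert5",
    n_boot: int = 200,
    seed: int | None = None,
    **kwargs,
) -> np.ndarray:
    """Respondent-level bootstrap replicates of the stationary vector.

    Resamples respondents with replacement, re-estimates the transition
    matrix and its stationary distribution per replicate. Returns an
    ``(n_boot, k)`` array; replicates whose resampled chain is reducible are
    redrawn (they carry no unique stationary vector).
    """
    rng = np.random.default_rng(seed)
    traj = panel.trajectories(regime)
    a, b = f"w{from_wave}", f"w{to_wave}"
    pair = traj[[a, b]].dropna().astype(int).to_numpy()
    n = len(pair)
    k = len(_STATE_SPACES[state_space])
    out = np.empty((n_boot, k))
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
    done = 0
    attempts = 0
    while done < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise RuntimeError("too many reducible bootstrap replicates")
        idx = rng.integers(0, n, size=n)
        src, dst = pair[idx, 0], pair[idx, 1]
        if state_space == "collapsed3":
            src = np.array([cat_idx[c] for c in _CAT_OF_LEVEL[src]])
            dst = np.array([cat_idx[c] for c in _CAT_OF_LEVEL[dst]])
        counts = np.zeros((k, k))
        np.add.at(counts, (src, dst), 1)
        tot = counts.sum(axis=1, keepdims=True)
        P = np.where(tot > 0, counts / np.where(tot == 0, 1, tot), 0.0)
        for i in np.where(tot.ravel() == 0)[0]:
            P[i, i] = 1.0
        try:
            out[done] = stationary_distribution(P).pi
        except ReducibleChainError:
            continue
        done += 1
    return out
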