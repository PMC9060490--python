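"""End-to-end orchestration: simulate/load -> classify -> markov -> error model
-> crowding (-> regression), with a JSON summary and CSV tables.

Every output is stamped with the package version, the seed and the SHA-256
digest of the input panel, so a report bundle is traceable to its exact
inputs. Given a fixed seed the whole bundle is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import CATEGORIES, consistency_shares, switching_table
from .crowding import crowding_table, naive_uptake_prediction
from .error_model import ErrorModelSpec, solve_error_model
from .markov import MarkovTransitionEstimator, ReducibleChainError, stationary_distribution
from .panel import PanelTable, read_panel, write_panel
from .regression import compare_models
from .simulate import SimulationConfig, simulate_panel

log = logging.getLogger("vaxdyn")


@dataclass
class PipelineConfig:
    """What to run and where to put it.

    Provide either ``panel_path`` (a CSV in the canonical or a mapped schema)
    or ``simulation`` (a :class:`SimulationConfig` or kwargs for one).
    """

    panel_path: str | None = None
    schema: dict | None = None
    simulation: SimulationConfig | dict | None = None
    regimes: tuple = ("voluntary", "mandated")
    wave_pairs: tuple = ((1, 2), (2, 3))
    state_space: str = "likert5"
    error_model_inputs: list = field(default_factory=list)  # [{consistent, cross_section}, ...]
    regression: dict | None = None  # kwargs for compare_models
    out_dir: str = "vaxdyn_report"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("regimes",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "wave_pairs" in raw:
            raw["wave_pairs"] = tuple(tuple(p) for p in raw["wave_pairs"])
        return cls(**raw)


def _get_panel(cfg: PipelineConfig) -> PanelTable:
    if cfg.panel_path is not None:
        log.info("loading panel from %s", cfg.panel_path)
        return read_panel(cfg.panel_path, schema=cfg.schema)
    sim = cfg.simulation
    if sim is None:
        sim = SimulationConfig(seed=cfg.seed)
    elif isinstance(sim, dict):
        sim = SimulationConfig(**{**sim, "seed": sim.get("seed", cfg.seed)})
    log.info("simulating panel (n=%d, seed=%d)", sim.n_respondents, sim.seed)
    panel, _ = simulate_panel(sim)
    return panel


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; write tables + summary; return the summary."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = _get_panel(config)
    stamp = {
        "package": "vaxdyn",
        "version": __version__,
        "seed": config.seed,
        "input_digest": panel.digest(),
        "n_respondents": panel.n_respondents,
        "wave_count": panel.wave_count,
    }
    summary: dict = {"schema_version": 1, "stamp": stamp}

    write_panel(panel, out / "panel.csv")

    for regime in config.regimes:
        reg_sum: dict = {}
        try:
            shares = consistency_shares(panel, regime)
        except ValueError as exc:
            raise RuntimeError(f"stage classify[{regime}] failed: {exc}") from exc
        reg_sum["consistency"] = {
            "shares": shares.shares,
            "counts": shares.counts,
            "opposed_by_wave": shares.opposed_by_wave,
            "mean_opposed": shares.mean_opposed,
            "n": shares.n,
        }

        reg_sum["switching"] = {}
        reg_sum["transitions"] = {}
        for a, b in config.wave_pairs:
            key = f"w{a}->w{b}"
            tables = {}
            for cat in ("opposed", "willing"):
                try:
                    t = switching_table(panel, regime, a, b, cat)
                    tables[cat] = {"shares": t.shares, "counts": t.counts, "n": t.n}
                except ValueError as exc:
                    tables[cat] = {"error": str(exc)}
            reg_sum["switching"][key] = tables

            try:
                est = MarkovTransitionEstimator(
                    regime=regime, from_wave=a, to_wave=b, state_space=config.state_space
                ).fit(panel)
            except ValueError as exc:
                raise RuntimeError(f"stage markov[{regime} {key}] failed: {exc}") from exc
            tm = est.transition_matrix_
            tm.to_frame().to_csv(out / f"transitions_{regime}_{a}{b}.csv")
            entry = {
                "states": [str(s) for s in tm.states],
                "P": tm.P.tolist(),
                "counts": tm.counts.tolist(),
                "imputed_rows": [str(s) for s in tm.imputed_rows],
            }
            try:
                st = stationary_distribution(tm)
                entry["stationary"] = st.pi.tolist()
                entry["stationary_residual"] = st.residual
            except ReducibleChainError as exc:
                entry["stationary_error"] = str(exc)
            reg_sum["transitions"][key] = entry

        # misreport bound from this panel's own shares
        c = reg_sum["consistency"]["shares"]["consistently_opposed"]
        a_share = reg_sum["consistency"]["mean_opposed"]
        try:
            sol = solve_error_model(c, a_share, ErrorModelSpec(W=panel.wave_count))
            reg_sum["error_model"] = _solution_dict(sol)
        except ValueError as exc:
            reg_sum["error_model"] = {"error": str(exc)}

        summary[regime] = reg_sum

    # crowding at the final wave
    final = panel.wave_count
    summary["crowding"] = {}
    for cat in CATEGORIES:
        try:
            t = crowding_table(panel, final, cat)
            summary["crowding"][cat] = {
                "conditioning_share": t.conditioning_share,
                "destination_shares": t.destination_shares,
                "counts": t.counts,
                "net_effect": t.net_effect,
            }
        except ValueError as exc:
            summary["crowding"][cat] = {"error": str(exc)}
    summary["naive_uptake_prediction"] = naive_uptake_prediction(panel, final)

    # externally supplied (consistent, cross-section) share pairs
    if config.error_model_inputs:
        sols = []
        for item in config.error_model_inputs:
            spec = ErrorModelSpec(
                K=item.get("K", 5), m=item.get("m", 2), W=item.get("W", 3)
            )
            sol = solve_error_model(item["consistent"], item["cross_section"], spec)
            d = _solution_dict(sol)
            d["inputs"] = {"consistent": item["consistent"], "cross_section": item["cross_section"]}
            sols.append(d)
        summary["error_model_external"] = sols

    if config.regression:
        try:
            cmp = compare_models(panel, **config.regression)
            summary["regression"] = {
                "tjur_r2_full": cmp.full.tjur_r2,
                "tjur_r2_sociodemographic": cmp.sociodemographic_only.tjur_r2,
                "delta_tjur_r2": cmp.delta_tjur_r2,
                "n": cmp.n,
                "coefficients_full": cmp.full.coefficients["coef"].to_dict(),
            }
            cmp.full.coefficients.to_csv(out / "regression_full.csv")
            cmp.sociodemographic_only.coefficients.to_csv(out / "regression_socio.csv")
        except Exception as exc:
            raise RuntimeError(f"stage regression failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("report bundle written to %s", out)
    return summary


def _solution_dict(sol) -> dict:
    return {
        "x": sol.x,
        "mu": sol.mu,
        "unique": sol.unique,
        "roots": [list(r) for r in sol.roots],
        "residual_consistent": sol.residual_consistent,
        "residual_cross_section": sol.residual_cross_section,
        "interpretation": sol.upper_bound_note,
    }
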