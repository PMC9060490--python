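import numpy as np
import pandas as pd
import pytest

from vaxdyn import PanelTable, SimulationConfig, simulate_panel


def make_panel(rows, wave_count=3, covariates=None):
    """Build a PanelTable from (id, wave, vol, man, vax) tuples.

    vol/man may be None for missing; vax defaults to 'unvaccinated'.
    """
    recs = []
    for r in rows:
        rid, wave, vol, man = r[:4]
        vax = r[4] if len(r) > 4 else "unvaccinated"
        rec = {"id": str(rid), "wave": wave, "vol_likert": vol,
               "man_likert": man, "vax_status": vax}
        if covariates:
            rec.update(covariates.get(str(rid), {}))
        recs.append(rec)
    df = pd.DataFrame(recs)
    for col in ("vol_likert", "man_likert"):
        df[col] = df[col].astype("Float64").astype("Int64")
    return PanelTable(df, wave_count=wave_count)


def trajectory_panel(trajs, wave_count=3, mandated=None):
    """Panel from per-respondent voluntary Likert trajectories.

    ``trajs`` is a list of level sequences; ``mandated`` optionally a parallel
    list (defaults to the same levels).
    """
    rows = []
    for i, tr in enumerate(trajs):
        man = mandated[i] if mandated is not None else tr
        for w, (v, m) in enumerate(zip(tr, man), start=1):
            rows.append((f"p{i}", w, v, m))
    return make_panel(rows, wave_count=wave_count)


@pytest.fixture(scope="session")
def default_panel():
    """The default study-condition panel (n=2018, 3 waves)."""
    panel, truth = simulate_panel(SimulationConfig(seed=11))
    return panel, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
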