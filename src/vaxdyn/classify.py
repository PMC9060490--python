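"""Attitude taxonomy: category collapse, consistency classes, switching tables.

The 5-point Likert scale collapses to three categories — opposed (levels 0-1),
undecided (level 2), willing (levels 3-4). A respondent with a complete
trajectory is *consistently opposed / undecided / willing* when they fall in
that category in every wave, and *inconsistent* otherwise.

Respondents vaccinated twice at a wave were not asked the attitude questions.
Two policies handle them: ``"as_willing"`` counts them as willing at that wave
(population-share analyses — having been vaccinated, they are in the willing
slice); ``"exclude"`` drops them from the analysis (wave-to-wave switching
tables). Each operation defaults to the policy its analysis calls for.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .panel import PanelTable, level_column, ID_COL, VAX_COL, WAVE_COL

CATEGORIES = ("opposed", "undecided", "willing")
CONSISTENCY_CLASSES = (
    "consistently_opposed",
    "consistently_undecided",
    "consistently_willing",
    "inconsistent",
)

_CAT_OF_LEVEL = np.array(
    ["opposed", "opposed", "undecided", "willing", "willing"], dtype=object
)


def categorize(level) -> str:
    """Collapse a Likert level (0..4) to opposed/undecided/willing.

    Accepts a scalar or array; missing input raises (callers must filter or
    apply an explicit vaccinated-twice policy first).
    """
    arr = np.asarray(level)
    if pd.isna(arr).any():
        raise ValueError("cannot categorize missing Likert levels")
    arr = arr.astype(int)
    if ((arr < 0) | (arr > 4)).any():
        raise ValueError(f"Likert level outside 0..4: {level!r}")
    out = _CAT_OF_LEVEL[arr]
    return out if arr.ndim else str(out)


def classify_consistency(trajectory) -> str:
    """Consistency class of one complete category trajectory.

    ``trajectory`` is a sequence of category labels (one per wave). Returns
    ``consistently_<cat>`` if every wave equals ``<cat>``, else
    ``inconsistent``.
    """
    cats = list(trajectory)
    if len(cats) == 0:
        raise ValueError("empty trajectory")
    for c in cats:
        if c not in CATEGORIES:
            raise ValueError(f"not a category label: {c!r}")
    first = cats[0]
    if all(c == first for c in cats):
        return f"consistently_{first}"
    return "inconsistent"


def _category_frame(panel: PanelTable, regime: str, vaccinated_policy: str) -> pd.DataFrame:
    """Per-respondent wide frame of categories; NaN where unresolvable.

    vaccinated_policy: 'as_willing' recodes twice-vaccinated missing levels to
    willing; 'exclude' leaves them missing (respondent later dropped).
    """
    if vaccinated_policy not in ("as_willing", "exclude"):
        raise ValueError(f"unknown vaccinated policy {vaccinated_policy!r}")
    levels = panel.trajectories(regime)
    cats = pd.DataFrame(index=levels.index, columns=levels.columns, dtype=object)
    for col in levels.columns:
        lv = levels[col]
        ok = lv.notna()
        cats.loc[ok, col] = _CAT_OF_LEVEL[lv[ok].astype(int).to_numpy()]
    if vaccinated_policy == "as_willing":
        vax = panel.vax_status_wide().reindex(levels.index)
        for col in levels.columns:
            if col in vax.columns:
                twice = (vax[col] == "twice") & levels[col].isna()
                cats.loc[twice, col] = "willing"
    return cats


@dataclass
class ConsistencyShares:
    """Consistency-class shares plus per-wave opposed shares.

    ``counts`` maps each consistency class to an integer count; ``shares`` to
    the corresponding fraction of ``n``. ``opposed_by_wave`` holds the opposed
    share of each wave's cross-section and ``mean_opposed`` their unweighted
    mean (the "average over the cross-sections" figure).
    """

    counts: dict
    shares: dict
    exact_shares: dict  # Fractions — exact rational counts/n
    opposed_by_wave: list
    mean_opposed: float
    n: int

    def __post_init__(self):
        assert abs(sum(self.shares.values()) - 1.0) < 1e-12


def consistency_shares(
    panel: PanelTable,
    regime: str,
    vaccinated_policy: str = "as_willing",
) -> ConsistencyShares:
    """Shares of the four consistency classes over complete trajectories.

    Respondents whose trajectory is still incomplete after applying the
    vaccinated-twice policy are dropped (list-wise). Raises on an empty panel.
    """
    cats = _category_frame(panel, regime, vaccinated_policy)
    complete = cats.dropna()
    n = len(complete)
    if n == 0:
        raise ValueError("no complete trajectories to classify")
    labels = complete.apply(lambda row: classify_consistency(row.tolist()), axis=1)
    counts = {cls: int((labels == cls).sum()) for cls in CONSISTENCY_CLASSES}
    shares = {cls: counts[cls] / n for cls in CONSISTENCY_CLASSES}
    exact = {cls: Fraction(counts[cls], n) for cls in CONSISTENCY_CLASSES}
    opposed_by_wave = [
        float((complete[col] == "opposed").mean()) for col in complete.columns
    ]
    return ConsistencyShares(
        counts=counts,
        shares=shares,
        exact_shares=exact,
        opposed_by_wave=opposed_by_wave,
        mean_opposed=float(np.mean(opposed_by_wave)),
        n=n,
    )


@dataclass
class SwitchingTable:
    """Destination-category distribution for one conditioning category.

    Shares are within-subgroup (sum to 1 over destinations); counts carry the
    underlying paired observations.
    """

    regime: str
    from_wave: int
    to_wave: int
    conditioned_on: str
    counts: dict
    shares: dict
    n: int

    def __post_init__(self):
        assert abs(sum(self.shares.values()) - 1.0) < 1e-12


def switching_table(
    panel: PanelTable,
    regime: str,
    from_wave: int,
    to_wave: int,
    conditioned_on: str,
    vaccinated_policy: str = "exclude",
) -> SwitchingTable:
    """How respondents in one category at ``from_wave`` answered at ``to_wave``."""
    if conditioned_on not in CATEGORIES:
        raise ValueError(f"unknown category {conditioned_on!r}")
    cats = _category_frame(panel, regime, vaccinated_policy)
    a, b = f"w{from_wave}", f"w{to_wave}"
    if a not in cats.columns or b not in cats.columns:
        raise ValueError(f"waves {from_wave},{to_wave} outside panel range")
    pair = cats[[a, b]].dropna()
    origin = pair[pair[a] == conditioned_on]
    n = len(origin)
    if n == 0:
        raise ValueError(
            f"no respondents in category {conditioned_on!r} at wave {from_wave}"
        )
    counts = {c: int((origin[b] == c).sum()) for c in CATEGORIES}
    shares = {c: counts[c] / n for c in CATEGORIES}
    return SwitchingTable(
        regime=regime,
        from_wave=from_wave,
        to_wave=to_wave,
        conditioned_on=conditioned_on,
        counts=counts,
        shares=shares,
        n=n,
    )
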