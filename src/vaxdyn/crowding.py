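"""Crowding-out tabulation: voluntary vs mandated attitudes within a wave.

A mandate can crowd out intrinsic willingness: respondents comfortable with
voluntary vaccination may oppose the same vaccination once enforced. The
cross-tabulation conditions on a respondent's category under the voluntary
regime and decomposes the same respondents' categories under the mandated
regime. Shares are expressed relative to the full wave population by default,
so the destination shares sum exactly to the conditioning category's share
(the decomposition identity); within-subgroup normalization is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CATEGORIES, _CAT_OF_LEVEL
from .panel import PanelTable, LEVEL_COLS, VAX_COL


@dataclass
class CrowdingTable:
    """Mandated-regime decomposition of one voluntary-regime category.

    ``conditioning_share`` and ``destination_shares`` are on the chosen
    denominator (population or subgroup); ``net_effect`` is the share
    becoming willing minus the share becoming opposed under the mandate.
    """

    wave: int
    conditioning: str
    conditioning_share: float
    destination_shares: dict
    counts: dict
    n_subgroup: int
    n_population: int
    normalization: str
    net_effect: float

    def __post_init__(self):
        # decomposition identity, exact on counts
        assert sum(self.counts.values()) == self.n_subgroup


def _paired_categories(panel: PanelTable, wave: int) -> pd.DataFrame:
    """Respondents of one wave with both regime responses, as categories."""
    rows = panel.wave(wave)
    both = rows.dropna(subset=[LEVEL_COLS["voluntary"], LEVEL_COLS["mandated"]])
    return pd.DataFrame(
        {
            "vol": _CAT_OF_LEVEL[both[LEVEL_COLS["voluntary"]].astype(int).to_numpy()],
            "man": _CAT_OF_LEVEL[both[LEVEL_COLS["mandated"]].astype(int).to_numpy()],
        },
        index=both["id"],
    )


def crowding_table(
    panel: PanelTable,
    wave: int,
    conditioning: str,
    normalization: str = "population",
) -> CrowdingTable:
    """How one voluntary-regime category would respond under a mandate.

    Respondents vaccinated twice at the wave lack attitude responses and are
    excluded. ``normalization='population'`` expresses all shares relative to
    the wave population with both responses; ``'subgroup'`` rescales the
    destination shares to sum to 1 within the conditioning category.
    """
    if conditioning not in CATEGORIES:
        raise ValueError(f"unknown category {conditioning!r}")
    if normalization not in ("population", "subgroup"):
        raise ValueError(f"unknown normalization {normalization!r}")
    cats = _paired_categories(panel, wave)
    n_pop = len(cats)
    sub = cats[cats["vol"] == conditioning]
    n_sub = len(sub)
    if n_sub == 0:
        raise ValueError(f"no respondents {conditioning!r} under voluntary at wave {wave}")
    counts = {c: int((sub["man"] == c).sum()) for c in CATEGORIES}
    denom = n_pop if normalization == "population" else n_sub
    shares = {c: counts[c] / denom for c in CATEGORIES}
    # net effect counts movements only: staying put is neither gain nor loss
    becoming_willing = shares["willing"] if conditioning != "willing" else 0.0
    becoming_opposed = shares["opposed"] if conditioning != "opposed" else 0.0
    return CrowdingTable(
        wave=wave,
        conditioning=conditioning,
        conditioning_share=n_sub / denom,
        destination_shares=shares,
        counts=counts,
        n_subgroup=n_sub,
        n_population=n_pop,
        normalization=normalization,
        net_effect=becoming_willing - becoming_opposed,
    )


def naive_uptake_prediction(panel: PanelTable, wave: int) -> float:
    """Predicted uptake: share willing voluntarily plus share vaccinated twice.

    The naive reading of a cross-section: once supply allows, vaccinations
    approach the fraction who agree with voluntary vaccination (levels 3-4)
    plus those already fully vaccinated.
    """
    rows = panel.wave(wave)
    n = len(rows)
    if n == 0:
        raise ValueError(f"no rows at wave {wave}")
    vol = rows[LEVEL_COLS["voluntary"]]
    willing = (vol >= 3).fillna(False)
    twice = rows[VAX_COL] == "twice"
    return float((willing | twice).sum() / n)
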