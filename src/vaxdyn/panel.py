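"""Panel data model: long-format attitude tables, validation, I/O.

A panel observes the same respondents over repeated survey waves. Each
respondent-wave row records agreement with being vaccinated under two policy
regimes — voluntary and mandated — on a 5-point Likert scale from 0 ("not
agree at all") to 4 ("fully agree"), plus vaccination status and covariates.
Respondents already vaccinated twice at a wave were not asked the attitude
questions, so their Likert levels are missing by construction.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

#: canonical long-format columns, in order
ID_COL = "id"
WAVE_COL = "wave"
LEVEL_COLS = {"voluntary": "vol_likert", "mandated": "man_likert"}
VAX_COL = "vax_status"
WEIGHT_COL = "weight"
CORE_COLS = (ID_COL, WAVE_COL, LEVEL_COLS["voluntary"], LEVEL_COLS["mandated"], VAX_COL)

VAX_STATES = ("unvaccinated", "once", "twice")
#: rank used to check that vaccination status never regresses across waves
_VAX_RANK = {s: i for i, s in enumerate(VAX_STATES)}

REGIMES = ("voluntary", "mandated")


class PanelSchemaError(ValueError):
    """A required column is absent or the column map is malformed."""


class PanelValidationError(ValueError):
    """Rows violate the panel invariants; the message lists offending rows."""


def level_column(regime: str) -> str:
    """Canonical Likert column name for a regime ('voluntary'/'mandated')."""
    try:
        return LEVEL_COLS[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}") from None


@dataclass
class PanelTable:
    """Validated long-format panel: one row per respondent x wave.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format with columns ``id, wave, vol_likert, man_likert,
        vax_status`` followed by covariates (and optionally ``weight``).
        Likert columns are nullable integers in {0..4}; missing = NA.
    wave_count : int
        Number of survey waves, indexed 1..wave_count.
    metadata : dict
        Free-form provenance (seed, source path, ...). Not validated.
    """

    data: pd.DataFrame
    wave_count: int = 3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _validate(self.data, self.wave_count)

    # -- basic introspection ------------------------------------------------

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.data[ID_COL].unique()

    @property
    def n_respondents(self) -> int:
        return int(self.data[ID_COL].nunique())

    @property
    def covariate_names(self) -> list[str]:
        extra = [c for c in self.data.columns if c not in CORE_COLS and c != WEIGHT_COL]
        return extra

    def __len__(self) -> int:  # number of respondents, not rows
        return self.n_respondents

    # -- derived views ------------------------------------------------------

    def trajectories(self, regime: str) -> pd.DataFrame:
        """Wide per-respondent Likert trajectories for one regime.

        Returns a DataFrame indexed by respondent id with one column per wave
        (``w1..wW``), nullable-integer Likert levels.
        """
        col = level_column(regime)
        wide = self.data.pivot(index=ID_COL, columns=WAVE_COL, values=col)
        wide = wide.reindex(columns=range(1, self.wave_count + 1))
        wide.columns = [f"w{w}" for w in range(1, self.wave_count + 1)]
        return wide.astype("Int64")

    def vax_status_wide(self) -> pd.DataFrame:
        wide = self.data.pivot(index=ID_COL, columns=WAVE_COL, values=VAX_COL)
        wide = wide.reindex(columns=range(1, self.wave_count + 1))
        wide.columns = [f"w{w}" for w in range(1, self.wave_count + 1)]
        return wide

    def wave(self, w: int) -> pd.DataFrame:
        """All rows of one wave."""
        if not 1 <= w <= self.wave_count:
            raise ValueError(f"wave {w} outside 1..{self.wave_count}")
        return self.data[self.data[WAVE_COL] == w]

    def covariates(self) -> pd.DataFrame:
        """One row per respondent: wave-1 values of every covariate column."""
        first = self.data[self.data[WAVE_COL] == 1]
        return first.set_index(ID_COL)[self.covariate_names]

    # -- subsetting ---------------------------------------------------------

    def complete_cases(self, regime: str) -> "PanelTable":
        """Respondents with a non-missing Likert level in every wave (list-wise)."""
        col = level_column(regime)
        per_id = self.data.groupby(ID_COL)[col].agg(
            n_obs="count", n_rows="size"
        )
        keep = per_id.index[
            (per_id["n_obs"] == self.wave_count) & (per_id["n_rows"] == self.wave_count)
        ]
        sub = self.data[self.data[ID_COL].isin(keep)].reset_index(drop=True)
        return PanelTable(sub, self.wave_count, dict(self.metadata))

    def subset(self, predicate: Callable[[pd.DataFrame], pd.Series] | str) -> "PanelTable":
        """Filter respondents by a covariate predicate.

        ``predicate`` is either a pandas ``query`` string evaluated on the
        per-respondent covariate frame (e.g. ``"region == 'East'"``) or a
        callable mapping that frame to a boolean Series. Unknown covariate
        names raise.
        """
        cov = self.covariates()
        if isinstance(predicate, str):
            try:
                mask = cov.eval(predicate)
            except Exception as exc:  # pandas raises several types here
                raise PanelSchemaError(
                    f"predicate {predicate!r} failed on covariates "
                    f"{list(cov.columns)}: {exc}"
                ) from exc
        else:
            mask = predicate(cov)
        mask = pd.Series(mask, index=cov.index).fillna(False).astype(bool)
        keep = cov.index[mask]
        sub = self.data[self.data[ID_COL].isin(keep)].reset_index(drop=True)
        return PanelTable(sub, self.wave_count, dict(self.metadata))

    # -- hashing ------------------------------------------------------------

    def digest(self) -> str:
        """SHA-256 of the canonical CSV serialization (provenance stamp)."""
        buf = io.StringIO()
        _write_csv(self, buf)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()


# ---------------------------------------------------------------------------
# validation


def _validate(df: pd.DataFrame, wave_count: int) -> pd.DataFrame:
    missing = [c for c in CORE_COLS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing required columns: {missing}")
    df = df.copy()

    problems: list[str] = []

    df[WAVE_COL] = pd.to_numeric(df[WAVE_COL], errors="raise").astype(int)
    bad_wave = df.index[(df[WAVE_COL] < 1) | (df[WAVE_COL] > wave_count)]
    for i in bad_wave:
        problems.append(f"row {i}: wave {df.at[i, WAVE_COL]} outside 1..{wave_count}")

    for reg in REGIMES:
        col = LEVEL_COLS[reg]
        vals = pd.to_numeric(df[col], errors="coerce")
        non_na = df[col].notna()
        unparsable = df.index[non_na & vals.isna()]
        for i in unparsable:
            problems.append(f"row {i}: {col}={df.at[i, col]!r} is not an integer")
        out_of_range = vals.notna() & (
            (vals < 0) | (vals > 4) | (vals != vals.round())
        )
        for i in df.index[out_of_range]:
            problems.append(f"row {i}: {col}={df.at[i, col]!r} outside Likert range 0..4")
        df[col] = vals.where(~out_of_range).round().astype("Int64")

    bad_vax = df.index[df[VAX_COL].notna() & ~df[VAX_COL].isin(VAX_STATES)]
    for i in bad_vax:
        problems.append(
            f"row {i}: vax_status={df.at[i, VAX_COL]!r} not in {VAX_STATES}"
        )

    dup = df.duplicated(subset=[ID_COL, WAVE_COL], keep=False)
    if dup.any():
        for i in df.index[dup]:
            problems.append(
                f"row {i}: duplicate (id={df.at[i, ID_COL]!r}, wave={df.at[i, WAVE_COL]})"
            )

    if problems:
        raise PanelValidationError(
            f"{len(problems)} invalid rows:\n  " + "\n  ".join(problems[:50])
        )

    # vaccination status must never regress across waves
    rank = df[VAX_COL].map(_VAX_RANK)
    ordered = df.sort_values([ID_COL, WAVE_COL])
    regress = ordered.groupby(ID_COL, sort=False).apply(
        lambda g: (rank.loc[g.index].diff().dropna() < 0).any(),
        include_groups=False,
    )
    bad_ids = regress.index[regress]
    if len(bad_ids):
        raise PanelValidationError(
            f"vaccination status decreases across waves for ids: {list(bad_ids[:20])}"
        )

    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O


def read_panel(
    path,
    schema: Mapping[str, str] | None = None,
    wave_count: int = 3,
) -> PanelTable:
    """Read a long-format panel CSV.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row, UTF-8, empty cells for missing values.
    schema : mapping, optional
        Column map from the file's column names to the canonical names
        ``id, wave, vol_likert, man_likert, vax_status`` (so arbitrary
        deposited schemas can be imported without rewriting the file).
        Unmapped columns are carried through as covariates.
    wave_count : int
        Number of waves the file is expected to cover.
    """
    df = pd.read_csv(
        path,
        dtype={"id": str} if schema is None else None,
        float_precision="round_trip",
    )
    if schema:
        unknown = [src for src in schema if src not in df.columns]
        if unknown:
            raise PanelSchemaError(f"schema maps absent columns: {unknown}")
        df = df.rename(columns=dict(schema))
    if ID_COL in df.columns:
        df[ID_COL] = df[ID_COL].astype(str)
    return PanelTable(df, wave_count=wave_count)


def _write_csv(panel: PanelTable, buf) -> None:
    df = panel.data.copy()
    cols = [c for c in CORE_COLS if c in df.columns]
    rest = [c for c in df.columns if c not in cols]
    # shortest-repr float formatting so doubles round-trip exactly
    df[cols + rest].to_csv(buf, index=False, float_format=lambda x: repr(float(x)))


def write_panel(panel: PanelTable, path) -> None:
    """Write the canonical CSV (core columns first, covariates after)."""
    if hasattr(path, "write"):
        _write_csv(panel, path)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _write_csv(panel, fh)


def complete_cases(panel: PanelTable, regime: str) -> PanelTable:
    """Function wrapper over :meth:`PanelTable.complete_cases`."""
    return panel.complete_cases(regime)


def subset(panel: PanelTable, predicate) -> PanelTable:
    """Function wrapper over :meth:`PanelTable.subset`."""
    return panel.subset(predicate)
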