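"""Tabular record schemas, CSV I/O, validation and eligibility filters.

Four record types flow through the pipeline, all as pandas DataFrames with
fixed column sets:

``registry``
    one row per individual per study year: ``individual_id, year, sex,
    age_class, colony, n_traps``.  ``sex`` is ``F``/``M``; ``age_class`` is
    ``adult`` (>2 y), ``yearling`` (1 y) or ``pup`` (<1 y); ``n_traps`` is
    the number of live-trapping captures that year.
``interactions``
    one row per directed social act: ``timestamp, initiator_id,
    recipient_id, itype, location`` with ``itype`` in
    ``{affiliative, agonistic}``.  Unidentified parties are coded with the
    sentinel ``UNKNOWN``.
``copresence``
    one row per sighting/trap event: ``individual_id, date, location``.
    Two individuals recorded at the same location on the same calendar day
    count as associated for the simple-ratio index.
``reproduction``
    one row per mother-year: ``mother_id, year, offspring, exposure``.
    ``offspring`` is the pedigree-assigned number of pups weaned;
    ``exposure`` (time at risk) defaults to 1.0 when the column is absent.

Downstream stages only see records that pass :func:`filter_agonistic_study_set`:
agonistic acts between known adult females of the focal year that were each
trapped more than ``trap_threshold`` times (transient individuals excluded).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger("skewnet")

UNKNOWN = "UNKNOWN"

#: Sighting/observation season bounds (month, day), inclusive.  Field data
#: collection runs from mid-April to early September; records outside the
#: season are dropped with a warning.
SEASON_START = (4, 15)
SEASON_END = (9, 7)

#: Minimum capture count for inclusion: strictly more than this many traps.
TRAP_THRESHOLD = 5

SCHEMAS: dict[str, dict] = {
    "registry": {
        "columns": ["individual_id", "year", "sex", "age_class", "colony", "n_traps"],
        "dates": [],
    },
    "interactions": {
        "columns": ["timestamp", "initiator_id", "recipient_id", "itype", "location"],
        "dates": ["timestamp"],
    },
    "copresence": {
        "columns": ["individual_id", "date", "location"],
        "dates": ["date"],
    },
    "reproduction": {
        "columns": ["mother_id", "year", "offspring"],
        "optional": ["exposure"],
        "dates": [],
    },
}

VALID_SEX = {"F", "M"}
VALID_AGE = {"adult", "yearling", "pup"}
VALID_ITYPE = {"affiliative", "agonistic"}


class SchemaError(ValueError):
    """The CSV is structurally unusable (missing column, unknown schema)."""


@dataclass
class RowError:
    line: int  # 1-based line number in the source CSV (header = line 1)
    message: str


@dataclass
class ReadReport:
    """Validated records plus the rows that failed validation."""

    records: pd.DataFrame
    errors: list[RowError] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def _validate_rows(df: pd.DataFrame, schema: str) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, msg: str) -> None:
        nonlocal bad
        for idx in df.index[mask & ~bad]:
            errors.append(RowError(line=int(idx) + 2, message=msg))
        bad |= mask

    for col in SCHEMAS[schema]["dates"]:
        parsed = pd.to_datetime(df[col], errors="coerce", format="mixed")
        flag(parsed.isna() & df[col].notna(), f"unparseable date in '{col}'")
        flag(df[col].isna(), f"missing date in '{col}'")
        df[col] = parsed

    if schema == "registry":
        flag(~df["sex"].isin(VALID_SEX), "sex must be F or M")
        flag(~df["age_class"].isin(VALID_AGE), "age_class must be adult/yearling/pup")
        n_traps = pd.to_numeric(df["n_traps"], errors="coerce")
        flag(n_traps.isna() | (n_traps < 0), "n_traps must be a non-negative integer")
        df["n_traps"] = n_traps
        year = pd.to_numeric(df["year"], errors="coerce")
        flag(year.isna(), "year must be an integer")
        df["year"] = year
        dup = df.duplicated(subset=["individual_id", "year"], keep="first")
        flag(dup, "duplicate (individual_id, year)")
    elif schema == "interactions":
        flag(~df["itype"].isin(VALID_ITYPE), "itype must be affiliative or agonistic")
        both_known = (df["initiator_id"] != UNKNOWN) & (df["recipient_id"] != UNKNOWN)
        flag(both_known & (df["initiator_id"] == df["recipient_id"]),
             "initiator and recipient must differ")
    elif schema == "reproduction":
        off = pd.to_numeric(df["offspring"], errors="coerce")
        flag(off.isna() | (off < 0), "offspring must be a non-negative integer")
        df["offspring"] = off
        year = pd.to_numeric(df["year"], errors="coerce")
        flag(year.isna(), "year must be an integer")
        df["year"] = year
        if "exposure" in df.columns:
            exp = pd.to_numeric(df["exposure"], errors="coerce")
            flag(exp.isna() | (exp <= 0), "exposure must be positive")
            df["exposure"] = exp
        else:
            df["exposure"] = 1.0

    good = df.loc[~bad].reset_index(drop=True)
    if schema == "registry":
        good["year"] = good["year"].astype(int)
        good["n_traps"] = good["n_traps"].astype(int)
    elif schema == "reproduction":
        good["year"] = good["year"].astype(int)
        good["offspring"] = good["offspring"].astype(int)
    return good, errors


def read_records(path, schema: str) -> ReadReport:
    """Read and validate one of the four record CSVs.

    Parameters
    ----------
    path
        CSV file (RFC 4180, UTF-8, header row).
    schema
        One of ``registry``, ``interactions``, ``copresence``, ``reproduction``.

    Returns
    -------
    ReadReport
        Validated records; malformed rows are dropped and reported in
        ``errors`` with their 1-based source line number.

    Raises
    ------
    SchemaError
        If ``schema`` is unknown or a required column is missing.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    df = pd.read_csv(path, dtype=str)
    required = SCHEMAS[schema]["columns"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"schema {schema!r}: missing required column(s) {missing}")
    keep = required + [c for c in SCHEMAS[schema].get("optional", []) if c in df.columns]
    df = df[keep].copy()
    records, errors = _validate_rows(df, schema)
    for err in errors:
        log.warning("%s row rejected (line %d): %s", schema, err.line, err.message)
    return ReadReport(records=records, errors=errors)


def write_records(df: pd.DataFrame, path, schema: str) -> None:
    """Write records to CSV in the canonical column order for ``schema``."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    cols = [c for c in SCHEMAS[schema]["columns"] + SCHEMAS[schema].get("optional", [])
            if c in df.columns]
    out = df[cols].copy()
    for col in SCHEMAS[schema]["dates"]:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False)


def season_filter(df: pd.DataFrame, date_col: str,
                  start: tuple[int, int] = SEASON_START,
                  end: tuple[int, int] = SEASON_END) -> pd.DataFrame:
    """Keep rows whose date falls inside the observation season (inclusive).

    The season is a (month, day)..(month, day) window applied within each
    calendar year.  Out-of-season rows are dropped with a warning.
    """
    dates = pd.to_datetime(df[date_col])
    md = dates.dt.month * 100 + dates.dt.day
    lo = start[0] * 100 + start[1]
    hi = end[0] * 100 + end[1]
    keep = (md >= lo) & (md <= hi)
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"{n_drop} record(s) outside the {start}-{end} season dropped",
                      stacklevel=2)
    return df.loc[keep].reset_index(drop=True)


def adult_females(registry: pd.DataFrame, year: int) -> pd.DataFrame:
    """Registry rows for adult females of the given year."""
    mask = (registry["year"] == year) & (registry["sex"] == "F") \
        & (registry["age_class"] == "adult")
    return registry.loc[mask].reset_index(drop=True)


def filter_agonistic_study_set(interactions: pd.DataFrame, registry: pd.DataFrame,
                               year: int, trap_threshold: int = TRAP_THRESHOLD
                               ) -> pd.DataFrame:
    """Reduce an interaction log to the analysis set for one study year.

    Retains directed agonistic acts where both the initiator and the
    recipient (i) are identified (not ``UNKNOWN``), (ii) are adult females
    registered for ``year``, and (iii) were trapped strictly more than
    ``trap_threshold`` times that year (transient-animal exclusion).

    The filter is idempotent and an empty result is valid (it yields an
    empty network downstream).
    """
    females = adult_females(registry, year)
    eligible = set(females.loc[females["n_traps"] > trap_threshold, "individual_id"])
    ix = interactions
    yr = pd.to_datetime(ix["timestamp"]).dt.year == year
    mask = (
        yr
        & (ix["itype"] == "agonistic")
        & (ix["initiator_id"] != UNKNOWN)
        & (ix["recipient_id"] != UNKNOWN)
        & ix["initiator_id"].isin(eligible)
        & ix["recipient_id"].isin(eligible)
    )
    return ix.loc[mask].reset_index(drop=True)
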