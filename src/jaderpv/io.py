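"""Reading, validating, deduplicating and merging JADER-style report tables.

A spontaneous-reporting extract in this schema consists of three CSV tables
keyed by an opaque case identifier:

``DEMO``
    one row per patient: ``case_id, sex, age_band``
``DRUG``
    one row per reported drug record: ``case_id, drug_name, involvement,
    start_date, end_date`` where ``involvement`` is the reporter's causality
    code (``suspected`` / ``concomitant`` / ``interaction``)
``REAC``
    one row per reported adverse event: ``case_id, pt_term, onset_date,
    outcome`` where ``pt_term`` is a MedDRA-style preferred term

Dates in spontaneous reports are frequently partial: year/month/day or
year/month.  They are carried as ISO-like strings (``YYYY``, ``YYYY-MM``,
``YYYY-MM-DD``); the empty string means missing.  Unparseable dates become
missing rather than raising — spontaneous report data are dirty and dropping
rows would corrupt the denominators of every downstream statistic.

The canonical in-memory container for each table is a ``pandas.DataFrame``
of strings with the column sets above, fully normalized (trimmed, internal
whitespace collapsed, case-folded names, canonical category tokens).
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime
import re
from pathlib import Path

import pandas as pd


class SchemaError(ValueError):
    """A table file does not conform to the documented column schema."""


#: Required columns per table kind, in canonical order.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "demo": ["case_id", "sex", "age_band"],
    "drug": ["case_id", "drug_name", "involvement", "start_date", "end_date"],
    "reac": ["case_id", "pt_term", "onset_date", "outcome"],
}

#: Column order of the merged analysis table (one row per case/drug/event).
ANALYSIS_COLUMNS: list[str] = [
    "case_id", "drug_name", "pt_term", "involvement",
    "sex", "age_band", "onset_date", "start_date", "end_date", "outcome",
]
TABLE_SCHEMAS["analysis"] = ANALYSIS_COLUMNS

SEX_CATEGORIES = ("male", "female", "unknown")
AGE_BANDS = ("10s", "20s", "30s", "40s", "50s", "60s", "70s", "80s", "90s", "unknown")
INVOLVEMENT_CODES = ("suspected", "concomitant", "interaction", "unknown")
OUTCOME_CATEGORIES = ("recovery", "remission", "not_recovered", "sequelae", "death", "unclear")

_WS = re.compile(r"\s+")


def normalize_text(value: object) -> str:
    """Trim, collapse internal whitespace and case-fold a name-like token.

    This is the only name normalization applied to drug names and preferred
    terms; no dictionary mapping is attempted.
    """
    return _WS.sub(" ", str(value).strip()).casefold()


def normalize_series(s: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_text`."""
    return (
        s.astype(str)
        .str.replace(r"\s+", " ", regex=True)
        .str.strip()
        .str.casefold()
    )


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(
    r"^\s*(\d{4})(?:[-/.](\d{1,2})(?:[-/.](\d{1,2}))?)?\s*$"
)


@dataclasses.dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to year, year/month or year/month/day precision.

    A fully absent date is represented outside this class as ``None`` (or the
    empty string in serialized tables), never as a sentinel year.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")
        if not (1 <= self.year <= 9999):
            raise ValueError(f"year out of range: {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # validates e.g. Feb 30
            datetime.date(self.year, self.month, self.day)

    @classmethod
    def parse(cls, text: object) -> "PartialDate | None":
        """Parse ``YYYY``, ``YYYY-MM`` or ``YYYY-MM-DD`` (also ``/`` or ``.``
        separated); return ``None`` for anything unparseable or blank."""
        if text is None:
            return None
        m = _DATE_RE.match(str(text))
        if m is None:
            return None
        year = int(m.group(1))
        month = int(m.group(2)) if m.group(2) else None
        day = int(m.group(3)) if m.group(3) else None
        try:
            return cls(year, month, day)
        except ValueError:
            return None

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def resolve(self, day_of_month: int = 1) -> datetime.date | None:
        """Resolve to a full calendar date.

        Year/month dates resolve to ``day_of_month`` (clamped to the month's
        length); year-only dates are too coarse for day arithmetic and
        resolve to ``None``.
        """
        if self.month is None:
            return None
        if self.day is not None:
            return datetime.date(self.year, self.month, self.day)
        last = calendar.monthrange(self.year, self.month)[1]
        return datetime.date(self.year, self.month, min(day_of_month, last))


def canonical_date_string(text: object) -> str:
    """Normalize a raw date cell to its ISO-like form ('' if unparseable)."""
    pd_ = PartialDate.parse(text)
    return "" if pd_ is None else pd_.isoformat()


# ---------------------------------------------------------------------------
# Categorical normalization
# ---------------------------------------------------------------------------

_SEX_MAP = {"male": "male", "m": "male", "female": "female", "f": "female"}
_INVOLVEMENT_MAP = {
    "suspected": "suspected",
    "suspect": "suspected",
    "suspected drug": "suspected",
    "concomitant": "concomitant",
    "concomitant drug": "concomitant",
    "interaction": "interaction",
}
_OUTCOME_MAP = {
    "recovery": "recovery",
    "recovered": "recovery",
    "remission": "remission",
    "not recovered": "not_recovered",
    "not_recovered": "not_recovered",
    "unrecovered": "not_recovered",
    "sequelae": "sequelae",
    "with sequelae": "sequelae",
    "with_sequelae": "sequelae",
    "death": "death",
    "fatal": "death",
    "unclear": "unclear",
}
_AGE_RE = re.compile(r"^([1-9]0)\s*s$")


def _norm_sex(s: pd.Series) -> pd.Series:
    return normalize_series(s).map(_SEX_MAP).fillna("unknown")


def _norm_age(s: pd.Series) -> pd.Series:
    return (
        normalize_series(s)
        .str.replace(_AGE_RE, lambda m: m.group(1) + "s", regex=True)
        .where(lambda x: x.isin(AGE_BANDS), "unknown")
    )


def _norm_involvement(s: pd.Series) -> pd.Series:
    return normalize_series(s).map(_INVOLVEMENT_MAP).fillna("unknown")


def _norm_outcome(s: pd.Series) -> pd.Series:
    # unrecognized / blank outcome -> missing ('' = no stated outcome)
    return normalize_series(s).map(_OUTCOME_MAP).fillna("")


def _norm_date(s: pd.Series) -> pd.Series:
    return s.map(canonical_date_string)


_COLUMN_NORMALIZERS = {
    "case_id": lambda s: s.astype(str).str.strip(),
    "sex": _norm_sex,
    "age_band": _norm_age,
    "drug_name": normalize_series,
    "pt_term": normalize_series,
    "involvement": _norm_involvement,
    "start_date": _norm_date,
    "end_date": _norm_date,
    "onset_date": _norm_date,
    "outcome": _norm_outcome,
}


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_table(path: str | Path, table_kind: str, encoding: str = "utf-8") -> pd.DataFrame:
    """Read one table kind from CSV and normalize every column.

    Row count is preserved exactly: dirty cells become missing/unknown
    values, never dropped rows.  Real JADER distributions are Shift-JIS;
    pass ``encoding='cp932'`` for those — UTF-8 is the tested contract.

    Raises
    ------
    FileNotFoundError
        if the file does not exist.
    SchemaError
        if a mandatory column is absent (named in the message) or the file
        has no header at all.
    """
    path = Path(path)
    if table_kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding=encoding)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file has no header row") from None
    df.columns = [str(c).strip().casefold() for c in df.columns]
    for col in TABLE_SCHEMAS[table_kind]:
        if col not in df.columns:
            raise SchemaError(
                f"{path}: {table_kind.upper()} table is missing mandatory column '{col}'"
            )
    df = df[TABLE_SCHEMAS[table_kind]].copy()
    return normalize_table(df, table_kind)


def normalize_table(df: pd.DataFrame, table_kind: str) -> pd.DataFrame:
    """Apply the per-column normalizers to an in-memory table (idempotent)."""
    out = df.copy()
    for col in TABLE_SCHEMAS[table_kind]:
        out[col] = _COLUMN_NORMALIZERS[col](out[col])
    return out[TABLE_SCHEMAS[table_kind]].reset_index(drop=True)


def dedup_records(df: pd.DataFrame, table_kind: str | None = None) -> pd.DataFrame:
    """Remove exact-duplicate rows (all fields equal), keeping first occurrence.

    Exact equality of every field is the duplicate definition: it is the only
    reproducible reading when no duplicate key is documented.  Idempotent and
    never increases the row count.
    """
    return df.drop_duplicates(keep="first").reset_index(drop=True)


_INVOLVEMENT_PRIORITY = {"suspected": 0, "interaction": 1, "concomitant": 2, "unknown": 3}


def merge_tables(
    demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame
) -> pd.DataFrame:
    """Merge the three tables into the analysis table by case identifier.

    One output row per (case, drug, preferred term) combination present in
    the inner join of DRUG and REAC on ``case_id``; demographics attached
    from DEMO (``unknown`` for cases absent from DEMO).  Cases lacking DRUG
    or REAC rows contribute nothing.

    Where a (case, drug) pair has several DRUG records, the pair collapses
    to the highest causality involvement (suspected > interaction >
    concomitant > unknown), first occurrence winning ties; a (case, term)
    pair with several REAC records collapses to its first occurrence.  The
    un-collapsed DRUG table remains the source of dosing episodes for
    time-to-onset work.
    """
    drug_u = drug.copy()
    drug_u["_prio"] = drug_u["involvement"].map(_INVOLVEMENT_PRIORITY)
    drug_u = (
        drug_u.sort_values("_prio", kind="stable")
        .drop_duplicates(["case_id", "drug_name"], keep="first")
        .drop(columns="_prio")
    )
    reac_u = reac.drop_duplicates(["case_id", "pt_term"], keep="first")
    demo_u = demo.drop_duplicates("case_id", keep="first")

    merged = drug_u.merge(reac_u, on="case_id", how="inner")
    merged = merged.merge(demo_u, on="case_id", how="left")
    merged["sex"] = merged["sex"].fillna("unknown")
    merged["age_band"] = merged["age_band"].fillna("unknown")
    merged = merged[ANALYSIS_COLUMNS]
    return (
        merged.sort_values(["case_id", "drug_name", "pt_term"], kind="stable")
        .reset_index(drop=True)
    )


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str | None = None) -> None:
    """Write a table to UTF-8 CSV so that it round-trips through read_table."""
    path = Path(path)
    cols = TABLE_SCHEMAS.get(table_kind, list(df.columns)) if table_kind else list(df.columns)
    df.to_csv(path, index=False, columns=cols, encoding="utf-8")
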