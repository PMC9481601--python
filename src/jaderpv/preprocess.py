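"""Building the suspected-drug data table and its drug/event subsets.

The analysis unit throughout is the unique (case, suspected drug, preferred
term) triple of the merged table: every denominator in the disproportionality
screen counts these triples.  Restricting to reporter-suspected drugs is what
turns a raw report dump into the "data table" that disproportionality
statistics are computed on.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._util import round_half_up
from .io import AGE_BANDS, SEX_CATEGORIES, normalize_series, normalize_text


@dataclasses.dataclass(frozen=True)
class DataTable:
    """An analysis table (suspected-drug rows only) plus its row count."""

    rows: pd.DataFrame
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total != len(self.rows):
            raise ValueError("n_total must equal the number of rows")


@dataclasses.dataclass(frozen=True)
class EventTermSet:
    """A named, ordered set of adverse-event preferred terms.

    Terms are normalized (trimmed, whitespace-collapsed, case-folded) at
    construction and must be unique afterwards.
    """

    name: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("term set must be nonempty")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("terms must be unique after normalization")

    @classmethod
    def from_iterable(cls, terms: Iterable[str], name: str = "custom") -> "EventTermSet":
        normalized: list[str] = []
        for t in terms:
            nt = normalize_text(t)
            if nt and nt not in normalized:
                normalized.append(nt)
        return cls(name=name, terms=tuple(normalized))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "EventTermSet":
        """Load one term per line from a UTF-8 text file ('#' comments allowed)."""
        path = Path(path)
        lines = [
            ln for ln in path.read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls.from_iterable(lines, name=name or path.stem)


def default_lung_terms() -> EventTermSet:
    """The packaged default event set: 29 lung-toxicity preferred terms."""
    text = resources.files("jaderpv").joinpath("data/lung_terms.txt").read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    return EventTermSet.from_iterable(lines, name="lung_toxicity")


def filter_suspected(merged: pd.DataFrame) -> DataTable:
    """Keep only rows where the reporter judged the drug causal (suspected)."""
    rows = merged.loc[merged["involvement"] == "suspected"].reset_index(drop=True)
    return DataTable(rows=rows, n_total=len(rows))


def subset_by_drug(table: DataTable, drug_name: str) -> DataTable:
    """Rows whose drug name matches ``drug_name`` after normalization."""
    target = normalize_text(drug_name)
    rows = table.rows.loc[
        normalize_series(table.rows["drug_name"]) == target
    ].reset_index(drop=True)
    return DataTable(rows=rows, n_total=len(rows))


def subset_by_terms(table: DataTable, terms: EventTermSet) -> DataTable:
    """Rows whose preferred term belongs to ``terms``."""
    rows = table.rows.loc[
        normalize_series(table.rows["pt_term"]).isin(terms.terms)
    ].reset_index(drop=True)
    return DataTable(rows=rows, n_total=len(rows))


def demographics_summary(table: DataTable) -> pd.DataFrame:
    """Per-category patient counts and percentages (sex and age band).

    Patients are unique case identifiers within the table, so a case
    reported with two qualifying events counts once.  Unknown categories are
    kept — dropping them would distort the percentages.  Percentages are of
    total patients, rounded half-up to one decimal; with zero patients the
    percentage column is NA.
    """
    patients = table.rows.drop_duplicates("case_id")
    n = len(patients)
    records: list[dict] = []
    for variable, categories in (("sex", SEX_CATEGORIES), ("age_band", AGE_BANDS)):
        counts = patients[variable].value_counts()
        for cat in categories:
            c = int(counts.get(cat, 0))
            pct = round_half_up(100.0 * c / n, 1) if n else float("nan")
            records.append(
                {"variable": variable, "category": cat, "count": c, "pct": pct}
            )
    out = pd.DataFrame.from_records(
        records, columns=["variable", "category", "count", "pct"]
    )
    out.attrs["n_patients"] = n
    return out
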