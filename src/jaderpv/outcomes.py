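"""Post-event outcome tabulation and fatality rates.

Spontaneous reports carry a six-category outcome field (recovery, remission,
not recovered, sequelae, death, unclear).  The fatality percentage of an
event term is deaths over reports with a *stated* outcome: ``unclear`` is a
stated category and stays in the denominator, record-level missingness does
not (it is reported separately).
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from ._util import round_half_up
from .io import OUTCOME_CATEGORIES


@dataclasses.dataclass(frozen=True)
class OutcomeSummary:
    """Outcome-category counts for one event term."""

    pt_term: str
    counts: dict[str, int]
    n_reported: int
    n_missing: int
    fatality_pct: float | None

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_reported:
            raise ValueError("category counts must sum to n_reported")


def tabulate_outcomes(rows: pd.DataFrame, pt_term: str | None = None) -> OutcomeSummary:
    """Count outcomes over analysis rows sharing one preferred term.

    Rows without a stated outcome are counted as missing, excluded from the
    fatality denominator; with no stated outcomes at all the fatality
    percentage is undefined (``None``).
    """
    if pt_term is None:
        terms = rows["pt_term"].unique()
        pt_term = str(terms[0]) if len(terms) else ""
    vc = rows["outcome"].value_counts()
    counts = {cat: int(vc.get(cat, 0)) for cat in OUTCOME_CATEGORIES}
    n_reported = sum(counts.values())
    n_missing = len(rows) - n_reported
    fatality = (
        round_half_up(100.0 * counts["death"] / n_reported, 1) if n_reported else None
    )
    return OutcomeSummary(
        pt_term=pt_term,
        counts=counts,
        n_reported=n_reported,
        n_missing=n_missing,
        fatality_pct=fatality,
    )


def outcome_report(summaries: list[OutcomeSummary]) -> pd.DataFrame:
    """Stacked-percentage table: one row per term, six percentage columns.

    Percentages are of reports with a stated outcome, rounded half-up to one
    decimal (so each row sums to 100 within rounding slack); raw counts and
    the missing count ride along.  Row order follows the input order, which
    callers typically take from the disproportionality screen.
    """
    records = []
    for s in summaries:
        rec: dict = {"pt_term": s.pt_term, "n_reported": s.n_reported, "n_missing": s.n_missing}
        for cat in OUTCOME_CATEGORIES:
            rec[f"pct_{cat}"] = (
                round_half_up(100.0 * s.counts[cat] / s.n_reported, 1)
                if s.n_reported else float("nan")
            )
        for cat in OUTCOME_CATEGORIES:
            rec[f"n_{cat}"] = s.counts[cat]
        rec["fatality_pct"] = s.fatality_pct if s.fatality_pct is not None else float("nan")
        records.append(rec)
    cols = (
        ["pt_term", "n_reported", "n_missing"]
        + [f"pct_{c}" for c in OUTCOME_CATEGORIES]
        + [f"n_{c}" for c in OUTCOME_CATEGORIES]
        + ["fatality_pct"]
    )
    return pd.DataFrame.from_records(records, columns=cols)
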