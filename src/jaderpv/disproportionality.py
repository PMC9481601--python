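"""Reporting odds ratio disproportionality screening.

For a target drug D and an event term E the data table partitions into the
2x2 contingency table

===============  =========  ============
..               event E    other events
===============  =========  ============
drug D           a          b
other drugs      c          d
===============  =========  ============

and the reporting odds ratio is ROR = (a/b)/(c/d) = ad/(bc): the odds of the
event among the target drug's reports relative to the same odds among every
other drug's reports.  The conventional signal criterion is a minimum case
count together with the lower bound of the Woolf (log-normal) 95% confidence
interval exceeding 1.  Because the comparator is other *reports* rather than
an exposed population, an ROR is a reporting disproportionality, not a
relative risk.
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd
from scipy import stats

from ._util import round_half_up
from .io import normalize_series, normalize_text
from .preprocess import DataTable, EventTermSet


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Counts (a, b, c, d) of the drug-by-event partition of the data table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "_CorrectedTable":
        """Haldane–Anscombe continuity correction: +0.5 on every cell."""
        return _CorrectedTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def transposed_treatment(self) -> "ContingencyTable":
        """Swap the drug rows (target <-> comparator)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclasses.dataclass(frozen=True)
class _CorrectedTable:
    a: float
    b: float
    c: float
    d: float


@dataclasses.dataclass(frozen=True)
class SignalResult:
    """One row of the screen: counts, rate, ROR with CI, Fisher p, flag.

    ``rate_pct``, ``ror``, ``ci_low`` and ``ci_high`` carry display rounding
    (half-up, two decimals); the ``*_exact`` fields carry full precision and
    are what the signal flag is decided on.
    """

    pt_term: str
    a: int
    b: int
    rate_pct: float
    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    signal: bool
    corrected: bool
    rate_exact: float = dataclasses.field(repr=False, default=float("nan"))
    ror_exact: float = dataclasses.field(repr=False, default=float("nan"))
    ci_low_exact: float = dataclasses.field(repr=False, default=float("nan"))
    ci_high_exact: float = dataclasses.field(repr=False, default=float("nan"))


def build_contingency(table: DataTable, drug_name: str, pt_term: str) -> ContingencyTable:
    """Partition the full data table on (drug match, term match).

    A drug absent from the table yields a zero target margin (a = b = 0),
    returned rather than raised, so screening a term list never aborts.
    """
    drug_match = normalize_series(table.rows["drug_name"]) == normalize_text(drug_name)
    term_match = normalize_series(table.rows["pt_term"]) == normalize_text(pt_term)
    a = int((drug_match & term_match).sum())
    b = int((drug_match & ~term_match).sum())
    c = int((~drug_match & term_match).sum())
    d = int((~drug_match & ~term_match).sum())
    return ContingencyTable(a, b, c, d)


def _cells(ct: ContingencyTable | _CorrectedTable, correction: bool):
    if isinstance(ct, ContingencyTable):
        if correction:
            ct = ct.corrected()
        else:
            for name in ("a", "b", "c", "d"):
                if getattr(ct, name) == 0:
                    raise ZeroDivisionError(
                        f"cell {name} is zero; the ROR is undefined without a "
                        "continuity correction"
                    )
    return ct.a, ct.b, ct.c, ct.d


def ror(ct: ContingencyTable, correction: bool = False) -> float:
    """Point estimate ad/(bc).

    With ``correction`` the Haldane–Anscombe +0.5 is applied to all cells;
    otherwise a zero cell raises, naming the cell — zero-cell handling should
    be an explicit caller decision, never silent.
    """
    a, b, c, d = _cells(ct, correction)
    return (a * d) / (b * c)


def ror_ci(
    ct: ContingencyTable, level: float = 0.95, correction: bool = False
) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval for the ROR.

    exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d)) with z the standard normal
    quantile for ``level``.
    """
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    a, b, c, d = _cells(ct, correction)
    point = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point * math.exp(-z * se), point * math.exp(z * se)


def fisher_exact_two_sided(ct: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the probability-mass rule.

    Sums hypergeometric probabilities (margins fixed) of every table at most
    as probable as the observed one.
    """
    res = stats.fisher_exact([[ct.a, ct.b], [ct.c, ct.d]], alternative="two-sided")
    return float(min(res.pvalue, 1.0))


def is_signal(a: int, ci_low: float, min_cases: int = 5) -> bool:
    """The detection criterion: at least ``min_cases`` reports and a lower
    confidence bound strictly above 1 (a bound of exactly 1 is no signal)."""
    return a >= min_cases and ci_low > 1.0


def screen_terms(
    table: DataTable,
    drug_name: str,
    terms: EventTermSet,
    min_cases: int = 5,
    level: float = 0.95,
    zero_cell: str = "correct",
) -> list[SignalResult]:
    """Screen every term of ``terms`` against ``drug_name`` on the full table.

    Terms with fewer than ``min_cases`` target-drug reports are excluded
    (the minimum is inclusive: five reports pass a five-case threshold).
    Results are ordered by descending case count, ties keeping the term-set
    order.  When a zero cell makes the ROR undefined, behaviour follows
    ``zero_cell``: ``"correct"`` applies the Haldane–Anscombe +0.5 and flags
    the row ``corrected``; ``"error"`` raises.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    if zero_cell not in ("correct", "error"):
        raise ValueError("zero_cell must be 'correct' or 'error'")
    # one normalization pass over the table, then O(1) per term
    drug_match = normalize_series(table.rows["drug_name"]) == normalize_text(drug_name)
    norm_pt = normalize_series(table.rows["pt_term"])
    n_target = int(drug_match.sum())
    n_other = len(table.rows) - n_target
    vc_target = norm_pt[drug_match].value_counts()
    vc_other = norm_pt[~drug_match].value_counts()
    results: list[SignalResult] = []
    for term in terms.terms:
        a = int(vc_target.get(term, 0))
        c = int(vc_other.get(term, 0))
        ct = ContingencyTable(a, n_target - a, c, n_other - c)
        if ct.a < min_cases:
            continue
        needs_correction = 0 in (ct.a, ct.b, ct.c, ct.d)
        if needs_correction and zero_cell == "error":
            # trigger the informative zero-cell error
            ror(ct, correction=False)
        use_corr = needs_correction
        point = ror(ct, correction=use_corr)
        low, high = ror_ci(ct, level=level, correction=use_corr)
        p = fisher_exact_two_sided(ct)
        rate = 100.0 * ct.a / (ct.a + ct.b) if (ct.a + ct.b) else float("nan")
        results.append(
            SignalResult(
                pt_term=term,
                a=ct.a,
                b=ct.b,
                rate_pct=round_half_up(rate, 2),
                ror=round_half_up(point, 2),
                ci_low=round_half_up(low, 2),
                ci_high=round_half_up(high, 2),
                p_value=p,
                signal=is_signal(ct.a, low, min_cases),
                corrected=use_corr,
                rate_exact=rate,
                ror_exact=point,
                ci_low_exact=low,
                ci_high_exact=high,
            )
        )
    results.sort(key=lambda r: -r.a)
    return results


def signals_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Render screen results as a table (display-rounded plus exact columns)."""
    cols = [
        "pt_term", "cases", "non_cases", "rate_pct", "ror", "ci_low", "ci_high",
        "p_value", "signal", "corrected",
        "rate_exact", "ror_exact", "ci_low_exact", "ci_high_exact",
    ]
    records = [
        {
            "pt_term": r.pt_term, "cases": r.a, "non_cases": r.b,
            "rate_pct": r.rate_pct, "ror": r.ror,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value, "signal": r.signal, "corrected": r.corrected,
            "rate_exact": r.rate_exact, "ror_exact": r.ror_exact,
            "ci_low_exact": r.ci_low_exact, "ci_high_exact": r.ci_high_exact,
        }
        for r in results
    ]
    return pd.DataFrame.from_records(records, columns=cols)
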