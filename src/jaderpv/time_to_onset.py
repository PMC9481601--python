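"""Time-to-onset samples and Weibull hazard-shape classification.

Onset time for an adverse event is counted in days from the first
administration of the most recent continuous dosing episode of the target
drug to the event onset, plus 0.5 day (the half-day convention treats a
same-day onset as half a day of exposure).  Dosing records separated by a
treatment gap longer than one year start a new episode.  Onsets beyond a
two-year horizon (730 days) are excluded.

The resulting uncensored samples are fit with a two-parameter Weibull
distribution, density

    f(t) = (beta/alpha) * (t/alpha)**(beta-1) * exp(-(t/alpha)**beta)

whose scale ``alpha`` (days) is the 63.2% quantile of onset and whose
dimensionless shape ``beta`` encodes how the hazard changes with time on
drug.  The position of beta's 95% confidence interval relative to 1
classifies the hazard: entirely below 1 -> early failure (decreasing
hazard), entirely above 1 -> wear-out failure (increasing hazard),
spanning 1 -> random failure (roughly constant hazard).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import PartialDate, normalize_series, normalize_text

logger = logging.getLogger(__name__)

FAILURE_TYPES = ("early", "random", "wear_out", "indeterminate")


@dataclasses.dataclass(frozen=True)
class DosingEpisode:
    """One continuous administration period (end may be open)."""

    start: datetime.date
    end: datetime.date | None = None

    def __post_init__(self) -> None:
        if self.end is not None and self.end < self.start:
            raise ValueError("episode end precedes start")


@dataclasses.dataclass(frozen=True)
class WeibullFit:
    """MLE of a two-parameter Weibull on uncensored onset-day samples."""

    n: int
    alpha: float
    beta: float
    alpha_ci: tuple[float, float] | None
    beta_ci: tuple[float, float] | None
    median_days: float
    iqr_days: tuple[float, float]
    failure_type: str
    loglik: float = dataclasses.field(repr=False, default=float("nan"))


def resolve_partial_date(
    pdate: PartialDate | None, day_of_month: int = 1
) -> datetime.date | None:
    """Resolve a partial date to a calendar date for day arithmetic.

    Year/month records resolve to ``day_of_month`` (default the 1st; a
    deliberate, conservative convention given the half-day onset formula);
    year-only or absent dates resolve to missing.
    """
    if pdate is None:
        return None
    return pdate.resolve(day_of_month=day_of_month)


def reconstruct_episodes(
    drug_records: pd.DataFrame,
    gap_days: int = 365,
    day_of_month: int = 1,
    require_end_date: bool = False,
) -> tuple[list[DosingEpisode], int]:
    """Merge one case's records for one drug into continuous dosing episodes.

    Records are sorted by resolved start date and merged into a running
    episode unless the gap from the episode's last known date (its end where
    recorded, else its start) to the next record's start exceeds
    ``gap_days`` — a non-administration period over one year starts a new
    episode.  Records whose start date cannot be resolved (and, with
    ``require_end_date``, records without a resolvable end) are skipped and
    counted; the count is returned alongside the episodes.
    """
    resolved: list[tuple[datetime.date, datetime.date | None]] = []
    n_skipped = 0
    for _, rec in drug_records.iterrows():
        start = resolve_partial_date(PartialDate.parse(rec["start_date"]), day_of_month)
        end = resolve_partial_date(PartialDate.parse(rec["end_date"]), day_of_month)
        if start is None or (require_end_date and end is None):
            n_skipped += 1
            continue
        if end is not None and end < start:
            n_skipped += 1
            continue
        resolved.append((start, end))
    if n_skipped:
        logger.debug("reconstruct_episodes: skipped %d undatable records", n_skipped)
    resolved.sort(key=lambda se: se[0])

    episodes: list[DosingEpisode] = []
    for start, end in resolved:
        if episodes:
            last = episodes[-1]
            anchor = last.end if last.end is not None else last.start
            anchor = max(anchor, last.start)
            if (start - anchor).days <= gap_days:
                new_end = end if last.end is None else (
                    last.end if end is None else max(last.end, end)
                )
                episodes[-1] = DosingEpisode(start=last.start, end=new_end)
                continue
        episodes.append(DosingEpisode(start=start, end=end))
    return episodes, n_skipped


def onset_days(
    onset: datetime.date,
    episodes: list[DosingEpisode],
    horizon: float = 730.0,
) -> float | None:
    """Days from the relevant episode start to onset, plus the half-day.

    The reference start is the start of the latest episode beginning on or
    before the onset date (the most recent continuous administration
    period).  Returns ``None`` (a rejection, to be counted by the caller)
    when no episode qualifies or the value exceeds ``horizon``.
    """
    starts = [ep.start for ep in episodes if ep.start <= onset]
    if not starts:
        return None
    days = (onset - max(starts)).days + 0.5
    if days <= 0 or days > horizon:
        return None
    return days


def collect_onset_samples(
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    drug_name: str,
    pt_term: str,
    horizon: float = 730.0,
    gap_days: int = 365,
    day_of_month: int = 1,
    require_end_date: bool = True,
) -> tuple[np.ndarray, dict[str, int]]:
    """Gather onset-day samples for one (drug, event term) pair.

    Eligible reports are cases carrying a *suspected* record of the target
    drug and a report of the term with a resolvable onset date.  By default
    a dosing record must carry both a resolvable start and end date to
    anchor the episode reconstruction (reports lacking any of the three
    dates at year/month precision or better do not enter the count);
    ``require_end_date=False`` relaxes this.  Returns the sample array and
    a dictionary of rejection counts.
    """
    dnorm = normalize_text(drug_name)
    tnorm = normalize_text(pt_term)
    dsub = drug.loc[normalize_series(drug["drug_name"]) == dnorm]
    suspected_cases = set(dsub.loc[dsub["involvement"] == "suspected", "case_id"])
    rsub = reac.loc[
        (normalize_series(reac["pt_term"]) == tnorm)
        & reac["case_id"].isin(suspected_cases)
    ]

    counts = {
        "case_terms": 0,
        "no_onset_date": 0,
        "no_episode": 0,
        "beyond_horizon": 0,
        "undatable_drug_records": 0,
        "used": 0,
    }
    samples: list[float] = []
    for case_id, case_rows in rsub.groupby("case_id", sort=True):
        counts["case_terms"] += 1
        onset = None
        for raw in case_rows["onset_date"]:
            onset = resolve_partial_date(PartialDate.parse(raw), day_of_month)
            if onset is not None:
                break
        if onset is None:
            counts["no_onset_date"] += 1
            continue
        episodes, n_skipped = reconstruct_episodes(
            dsub.loc[dsub["case_id"] == case_id],
            gap_days=gap_days,
            day_of_month=day_of_month,
            require_end_date=require_end_date,
        )
        counts["undatable_drug_records"] += n_skipped
        if not episodes:
            counts["no_episode"] += 1
            continue
        days = onset_days(onset, episodes, horizon=horizon)
        if days is None:
            if any(ep.start <= onset for ep in episodes):
                counts["beyond_horizon"] += 1
            else:
                counts["no_episode"] += 1
            continue
        counts["used"] += 1
        samples.append(days)
    return np.asarray(samples, dtype=float), counts


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------

def _loglik(t: np.ndarray, log_alpha: float, log_beta: float) -> float:
    beta = math.exp(log_beta)
    lt = np.log(t)
    return float(
        t.size * log_beta
        - t.size * beta * log_alpha
        + (beta - 1.0) * lt.sum()
        - np.exp(beta * (lt - log_alpha)).sum()
    )


def _mle_point(t: np.ndarray) -> tuple[float, float]:
    """Solve the profile score equation for beta, then alpha in closed form."""
    lt = np.log(t)
    mean_lt = lt.mean()

    def score(beta: float) -> float:
        w = np.exp(beta * (lt - lt.max()))  # stabilized t**beta
        return float((w * lt).sum() / w.sum() - 1.0 / beta - mean_lt)

    lo, hi = 1e-3, 2.0
    while score(hi) < 0 and hi < 1e4:
        hi *= 2.0
    while score(lo) > 0 and lo > 1e-8:
        lo /= 2.0
    beta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12)
    alpha = float(np.exp(lt.max()) * (np.exp(beta * (lt - lt.max())).mean()) ** (1.0 / beta))
    return alpha, beta


def _wald_ci_log_scale(
    t: np.ndarray, alpha: float, beta: float, level: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Wald intervals from the observed information in (log alpha, log beta)."""
    la, lb = math.log(alpha), math.log(beta)
    h = 1e-5
    H = np.empty((2, 2))

    def nll(p):
        return -_loglik(t, p[0], p[1])

    p0 = np.array([la, lb])
    for i in range(2):
        for j in range(2):
            pp = p0.copy(); pp[i] += h; pp[j] += h
            pm = p0.copy(); pm[i] += h; pm[j] -= h
            mp = p0.copy(); mp[i] -= h; mp[j] += h
            mm = p0.copy(); mm[i] -= h; mm[j] -= h
            H[i, j] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h * h)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        (alpha * math.exp(-z * se[0]), alpha * math.exp(z * se[0])),
        (beta * math.exp(-z * se[1]), beta * math.exp(z * se[1])),
    )


def _profile_ci(
    t: np.ndarray, alpha: float, beta: float, level: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Profile-likelihood intervals by inverting the likelihood-ratio test."""
    lmax = _loglik(t, math.log(alpha), math.log(beta))
    crit = lmax - stats.chi2.ppf(level, df=1) / 2.0
    lt = np.log(t)

    def prof_beta(lb: float) -> float:
        b = math.exp(lb)
        # closed-form profiled scale: log alpha(beta) = max(lt) + log(mean(e^{b(lt-max)}))/b
        la = lt.max() + math.log(np.exp(b * (lt - lt.max())).mean()) / b
        return _loglik(t, la, lb)

    def prof_alpha(la: float) -> float:
        res = optimize.minimize_scalar(
            lambda lb: -_loglik(t, la, lb),
            bracket=(math.log(beta) - 1.0, math.log(beta) + 1.0),
            method="brent",
        )
        return -res.fun

    def invert(prof, center: float) -> tuple[float, float]:
        def g(x):
            return prof(x) - crit

        step = 0.1
        lo = center - step
        while g(lo) > 0 and center - lo < 50:
            lo -= step
            step *= 1.5
        low = optimize.brentq(g, lo, center, xtol=1e-9)
        step = 0.1
        hi = center + step
        while g(hi) > 0 and hi - center < 50:
            hi += step
            step *= 1.5
        high = optimize.brentq(g, center, hi, xtol=1e-9)
        return math.exp(low), math.exp(high)

    return invert(prof_alpha, math.log(alpha)), invert(prof_beta, math.log(beta))


def classify_failure_type(beta_ci: tuple[float, float] | None) -> str:
    """Map beta's confidence interval to the hazard-shape taxonomy.

    Upper bound below 1 -> ``early`` (decreasing hazard); lower bound above
    1 -> ``wear_out`` (increasing hazard); interval spanning 1 ->
    ``random``; no interval -> ``indeterminate``.  Scale-free: beta is
    dimensionless, so the classification is invariant to the time unit.
    """
    if beta_ci is None:
        return "indeterminate"
    low, high = beta_ci
    if not (math.isfinite(low) and math.isfinite(high)) or low > high:
        return "indeterminate"
    if high < 1.0:
        return "early"
    if low > 1.0:
        return "wear_out"
    return "random"


def weibull_mle(
    samples: np.ndarray | list[float],
    level: float = 0.95,
    ci_method: str = "wald",
    fixed_beta: float | None = None,
) -> WeibullFit:
    """Fit a two-parameter Weibull by maximum likelihood on uncensored data.

    Confidence intervals are Wald intervals on the log-parameter scale,
    back-transformed (``ci_method='profile'`` inverts the likelihood-ratio
    test instead); they require n >= 3 and are omitted below that, which
    also makes the classification indeterminate.  Median and interquartile
    range are distribution-free (linear-interpolation sample quantiles),
    reported alongside the parametric fit.  With ``fixed_beta`` the shape is
    constrained and only the scale estimated (``fixed_beta=1`` reduces to
    the exponential, whose scale MLE is the sample mean).
    """
    t = np.asarray(samples, dtype=float)
    if t.size == 0:
        raise ValueError("empty sample: cannot fit a Weibull distribution")
    if np.any(t <= 0):
        raise ValueError("onset-day samples must be strictly positive")
    if ci_method not in ("wald", "profile"):
        raise ValueError("ci_method must be 'wald' or 'profile'")

    n = int(t.size)
    median = float(np.quantile(t, 0.5))
    iqr = (float(np.quantile(t, 0.25)), float(np.quantile(t, 0.75)))

    if fixed_beta is not None:
        if fixed_beta <= 0:
            raise ValueError("fixed_beta must be positive")
        alpha = float((np.power(t, fixed_beta).mean()) ** (1.0 / fixed_beta))
        return WeibullFit(
            n=n, alpha=alpha, beta=float(fixed_beta),
            alpha_ci=None, beta_ci=None,
            median_days=median, iqr_days=iqr,
            failure_type="indeterminate",
            loglik=_loglik(t, math.log(alpha), math.log(fixed_beta)),
        )

    degenerate = n == 1 or bool(np.all(t == t[0]))
    if degenerate:
        warnings.warn(
            "degenerate onset sample (all values identical); the Weibull shape "
            "diverges and the fit is indeterminate",
            RuntimeWarning,
            stacklevel=2,
        )
        return WeibullFit(
            n=n, alpha=float(t[0]), beta=math.inf,
            alpha_ci=None, beta_ci=None,
            median_days=median, iqr_days=iqr,
            failure_type="indeterminate",
        )

    alpha, beta = _mle_point(t)
    alpha_ci = beta_ci = None
    if n >= 3:
        if ci_method == "wald":
            alpha_ci, beta_ci = _wald_ci_log_scale(t, alpha, beta, level)
        else:
            alpha_ci, beta_ci = _profile_ci(t, alpha, beta, level)
    return WeibullFit(
        n=n, alpha=alpha, beta=beta,
        alpha_ci=alpha_ci, beta_ci=beta_ci,
        median_days=median, iqr_days=iqr,
        failure_type=classify_failure_type(beta_ci),
        loglik=_loglik(t, math.log(alpha), math.log(beta)),
    )


def onset_histogram(
    samples: np.ndarray | list[float], bin_width: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram onset days into left-closed bins of ``bin_width`` days from 0.

    The final edge is the smallest multiple of ``bin_width`` covering the
    largest sample, and (numpy convention) the last bin includes its right
    edge, so a sample exactly at the horizon lands in the last bin.  Counts
    always sum to the sample size.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = np.asarray(samples, dtype=float)
    if t.size == 0:
        return np.array([0.0, bin_width]), np.array([0], dtype=int)
    n_bins = max(1, int(math.ceil(t.max() / bin_width)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    counts, _ = np.histogram(t, bins=edges)
    return edges, counts.astype(int)
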