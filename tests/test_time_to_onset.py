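"""Dating rules, episode reconstruction and the Weibull hazard classification."""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd
import pytest

from jaderpv.io import PartialDate
from jaderpv.time_to_onset import (
    DosingEpisode,
    classify_failure_type,
    collect_onset_samples,
    onset_days,
    onset_histogram,
    reconstruct_episodes,
    resolve_partial_date,
    weibull_mle,
)


def _drug_records(rows):
    return pd.DataFrame(
        rows, columns=["case_id", "drug_name", "involvement", "start_date", "end_date"]
    )


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------

def test_single_record_single_episode():
    eps, skipped = reconstruct_episodes(
        _drug_records([("C1", "a", "suspected", "2018-03-01", "2018-05-01")])
    )
    assert skipped == 0
    assert eps == [DosingEpisode(datetime.date(2018, 3, 1), datetime.date(2018, 5, 1))]


def test_gap_over_one_year_starts_new_episode():
    # end 2018-03-01 -> next start 2019-06-01 is a 457-day gap
    eps, _ = reconstruct_episodes(
        _drug_records(
            [
                ("C1", "a", "suspected", "2018-01-01", "2018-03-01"),
                ("C1", "a", "suspected", "2019-06-01", "2019-08-01"),
            ]
        )
    )
    assert len(eps) == 2
    assert eps[1].start == datetime.date(2019, 6, 1)


def test_gap_within_one_year_merges():
    # end 2018-03-01 -> next start 2018-09-01 is 184 days: one episode
    eps, _ = reconstruct_episodes(
        _drug_records(
            [
                ("C1", "a", "suspected", "2018-01-01", "2018-03-01"),
                ("C1", "a", "suspected", "2018-09-01", "2018-10-01"),
            ]
        )
    )
    assert len(eps) == 1
    assert eps[0].start == datetime.date(2018, 1, 1)
    assert eps[0].end == datetime.date(2018, 10, 1)


def test_records_without_resolvable_start_are_skipped_and_counted():
    eps, skipped = reconstruct_episodes(
        _drug_records(
            [
                ("C1", "a", "suspected", "", "2018-05-01"),
                ("C1", "a", "suspected", "2018", "2018-05-01"),  # year-only
                ("C1", "a", "suspected", "2018-04", "2018-05-01"),
            ]
        )
    )
    assert skipped == 2
    assert len(eps) == 1
    assert eps[0].start == datetime.date(2018, 4, 1)  # year/month -> day 1


def test_require_end_date_drops_open_records():
    records = _drug_records(
        [
            ("C1", "a", "suspected", "2018-04-01", ""),
            ("C1", "a", "suspected", "2018-06-01", "2018-07-01"),
        ]
    )
    eps, skipped = reconstruct_episodes(records, require_end_date=True)
    assert skipped == 1
    assert eps[0].start == datetime.date(2018, 6, 1)
    eps2, skipped2 = reconstruct_episodes(records, require_end_date=False)
    assert skipped2 == 0
    assert eps2[0].start == datetime.date(2018, 4, 1)


# ---------------------------------------------------------------------------
# Onset days
# ---------------------------------------------------------------------------

def test_same_day_onset_is_half_a_day():
    eps = [DosingEpisode(datetime.date(2019, 5, 1), None)]
    assert onset_days(datetime.date(2019, 5, 1), eps) == 0.5


def test_onset_arithmetic():
    eps = [DosingEpisode(datetime.date(2019, 5, 1), None)]
    assert onset_days(datetime.date(2019, 5, 31), eps) == 30.5


def test_onset_beyond_horizon_rejected():
    eps = [DosingEpisode(datetime.date(2017, 1, 1), None)]
    onset = datetime.date(2017, 1, 1) + datetime.timedelta(days=800)
    assert onset_days(onset, eps, horizon=730) is None
    assert onset_days(onset, eps, horizon=1000) == 800.5


def test_onset_uses_most_recent_qualifying_episode():
    eps = [
        DosingEpisode(datetime.date(2016, 1, 1), datetime.date(2016, 3, 1)),
        DosingEpisode(datetime.date(2019, 1, 1), None),
    ]
    assert onset_days(datetime.date(2019, 1, 11), eps) == 10.5
    # onset before every episode start: rejected
    assert onset_days(datetime.date(2015, 1, 1), eps) is None


def test_onset_days_translation_invariant():
    base = datetime.date(2018, 1, 1)
    for k in (0, 37, 400):
        shift = datetime.timedelta(days=k)
        eps = [DosingEpisode(base + shift, base + datetime.timedelta(days=60) + shift)]
        assert onset_days(base + datetime.timedelta(days=45) + shift, eps) == 45.5


def test_collect_onset_samples_pipeline():
    drug = _drug_records(
        [
            ("C1", "bev", "suspected", "2018-01-01", "2018-06-01"),
            ("C2", "bev", "suspected", "2018-01-01", ""),       # no end date
            ("C3", "bev", "concomitant", "2018-01-01", "2018-02-01"),
            ("C4", "bev", "suspected", "2018-01-01", "2018-03-01"),
        ]
    )
    reac = pd.DataFrame(
        [
            ("C1", "rash", "2018-01-31", "recovery"),
            ("C2", "rash", "2018-02-10", "death"),
            ("C3", "rash", "2018-01-15", ""),
            ("C4", "rash", "", ""),                              # no onset date
        ],
        columns=["case_id", "pt_term", "onset_date", "outcome"],
    )
    samples, counts = collect_onset_samples(drug, reac, "bev", "rash")
    # C1 only: C2 lacks an end date, C3 is not suspected, C4 has no onset
    assert list(samples) == [30.5]
    assert counts["used"] == 1
    assert counts["no_onset_date"] == 1
    assert counts["no_episode"] == 1  # C2's record dropped under require_end_date
    samples2, _ = collect_onset_samples(drug, reac, "bev", "rash", require_end_date=False)
    assert sorted(samples2) == [30.5, 40.5]


# ---------------------------------------------------------------------------
# Weibull MLE
# ---------------------------------------------------------------------------

def test_weibull_parameter_recovery():
    rng = np.random.default_rng(42)
    t = 100.0 * rng.weibull(2.0, size=1000)
    fit = weibull_mle(t)
    assert abs(fit.alpha - 100.0) <= 5.0
    assert abs(fit.beta - 2.0) <= 0.15
    assert fit.alpha_ci[0] <= fit.alpha <= fit.alpha_ci[1]
    assert fit.beta_ci[0] <= fit.beta <= fit.beta_ci[1]


def test_weibull_matches_independent_fitter():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    t = 60.0 * rng.weibull(1.3, size=200)
    fit = weibull_mle(t)
    wf = lifelines.WeibullFitter().fit(t)
    assert fit.alpha == pytest.approx(wf.lambda_, rel=2e-3)
    assert fit.beta == pytest.approx(wf.rho_, rel=2e-3)


def test_exponential_constraint_gives_sample_mean():
    rng = np.random.default_rng(3)
    t = rng.exponential(50.0, size=400)
    fit = weibull_mle(t, fixed_beta=1.0)
    assert fit.alpha == pytest.approx(t.mean())


def test_degenerate_sample_is_indeterminate_with_warning():
    with pytest.warns(RuntimeWarning, match="degenerate"):
        fit = weibull_mle([35.5, 35.5, 35.5])
    assert fit.failure_type == "indeterminate"
    assert fit.alpha_ci is None and fit.beta_ci is None
    assert fit.median_days == 35.5


def test_small_samples_have_no_intervals():
    fit = weibull_mle([2.5, 475.5])
    assert fit.n == 2
    assert fit.alpha_ci is None and fit.beta_ci is None
    assert fit.failure_type == "indeterminate"
    assert fit.median_days == pytest.approx(239.0)
    with pytest.raises(ValueError):
        weibull_mle([])


def test_profile_ci_close_to_wald_at_moderate_n():
    rng = np.random.default_rng(11)
    t = 120.0 * rng.weibull(1.8, size=400)
    wald = weibull_mle(t, ci_method="wald")
    prof = weibull_mle(t, ci_method="profile")
    for w, p in zip(wald.beta_ci, prof.beta_ci):
        assert p == pytest.approx(w, rel=0.05)
    for w, p in zip(wald.alpha_ci, prof.alpha_ci):
        assert p == pytest.approx(w, rel=0.05)


def test_wald_interval_bias_and_coverage():
    """Median relative bias < 5% and ~95% CI coverage at the n=150 scale."""
    rng = np.random.default_rng(2026)
    true_alpha, true_beta = 100.0, 1.5
    rel_a, rel_b, covered = [], [], 0
    n_rep = 200
    for _ in range(n_rep):
        t = true_alpha * rng.weibull(true_beta, size=150)
        fit = weibull_mle(t)
        rel_a.append((fit.alpha - true_alpha) / true_alpha)
        rel_b.append((fit.beta - true_beta) / true_beta)
        covered += fit.beta_ci[0] <= true_beta <= fit.beta_ci[1]
    assert abs(np.median(rel_a)) < 0.05
    assert abs(np.median(rel_b)) < 0.05
    assert covered / n_rep == pytest.approx(0.95, abs=0.04)


# ---------------------------------------------------------------------------
# Failure-type classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ci,expected",
    [
        ((1.25, 3.28), "wear_out"),   # shape CI entirely above 1
        ((0.43, 0.95), "early"),      # entirely below 1
        ((0.93, 1.19), "random"),     # spans 1
        ((0.84, 1.84), "random"),
        (None, "indeterminate"),
    ],
)
def test_classification_rule(ci, expected):
    assert classify_failure_type(ci) == expected


def test_classification_invariant_to_time_units():
    rng = np.random.default_rng(5)
    t = 90.0 * rng.weibull(2.2, size=300)
    days = weibull_mle(t)
    hours = weibull_mle(t * 24.0)
    assert days.beta == pytest.approx(hours.beta, rel=1e-6)
    assert days.failure_type == hours.failure_type
    assert hours.alpha == pytest.approx(days.alpha * 24.0, rel=1e-6)


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------

def test_histogram_bins():
    edges, counts = onset_histogram([0.5, 30.5], bin_width=30)
    assert list(edges) == [0.0, 30.0, 60.0]
    assert list(counts) == [1, 1]


def test_histogram_counts_conserved(rng):
    t = 730.0 * rng.random(257)
    _, counts = onset_histogram(t, bin_width=30)
    assert counts.sum() == 257


def test_histogram_horizon_sample_in_last_bin():
    edges, counts = onset_histogram([730.0], bin_width=73)
    assert edges[-1] == 730.0
    assert counts[-1] == 1


def test_histogram_rejects_bad_width():
    with pytest.raises(ValueError):
        onset_histogram([1.0], bin_width=0)
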