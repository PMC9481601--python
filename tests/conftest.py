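"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Integer binomial coefficients make the probability-mass comparison
    exact: a table enters the sum iff its (integer) unnormalized pmf is at
    most the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return num / math.comb(n, c1)


def brute_force_merge_count(demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame) -> int:
    """Count unique (case, drug, term) pairs by nested loops over raw rows."""
    drug_pairs = {(r.case_id, r.drug_name) for r in drug.itertuples()}
    reac_pairs = {(r.case_id, r.pt_term) for r in reac.itertuples()}
    triples = set()
    for case_d, d in drug_pairs:
        for case_r, t in reac_pairs:
            if case_d == case_r:
                triples.add((case_d, d, t))
    return len(triples)


# ---------------------------------------------------------------------------
# Random table builders
# ---------------------------------------------------------------------------

DRUG_VOCAB = ["alpha", "beta", "gamma"]
TERM_VOCAB = ["headache", "nausea", "rash", "fever"]


def random_raw_tables(rng: np.random.Generator, n_cases: int = 20):
    """Small random DEMO/DRUG/REAC tables with dirt (dups, partial dates)."""
    cases = [f"C{i:03d}" for i in range(n_cases)]
    demo = pd.DataFrame(
        {
            "case_id": cases,
            "sex": rng.choice(["male", "female", "??"], n_cases),
            "age_band": rng.choice(["20s", "60s", "unknown"], n_cases),
        }
    )
    n_drug = int(rng.integers(n_cases, 3 * n_cases + 1))
    drug = pd.DataFrame(
        {
            "case_id": rng.choice(cases, n_drug),
            "drug_name": rng.choice(DRUG_VOCAB, n_drug),
            "involvement": rng.choice(
                ["suspected", "concomitant", "interaction"], n_drug
            ),
            "start_date": rng.choice(["2018-02-03", "2018-06", "2019", ""], n_drug),
            "end_date": rng.choice(["2018-09-01", ""], n_drug),
        }
    )
    n_reac = int(rng.integers(n_cases, 3 * n_cases + 1))
    reac = pd.DataFrame(
        {
            "case_id": rng.choice(cases, n_reac),
            "pt_term": rng.choice(TERM_VOCAB, n_reac),
            "onset_date": rng.choice(["2018-03-05", "2018-07", ""], n_reac),
            "outcome": rng.choice(["recovery", "death", "unclear", ""], n_reac),
        }
    )
    return demo, drug, reac


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def small_analysis_rows() -> pd.DataFrame:
    """A hand-written merged analysis table for filter/subset tests."""
    rows = []
    for i, (drug, inv, term) in enumerate(
        [
            ("alpha", "suspected", "headache"),
            ("alpha", "suspected", "nausea"),
            ("alpha", "concomitant", "rash"),
            ("beta", "suspected", "headache"),
            ("beta", "interaction", "fever"),
            ("gamma", "suspected", "rash"),
            ("gamma", "concomitant", "nausea"),
            ("alpha", "suspected", "fever"),
            ("beta", "concomitant", "rash"),
            ("gamma", "suspected", "headache"),
        ]
    ):
        rows.append(
            {
                "case_id": f"C{i:03d}",
                "drug_name": drug,
                "pt_term": term,
                "involvement": inv,
                "sex": "male" if i % 2 else "female",
                "age_band": "60s",
                "onset_date": "",
                "start_date": "",
                "end_date": "",
                "outcome": "",
            }
        )
    return pd.DataFrame(rows)
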