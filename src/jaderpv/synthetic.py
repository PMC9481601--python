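"""Synthetic spontaneous-report generator and reference margin fixture.

Two generators live here:

``generate``
    samples JADER-shaped DEMO/DRUG/REAC tables from an explicit statistical
    model — per-case drug exposure, background event reporting rates
    multiplied by planted drug–event rate ratios, Weibull-distributed onset
    times anchored to drug start dates, a six-category outcome model, plus
    the classic dirt of spontaneous data (exact-duplicate rows, dates
    degraded to year/month precision).  Every pipeline stage is testable
    against the planted truth without access to a regulator database.

``reference_margin_fixture``
    a deterministic table set reproducing the published per-term margins of
    the bevacizumab lung-toxicity screen in JADER (April 2004 – March 2021):
    20,399 suspected-bevacizumab report triples, 1,679 of them across 29
    lung-toxicity preferred terms with the exact reported case counts and
    patient demographics.  The other-drug margin is back-solved per term
    from the reported RORs against the full-database totals and scaled down
    100-fold so the fixture stays desk-sized; rates, counts and percentages
    on the target-drug side are exact, other-drug-side statistics are
    approximate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .io import (
    AGE_BANDS,
    OUTCOME_CATEGORIES,
    SEX_CATEGORIES,
    TABLE_SCHEMAS,
    normalize_text,
)


class ConfigError(ValueError):
    """A simulation configuration field is invalid (named in the message)."""


_DEFAULT_SEX = {"male": 0.55, "female": 0.42, "unknown": 0.03}
_DEFAULT_AGE = {
    "10s": 0.005, "20s": 0.01, "30s": 0.03, "40s": 0.07, "50s": 0.15,
    "60s": 0.33, "70s": 0.30, "80s": 0.09, "90s": 0.005, "unknown": 0.01,
}
_DEFAULT_OUTCOME = {
    "recovery": 0.35, "remission": 0.10, "not_recovered": 0.10,
    "sequelae": 0.03, "death": 0.07, "unclear": 0.15, "missing": 0.20,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the report simulator.

    ``association`` maps drug -> event -> reporting-rate ratio (1 = no
    planted signal); an exposed case reports an event with probability
    ``background * product(rate ratios of its drugs)``, capped at 1.
    ``onset`` maps drug -> event -> (alpha, beta) of the Weibull onset-time
    model used when that drug anchors the event (default ``default_onset``).
    Identical (config, seed) pairs yield byte-identical tables.
    """

    n_cases: int = 1000
    drugs: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"bevacizumab": 0.10, "comparator": 0.50}
    )
    events: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "interstitial lung disease": 0.02,
            "pulmonary embolism": 0.01,
            "pneumonia": 0.03,
            "hypertension": 0.05,
        }
    )
    association: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    onset: dict[str, dict[str, tuple[float, float]]] = dataclasses.field(default_factory=dict)
    default_onset: tuple[float, float] = (100.0, 1.5)
    outcome_probs: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    sex_probs: dict[str, float] = dataclasses.field(default_factory=lambda: dict(_DEFAULT_SEX))
    age_probs: dict[str, float] = dataclasses.field(default_factory=lambda: dict(_DEFAULT_AGE))
    concomitant_prob: float = 0.30
    mean_duration_days: float = 120.0
    missing_date_frac: float = 0.10
    duplicate_frac: float = 0.05
    start_window: tuple[str, str] = ("2004-04-01", "2021-03-31")
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        def _prob(name: str, v: float) -> None:
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v!r}")

        if not (isinstance(self.n_cases, int) and self.n_cases >= 1):
            raise ConfigError(f"n_cases must be a positive integer, got {self.n_cases!r}")
        if not self.drugs:
            raise ConfigError("drugs must be nonempty")
        if not self.events:
            raise ConfigError("events must be nonempty")
        for d, p in self.drugs.items():
            _prob(f"drugs[{d!r}]", p)
        for e, p in self.events.items():
            _prob(f"events[{e!r}]", p)
        for d, evs in self.association.items():
            if d not in self.drugs:
                raise ConfigError(f"association references unknown drug {d!r}")
            for e, rr in evs.items():
                if e not in self.events:
                    raise ConfigError(f"association references unknown event {e!r}")
                if not rr > 0:
                    raise ConfigError(f"association[{d!r}][{e!r}] must be > 0, got {rr!r}")
        for d, evs in self.onset.items():
            for e, ab in evs.items():
                if len(ab) != 2 or ab[0] <= 0 or ab[1] <= 0:
                    raise ConfigError(
                        f"onset[{d!r}][{e!r}] must be (alpha>0, beta>0), got {ab!r}"
                    )
        if self.default_onset[0] <= 0 or self.default_onset[1] <= 0:
            raise ConfigError(f"default_onset must be positive, got {self.default_onset!r}")
        for label, probs, cats in (
            ("sex_probs", self.sex_probs, SEX_CATEGORIES),
            ("age_probs", self.age_probs, AGE_BANDS),
        ):
            for k in probs:
                if k not in cats:
                    raise ConfigError(f"{label} has unknown category {k!r}")
            for k, p in probs.items():
                _prob(f"{label}[{k!r}]", p)
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{label} must sum to 1")
        valid_outcomes = set(OUTCOME_CATEGORIES) | {"missing"}
        for e, probs in self.outcome_probs.items():
            for k, p in probs.items():
                if k not in valid_outcomes:
                    raise ConfigError(f"outcome_probs[{e!r}] has unknown category {k!r}")
                _prob(f"outcome_probs[{e!r}][{k!r}]", p)
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigError(f"outcome_probs[{e!r}] must sum to 1")
        for name in ("concomitant_prob", "missing_date_frac", "duplicate_frac"):
            _prob(name, getattr(self, name))
        if self.mean_duration_days <= 0:
            raise ConfigError("mean_duration_days must be positive")
        lo, hi = np.datetime64(self.start_window[0]), np.datetime64(self.start_window[1])
        if hi < lo:
            raise ConfigError("start_window end precedes start")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    # -- (de)serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        if "onset" in kwargs:
            kwargs["onset"] = {
                d: {e: tuple(ab) for e, ab in evs.items()}
                for d, evs in kwargs["onset"].items()
            }
        if "default_onset" in kwargs:
            kwargs["default_onset"] = tuple(kwargs["default_onset"])
        if "start_window" in kwargs:
            kwargs["start_window"] = tuple(kwargs["start_window"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["default_onset"] = list(self.default_onset)
        d["start_window"] = list(self.start_window)
        d["onset"] = {dr: {e: list(ab) for e, ab in evs.items()} for dr, evs in self.onset.items()}
        return d


def _dates_to_strings(offsets: np.ndarray, origin: np.datetime64) -> np.ndarray:
    return (origin + offsets.astype("timedelta64[D]")).astype("datetime64[D]").astype(str)


def _degrade_dates(dates: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Truncate a fraction of full dates to year/month precision."""
    if frac <= 0 or dates.size == 0:
        return dates
    mask = (rng.random(dates.size) < frac) & (np.char.str_len(dates.astype(str)) == 10)
    out = dates.astype(object)
    out[mask] = [s[:7] for s in out[mask]]
    return out.astype(str)


def generate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample (demo, drug, reac) tables from the configured model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = list(config.drugs)
    events = list(config.events)
    D, E = len(drugs), len(events)
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    # demographics
    sex_cats = list(config.sex_probs)
    age_cats = list(config.age_probs)
    sex = rng.choice(sex_cats, size=n, p=[config.sex_probs[c] for c in sex_cats])
    age = rng.choice(age_cats, size=n, p=[config.age_probs[c] for c in age_cats])
    demo = pd.DataFrame({"case_id": case_ids, "sex": sex, "age_band": age})

    # drug exposure and dosing dates
    p_drug = np.array([config.drugs[d] for d in drugs])
    expo = rng.random((n, D)) < p_drug
    origin = np.datetime64(config.start_window[0])
    span = int(
        (np.datetime64(config.start_window[1]) - origin) / np.timedelta64(1, "D")
    )
    start_off = rng.integers(0, span + 1, size=(n, D))
    durations = np.maximum(1, rng.exponential(config.mean_duration_days, (n, D)).astype(int))

    # events: background * product of exposed drugs' rate ratios, capped at 1
    log_rr = np.zeros((D, E))
    for di, d in enumerate(drugs):
        for ei, e in enumerate(events):
            log_rr[di, ei] = np.log(config.association.get(d, {}).get(e, 1.0))
    bg = np.array([config.events[e] for e in events])
    p_event = np.minimum(1.0, bg * np.exp(expo.astype(float) @ log_rr))
    occur = rng.random((n, E)) < p_event

    rr = np.exp(log_rr)
    alpha_de = np.empty((D, E))
    beta_de = np.empty((D, E))
    for di, d in enumerate(drugs):
        for ei, e in enumerate(events):
            ab = config.onset.get(d, {}).get(e, config.default_onset)
            alpha_de[di, ei], beta_de[di, ei] = ab

    drug_rows: list[pd.DataFrame] = []
    for di, d in enumerate(drugs):
        cases = np.nonzero(expo[:, di])[0]
        if cases.size == 0:
            continue
        starts = _dates_to_strings(start_off[cases, di], origin)
        ends = _dates_to_strings(start_off[cases, di] + durations[cases, di], origin)
        drug_rows.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[cases],
                    "drug_name": d,
                    "involvement": "suspected",
                    "start_date": _degrade_dates(starts, config.missing_date_frac, rng),
                    "end_date": _degrade_dates(ends, config.missing_date_frac, rng),
                }
            )
        )
    # concomitant background medication rows (no dates): exercises the
    # suspected-only filter downstream
    conc = np.nonzero(rng.random(n) < config.concomitant_prob)[0]
    if conc.size:
        drug_rows.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[conc],
                    "drug_name": "co-medication",
                    "involvement": "concomitant",
                    "start_date": "",
                    "end_date": "",
                }
            )
        )

    reac_rows: list[pd.DataFrame] = []
    for ei, e in enumerate(events):
        cases = np.nonzero(occur[:, ei])[0]
        if cases.size == 0:
            continue
        # anchor each event to the exposed drug with the largest rate ratio
        scores = np.where(expo[cases], rr[:, ei][None, :], -np.inf)
        anchor = np.argmax(scores, axis=1)
        has_drug = expo[cases].any(axis=1)
        tto = alpha_de[anchor, ei] * rng.weibull(beta_de[anchor, ei], size=cases.size)
        onset_off = start_off[cases, anchor] + np.floor(tto).astype(int)
        onset = _dates_to_strings(onset_off, origin)
        onset = _degrade_dates(onset, config.missing_date_frac, rng)
        onset = np.where(has_drug, onset, "")
        probs = config.outcome_probs.get(e, _DEFAULT_OUTCOME)
        cats = list(probs)
        drawn = rng.choice(cats, size=cases.size, p=[probs[c] for c in cats])
        outcome = np.where(drawn == "missing", "", drawn)
        reac_rows.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[cases],
                    "pt_term": e,
                    "onset_date": onset,
                    "outcome": outcome,
                }
            )
        )

    drug_df = (
        pd.concat(drug_rows, ignore_index=True)
        if drug_rows else pd.DataFrame(columns=TABLE_SCHEMAS["drug"])
    )
    reac_df = (
        pd.concat(reac_rows, ignore_index=True)
        if reac_rows else pd.DataFrame(columns=TABLE_SCHEMAS["reac"])
    )

    # exact-duplicate injection (DRUG and REAC, as in real distributions)
    for name in ("drug", "reac"):
        df = drug_df if name == "drug" else reac_df
        k = int(round(config.duplicate_frac * len(df)))
        if k > 0:
            dup = df.iloc[rng.integers(0, len(df), size=k)]
            df = pd.concat([df, dup], ignore_index=True)
            if name == "drug":
                drug_df = df
            else:
                reac_df = df

    return (
        demo.astype(str)[TABLE_SCHEMAS["demo"]],
        drug_df.astype(str)[TABLE_SCHEMAS["drug"]],
        reac_df.astype(str)[TABLE_SCHEMAS["reac"]],
    )


# ---------------------------------------------------------------------------
# Reference margins: bevacizumab lung toxicity in JADER, 2004-04 .. 2021-03
# ---------------------------------------------------------------------------

#: (preferred term, reported bevacizumab case count, reported ROR)
REFERENCE_SCREEN: list[tuple[str, int, float]] = [
    ("Interstitial lung disease", 609, 1.06),
    ("Pneumonia", 246, 0.87),
    ("Pulmonary embolism", 225, 5.28),
    ("Pulmonary artery thrombosis", 86, 14.21),
    ("Pneumonitis", 62, 1.85),
    ("Lung disorder", 54, 1.37),
    ("Respiratory failure", 42, 0.91),
    ("Dyspnoea", 37, 0.49),
    ("Aspiration pneumonia", 35, 1.08),
    ("Cardiorespiratory arrest", 35, 0.73),
    ("Pneumocystis jirovecii pneumonia", 28, 0.33),
    ("Acute respiratory distress syndrome", 26, 1.08),
    ("Pulmonary haemorrhage", 23, 1.97),
    ("Pulmonary alveolar haemorrhage", 21, 0.97),
    ("Pneumonia bacterial", 21, 0.59),
    ("Pulmonary infarction", 19, 5.63),
    ("Pulmonary thrombosis", 18, 8.14),
    ("Pulmonary tuberculosis", 12, 0.80),
    ("Pulmonary oedema", 11, 0.38),
    ("Acute respiratory failure", 10, 0.84),
    ("Pulmonary hypertension", 9, 0.87),
    ("Eosinophilic pneumonia", 8, 0.47),
    ("Pulmonary cavitation", 7, 8.24),
    ("Pulmonary fibrosis", 7, 1.35),
    ("Lung abscess", 6, 2.05),
    ("Idiopathic pulmonary fibrosis", 6, 1.31),
    ("Organising pneumonia", 6, 0.34),
    ("Pulmonary venous thrombosis", 5, 13.42),
    ("Acute pulmonary oedema", 5, 2.03),
]

#: Total unique (case, suspected drug, term) triples in the database extract.
REFERENCE_DB_ROWS = 5_273_115
#: Suspected-bevacizumab triples.
REFERENCE_TARGET_ROWS = 20_399
#: Lung-toxicity triples among them (sum of the case counts above).
REFERENCE_LUNG_ROWS = 1_679

#: Demographics of the 1,679 lung-toxicity patients.
REFERENCE_SEX_COUNTS = {"male": 1071, "female": 546, "unknown": 62}
REFERENCE_AGE_COUNTS = {
    "10s": 2, "20s": 1, "30s": 22, "40s": 84, "50s": 222,
    "60s": 585, "70s": 565, "80s": 94, "90s": 1, "unknown": 103,
}

#: The five thromboembolic terms of the screen.
THROMBOEMBOLIC_TERMS = (
    "Pulmonary embolism",
    "Pulmonary artery thrombosis",
    "Pulmonary infarction",
    "Pulmonary thrombosis",
    "Pulmonary venous thrombosis",
)

TARGET_DRUG = "bevacizumab"
_FILLER_TERM = "drug ineffective"  # a common non-lung preferred term
_OTHER_DRUG = "other suspected drug"


def reference_margin_fixture(
    scale: int = 100, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic DEMO/DRUG/REAC tables reproducing the reference margins.

    Every case carries exactly one suspected drug and one event, so the
    merged data table has one row per case.  Target-drug margins are exact:
    20,399 bevacizumab rows of which 1,679 carry the 29 lung terms at the
    reported per-term counts, with the reported sex/age distribution.  The
    other-drug margin is back-solved from the reported RORs against the
    full-database row totals and divided by ``scale`` (integer-rounded), so
    other-drug-side statistics are approximate while all target-drug-side
    rates and counts are exact.

    ``seed`` only permutes row order (the margins are order-invariant),
    which is useful for checking that downstream statistics do not depend on
    table ordering.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    terms = np.array([normalize_text(t) for t, _, _ in REFERENCE_SCREEN])
    counts = np.array([c for _, c, _ in REFERENCE_SCREEN])
    rors = np.array([r for _, _, r in REFERENCE_SCREEN])

    # target drug side
    lung_pts = np.repeat(terms, counts)
    n_lung = int(counts.sum())
    n_nonlung = REFERENCE_TARGET_ROWS - n_lung
    bev_pts = np.concatenate([lung_pts, np.repeat(_FILLER_TERM, n_nonlung)])
    bev_ids = np.array([f"B{i:06d}" for i in range(REFERENCE_TARGET_ROWS)])

    # other-drug side: per-term counts back-solved from ROR = (a/b)/(c/d)
    n_other_full = REFERENCE_DB_ROWS - REFERENCE_TARGET_ROWS
    b = REFERENCE_TARGET_ROWS - counts
    c_full = counts * n_other_full / (counts + rors * b)
    c_scaled = np.maximum(1, np.round(c_full / scale)).astype(int)
    n_other = int(round(n_other_full / scale))
    n_filler = n_other - int(c_scaled.sum())
    if n_filler < 0:
        raise ValueError("scale too large: other-drug margin underflows")
    other_pts = np.concatenate([np.repeat(terms, c_scaled), np.repeat(_FILLER_TERM, n_filler)])
    other_ids = np.array([f"O{i:06d}" for i in range(n_other)])

    case_ids = np.concatenate([bev_ids, other_ids])
    drug = pd.DataFrame(
        {
            "case_id": case_ids,
            "drug_name": np.concatenate(
                [np.repeat(TARGET_DRUG, REFERENCE_TARGET_ROWS), np.repeat(_OTHER_DRUG, n_other)]
            ),
            "involvement": "suspected",
            "start_date": "",
            "end_date": "",
        }
    )
    reac = pd.DataFrame(
        {
            "case_id": case_ids,
            "pt_term": np.concatenate([bev_pts, other_pts]),
            "onset_date": "",
            "outcome": "",
        }
    )

    sex = np.concatenate(
        [
            np.repeat(list(REFERENCE_SEX_COUNTS), list(REFERENCE_SEX_COUNTS.values())),
            np.repeat("unknown", len(case_ids) - n_lung),
        ]
    )
    age = np.concatenate(
        [
            np.repeat(list(REFERENCE_AGE_COUNTS), list(REFERENCE_AGE_COUNTS.values())),
            np.repeat("unknown", len(case_ids) - n_lung),
        ]
    )
    demo = pd.DataFrame({"case_id": case_ids, "sex": sex, "age_band": age})

    if seed is not None:
        rng = np.random.default_rng(seed)
        demo = demo.iloc[rng.permutation(len(demo))].reset_index(drop=True)
        drug = drug.iloc[rng.permutation(len(drug))].reset_index(drop=True)
        reac = reac.iloc[rng.permutation(len(reac))].reset_index(drop=True)
    return demo.astype(str), drug.astype(str), reac.astype(str)
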