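"""Synthetic four-table spontaneous-report dumps with known ground truth.

The generator emulates the structure of a JADER-style snapshot so that every
pipeline stage has an exact oracle without downloading anything: decade-band
age strings (including non-numeric labels like "adult"), drug rows with the
three involvement categories, daily doses in mg, partial and missing dates,
a seizure outcome drawn from a logistic model with known log-odds over the
same dummy coding the analysis uses, and Weibull-distributed onset days for
seizure cases.

Missingness is missing-completely-at-random (MCAR), applied *after* the
outcome is generated; a complete-case analysis is unbiased under MCAR, which
is exactly the assumption the exclusion cascade leans on. Onset days are
rounded up to whole days so they stay positive. Ground truth records each
case's latent covariates, outcome, onset day, and exclusion fate, so the
join, the cohort ledger, and the onset sample can all be checked exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    AgeCat,
    CohortConfig,
    CohortRow,
    DoseCat,
    ExclusionLedger,
    ExclusionReason,
    LithiumCat,
    categorize_age,
)
from .dispro import Coding, dummy_code
from .errors import ValidationError
from .jader import Sex
from .smq import TermQuery, bundled_demo_terms

_NONNUMERIC_AGES = ["adult", "child", "elderly"]
_FILLER_PTS = ["Nausea", "Somnolence", "Constipation", "Neutropenia", "Pyrexia", "Tachycardia"]
_OTHER_DRUGS = ["omeprazole", "metformin", "amlodipine", "sennoside", "biperiden"]
_ANTIPSYCHOTICS = ["risperidone", "olanzapine", "quetiapine", "aripiprazole", "haloperidol"]
_ANTIEPILEPTICS = ["sodium valproate", "carbamazepine", "lamotrigine", "clonazepam", "diazepam"]

#: planted log-odds, keyed by the analysis design columns. Effects mirror a
#: published clozapine-seizure reporting profile: strong dose dependence
#: (medium ~3x, high ~9.8x vs low), younger age at higher reporting odds,
#: polypharmacy and lithium moderately up, antiepileptics protective (~0.5),
#: history of convulsive disorder strongly up (~8.5).
DEFAULT_LOG_ODDS: dict[str, float] = {
    "intercept": -3.0,
    "sex_female": math.log(0.9),
    "age_30s": -0.7,
    "age_40s": -0.9,
    "age_50s": -1.1,
    "age_ge60": -1.2,
    "cloz_medium": math.log(3.05),
    "cloz_high": math.log(9.81),
    "polypharmacy": math.log(1.68),
    "lithium_low": math.log(1.63),
    "lithium_high": math.log(1.66),
    "fluvoxamine": math.log(2.79),
    "antiepileptic": math.log(0.49),
    "convulsive_history": math.log(8.49),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dump. Defaults emulate a
    clozapine safety profile in a national spontaneous-report snapshot."""

    n_cases: int = 500
    seed: int = 0
    p_clozapine: float = 0.24

    # demographics
    p_female: float = 0.45
    age_dist: dict[str, float] = field(
        default_factory=lambda: {
            "10s": 0.05, "20s": 0.20, "30s": 0.25, "40s": 0.25,
            "50s": 0.15, "60s": 0.07, "70s": 0.03,
        }
    )

    # exposure and co-medication prevalences among study-drug cases
    dose_probs: tuple[float, float, float] = (0.35, 0.40, 0.25)  # low/medium/high
    p_polypharmacy: float = 0.50
    p_lithium: float = 0.12
    p_lithium_high_given_use: float = 0.30
    p_fluvoxamine: float = 0.02
    p_antiepileptic: float = 0.25
    p_history: float = 0.03

    # outcome model and onset process
    log_odds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ODDS))
    weibull_alpha: float = 193.0  # days; exponential-like onset, median ~134 d
    weibull_beta: float = 1.0

    # missingness (MCAR, applied after outcome generation)
    m_sex: float = 0.02
    m_age: float = 0.03
    p_age_nonnumeric: float = 0.05
    m_dose: float = 0.28
    m_lithium_dose: float = 0.15
    m_date: float = 0.05
    p_partial_date: float = 0.05

    window_start: _dt.date = _dt.date(2004, 4, 1)
    window_end: _dt.date = _dt.date(2021, 11, 30)
    window_days: int = 1095

    def __post_init__(self) -> None:
        probs = [
            self.p_clozapine, self.p_female, self.p_polypharmacy, self.p_lithium,
            self.p_lithium_high_given_use, self.p_fluvoxamine, self.p_antiepileptic,
            self.p_history, self.m_sex, self.m_age, self.p_age_nonnumeric,
            self.m_dose, self.m_lithium_dose, self.m_date, self.p_partial_date,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.m_age + self.p_age_nonnumeric > 1.0:
            raise ValidationError("age missing + non-numeric fractions exceed 1")
        if not (self.weibull_alpha > 0 and self.weibull_beta > 0):
            raise ValidationError("Weibull parameters must be positive")
        if abs(sum(self.dose_probs) - 1.0) > 1e-9:
            raise ValidationError("dose category probabilities must sum to 1")
        if abs(sum(self.age_dist.values()) - 1.0) > 1e-9:
            raise ValidationError("age distribution must sum to 1")
        if self.n_cases <= 0:
            raise ValidationError("n_cases must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")

    def log_odds_vector(self, coding: Coding) -> np.ndarray:
        return np.array([self.log_odds[name] for name in coding.column_names])


@dataclass
class GroundTruth:
    """Latent per-case truth, plus the cohort/ledger/onset-sample the
    pipeline is expected to reproduce from the emitted tables."""

    cases: pd.DataFrame  # one row per simulated report
    cohort_rows: list[CohortRow]
    ledger: ExclusionLedger
    onset_days: np.ndarray  # in-window onset days of seizure cases
    n_onset_missing: int
    n_onset_beyond: int
    n_clozapine: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_clozapine": self.n_clozapine,
                "ledger": self.ledger.to_dict(),
                "onset": {
                    "days": [float(d) for d in self.onset_days],
                    "n_excluded_missing_dates": self.n_onset_missing,
                    "n_excluded_beyond_window": self.n_onset_beyond,
                },
                "n_cohort": len(self.cohort_rows),
            },
            indent=2,
        )


@dataclass
class SimResult:
    tables: dict[str, pd.DataFrame]  # keys DEMO, DRUG, REAC, HIST
    truth: GroundTruth
    config: SimConfig


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _fmt_date(d: Optional[_dt.date], partial: bool = False) -> str:
    if d is None:
        return ""
    if partial:
        return f"{d.year:04d}-{d.month:02d}"
    return d.isoformat()


def _draw_age_band(cfg: SimConfig, rng: np.random.Generator) -> str:
    bands = list(cfg.age_dist)
    probs = np.array([cfg.age_dist[b] for b in bands])
    return bands[rng.choice(len(bands), p=probs)]


def _draw_dose(cat: DoseCat, rng: np.random.Generator) -> float:
    if cat is DoseCat.LOW:
        return float(rng.integers(25, 200))
    if cat is DoseCat.MEDIUM:
        return float(rng.integers(200, 401))
    return float(rng.integers(401, 901))


def simulate(config: SimConfig, terms: TermQuery | None = None) -> SimResult:
    """Generate a four-table dump plus exact ground truth.

    Reproducible given ``config.seed``. Seizure cases receive an
    adverse-event row whose preferred term is drawn from ``terms`` (default:
    the bundled demo convulsions list) and an onset date equal to the
    study-drug start plus a Weibull draw rounded up; other cases receive a
    non-matching term. Missingness is applied after outcome generation.
    """
    rng = np.random.default_rng(config.seed)
    terms = terms or bundled_demo_terms()
    seizure_pts = sorted(terms.terms)
    window_span = (config.window_end - config.window_start).days

    demo_rows, drug_rows, reac_rows, hist_rows = [], [], [], []
    truth_records = []
    cohort_rows: list[CohortRow] = []
    ledger = ExclusionLedger()
    onset_days_list: list[float] = []
    n_onset_missing = 0
    n_onset_beyond = 0
    n_cloz = 0

    age_levels = {AgeCat.A30S: "age_30s", AgeCat.A40S: "age_40s",
                  AgeCat.A50S: "age_50s", AgeCat.GE60: "age_ge60"}

    for i in range(config.n_cases):
        case_id = f"SYN-{i + 1:06d}"
        sex_true = Sex.FEMALE if rng.random() < config.p_female else Sex.MALE
        age_band = _draw_age_band(config, rng)
        is_cloz = rng.random() < config.p_clozapine

        if not is_cloz:
            demo_rows.append({"case_id": case_id, "sex": sex_true.value, "age": age_band})
            other = _OTHER_DRUGS[rng.integers(len(_OTHER_DRUGS))]
            start = config.window_start + _dt.timedelta(days=int(rng.integers(window_span)))
            drug_rows.append({
                "case_id": case_id, "drug_name": other, "involvement": "suspected",
                "dose_mg_per_day": "", "start_date": _fmt_date(start),
            })
            reac_rows.append({
                "case_id": case_id,
                "pt": _FILLER_PTS[rng.integers(len(_FILLER_PTS))],
                "onset_date": _fmt_date(start + _dt.timedelta(days=int(rng.integers(1, 200)))),
            })
            truth_records.append({
                "case_id": case_id, "is_clozapine": False, "outcome": False,
                "exclusion": "not_study_drug", "onset_day": np.nan,
            })
            continue

        n_cloz += 1
        # latent covariates
        age_cat = categorize_age(age_band)
        dose_cat = [DoseCat.LOW, DoseCat.MEDIUM, DoseCat.HIGH][
            rng.choice(3, p=np.array(config.dose_probs))
        ]
        dose_val = _draw_dose(dose_cat, rng)
        poly = rng.random() < config.p_polypharmacy
        lithium_use = rng.random() < config.p_lithium
        lithium_high = lithium_use and rng.random() < config.p_lithium_high_given_use
        lithium_cat = (
            LithiumCat.NONE if not lithium_use
            else (LithiumCat.HIGH if lithium_high else LithiumCat.LOW)
        )
        lithium_dose = (
            None if not lithium_use
            else float(rng.choice([800, 1000, 1200]) if lithium_high
                       else rng.choice([200, 400, 600]))
        )
        fluvox = rng.random() < config.p_fluvoxamine
        antiep = rng.random() < config.p_antiepileptic
        history = rng.random() < config.p_history

        # outcome via the same dummy coding the analysis uses
        eta = config.log_odds["intercept"]
        if sex_true is Sex.FEMALE:
            eta += config.log_odds["sex_female"]
        if age_cat in age_levels:
            eta += config.log_odds[age_levels[age_cat]]
        if dose_cat is DoseCat.MEDIUM:
            eta += config.log_odds["cloz_medium"]
        elif dose_cat is DoseCat.HIGH:
            eta += config.log_odds["cloz_high"]
        if poly:
            eta += config.log_odds["polypharmacy"]
        if lithium_cat is LithiumCat.LOW:
            eta += config.log_odds["lithium_low"]
        elif lithium_cat is LithiumCat.HIGH:
            eta += config.log_odds["lithium_high"]
        if fluvox:
            eta += config.log_odds["fluvoxamine"]
        if antiep:
            eta += config.log_odds["antiepileptic"]
        if history:
            eta += config.log_odds["convulsive_history"]
        outcome = rng.random() < _expit(eta)

        start = config.window_start + _dt.timedelta(days=int(rng.integers(window_span)))
        onset_day_true = np.nan
        onset_date: Optional[_dt.date] = None
        if outcome:
            t = float(rng.weibull(config.weibull_beta)) * config.weibull_alpha
            onset_day_true = float(max(1, math.ceil(t)))
            onset_date = start + _dt.timedelta(days=int(onset_day_true) - 1)

        # --- missingness (MCAR), applied to the *observed* tables only ---
        sex_obs = "" if rng.random() < config.m_sex else sex_true.value
        u_age = rng.random()
        if u_age < config.m_age:
            age_obs = ""
        elif u_age < config.m_age + config.p_age_nonnumeric:
            age_obs = _NONNUMERIC_AGES[rng.integers(len(_NONNUMERIC_AGES))]
        else:
            age_obs = age_band
        dose_obs = "" if rng.random() < config.m_dose else f"{dose_val:.0f}"
        lithium_dose_obs = (
            "" if (lithium_use and rng.random() < config.m_lithium_dose)
            else (f"{lithium_dose:.0f}" if lithium_dose is not None else "")
        )
        u_start = rng.random()
        start_obs = (
            "" if u_start < config.m_date
            else _fmt_date(start, partial=u_start < config.m_date + config.p_partial_date)
        )
        u_onset = rng.random()
        onset_obs = (
            "" if u_onset < config.m_date
            else _fmt_date(onset_date, partial=u_onset < config.m_date + config.p_partial_date)
        ) if onset_date is not None else ""

        demo_rows.append({"case_id": case_id, "sex": sex_obs, "age": age_obs})
        involvement = ["suspected", "concomitant", "interaction"][
            rng.choice(3, p=np.array([0.8, 0.15, 0.05]))
        ]
        drug_rows.append({
            "case_id": case_id, "drug_name": "clozapine", "involvement": involvement,
            "dose_mg_per_day": dose_obs, "start_date": start_obs,
        })
        if poly:
            drug_rows.append({
                "case_id": case_id,
                "drug_name": _ANTIPSYCHOTICS[rng.integers(len(_ANTIPSYCHOTICS))],
                "involvement": "concomitant", "dose_mg_per_day": "",
                "start_date": _fmt_date(start),
            })
        if lithium_use:
            drug_rows.append({
                "case_id": case_id, "drug_name": "lithium", "involvement": "concomitant",
                "dose_mg_per_day": lithium_dose_obs, "start_date": _fmt_date(start),
            })
        if fluvox:
            drug_rows.append({
                "case_id": case_id, "drug_name": "fluvoxamine",
                "involvement": "concomitant", "dose_mg_per_day": "",
                "start_date": _fmt_date(start),
            })
        if antiep:
            # started with the study drug, so always concomitant under the
            # temporal rule; keeps the covariate's ground truth exact
            drug_rows.append({
                "case_id": case_id,
                "drug_name": _ANTIEPILEPTICS[rng.integers(len(_ANTIEPILEPTICS))],
                "involvement": "concomitant", "dose_mg_per_day": "",
                "start_date": _fmt_date(start),
            })

        if outcome:
            reac_rows.append({
                "case_id": case_id,
                "pt": seizure_pts[rng.integers(len(seizure_pts))],
                "onset_date": onset_obs,
            })
        else:
            reac_rows.append({
                "case_id": case_id,
                "pt": _FILLER_PTS[rng.integers(len(_FILLER_PTS))],
                "onset_date": _fmt_date(start + _dt.timedelta(days=int(rng.integers(1, 200)))),
            })
        hist_rows.append({"case_id": case_id, "disease_pt": "Schizophrenia"})
        if history:
            hist_rows.append({
                "case_id": case_id,
                "disease_pt": seizure_pts[rng.integers(len(seizure_pts))],
            })

        # --- expected exclusion fate (first failing rule) ---
        ledger.n_input += 1
        exclusion = None
        if sex_obs == "":
            exclusion = ExclusionReason.UNKNOWN_SEX
        elif categorize_age(age_obs) is None:
            exclusion = ExclusionReason.UNKNOWN_AGE
        elif dose_obs == "":
            exclusion = ExclusionReason.UNKNOWN_DOSE
        elif lithium_use and lithium_dose_obs == "":
            exclusion = ExclusionReason.UNKNOWN_LITHIUM_DOSE
        if exclusion is None:
            ledger.n_retained += 1
            cohort_rows.append(CohortRow(
                case_id=case_id, outcome_seizure=bool(outcome), sex=sex_true,
                age_cat=age_cat, cloz_dose_cat=dose_cat, polypharmacy=poly,
                lithium_cat=lithium_cat, fluvoxamine=fluvox, antiepileptic=antiep,
                convulsive_history=history,
            ))
        else:
            ledger.counts[exclusion] += 1

        # --- expected onset-sample fate (seizure cases only) ---
        if outcome:
            start_complete = start_obs != "" and len(start_obs) == 10
            onset_complete = onset_obs != "" and len(onset_obs) == 10
            if not (start_complete and onset_complete):
                n_onset_missing += 1
            elif onset_day_true > config.window_days:
                n_onset_beyond += 1
            else:
                onset_days_list.append(onset_day_true)

        truth_records.append({
            "case_id": case_id, "is_clozapine": True, "outcome": bool(outcome),
            "sex": sex_true.value, "age_cat": age_cat.value,
            "cloz_dose_cat": dose_cat.value, "cloz_dose": dose_val,
            "polypharmacy": poly, "lithium_cat": lithium_cat.value,
            "fluvoxamine": fluvox, "antiepileptic": antiep, "history": history,
            "exclusion": exclusion.value if exclusion else "retained",
            "onset_day": onset_day_true,
        })

    ledger.check()
    tables = {
        "DEMO": pd.DataFrame(demo_rows, columns=["case_id", "sex", "age"]),
        "DRUG": pd.DataFrame(
            drug_rows,
            columns=["case_id", "drug_name", "involvement", "dose_mg_per_day", "start_date"],
        ),
        "REAC": pd.DataFrame(reac_rows, columns=["case_id", "pt", "onset_date"]),
        "HIST": pd.DataFrame(hist_rows, columns=["case_id", "disease_pt"]),
    }
    truth = GroundTruth(
        cases=pd.DataFrame(truth_records),
        cohort_rows=cohort_rows,
        ledger=ledger,
        onset_days=np.asarray(onset_days_list, dtype=float),
        n_onset_missing=n_onset_missing,
        n_onset_beyond=n_onset_beyond,
        n_clozapine=n_cloz,
    )
    return SimResult(tables=tables, truth=truth, config=config)


def simulate_cohort(
    config: SimConfig, n: int | None = None, rng: np.random.Generator | None = None
) -> tuple[list[CohortRow], np.ndarray, Coding]:
    """Cohort-level shortcut: draw complete covariate rows and outcomes
    directly from the planted logistic model (no tables, no missingness).

    Returns the rows, the true log-odds vector in design order, and the
    coding. Intended for estimator-recovery studies where only the
    regression layer is exercised.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = n or config.n_cases
    rows: list[CohortRow] = []
    for i in range(n):
        sex = Sex.FEMALE if rng.random() < config.p_female else Sex.MALE
        age_cat = categorize_age(_draw_age_band(config, rng))
        dose_cat = [DoseCat.LOW, DoseCat.MEDIUM, DoseCat.HIGH][
            rng.choice(3, p=np.array(config.dose_probs))
        ]
        lithium_use = rng.random() < config.p_lithium
        lithium_cat = (
            LithiumCat.NONE if not lithium_use
            else (LithiumCat.HIGH if rng.random() < config.p_lithium_high_given_use
                  else LithiumCat.LOW)
        )
        rows.append(CohortRow(
            case_id=f"C{i}", outcome_seizure=False, sex=sex, age_cat=age_cat,
            cloz_dose_cat=dose_cat,
            polypharmacy=rng.random() < config.p_polypharmacy,
            lithium_cat=lithium_cat,
            fluvoxamine=rng.random() < config.p_fluvoxamine,
            antiepileptic=rng.random() < config.p_antiepileptic,
            convulsive_history=rng.random() < config.p_history,
        ))
    _, X, coding = dummy_code(rows)
    b = config.log_odds_vector(coding)
    p = 1.0 / (1.0 + np.exp(-(X @ b)))
    y = rng.random(n) < p
    rows = [dataclasses.replace(r, outcome_seizure=bool(yi)) for r, yi in zip(rows, y)]
    return rows, b, coding


def simulate_onset_sample(
    n: int, alpha: float, beta: float, rng: np.random.Generator, round_up: bool = True
) -> np.ndarray:
    """Weibull onset days: scale ``alpha`` (days), shape ``beta``.

    ``round_up=True`` mimics date arithmetic (whole positive days)."""
    t = rng.weibull(beta, size=n) * alpha
    return np.maximum(1.0, np.ceil(t)) if round_up else t


def recovery_config(n_cases: int = 2000, seed: int = 0) -> SimConfig:
    """Conditions for parameter-recovery studies of the regression layer.

    Same planted effects as the default profile, but co-medication and
    history prevalences are raised so every design column carries adequate
    information (expected event counts per dummy well above ~30); Wald
    intervals are only near-nominal when no cell is sparse, and a recovery
    experiment is meant to probe the estimator, not small-sample sparsity.
    """
    return SimConfig(
        n_cases=n_cases,
        seed=seed,
        p_clozapine=1.0,
        p_fluvoxamine=0.15,
        p_history=0.10,
        p_lithium=0.25,
        p_lithium_high_given_use=0.40,
    )


def paperlike_config(n_cases: int = 100_000, seed: int = 0) -> SimConfig:
    """Conditions calibrated to a published clozapine-seizure profile:
    every report is a study-drug case, dose/comedication/history effects at
    their published adjusted reporting odds ratios, and exponential-like
    onset (shape 1, median ~134 days)."""
    return SimConfig(n_cases=n_cases, seed=seed, p_clozapine=1.0)


def write_tables(result: SimResult, outdir: str | Path, delimiter: str = ",") -> dict[str, Path]:
    """Write the four tables (and ground-truth summaries) as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in result.tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, sep=delimiter, index=False)
        paths[name] = p
    (outdir / "truth.json").write_text(result.truth.to_json(), encoding="utf-8")
    result.truth.cases.to_csv(outdir / "truth_cases.csv", index=False)
    return paths
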