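"""Seed-reproducible synthetic claims bundles with planted ground truth.

The generator emulates the statistical structure of a large inpatient
diabetic-foot-infection population: a mixture over six severity groups
plus an "other" (leg-infection) group, coexisting less-severe infection
codes, pre-index comorbidity coding in a two-year lookback, per-group
length-of-stay distributions, amputation history, and one-year outcome
rates (subsequent amputation, transition to long-term care, death) with
a calibrated 90-day fraction.  Every knob lives in
:class:`SimulationConfig`; defaults reproduce the published cohort's
group mixture, co-infection proportions, comorbidity prevalences and
outcome gradients.

Each patient's planted group, coexisting infections, comorbidity flags
and outcome indicators are returned in a ground-truth table so that
classification and outcome measurement can be validated by round-trip.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .io import ClaimsBundle

__all__ = ["SimulationConfig", "simulate", "perturb", "GROUPS", "CLASSIFIED_GROUPS"]

CLASSIFIED_GROUPS = (
    "GANGRENE",
    "OSTEOMYELITIS",
    "ULCER",
    "FOOT_CELLULITIS_ABSCESS",
    "TOE_CELLULITIS_ABSCESS",
    "PARONYCHIA",
)
GROUPS = CLASSIFIED_GROUPS + ("OTHER",)

COMORBIDITIES = ("PVD", "NEUROPATHY", "EYE", "CVD", "MI", "RENAL")

# published cohort group shares (renormalized on validation; the printed
# percentages sum to 100.1% from rounding)
DEFAULT_MIXTURE = {
    "ULCER": 0.330,
    "GANGRENE": 0.191,
    "FOOT_CELLULITIS_ABSCESS": 0.073,
    "OSTEOMYELITIS": 0.068,
    "TOE_CELLULITIS_ABSCESS": 0.023,
    "PARONYCHIA": 0.005,
    "OTHER": 0.311,
}

# co-infection proportions: group -> {strictly less severe category: p};
# cells printed as "< 1%" are planted at 0.005
DEFAULT_COINFECTION = {
    "GANGRENE": {
        "OSTEOMYELITIS": 0.005,
        "ULCER": 0.172,
        "FOOT_CELLULITIS_ABSCESS": 0.160,
        "TOE_CELLULITIS_ABSCESS": 0.005,
        "PARONYCHIA": 0.005,
    },
    "OSTEOMYELITIS": {
        "ULCER": 0.250,
        "FOOT_CELLULITIS_ABSCESS": 0.235,
        "TOE_CELLULITIS_ABSCESS": 0.116,
        "PARONYCHIA": 0.005,
    },
    "ULCER": {
        "FOOT_CELLULITIS_ABSCESS": 0.176,
        "TOE_CELLULITIS_ABSCESS": 0.005,
        "PARONYCHIA": 0.005,
    },
    "FOOT_CELLULITIS_ABSCESS": {
        "TOE_CELLULITIS_ABSCESS": 0.005,
        "PARONYCHIA": 0.005,
    },
    "TOE_CELLULITIS_ABSCESS": {"PARONYCHIA": 0.005},
    "PARONYCHIA": {},
    "OTHER": {},
}

# comorbidity prevalence per group (PVD, neuropathy, eye, cerebrovascular,
# myocardial infarction, renal)
DEFAULT_COMORBIDITY = {
    "GANGRENE": {"PVD": 0.772, "NEUROPATHY": 0.556, "EYE": 0.489, "CVD": 0.292, "MI": 0.240, "RENAL": 0.262},
    "OSTEOMYELITIS": {"PVD": 0.715, "NEUROPATHY": 0.627, "EYE": 0.487, "CVD": 0.192, "MI": 0.170, "RENAL": 0.169},
    "ULCER": {"PVD": 0.738, "NEUROPATHY": 0.599, "EYE": 0.473, "CVD": 0.261, "MI": 0.227, "RENAL": 0.221},
    "FOOT_CELLULITIS_ABSCESS": {"PVD": 0.584, "NEUROPATHY": 0.555, "EYE": 0.414, "CVD": 0.212, "MI": 0.205, "RENAL": 0.170},
    "TOE_CELLULITIS_ABSCESS": {"PVD": 0.646, "NEUROPATHY": 0.581, "EYE": 0.465, "CVD": 0.247, "MI": 0.222, "RENAL": 0.185},
    "PARONYCHIA": {"PVD": 0.557, "NEUROPATHY": 0.495, "EYE": 0.343, "CVD": 0.277, "MI": 0.235, "RENAL": 0.194},
    "OTHER": {"PVD": 0.546, "NEUROPATHY": 0.425, "EYE": 0.342, "CVD": 0.210, "MI": 0.230, "RENAL": 0.175},
}

# demographics per group: male share, age mean/SD, known-race shares
# (white / african-american / other; an unknown-race share masks on top)
DEFAULT_DEMOGRAPHY = {
    "GANGRENE": {"male": 0.991, "age_mean": 70.0, "age_sd": 10.2, "white": 0.680, "african_american": 0.231, "other": 0.089, "unknown": 0.031},
    "OSTEOMYELITIS": {"male": 0.989, "age_mean": 66.3, "age_sd": 11.0, "white": 0.751, "african_american": 0.175, "other": 0.074, "unknown": 0.062},
    "ULCER": {"male": 0.986, "age_mean": 68.7, "age_sd": 10.9, "white": 0.779, "african_american": 0.157, "other": 0.064, "unknown": 0.031},
    "FOOT_CELLULITIS_ABSCESS": {"male": 0.984, "age_mean": 66.9, "age_sd": 11.4, "white": 0.766, "african_american": 0.143, "other": 0.091, "unknown": 0.029},
    "TOE_CELLULITIS_ABSCESS": {"male": 0.984, "age_mean": 67.3, "age_sd": 11.4, "white": 0.811, "african_american": 0.120, "other": 0.069, "unknown": 0.033},
    "PARONYCHIA": {"male": 0.969, "age_mean": 66.7, "age_sd": 12.6, "white": 0.766, "african_american": 0.174, "other": 0.060, "unknown": 0.024},
    "OTHER": {"male": 0.980, "age_mean": 66.9, "age_sd": 11.3, "white": 0.797, "african_american": 0.121, "other": 0.082, "unknown": 0.037},
}

# per-group length of stay: log-normal matched to the printed median and
# mean (mu = ln median, sigma = sqrt(2 ln(mean/median)))
DEFAULT_LOS = {
    "GANGRENE": {"median": 14.0, "mean": 31.1},
    "OSTEOMYELITIS": {"median": 10.0, "mean": 28.5},
    "ULCER": {"median": 7.0, "mean": 20.0},
    "FOOT_CELLULITIS_ABSCESS": {"median": 6.0, "mean": 12.6},
    "TOE_CELLULITIS_ABSCESS": {"median": 5.0, "mean": 15.2},
    "PARONYCHIA": {"median": 6.0, "mean": 27.8},
    "OTHER": {"median": 6.0, "mean": 13.9},
}

# one-year outcome probabilities per group
DEFAULT_OUTCOMES = {
    "GANGRENE": {"amputation": 0.188, "ltc": 0.165, "death": 0.244},
    "OSTEOMYELITIS": {"amputation": 0.100, "ltc": 0.146, "death": 0.125},
    "ULCER": {"amputation": 0.077, "ltc": 0.111, "death": 0.193},
    "FOOT_CELLULITIS_ABSCESS": {"amputation": 0.042, "ltc": 0.105, "death": 0.115},
    "TOE_CELLULITIS_ABSCESS": {"amputation": 0.054, "ltc": 0.082, "death": 0.120},
    "PARONYCHIA": {"amputation": 0.017, "ltc": 0.079, "death": 0.149},
    "OTHER": {"amputation": 0.018, "ltc": 0.086, "death": 0.132},
}

# fraction of one-year events falling in the first 90 days
DEFAULT_FRAC_90D = {"amputation": 4.8 / 7.8, "ltc": 5.1 / 8.7, "death": 8.8 / 17.0}

DEFAULT_CURRENT_AMPUTATION = {
    "GANGRENE": 0.019, "OSTEOMYELITIS": 0.015, "ULCER": 0.003,
    "FOOT_CELLULITIS_ABSCESS": 0.003, "TOE_CELLULITIS_ABSCESS": 0.007,
    "PARONYCHIA": 0.0, "OTHER": 0.002,
}
DEFAULT_PAST_AMPUTATION = {
    "GANGRENE": 0.110, "OSTEOMYELITIS": 0.057, "ULCER": 0.042,
    "FOOT_CELLULITIS_ABSCESS": 0.020, "TOE_CELLULITIS_ABSCESS": 0.020,
    "PARONYCHIA": 0.014, "OTHER": 0.017,
}

# index-stay ICD-9 procedure coding: excisional debridement (86.22),
# skin/subcutaneous incision & drainage (86.04), leg arteriogram (88.48),
# aortogram (88.42)
DEFAULT_PROCEDURES = {
    "8622": {"GANGRENE": 0.035, "OSTEOMYELITIS": 0.054, "ULCER": 0.038, "FOOT_CELLULITIS_ABSCESS": 0.020, "TOE_CELLULITIS_ABSCESS": 0.021, "PARONYCHIA": 0.014, "OTHER": 0.010},
    "8604": {"GANGRENE": 0.012, "OSTEOMYELITIS": 0.025, "ULCER": 0.016, "FOOT_CELLULITIS_ABSCESS": 0.039, "TOE_CELLULITIS_ABSCESS": 0.038, "PARONYCHIA": 0.028, "OTHER": 0.030},
    "8848": {"GANGRENE": 0.127, "OSTEOMYELITIS": 0.041, "ULCER": 0.058, "FOOT_CELLULITIS_ABSCESS": 0.024, "TOE_CELLULITIS_ABSCESS": 0.033, "PARONYCHIA": 0.021, "OTHER": 0.016},
    "8842": {"GANGRENE": 0.078, "OSTEOMYELITIS": 0.026, "ULCER": 0.037, "FOOT_CELLULITIS_ABSCESS": 0.016, "TOE_CELLULITIS_ABSCESS": 0.025, "PARONYCHIA": 0.005, "OTHER": 0.012},
}

# index-stay primary diagnosis codes per group, with sampling weights
PRIMARY_CODES = {
    "GANGRENE": (["44024", "7854", "0400"], [0.55, 0.40, 0.05]),
    "OSTEOMYELITIS": (["73007", "73017", "73027", "73097"], [0.4, 0.3, 0.2, 0.1]),
    "ULCER": (["70714", "70715", "7071", "44023"], [0.35, 0.35, 0.20, 0.10]),
    "FOOT_CELLULITIS_ABSCESS": (["6827", "6807"], [0.9, 0.1]),
    "TOE_CELLULITIS_ABSCESS": (["68110", "6811"], [0.6, 0.4]),
    "PARONYCHIA": (["68111"], [1.0]),
    # leg infections dominate the unclassified group (84% leg cellulitis)
    "OTHER": (["6826", "8920", "70710", "73026"], [0.84, 0.06, 0.05, 0.05]),
}

# one fixed code per category for coexisting infections and readmissions
REPRESENTATIVE_CODE = {
    "GANGRENE": "44024",
    "OSTEOMYELITIS": "73017",
    "ULCER": "70714",
    "FOOT_CELLULITIS_ABSCESS": "6827",
    "TOE_CELLULITIS_ABSCESS": "68110",
    "PARONYCHIA": "68111",
    "OTHER": "6826",
}

COMORBIDITY_CODE = {
    "PVD": "4400",
    "NEUROPATHY": "3572",
    "EYE": "36201",
    "CVD": "4359",
    "MI": "41091",
    "RENAL": "5859",
}

GANGRENE_COMPANIONS = ["25070", "44021", "44022"]
FILLER_DX = "25000"  # diabetes mellitus without complication; never matches


def _default_readmit_matrix() -> dict[str, dict[str, float]]:
    """Conditional readmission-group rows from the published same-group and
    ulcer-readmission rates; remainder spread proportional to the mixture."""
    overall = 0.398
    pinned = {
        "GANGRENE": {"GANGRENE": 0.28 / overall},
        "ULCER": {"ULCER": 0.25 / overall},
        "OSTEOMYELITIS": {"OSTEOMYELITIS": 0.17 / overall},
        "FOOT_CELLULITIS_ABSCESS": {"ULCER": 0.12 / overall},
        "TOE_CELLULITIS_ABSCESS": {"ULCER": 0.11 / overall},
        "PARONYCHIA": {"ULCER": 0.06 / overall},
        "OTHER": {"OTHER": 0.5},
    }
    mix_cl = {g: DEFAULT_MIXTURE[g] for g in CLASSIFIED_GROUPS}
    out: dict[str, dict[str, float]] = {}
    for g in GROUPS:
        row = dict(pinned[g])
        rest = 1.0 - sum(row.values())
        free = {c: w for c, w in mix_cl.items() if c not in row}
        z = sum(free.values())
        for c, w in free.items():
            row[c] = row.get(c, 0.0) + rest * w / z
        out[g] = row
    return out


DEFAULT_READMIT_MATRIX = _default_readmit_matrix()


class SimulationConfig(BaseModel):
    """All generator parameters; defaults are the published study conditions."""

    model_config = ConfigDict(validate_default=True)

    n_patients: int = Field(default=10_000, ge=0)
    seed: int = 0
    group_mixture: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    coinfection_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COINFECTION.items()}
    )
    comorbidity_prevalence: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COMORBIDITY.items()}
    )
    demography: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DEMOGRAPHY.items()}
    )
    los_model: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_LOS.items()}
    )
    outcome_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_OUTCOMES.items()}
    )
    frac_90d: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FRAC_90D))
    current_amputation_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CURRENT_AMPUTATION)
    )
    past_amputation_probs: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PAST_AMPUTATION)
    )
    procedure_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_PROCEDURES.items()}
    )
    readmit_prob: float = Field(default=0.398, ge=0.0, le=1.0)
    readmit_matrix: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_READMIT_MATRIX.items()}
    )
    prior_ltc_prob: float = Field(default=0.22, ge=0.0, le=1.0)
    ltc_inpatient_fraction: float = Field(default=0.75, ge=0.0, le=1.0)
    late_death_prob: float = Field(default=0.21, ge=0.0, le=1.0)
    late_amputation_prob: float = Field(default=0.057, ge=0.0, le=1.0)
    index_start: str = "2000-01-01"  # leaves lookback room in a 1998-2004 span
    index_end: str = "2003-12-31"

    @field_validator("group_mixture")
    @classmethod
    def _check_mixture(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups in mixture: {sorted(unknown)}")
        total = sum(v.values())
        if not math.isclose(total, 1.0, abs_tol=5e-3):
            raise ValueError(f"group mixture sums to {total}, not 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("mixture probabilities must be non-negative")
        return {g: p / total for g, p in v.items()}

    @model_validator(mode="after")
    def _check_probs(self) -> "SimulationConfig":
        problems: list[str] = []
        for name, nested in (
            ("coinfection_probs", self.coinfection_probs),
            ("comorbidity_prevalence", self.comorbidity_prevalence),
            ("outcome_probs", self.outcome_probs),
            ("procedure_probs", self.procedure_probs),
            ("readmit_matrix", self.readmit_matrix),
        ):
            for k, inner in nested.items():
                for kk, p in inner.items():
                    if not 0.0 <= p <= 1.0:
                        problems.append(f"{name}[{k}][{kk}] = {p} outside [0, 1]")
        for name, flat in (
            ("frac_90d", self.frac_90d),
            ("current_amputation_probs", self.current_amputation_probs),
            ("past_amputation_probs", self.past_amputation_probs),
        ):
            for k, p in flat.items():
                if not 0.0 <= p <= 1.0:
                    problems.append(f"{name}[{k}] = {p} outside [0, 1]")
        for g, los in self.los_model.items():
            if los["median"] <= 0 or los["mean"] < los["median"]:
                problems.append(f"los_model[{g}]: need mean >= median > 0")
        if problems:
            raise ValueError("invalid simulation config:\n  " + "\n  ".join(problems))
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _lognormal_params(median: float, mean: float) -> tuple[float, float]:
    mu = math.log(median)
    sigma = math.sqrt(max(2.0 * math.log(mean / median), 1e-12))
    return mu, sigma


class _Frames:
    """Accumulators for the seven bundle tables."""

    def __init__(self) -> None:
        self.stays: list[pd.DataFrame] = []
        self.stay_dx: list[pd.DataFrame] = []
        self.stay_proc: list[pd.DataFrame] = []
        self.visits: list[pd.DataFrame] = []
        self.visit_dx: list[pd.DataFrame] = []
        self.visit_proc: list[pd.DataFrame] = []
        self._stay_counter = 0
        self._visit_counter = 0

    def new_stay_ids(self, k: int) -> np.ndarray:
        ids = np.array(
            [f"S{i:08d}" for i in range(self._stay_counter + 1, self._stay_counter + k + 1)]
        )
        self._stay_counter += k
        return ids

    def new_visit_ids(self, k: int) -> np.ndarray:
        ids = np.array(
            [f"V{i:08d}" for i in range(self._visit_counter + 1, self._visit_counter + k + 1)]
        )
        self._visit_counter += k
        return ids

    def add_stays(self, stay_id, patient_id, admit_day, discharge_day, care_setting):
        self.stays.append(
            pd.DataFrame(
                {
                    "stay_id": stay_id,
                    "patient_id": patient_id,
                    "admit_day": np.asarray(admit_day, dtype=np.int64),
                    "discharge_day": np.asarray(discharge_day, dtype=np.int64),
                    "care_setting": care_setting,
                }
            )
        )

    def add_stay_dx(self, stay_id, code):
        self.stay_dx.append(pd.DataFrame({"stay_id": stay_id, "icd9_code": code}))

    def add_stay_proc(self, stay_id, code):
        self.stay_proc.append(
            pd.DataFrame({"stay_id": stay_id, "icd9_proc_code": code})
        )

    def add_visits(self, visit_id, patient_id, visit_day, care_setting):
        self.visits.append(
            pd.DataFrame(
                {
                    "visit_id": visit_id,
                    "patient_id": patient_id,
                    "visit_day": np.asarray(visit_day, dtype=np.int64),
                    "care_setting": care_setting,
                }
            )
        )

    def add_visit_dx(self, visit_id, code):
        self.visit_dx.append(pd.DataFrame({"visit_id": visit_id, "icd9_code": code}))

    def add_visit_proc(self, visit_id, code):
        self.visit_proc.append(pd.DataFrame({"visit_id": visit_id, "cpt_code": code}))


def _days_to_dates(days: pd.Series) -> pd.Series:
    return pd.to_datetime(days, unit="D", origin="unix")


def simulate(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle plus a planted ground-truth table.

    Identical (config, seed) yield byte-identical bundles.  ``seed``
    overrides ``config.seed`` when given.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients

    mix_groups = list(config.group_mixture)
    mix_p = np.array([config.group_mixture[g] for g in mix_groups])
    groups = rng.choice(np.array(mix_groups, dtype=object), size=n, p=mix_p)

    pid = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    start = (pd.Timestamp(config.index_start) - pd.Timestamp(0)).days
    end = (pd.Timestamp(config.index_end) - pd.Timestamp(0)).days
    admit_day = rng.integers(start, end + 1, size=n)

    def per_group(fn) -> np.ndarray:
        """Fill an n-vector by applying fn(group, mask) groupwise."""
        out = np.zeros(n)
        for g in GROUPS:
            m = groups == g
            if m.any():
                out[m] = fn(g, int(m.sum()))
        return out

    # length of stay and demographics
    los = per_group(
        lambda g, k: rng.lognormal(*_lognormal_params(
            config.los_model[g]["median"], config.los_model[g]["mean"]
        ), size=k)
    )
    los = np.clip(np.rint(los), 1, 730).astype(np.int64)
    discharge_day = admit_day + los

    male = rng.random(n) < per_group(lambda g, k: config.demography[g]["male"])
    sex = np.where(male, "M", "F")
    age = np.rint(
        per_group(lambda g, k: rng.normal(
            config.demography[g]["age_mean"], config.demography[g]["age_sd"], size=k
        ))
    ).clip(25, 100).astype(int)
    # birth on Jan 1 so that floor(calendar years) at index equals the drawn age
    admit_year = (1970 + _days_to_dates(pd.Series(admit_day)).dt.year - 1970).to_numpy()
    birth_date = pd.to_datetime(
        {"year": admit_year - age, "month": np.ones(n, dtype=int), "day": np.ones(n, dtype=int)}
    )

    race = np.empty(n, dtype=object)
    for g in GROUPS:
        m = groups == g
        if not m.any():
            continue
        d = config.demography[g]
        w = np.array([d["white"], d["african_american"], d["other"]])
        race[m] = rng.choice(
            np.array(["WHITE", "AFRICAN_AMERICAN", "OTHER"], dtype=object),
            size=int(m.sum()),
            p=w / w.sum(),
        )
        unk = rng.random(int(m.sum())) < d["unknown"]
        idx = np.flatnonzero(m)[unk]
        race[idx] = "UNKNOWN"

    frames = _Frames()
    index_stay_ids = frames.new_stay_ids(n)
    frames.add_stays(index_stay_ids, pid, admit_day, discharge_day, "ACUTE")

    # --- index-stay diagnoses ---
    primary = np.empty(n, dtype=object)
    for g in GROUPS:
        m = groups == g
        if not m.any():
            continue
        codes, w = PRIMARY_CODES[g]
        primary[m] = rng.choice(np.array(codes, dtype=object), size=int(m.sum()), p=w)
    frames.add_stay_dx(index_stay_ids, primary)

    needs_companion = primary == "7854"
    if needs_companion.any():
        comp = rng.choice(
            np.array(GANGRENE_COMPANIONS, dtype=object), size=int(needs_companion.sum())
        )
        frames.add_stay_dx(index_stay_ids[needs_companion], comp)

    coex = {c: np.zeros(n, dtype=bool) for c in CLASSIFIED_GROUPS}
    for g in GROUPS:
        m = groups == g
        if not m.any():
            continue
        for cat, p in config.coinfection_probs.get(g, {}).items():
            hit = m & (rng.random(n) < p)
            coex[cat] |= hit
            if hit.any():
                frames.add_stay_dx(index_stay_ids[hit], REPRESENTATIVE_CODE[cat])
    frames.add_stay_dx(index_stay_ids, FILLER_DX)

    # --- index-stay procedures ---
    current_amp = rng.random(n) < per_group(
        lambda g, k: config.current_amputation_probs[g]
    )
    if current_amp.any():
        frames.add_stay_proc(index_stay_ids[current_amp], "8411")
    for code, probs in config.procedure_probs.items():
        hit = rng.random(n) < per_group(lambda g, k, probs=probs: probs[g])
        if hit.any():
            frames.add_stay_proc(index_stay_ids[hit], code)

    # --- pre-index history ---
    truth_comorb = {}
    for cond in COMORBIDITIES:
        hit = rng.random(n) < per_group(
            lambda g, k, cond=cond: config.comorbidity_prevalence[g][cond]
        )
        truth_comorb[cond] = hit
        k = int(hit.sum())
        if k:
            vids = frames.new_visit_ids(k)
            vday = admit_day[hit] - rng.integers(1, 731, size=k)
            frames.add_visits(vids, pid[hit], vday, "OUTPATIENT")
            frames.add_visit_dx(vids, COMORBIDITY_CODE[cond])

    past_amp = rng.random(n) < per_group(
        lambda g, k: config.past_amputation_probs[g]
    )
    if past_amp.any():
        k = int(past_amp.sum())
        vids = frames.new_visit_ids(k)
        vday = admit_day[past_amp] - rng.integers(100, 1401, size=k)
        frames.add_visits(vids, pid[past_amp], vday, "OUTPATIENT")
        via_cpt = rng.random(k) < 0.5
        if (~via_cpt).any():
            frames.add_visit_dx(vids[~via_cpt], "V4975")
        if via_cpt.any():
            frames.add_visit_proc(vids[via_cpt], "27880")
            frames.add_visit_dx(vids[via_cpt], FILLER_DX)

    prior_ltc = rng.random(n) < config.prior_ltc_prob
    if prior_ltc.any():
        k = int(prior_ltc.sum())
        inpatient = rng.random(k) < 0.5
        if inpatient.any():
            kk = int(inpatient.sum())
            sids = frames.new_stay_ids(kk)
            a = admit_day[prior_ltc][inpatient] - rng.integers(800, 1501, size=kk)
            d = a + rng.integers(30, 201, size=kk)
            frames.add_stays(sids, pid[prior_ltc][inpatient], a, d, "LTC_INPATIENT")
            frames.add_stay_dx(sids, FILLER_DX)
        if (~inpatient).any():
            kk = int((~inpatient).sum())
            vids = frames.new_visit_ids(kk)
            vday = admit_day[prior_ltc][~inpatient] - rng.integers(800, 1501, size=kk)
            frames.add_visits(vids, pid[prior_ltc][~inpatient], vday, "LTC_OUTPATIENT")
            frames.add_visit_dx(vids, FILLER_DX)

    # --- post-discharge outcomes ---
    def _event_days(mask_365: np.ndarray, family: str) -> tuple[np.ndarray, np.ndarray]:
        """(within-90 submask, event day offsets) for one outcome family."""
        k = int(mask_365.sum())
        in90 = np.zeros(n, dtype=bool)
        offsets = np.zeros(n, dtype=np.int64)
        if k:
            sub = rng.random(k) < config.frac_90d[family]
            in90[np.flatnonzero(mask_365)[sub]] = True
            off = np.where(sub, rng.integers(1, 91, size=k), rng.integers(91, 366, size=k))
            offsets[mask_365] = off
        return in90, offsets

    amp_365 = rng.random(n) < per_group(
        lambda g, k: config.outcome_probs[g]["amputation"]
    )
    amp_90, amp_off = _event_days(amp_365, "amputation")
    late_amp = (~amp_365) & (rng.random(n) < config.late_amputation_prob)
    amp_any = amp_365 | late_amp
    amp_off = np.where(late_amp, rng.integers(366, 1501, size=n), amp_off)
    if amp_any.any():
        k = int(amp_any.sum())
        sids = frames.new_stay_ids(k)
        a = discharge_day[amp_any] + amp_off[amp_any]
        frames.add_stays(sids, pid[amp_any], a, a + rng.integers(3, 31, size=k), "ACUTE")
        frames.add_stay_dx(sids, FILLER_DX)
        frames.add_stay_proc(sids, "8411")

    ltc_365 = rng.random(n) < per_group(lambda g, k: config.outcome_probs[g]["ltc"])
    ltc_90, ltc_off = _event_days(ltc_365, "ltc")
    ltc_inpatient = rng.random(n) < config.ltc_inpatient_fraction
    m_in = ltc_365 & ltc_inpatient
    if m_in.any():
        k = int(m_in.sum())
        sids = frames.new_stay_ids(k)
        a = discharge_day[m_in] + ltc_off[m_in]
        frames.add_stays(sids, pid[m_in], a, a + rng.integers(30, 301, size=k), "LTC_INPATIENT")
        frames.add_stay_dx(sids, FILLER_DX)
    m_out = ltc_365 & ~ltc_inpatient
    if m_out.any():
        k = int(m_out.sum())
        vids = frames.new_visit_ids(k)
        frames.add_visits(vids, pid[m_out], discharge_day[m_out] + ltc_off[m_out], "LTC_OUTPATIENT")
        frames.add_visit_dx(vids, FILLER_DX)

    death_365 = rng.random(n) < per_group(lambda g, k: config.outcome_probs[g]["death"])
    death_90, death_off = _event_days(death_365, "death")
    late_death = (~death_365) & (rng.random(n) < config.late_death_prob)
    death_any = death_365 | late_death
    death_off = np.where(late_death, rng.integers(366, 2001, size=n), death_off)
    death_day = np.where(death_any, discharge_day + death_off, -1)

    readmitted = rng.random(n) < config.readmit_prob
    readmit_group = np.full(n, "", dtype=object)
    readmit_off = np.zeros(n, dtype=np.int64)
    for g in GROUPS:
        m = (groups == g) & readmitted
        if not m.any():
            continue
        row = config.readmit_matrix[g]
        cats = list(row)
        p = np.array([row[c] for c in cats], dtype=float)
        readmit_group[m] = rng.choice(np.array(cats, dtype=object), size=int(m.sum()), p=p / p.sum())
    if readmitted.any():
        k = int(readmitted.sum())
        readmit_off[readmitted] = rng.integers(15, 1001, size=k)
        sids = frames.new_stay_ids(k)
        a = discharge_day[readmitted] + readmit_off[readmitted]
        rg = readmit_group[readmitted]
        codes = np.array([REPRESENTATIVE_CODE[g] for g in rg], dtype=object)
        frames.add_stays(sids, pid[readmitted], a, a + rng.integers(2, 31, size=k), "ACUTE")
        frames.add_stay_dx(sids, codes)
        frames.add_stay_dx(sids, FILLER_DX)

    # --- assemble bundle ---
    def concat(parts: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
        if not parts:
            return pd.DataFrame(columns=columns)
        return pd.concat(parts, ignore_index=True)[columns]

    stays = concat(
        frames.stays, ["stay_id", "patient_id", "admit_day", "discharge_day", "care_setting"]
    )
    stays["admit_date"] = _days_to_dates(stays.pop("admit_day"))
    stays["discharge_date"] = _days_to_dates(stays.pop("discharge_day"))
    stays = stays[["stay_id", "patient_id", "admit_date", "discharge_date", "care_setting"]]

    stay_dx = concat(frames.stay_dx, ["stay_id", "icd9_code"])
    stay_dx["position"] = (stay_dx.groupby("stay_id").cumcount() + 1).astype("Int64")
    stay_dx = stay_dx[["stay_id", "position", "icd9_code"]]

    visits = concat(frames.visits, ["visit_id", "patient_id", "visit_day", "care_setting"])
    visits["visit_date"] = _days_to_dates(visits.pop("visit_day"))
    visits = visits[["visit_id", "patient_id", "visit_date", "care_setting"]]

    visit_dx = concat(frames.visit_dx, ["visit_id", "icd9_code"])
    visit_dx["position"] = (visit_dx.groupby("visit_id").cumcount() + 1).astype("Int64")
    visit_dx = visit_dx[["visit_id", "position", "icd9_code"]]

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": sex,
            "birth_date": birth_date,
            "race": race,
            "death_date": _days_to_dates(pd.Series(death_day)).where(death_day >= 0, pd.NaT)
            if n
            else pd.Series([], dtype="datetime64[ns]"),
        }
    )

    bundle = ClaimsBundle(
        patients=patients,
        stays=stays,
        stay_dx=stay_dx,
        stay_proc=concat(frames.stay_proc, ["stay_id", "icd9_proc_code"]),
        visits=visits,
        visit_dx=visit_dx,
        visit_proc=concat(frames.visit_proc, ["visit_id", "cpt_code"]),
        provenance={"generator": "dfi.simulate", "n_patients": n},
    ).sorted()

    rank_order = list(CLASSIFIED_GROUPS)  # most severe first
    coex_str = [
        ";".join(c for c in rank_order if coex[c][i] and c != groups[i]) for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "group": groups,
            "coexisting": coex_str,
            **{c: truth_comorb[c] for c in COMORBIDITIES},
            "prior_amputation": past_amp,
            "prior_ltc": prior_ltc,
            "current_amputation": current_amp,
            "amputation_365": amp_365,
            "amputation_90": amp_90,
            "ltc_365": ltc_365,
            "ltc_90": ltc_90,
            "ltc_inpatient": ltc_365 & ltc_inpatient,
            "death_365": death_365,
            "death_90": death_90,
            "readmitted": readmitted,
            "readmit_group": readmit_group,
            "days_to_readmit": readmit_off,
            "index_admit_date": _days_to_dates(pd.Series(admit_day)) if n else pd.Series([], dtype="datetime64[ns]"),
            "los_days": los,
            "age": age,
        }
    )
    return bundle, truth


def perturb(
    bundle: ClaimsBundle,
    noise_dx: int = 0,
    moderate_confounders: int = 0,
    duplicate_dx_rows: int = 0,
    seed: int = 0,
) -> tuple[ClaimsBundle, dict[str, int]]:
    """Inject controlled corruptions into a bundle (returns a new bundle).

    ``noise_dx`` adds unrelated chronic-disease codes to random stays,
    ``moderate_confounders`` adds a lower-leg osteomyelitis code (730.26,
    moderately specific for a severe infection type) to random stays, and
    ``duplicate_dx_rows`` duplicates random stay-diagnosis rows.  The
    report dict documents what was injected.
    """
    rng = np.random.default_rng(seed)
    stay_dx = bundle.stay_dx.copy()
    stay_ids = bundle.stays["stay_id"].to_numpy()
    extra = []
    noise_codes = np.array(["4019", "2724", "4280", "49121"], dtype=object)
    if noise_dx and len(stay_ids):
        extra.append(
            pd.DataFrame(
                {
                    "stay_id": rng.choice(stay_ids, size=noise_dx),
                    "position": 99,
                    "icd9_code": rng.choice(noise_codes, size=noise_dx),
                }
            )
        )
    if moderate_confounders and len(stay_ids):
        extra.append(
            pd.DataFrame(
                {
                    "stay_id": rng.choice(stay_ids, size=moderate_confounders),
                    "position": 98,
                    "icd9_code": "73026",
                }
            )
        )
    if duplicate_dx_rows and len(stay_dx):
        rows = stay_dx.sample(
            n=min(duplicate_dx_rows, len(stay_dx)), random_state=int(rng.integers(2**31))
        )
        extra.append(rows)
    if extra:
        stay_dx = pd.concat([stay_dx] + extra, ignore_index=True)
    out = ClaimsBundle(
        patients=bundle.patients.copy(),
        stays=bundle.stays.copy(),
        stay_dx=stay_dx,
        stay_proc=bundle.stay_proc.copy(),
        visits=bundle.visits.copy(),
        visit_dx=bundle.visit_dx.copy(),
        visit_proc=bundle.visit_proc.copy(),
        provenance=dict(bundle.provenance),
    )
    report = {
        "noise_dx": noise_dx,
        "moderate_confounders": moderate_confounders,
        "duplicate_dx_rows": duplicate_dx_rows,
    }
    return out, report
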