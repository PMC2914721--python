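"""Analytic cohort construction from a claims bundle.

The cohort is anchored on each patient's *index hospitalization*: the
earliest inpatient stay carrying any foot-infection code (specific or
moderately specific).  Demographics are taken at the index admission,
comorbidities are flagged from inpatient and outpatient codes in a
two-year lookback window strictly prior to the index admission, and
prior-amputation / prior-long-term-care history is derived from all
records before the index date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import classify_codes, classify_stays_frame
from .codes import (
    CodeRegistry,
    MatchMode,
    Specificity,
    categories_present,
)
from .io import ClaimsBundle

__all__ = [
    "InpatientStay",
    "find_index_stay",
    "find_index_stays_frame",
    "comorbidity_flags",
    "cerebrovascular_flag",
    "treatment_frequency",
    "build_cohort",
    "load_procedure_exclusions",
    "DEFAULT_LOOKBACK_DAYS",
]

log = logging.getLogger(__name__)

DEFAULT_LOOKBACK_DAYS = 730  # "two-year period prior", half-open [index-730, index)

RACE_CATEGORIES = ("WHITE", "AFRICAN_AMERICAN", "OTHER", "UNKNOWN")

# Positional clauses of the cerebrovascular-disease algorithm (three-digit
# diagnosis roots; a plain 435 anywhere also qualifies and is carried by
# the comorbidity code table).
_CVD_PRIMARY = ("430", "431", "432", "434", "436")
_CVD_REHAB_SECONDARY = ("342", "430", "431", "432", "433", "434", "435", "436", "437", "438")
_CVD_COND_PRIMARY = ("433", "435")
_CVD_COND_SECONDARY = ("342", "430", "431", "432", "434", "436")


@dataclass(frozen=True)
class InpatientStay:
    """One admission episode; the unit of classification."""

    stay_id: str
    patient_id: str
    admit_date: date
    discharge_date: date
    care_setting: str = "ACUTE"
    diagnoses: tuple[tuple[int, str], ...] = ()  # (position, normalized code)
    procedures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.discharge_date < self.admit_date:
            raise ValueError(
                f"stay {self.stay_id}: discharge before admission"
            )
        positions = [p for p, _ in self.diagnoses]
        if len(positions) != len(set(positions)):
            raise ValueError(f"stay {self.stay_id}: duplicate diagnosis positions")

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(c for _, c in self.diagnoses)

    @property
    def los_days(self) -> int:
        return (self.discharge_date - self.admit_date).days


def _has_infection_code(codes: Iterable[str], registry: CodeRegistry) -> bool:
    codes = frozenset(codes)
    return bool(
        categories_present(codes, registry, Specificity.SPECIFIC)
        or categories_present(codes, registry, Specificity.MODERATE)
    )


def find_index_stay(
    stays: Sequence[InpatientStay], registry: CodeRegistry
) -> Optional[InpatientStay]:
    """Earliest stay with any foot-infection code; ties broken by stay_id.

    Returns None (and logs) when no stay qualifies — the patient is then
    omitted from the cohort.
    """
    qualifying = [s for s in stays if _has_infection_code(s.codes, registry)]
    if not qualifying:
        if stays:
            log.info(
                "patient %s: no stay with a foot-infection code; omitted",
                stays[0].patient_id,
            )
        return None
    return min(qualifying, key=lambda s: (s.admit_date, s.stay_id))


def find_index_stays_frame(
    bundle: ClaimsBundle, registry: CodeRegistry
) -> pd.DataFrame:
    """Index stay per patient, vectorized over the whole bundle.

    Returns columns ``patient_id, stay_id, admit_date, discharge_date``.
    """
    cls = classify_stays_frame(bundle.stay_dx, registry)
    if cls.empty:
        return pd.DataFrame(
            columns=["patient_id", "stay_id", "admit_date", "discharge_date"]
        )
    stays = bundle.stays.merge(cls[["stay_id"]], on="stay_id")
    stays = stays.sort_values(["patient_id", "admit_date", "stay_id"], kind="mergesort")
    idx = stays.groupby("patient_id", as_index=False).first()
    return idx[["patient_id", "stay_id", "admit_date", "discharge_date"]]


# ---------------------------------------------------------------------------
# comorbidity lookback

def _coded_events(bundle: ClaimsBundle) -> pd.DataFrame:
    """All dated diagnosis events: patient_id, date, scope_id, position, code."""
    stay_ev = bundle.stay_dx.merge(
        bundle.stays[["stay_id", "patient_id", "admit_date"]], on="stay_id"
    ).rename(columns={"admit_date": "date"})
    stay_ev["scope_id"] = "S:" + stay_ev["stay_id"].astype(str)
    visit_ev = bundle.visit_dx.merge(
        bundle.visits[["visit_id", "patient_id", "visit_date"]], on="visit_id"
    ).rename(columns={"visit_date": "date"})
    visit_ev["scope_id"] = "V:" + visit_ev["visit_id"].astype(str)
    cols = ["patient_id", "date", "scope_id", "position", "icd9_code"]
    return pd.concat([stay_ev[cols], visit_ev[cols]], ignore_index=True)


def cerebrovascular_flag(events: pd.DataFrame) -> pd.Series:
    """Compound cerebrovascular-disease flag per patient.

    ``events`` carries one diagnosis per row with columns ``patient_id,
    scope_id, position, icd9_code`` (already restricted to the lookback
    window).  A patient qualifies through any of: a 435.x code anywhere;
    a primary diagnosis in 430-432, 434, 436; a rehabilitation record
    (V57.x) with a secondary diagnosis in 342 or 430-438; or a primary
    diagnosis in 433/435 with a secondary diagnosis in 342, 430-432, 434
    or 436.
    """
    if events.empty:
        return pd.Series(dtype=bool)
    codes = events["icd9_code"].astype(str)
    primary = events["position"] == 1
    secondary = events["position"] > 1

    def anyprefix(prefixes) -> pd.Series:
        return codes.str.startswith(tuple(prefixes))

    plain_435 = anyprefix(("435",))
    primary_cvd = primary & anyprefix(_CVD_PRIMARY)

    scope = events["scope_id"]
    rehab_scopes = set(scope[anyprefix(("V57",))])
    rehab_secondary = (
        secondary & anyprefix(_CVD_REHAB_SECONDARY) & scope.isin(rehab_scopes)
    )
    cond_primary_scopes = set(scope[primary & anyprefix(_CVD_COND_PRIMARY)])
    cond_secondary = (
        secondary & anyprefix(_CVD_COND_SECONDARY) & scope.isin(cond_primary_scopes)
    )

    hit = plain_435 | primary_cvd | rehab_secondary | cond_secondary
    return events.assign(hit=hit).groupby("patient_id")["hit"].any()


def comorbidity_flags(
    bundle: ClaimsBundle,
    index_frame: pd.DataFrame,
    registry: CodeRegistry,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> pd.DataFrame:
    """Per-patient comorbidity flags from the pre-index lookback window.

    The window is half-open, ``[index_admit - lookback_days,
    index_admit)``: a code dated exactly ``lookback_days`` before the
    index admission counts, a code on the index admission date does not.
    Returns one boolean column per comorbidity label in the registry,
    indexed like ``index_frame`` (one row per patient).
    """
    conditions = registry.comorbidity_conditions()
    out = pd.DataFrame(
        False, index=index_frame["patient_id"], columns=list(conditions)
    )
    events = _coded_events(bundle)
    if events.empty:
        return out.reset_index()

    ev = events.merge(
        index_frame[["patient_id", "admit_date"]].rename(
            columns={"admit_date": "index_date"}
        ),
        on="patient_id",
    )
    lo = ev["index_date"] - pd.to_timedelta(lookback_days, unit="D")
    ev = ev[(ev["date"] >= lo) & (ev["date"] < ev["index_date"])]
    if ev.empty:
        return out.reset_index()

    codes = ev["icd9_code"].astype(str)
    for cond in conditions:
        mask = pd.Series(False, index=ev.index)
        for rule in registry.rules_for("comorbidity"):
            if rule.category != cond:
                continue
            if rule.match_mode is MatchMode.EXACT:
                mask |= codes == rule.pattern
            else:
                mask |= codes.str.startswith(rule.pattern)
        flagged = ev.loc[mask, "patient_id"].unique()
        out.loc[out.index.isin(flagged), cond] = True

    if "CVD" in conditions:
        cvd = cerebrovascular_flag(ev)
        flagged = cvd.index[cvd]
        out.loc[out.index.isin(flagged), "CVD"] = True

    return out.reset_index()


# ---------------------------------------------------------------------------
# history flags

def _amputation_proc_patterns(registry: CodeRegistry) -> tuple[str, ...]:
    return tuple(
        r.pattern
        for r in registry.rules_for("current_amputation")
    )


def _past_amputation_flags(
    bundle: ClaimsBundle, index_frame: pd.DataFrame, registry: CodeRegistry
) -> set:
    """Patients with any pre-index amputation evidence.

    Broader definition: ICD-9 amputation procedures, amputation-status /
    prosthesis-fitting diagnoses, or CPT-4 amputation codes, any time
    strictly before the index admission.
    """
    idx = index_frame.set_index("patient_id")["admit_date"]
    flagged: set = set()

    proc_pats = set(_amputation_proc_patterns(registry))
    sp = bundle.stay_proc.merge(
        bundle.stays[["stay_id", "patient_id", "admit_date"]], on="stay_id"
    )
    sp = sp.merge(idx.rename("index_date"), left_on="patient_id", right_index=True)
    hit = sp["icd9_proc_code"].isin(proc_pats) & (sp["admit_date"] < sp["index_date"])
    flagged.update(sp.loc[hit, "patient_id"])

    dx_pats = {
        r.pattern
        for r in registry.rules_for("past_amputation")
        if r.system.value == "ICD9CM_DX"
    }
    events = _coded_events(bundle)
    if not events.empty:
        ev = events.merge(
            idx.rename("index_date"), left_on="patient_id", right_index=True
        )
        hit = ev["icd9_code"].isin(dx_pats) & (ev["date"] < ev["index_date"])
        flagged.update(ev.loc[hit, "patient_id"])

    cpt_pats = {
        r.pattern
        for r in registry.rules_for("past_amputation")
        if r.system.value == "CPT4"
    }
    vp = bundle.visit_proc.merge(
        bundle.visits[["visit_id", "patient_id", "visit_date"]], on="visit_id"
    )
    vp = vp.merge(idx.rename("index_date"), left_on="patient_id", right_index=True)
    hit = vp["cpt_code"].isin(cpt_pats) & (vp["visit_date"] < vp["index_date"])
    flagged.update(vp.loc[hit, "patient_id"])

    return flagged


def _prior_ltc_flags(bundle: ClaimsBundle, index_frame: pd.DataFrame) -> set:
    idx = index_frame.set_index("patient_id")["admit_date"]
    flagged: set = set()
    st = bundle.stays.merge(
        idx.rename("index_date"), left_on="patient_id", right_index=True
    )
    hit = (st["care_setting"] == "LTC_INPATIENT") & (st["admit_date"] < st["index_date"])
    flagged.update(st.loc[hit, "patient_id"])
    vi = bundle.visits.merge(
        idx.rename("index_date"), left_on="patient_id", right_index=True
    )
    hit = (vi["care_setting"] == "LTC_OUTPATIENT") & (
        vi["visit_date"] < vi["index_date"]
    )
    flagged.update(vi.loc[hit, "patient_id"])
    return flagged


# ---------------------------------------------------------------------------
# inpatient treatment frequencies

def load_procedure_exclusions(path: Optional[Path | str] = None) -> set[str]:
    """Editable exclusion list for the treatment table (non-surgical codes)."""
    if path is None:
        path = Path(str(resources.files("dfi") / "data" / "procedure_exclusions.csv"))
    df = pd.read_csv(path, comment="#", dtype=str)
    return set(df["icd9_proc_code"].str.strip())


AMPUTATION_ROW = "ANY_CURRENT_AMPUTATION"


def treatment_frequency(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    min_fraction: float = 0.01,
    exclusion_list: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Per-group index-stay procedure frequencies.

    A code is retained when it occurs on at least ``min_fraction`` of all
    index stays (amputation procedure codes are first collapsed into one
    grouped row).  Codes on the exclusion list — the configurable
    stand-in for procedures that are not surgical in nature — are
    dropped.  Returns tidy rows ``(code, group, proportion)``.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if exclusion_list is None:
        exclusion_list = load_procedure_exclusions()
    if cohort.empty:
        return pd.DataFrame(columns=["code", "group", "proportion"])

    procs = bundle.stay_proc.merge(
        cohort[["index_stay_id", "patient_id", "group"]],
        left_on="stay_id",
        right_on="index_stay_id",
    )
    procs = procs[~procs["icd9_proc_code"].isin(exclusion_list)]
    amput = set(_amputation_proc_patterns(registry))
    procs = procs.assign(
        code=procs["icd9_proc_code"].where(
            ~procs["icd9_proc_code"].isin(amput), AMPUTATION_ROW
        )
    ).drop_duplicates(["patient_id", "code"])

    n_total = len(cohort)
    overall = procs.groupby("code")["patient_id"].nunique() / n_total
    keep = set(overall.index[overall >= min_fraction])
    procs = procs[procs["code"].isin(keep)]
    if procs.empty:
        return pd.DataFrame(columns=["code", "group", "proportion"])

    group_sizes = cohort.groupby("group")["patient_id"].nunique()
    counts = (
        procs.groupby(["code", "group"])["patient_id"].nunique().rename("n").reset_index()
    )
    counts["proportion"] = counts.apply(
        lambda r: r["n"] / group_sizes[r["group"]], axis=1
    )
    return counts[["code", "group", "proportion"]].sort_values(
        ["code", "group"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort assembly

def _age_years(birth: pd.Series, at: pd.Series) -> pd.Series:
    """Floor of whole calendar years between two date series."""
    b, a = pd.to_datetime(birth), pd.to_datetime(at)
    years = a.dt.year - b.dt.year
    before_birthday = (a.dt.month < b.dt.month) | (
        (a.dt.month == b.dt.month) & (a.dt.day < b.dt.day)
    )
    return (years - before_birthday.astype(int)).astype("Int64")


def build_cohort(
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    classifier_mode: str = "index_stay",
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
    race_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Build the analytic cohort: one row per patient with a qualifying stay.

    Columns: patient identifiers and index-stay anchors, the assigned
    infection group (with coexisting categories and the
    moderate-exclusion flag), demographics at index, length of stay, one
    boolean per comorbidity, and prior amputation / prior long-term-care
    history flags.  Deterministic given inputs.
    """
    bundle.validate()
    index_frame = find_index_stays_frame(bundle, registry)
    if index_frame.empty:
        cols = [
            "patient_id", "index_stay_id", "group", "category", "coexisting",
            "excluded_by_moderate", "index_admit_date", "index_discharge_date",
            "age_at_index", "sex", "race", "los_days",
            *registry.comorbidity_conditions(), "prior_amputation", "prior_ltc",
        ]
        return pd.DataFrame(columns=cols)

    if classifier_mode == "index_stay":
        dx = bundle.stay_dx[bundle.stay_dx["stay_id"].isin(index_frame["stay_id"])]
        cls = classify_stays_frame(dx, registry)
        cls = cls.merge(index_frame[["patient_id", "stay_id"]], on="stay_id")
    elif classifier_mode == "pooled":
        pooled = bundle.stay_dx.merge(
            bundle.stays[["stay_id", "patient_id"]], on="stay_id"
        )
        pooled = pooled.assign(stay_id=pooled["patient_id"])
        cls = classify_stays_frame(
            pooled[["stay_id", "icd9_code"]], registry
        ).rename(columns={"stay_id": "patient_id"})
        cls = cls.merge(index_frame[["patient_id"]], on="patient_id")
    else:
        raise ValueError(f"unknown classifier mode {classifier_mode!r}")

    out = index_frame.rename(
        columns={
            "stay_id": "index_stay_id",
            "admit_date": "index_admit_date",
            "discharge_date": "index_discharge_date",
        }
    ).merge(
        cls[["patient_id", "category", "final_group", "excluded_by_moderate", "coexisting"]],
        on="patient_id",
    ).rename(columns={"final_group": "group"})

    pat = bundle.patients.set_index("patient_id")
    out = out.merge(
        pat[["sex", "birth_date", "race"]], left_on="patient_id", right_index=True
    )
    out["age_at_index"] = _age_years(out["birth_date"], out["index_admit_date"])
    out["los_days"] = (
        out["index_discharge_date"] - out["index_admit_date"]
    ).dt.days.astype("Int64")
    rmap = race_map or {}
    out["race"] = (
        out["race"].map(lambda r: rmap.get(r, r))
        .where(lambda s: s.isin(RACE_CATEGORIES), "UNKNOWN")
    )
    out = out.drop(columns=["birth_date"])

    flags = comorbidity_flags(bundle, index_frame, registry, lookback_days)
    out = out.merge(flags, on="patient_id", how="left")
    for cond in registry.comorbidity_conditions():
        out[cond] = out[cond].fillna(False).astype(bool)

    out["prior_amputation"] = out["patient_id"].isin(
        _past_amputation_flags(bundle, index_frame, registry)
    )
    out["prior_ltc"] = out["patient_id"].isin(_prior_ltc_flags(bundle, index_frame))

    return out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
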