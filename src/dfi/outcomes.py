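"""Post-discharge outcomes: readmission, amputation, long-term care, death.

All follow-up windows are measured from the *index discharge date* and
are half-open on the left, ``(discharge, discharge + horizon]``: an
event on the discharge day itself is not a post-discharge event.  The
windows nest, so any 90-day indicator implies the 365-day indicator,
which implies the ever indicator.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import classify_stays_frame
from .codes import CodeRegistry, InfectionCategory
from .io import ClaimsBundle

__all__ = [
    "readmissions",
    "readmit_pairs",
    "detect_current_amputation",
    "current_amputation_in",
    "subsequent_amputation",
    "ltc_transition",
    "mortality",
    "outcomes_frame",
    "outcome_table",
    "DEFAULT_HORIZONS",
]

log = logging.getLogger(__name__)

DEFAULT_HORIZONS = (90, 365)


def _amputation_patterns(registry: CodeRegistry) -> set[str]:
    return {r.pattern for r in registry.rules_for("current_amputation")}


def _cohort_anchor(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[
        ["patient_id", "index_stay_id", "index_admit_date", "index_discharge_date"]
    ]


# ---------------------------------------------------------------------------
# readmission

def readmissions(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    interval: str = "discharge_to_admit",
) -> pd.DataFrame:
    """First post-index rehospitalization for any foot infection.

    The readmission group is the severity classification of that stay's
    own diagnosis codes.  ``interval`` selects the day count:
    ``discharge_to_admit`` (the hospital-free interval, default) or
    ``admit_to_admit``.  Stays that overlap the index stay (admission
    before the index discharge) are skipped with a data-quality warning.

    Returns one row per cohort patient: ``patient_id, readmitted,
    readmit_stay_id, readmit_group, days_to_readmit``.
    """
    if interval not in ("discharge_to_admit", "admit_to_admit"):
        raise ValueError(f"unknown interval convention {interval!r}")
    out = cohort[["patient_id"]].copy()

    cls = classify_stays_frame(bundle.stay_dx, registry)
    st = bundle.stays.merge(cls[["stay_id", "final_group"]], on="stay_id")
    st = st.merge(_cohort_anchor(cohort), on="patient_id")
    st = st[st["stay_id"] != st["index_stay_id"]]
    st = st[st["admit_date"] >= st["index_admit_date"]]

    overlap = st["admit_date"] < st["index_discharge_date"]
    if overlap.any():
        log.warning(
            "%d infection stay(s) overlap the index stay and were skipped",
            int(overlap.sum()),
        )
        st = st[~overlap]

    st = st.sort_values(["patient_id", "admit_date", "stay_id"], kind="mergesort")
    first = st.groupby("patient_id", as_index=False).first()
    if interval == "discharge_to_admit":
        days = (first["admit_date"] - first["index_discharge_date"]).dt.days
    else:
        days = (first["admit_date"] - first["index_admit_date"]).dt.days
    first = first.assign(days_to_readmit=days)

    out = out.merge(
        first[["patient_id", "stay_id", "final_group", "days_to_readmit"]],
        on="patient_id",
        how="left",
    ).rename(columns={"stay_id": "readmit_stay_id", "final_group": "readmit_group"})
    out["readmitted"] = out["readmit_stay_id"].notna()
    out["days_to_readmit"] = out["days_to_readmit"].astype("Int64")
    return out[
        ["patient_id", "readmitted", "readmit_stay_id", "readmit_group", "days_to_readmit"]
    ]


def readmit_pairs(cohort: pd.DataFrame, readmit: pd.DataFrame) -> pd.DataFrame:
    """Auxiliary (index group, readmission group) interval table.

    One row per observed pair with the patient count and median days to
    readmission — the basis of earliest-readmission-by-type summaries.
    """
    merged = cohort[["patient_id", "group"]].merge(
        readmit[readmit["readmitted"]], on="patient_id"
    )
    if merged.empty:
        return pd.DataFrame(columns=["index_group", "readmit_group", "n", "median_days"])
    tab = (
        merged.groupby(["group", "readmit_group"])
        .agg(n=("patient_id", "size"), median_days=("days_to_readmit", "median"))
        .reset_index()
        .rename(columns={"group": "index_group"})
    )
    return tab.sort_values(["index_group", "readmit_group"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# amputation

def current_amputation_in(procedures: Iterable[str], registry: CodeRegistry) -> bool:
    """True iff any procedure code is a lower-extremity amputation (84.11-17)."""
    pats = _amputation_patterns(registry)
    return any(p in pats for p in procedures)


def detect_current_amputation(
    cohort: pd.DataFrame, bundle: ClaimsBundle, registry: CodeRegistry
) -> pd.Series:
    """Amputation during the index stay itself, per cohort patient."""
    pats = _amputation_patterns(registry)
    sp = bundle.stay_proc[bundle.stay_proc["icd9_proc_code"].isin(pats)]
    flagged = set(
        cohort.merge(sp, left_on="index_stay_id", right_on="stay_id")["patient_id"]
    )
    return cohort["patient_id"].isin(flagged).rename("current_amputation")


def subsequent_amputation(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
) -> pd.DataFrame:
    """Post-discharge amputations from inpatient procedure codes.

    An amputation during the index stay is *not* subsequent; windows are
    ``(index discharge, index discharge + horizon]`` keyed on the
    amputation stay's admission date.  Returns indicator columns
    ``amputation_{h}d`` per horizon plus ``amputation_ever`` and
    ``first_amputation_date``.
    """
    pats = _amputation_patterns(registry)
    sp = bundle.stay_proc[bundle.stay_proc["icd9_proc_code"].isin(pats)]
    st = bundle.stays[bundle.stays["stay_id"].isin(set(sp["stay_id"]))]
    st = st.merge(_cohort_anchor(cohort), on="patient_id")
    st = st[st["stay_id"] != st["index_stay_id"]]
    st = st[st["admit_date"] > st["index_discharge_date"]]

    first = (
        st.sort_values(["patient_id", "admit_date"], kind="mergesort")
        .groupby("patient_id", as_index=False)
        .first()[["patient_id", "admit_date", "index_discharge_date"]]
    )
    out = cohort[["patient_id"]].merge(first, on="patient_id", how="left")
    delta = (out["admit_date"] - out["index_discharge_date"]).dt.days
    for h in horizons:
        out[f"amputation_{h}d"] = (delta <= h).fillna(False)
    out["amputation_ever"] = out["admit_date"].notna()
    out = out.rename(columns={"admit_date": "first_amputation_date"})
    return out.drop(columns=["index_discharge_date"])


# ---------------------------------------------------------------------------
# long-term care

def ltc_transition(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
    inpatient_only: bool = False,
    restrict_prior: bool = True,
) -> pd.DataFrame:
    """Transition to long-term care after index discharge.

    Long-term care covers inpatient (nursing home) stays and outpatient
    (home-health / skilled-nursing) visits; ``inpatient_only`` restricts
    to nursing-home care.  With ``restrict_prior`` (default) the
    indicators are defined only for patients with no long-term care
    before the index admission; other patients get NA.
    """
    records = []
    st = bundle.stays[bundle.stays["care_setting"] == "LTC_INPATIENT"]
    st = st.merge(_cohort_anchor(cohort), on="patient_id")
    records.append(
        st[st["admit_date"] > st["index_discharge_date"]][
            ["patient_id", "admit_date", "index_discharge_date"]
        ].rename(columns={"admit_date": "date"})
    )
    if not inpatient_only:
        vi = bundle.visits[bundle.visits["care_setting"] == "LTC_OUTPATIENT"]
        vi = vi.merge(_cohort_anchor(cohort), on="patient_id")
        records.append(
            vi[vi["visit_date"] > vi["index_discharge_date"]][
                ["patient_id", "visit_date", "index_discharge_date"]
            ].rename(columns={"visit_date": "date"})
        )
    ev = pd.concat(records, ignore_index=True)

    prefix = "ltc_inpatient" if inpatient_only else "ltc"
    out = cohort[["patient_id"]].copy()
    if ev.empty:
        delta = pd.Series(np.nan, index=out.index)
    else:
        first = (
            ev.sort_values(["patient_id", "date"], kind="mergesort")
            .groupby("patient_id", as_index=False)
            .first()
        )
        out = out.merge(first, on="patient_id", how="left")
        delta = (out["date"] - out["index_discharge_date"]).dt.days
        out = out.drop(columns=["date", "index_discharge_date"])
    for h in horizons:
        out[f"{prefix}_{h}d"] = (delta <= h).fillna(False).astype(object)

    if restrict_prior:
        prior = cohort.set_index("patient_id")["prior_ltc"]
        mask = out["patient_id"].map(prior).astype(bool)
        for h in horizons:
            out.loc[mask, f"{prefix}_{h}d"] = pd.NA
    return out


# ---------------------------------------------------------------------------
# mortality

def mortality(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
) -> pd.DataFrame:
    """Post-discharge death indicators plus an in-hospital death flag.

    A death on or before the index discharge date is an in-hospital
    death and is excluded from the post-discharge indicators.
    """
    out = cohort[["patient_id", "index_discharge_date"]].merge(
        bundle.patients[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    delta = (out["death_date"] - out["index_discharge_date"]).dt.days
    post = delta > 0
    for h in horizons:
        out[f"death_{h}d"] = (post & (delta <= h)).fillna(False)
    out["death_ever"] = post.fillna(False)
    out["in_hospital_death"] = (delta <= 0).fillna(False)
    return out.drop(columns=["index_discharge_date", "death_date"])


# ---------------------------------------------------------------------------
# assembly and reporting

def outcomes_frame(
    cohort: pd.DataFrame,
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
    interval: str = "discharge_to_admit",
) -> pd.DataFrame:
    """One row per cohort patient with every outcome family."""
    out = cohort[["patient_id", "group", "prior_amputation", "prior_ltc"]].rename(
        columns={"prior_amputation": "past_amputation"}
    )
    out = out.merge(
        readmissions(cohort, bundle, registry, interval=interval), on="patient_id"
    )
    out["current_amputation"] = detect_current_amputation(
        cohort, bundle, registry
    ).values
    out = out.merge(
        subsequent_amputation(cohort, bundle, registry, horizons), on="patient_id"
    )
    out = out.merge(
        ltc_transition(cohort, bundle, horizons, inpatient_only=False), on="patient_id"
    )
    out = out.merge(
        ltc_transition(cohort, bundle, horizons, inpatient_only=True), on="patient_id"
    )
    out = out.merge(mortality(cohort, bundle, horizons), on="patient_id")
    return out


def outcome_table(
    cohort: pd.DataFrame,
    outcomes: pd.DataFrame,
    horizon: int = 365,
) -> pd.DataFrame:
    """Per-group one-year outcome proportions (amputation, LTC, death).

    LTC is reported with both denominators: the no-prior-LTC subset
    (``ltc``) and the whole group (``ltc_all``, counting patients with
    prior long-term care as non-events of the restricted definition).
    """
    merged = cohort[["patient_id", "group"]].merge(
        outcomes.drop(columns=["group"], errors="ignore"), on="patient_id"
    )
    amp = f"amputation_{horizon}d"
    ltc = f"ltc_{horizon}d"
    death = f"death_{horizon}d"
    rows = []
    for group, g in merged.groupby("group"):
        n = len(g)
        ltc_defined = g[ltc].notna()
        rows.append(
            {
                "group": group,
                "n": n,
                "amputation": g[amp].mean(),
                "ltc": (
                    g.loc[ltc_defined, ltc].astype(bool).mean()
                    if ltc_defined.any()
                    else np.nan
                ),
                "ltc_all": (g[ltc] == True).mean(),  # noqa: E712 (NA-safe)
                "death": g[death].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("group")
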