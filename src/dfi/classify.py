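"""Severity classification of foot-infection code sets.

Patients frequently carry codes for more than one kind of foot infection
(e.g. an ulcer with cellulitis of the foot).  To obtain mutually
exclusive groups, each patient/stay is assigned the *most severe*
category for which a specific code is present, with the remaining
matches recorded as coexisting, strictly less severe infections.  A
patient whose only evidence for a *more* severe infection type is a
moderately specific (non-foot-localizing) code is excluded from the
specific groups and reported in the OTHER group, which keeps the
specific groups homogeneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codes import (
    RANKED_CATEGORIES,
    SEVERITY_RANK,
    CodeRegistry,
    InfectionCategory,
    MatchMode,
    Specificity,
    categories_present,
)

__all__ = [
    "StayClassification",
    "ClassificationFlow",
    "classify_codes",
    "classify_patient",
    "classify_stays_frame",
    "coinfection_matrix",
    "build_flow",
]


@dataclass(frozen=True)
class StayClassification:
    """Result of classifying one code scope (a stay or a patient)."""

    stay_id: Optional[str]
    category: InfectionCategory
    coexisting: frozenset[InfectionCategory] = frozenset()
    excluded_by_moderate: bool = False
    matched_specific_codes: frozenset[str] = frozenset()
    matched_moderate_categories: frozenset[InfectionCategory] = frozenset()

    @property
    def final_group(self) -> InfectionCategory:
        """Reported group: OTHER when excluded by a moderate code for a
        more severe infection type, otherwise the assigned category."""
        if self.excluded_by_moderate:
            return InfectionCategory.OTHER
        return self.category


@dataclass
class ClassificationFlow:
    """Patient-flow counts: total, per specific group, OTHER, exclusions."""

    n_total: int
    n_per_category: dict[InfectionCategory, int]
    n_other: int
    n_excluded_by_moderate: dict[InfectionCategory, int]

    def check(self) -> None:
        assert self.n_total == sum(self.n_per_category.values()) + self.n_other


def classify_codes(
    scope_codes: Iterable[str], registry: CodeRegistry, stay_id: Optional[str] = None
) -> StayClassification:
    """Classify one set of normalized diagnosis codes.

    The assigned category is the highest-ranked specific match; all other
    specific matches become coexisting infections.  If a moderately
    specific code maps to a category outranking the assigned one, the
    record is flagged ``excluded_by_moderate`` (final group OTHER).  With
    no specific match at all, a moderate match yields OTHER and no match
    yields NONE.  Invariant to code order and duplication.
    """
    scope = frozenset(scope_codes)
    spec_cats = categories_present(scope, registry, Specificity.SPECIFIC)
    mod_cats = categories_present(scope, registry, Specificity.MODERATE)

    if not spec_cats:
        category = InfectionCategory.OTHER if mod_cats else InfectionCategory.NONE
        return StayClassification(
            stay_id=stay_id,
            category=category,
            matched_moderate_categories=frozenset(mod_cats),
        )

    category = max(spec_cats, key=lambda c: SEVERITY_RANK[c])
    coexisting = frozenset(spec_cats - {category})
    excluded = any(SEVERITY_RANK[m] > SEVERITY_RANK[category] for m in mod_cats)

    matched = frozenset(
        c
        for c in scope
        if any(
            r.matches(c, scope)
            for r in registry.infection_rules(Specificity.SPECIFIC)
        )
    )
    return StayClassification(
        stay_id=stay_id,
        category=category,
        coexisting=coexisting,
        excluded_by_moderate=excluded,
        matched_specific_codes=matched,
        matched_moderate_categories=frozenset(mod_cats),
    )


def _stay_codes(stay) -> frozenset[str]:
    """Diagnosis codes of a stay object or mapping."""
    if hasattr(stay, "diagnoses"):
        dx = stay.diagnoses
    else:
        dx = stay["diagnoses"]
    return frozenset(code for _pos, code in dx)


def classify_patient(
    stays: Sequence, registry: CodeRegistry, mode: str = "index_stay"
) -> StayClassification:
    """Classify a patient from their date-ordered inpatient stays.

    ``index_stay`` classifies on the first stay carrying any specific or
    moderately specific infection code; ``pooled`` classifies on the
    union of all inpatient diagnosis codes.

    Raises
    ------
    ValueError
        If no stay carries any infection code, or mode is unknown.
    """
    if mode not in ("index_stay", "pooled"):
        raise ValueError(f"unknown classification mode {mode!r}")
    qualifying = []
    for stay in stays:
        codes = _stay_codes(stay)
        if categories_present(codes, registry, Specificity.SPECIFIC) or (
            categories_present(codes, registry, Specificity.MODERATE)
        ):
            qualifying.append(stay)
    if not qualifying:
        raise ValueError("no stay carries any foot-infection code")
    if mode == "index_stay":
        stay = qualifying[0]
        sid = getattr(stay, "stay_id", None)
        return classify_codes(_stay_codes(stay), registry, stay_id=sid)
    pooled: set[str] = set()
    for stay in stays:
        pooled |= _stay_codes(stay)
    return classify_codes(pooled, registry)


# ---------------------------------------------------------------------------
# vectorized stay-level classification over a diagnosis frame

def classify_stays_frame(
    stay_dx: pd.DataFrame, registry: CodeRegistry
) -> pd.DataFrame:
    """Classify every stay in a ``stay_dx`` frame (columns stay_id, icd9_code).

    Vectorized equivalent of running :func:`classify_codes` per stay;
    returns one row per stay that carries at least one infection code,
    with columns ``stay_id, category, final_group, excluded_by_moderate,
    coexisting`` (semicolon-joined category names).  Agreement with the
    per-set path is covered by tests.
    """
    if stay_dx.empty:
        return pd.DataFrame(
            columns=[
                "stay_id",
                "category",
                "final_group",
                "excluded_by_moderate",
                "coexisting",
            ]
        )
    dx = stay_dx[["stay_id", "icd9_code"]].drop_duplicates()
    codes = dx["icd9_code"].astype(str)

    spec_rank = pd.Series(0, index=dx.index)  # rank of specific match per row
    mod_rank = pd.Series(0, index=dx.index)
    cond_pending: list[tuple[pd.Series, int, object]] = []

    for rule in registry.infection_rules():
        if rule.match_mode is MatchMode.EXACT:
            hit = codes == rule.pattern
        else:
            hit = codes.str.startswith(rule.pattern)
        if not hit.any():
            continue
        rank = SEVERITY_RANK[rule.infection_category]
        if rule.condition:
            cond_pending.append((hit, rank, rule))
            continue
        if rule.specificity is Specificity.SPECIFIC:
            spec_rank = spec_rank.where(~hit, np.maximum(spec_rank, rank))
        else:
            mod_rank = mod_rank.where(~hit, np.maximum(mod_rank, rank))

    # conditional rules: companion must match some code of the same stay
    for hit, rank, rule in cond_pending:
        comp = pd.Series(False, index=dx.index)
        for c in rule.condition:
            if c.match_mode is MatchMode.EXACT:
                comp |= codes == c.pattern
            else:
                comp |= codes.str.startswith(c.pattern)
        stays_with_comp = set(dx.loc[comp, "stay_id"])
        ok = hit & dx["stay_id"].isin(stays_with_comp)
        if rule.specificity is Specificity.SPECIFIC:
            spec_rank = spec_rank.where(~ok, np.maximum(spec_rank, rank))
        else:
            mod_rank = mod_rank.where(~ok, np.maximum(mod_rank, rank))

    work = dx.assign(spec_rank=spec_rank, mod_rank=mod_rank)
    by_rank = {SEVERITY_RANK[c]: c for c in RANKED_CATEGORIES}

    # per stay: max specific rank, set of specific ranks, max moderate rank
    grp = work.groupby("stay_id")
    agg = grp.agg(
        max_spec=("spec_rank", "max"),
        max_mod=("mod_rank", "max"),
    )
    agg = agg[(agg["max_spec"] > 0) | (agg["max_mod"] > 0)]
    if agg.empty:
        return pd.DataFrame(
            columns=[
                "stay_id",
                "category",
                "final_group",
                "excluded_by_moderate",
                "coexisting",
            ]
        )

    spec_sets = (
        work[work["spec_rank"] > 0]
        .groupby("stay_id")["spec_rank"]
        .agg(lambda s: frozenset(s))
    )

    records = []
    for stay_id, row in agg.iterrows():
        max_spec = int(row["max_spec"])
        max_mod = int(row["max_mod"])
        if max_spec == 0:
            records.append(
                (stay_id, InfectionCategory.OTHER.value,
                 InfectionCategory.OTHER.value, False, "")
            )
            continue
        category = by_rank[max_spec]
        ranks = spec_sets.get(stay_id, frozenset())
        coexisting = sorted((r for r in ranks if r != max_spec), reverse=True)
        excluded = max_mod > max_spec
        final = InfectionCategory.OTHER if excluded else category
        records.append(
            (
                stay_id,
                category.value,
                final.value,
                excluded,
                ";".join(by_rank[r].value for r in coexisting),
            )
        )
    return pd.DataFrame(
        records,
        columns=[
            "stay_id",
            "category",
            "final_group",
            "excluded_by_moderate",
            "coexisting",
        ],
    )


# ---------------------------------------------------------------------------
# reporting structures

def coinfection_matrix(
    classifications: Iterable[StayClassification],
) -> pd.DataFrame:
    """Lower-triangular co-infection proportion matrix.

    Cell (row = less severe category R, column = group G) is the
    proportion of group-G patients with R among their coexisting
    infections.  Cells at or above the severity diagonal are structurally
    empty (NaN): a patient cannot have a coexisting infection at least as
    severe as their assigned group.

    Raises
    ------
    ValueError
        On empty input or classifications without a specific category.
    """
    cls = list(classifications)
    if not cls:
        raise ValueError("no classifications given")
    if any(c.category.severity_rank is None for c in cls):
        raise ValueError("co-infection matrix requires specific categories only")

    cats = list(RANKED_CATEGORIES)
    counts = pd.DataFrame(0.0, index=cats, columns=cats)
    totals = pd.Series(0, index=cats, dtype=float)
    for c in cls:
        totals[c.category] += 1
        for co in c.coexisting:
            counts.loc[co, c.category] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = counts.divide(totals.replace(0, np.nan), axis=1)
    # structural empties: row rank >= column rank
    for r in cats:
        for g in cats:
            if SEVERITY_RANK[r] >= SEVERITY_RANK[g]:
                prop.loc[r, g] = np.nan
            elif totals[g] > 0 and np.isnan(prop.loc[r, g]):
                prop.loc[r, g] = 0.0
    prop.index = [c.value for c in cats]
    prop.columns = [c.value for c in cats]
    return prop


def build_flow(
    classifications: Iterable[StayClassification],
) -> ClassificationFlow:
    """Count the classification flow: per-group sizes, OTHER, exclusions.

    NONE classifications (no infection code at all) are not part of the
    flow and are ignored.
    """
    n_per = {c: 0 for c in RANKED_CATEGORIES}
    n_other = 0
    n_excl: dict[InfectionCategory, int] = {c: 0 for c in RANKED_CATEGORIES}
    n_total = 0
    for c in classifications:
        if c.category is InfectionCategory.NONE:
            continue
        n_total += 1
        final = c.final_group
        if final is InfectionCategory.OTHER:
            n_other += 1
            if c.excluded_by_moderate:
                n_excl[c.category] += 1
        else:
            n_per[final] += 1
    flow = ClassificationFlow(
        n_total=n_total,
        n_per_category=n_per,
        n_other=n_other,
        n_excluded_by_moderate=n_excl,
    )
    flow.check()
    return flow
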