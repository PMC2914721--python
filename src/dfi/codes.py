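"""Code registry: ICD-9-CM / ICD-9-procedure / CPT-4 code sets with explicit matching semantics.

Administrative claims carry diagnosis and procedure codes whose meaning
depends on how they are matched: an exact five-digit ICD-9-CM code
(``681.11``, onychia/paronychia of toe) identifies a different lesion from
its four-digit parent (``681.1``, cellulitis/abscess of toe), while a
three-digit root such as ``440`` (atherosclerosis) is conventionally used
as a prefix covering every subcode.  This module makes those semantics
explicit: every matchable pattern is a :class:`DiagnosisCodeRule` with a
coding system, a match mode (exact or prefix), and optionally a companion
condition — the gangrene symptom code 785.4 counts as foot gangrene only
when a diabetic peripheral-circulatory or lower-extremity-atherosclerosis
code is also present in the same record scope.

The shipped default tables encode the published foot-infection phenotype:
six mutually exclusive infection categories ranked by severity
(gangrene > osteomyelitis > ulcer > cellulitis/abscess of foot >
cellulitis/abscess of toe > paronychia), a moderately-specific tier (open
wounds of the foot, infections of the leg), amputation procedure and
aftercare codes, diabetes-complication comorbidity sets, and CPT-4
treatment codes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "InfectionCategory",
    "CodingSystem",
    "MatchMode",
    "Specificity",
    "DiagnosisCodeRule",
    "CodeRegistry",
    "CodeValidationError",
    "RegistryError",
    "SEVERITY_RANK",
    "RANKED_CATEGORIES",
    "normalize_code",
    "load_registry",
    "write_registry",
    "default_table_paths",
    "categories_present",
]


class CodeValidationError(ValueError):
    """Raised for malformed diagnosis/procedure code strings."""


class RegistryError(ValueError):
    """Raised when a code table violates the registry schema or invariants."""


class InfectionCategory(str, enum.Enum):
    """Mutually exclusive foot-infection categories plus OTHER / NONE.

    The six specific categories carry a total severity order used to
    resolve co-occurring codes to a single group; OTHER collects patients
    with only moderately specific (non-foot-localizing) codes and NONE
    marks code sets with no infection code at all.
    """

    GANGRENE = "GANGRENE"
    OSTEOMYELITIS = "OSTEOMYELITIS"
    ULCER = "ULCER"
    FOOT_CELLULITIS_ABSCESS = "FOOT_CELLULITIS_ABSCESS"
    TOE_CELLULITIS_ABSCESS = "TOE_CELLULITIS_ABSCESS"
    PARONYCHIA = "PARONYCHIA"
    OTHER = "OTHER"
    NONE = "NONE"

    @property
    def severity_rank(self) -> Optional[int]:
        """6 (gangrene, most severe) .. 1 (paronychia); None for OTHER/NONE."""
        return SEVERITY_RANK.get(self)


SEVERITY_RANK: Mapping[InfectionCategory, int] = {
    InfectionCategory.GANGRENE: 6,
    InfectionCategory.OSTEOMYELITIS: 5,
    InfectionCategory.ULCER: 4,
    InfectionCategory.FOOT_CELLULITIS_ABSCESS: 3,
    InfectionCategory.TOE_CELLULITIS_ABSCESS: 2,
    InfectionCategory.PARONYCHIA: 1,
}

#: The six specific categories, most severe first.
RANKED_CATEGORIES: tuple[InfectionCategory, ...] = tuple(
    sorted(SEVERITY_RANK, key=lambda c: -SEVERITY_RANK[c])
)


class CodingSystem(str, enum.Enum):
    ICD9CM_DX = "ICD9CM_DX"
    ICD9_PROC = "ICD9_PROC"
    CPT4 = "CPT4"


class MatchMode(str, enum.Enum):
    EXACT = "EXACT"
    PREFIX = "PREFIX"


class Specificity(str, enum.Enum):
    SPECIFIC = "SPECIFIC"   # definitively localizes infection to the foot
    MODERATE = "MODERATE"   # open foot wounds / leg infections: suggestive only
    NA = "NA"               # non-infection purposes (amputation, comorbidity, ...)


# registry purposes
PURPOSE_INFECTION = "infection"
PURPOSE_CURRENT_AMPUTATION = "current_amputation"
PURPOSE_PAST_AMPUTATION = "past_amputation"
PURPOSE_COMORBIDITY = "comorbidity"
PURPOSE_TREATMENT_CPT = "treatment_cpt"

PURPOSES = (
    PURPOSE_INFECTION,
    PURPOSE_CURRENT_AMPUTATION,
    PURPOSE_PAST_AMPUTATION,
    PURPOSE_COMORBIDITY,
    PURPOSE_TREATMENT_CPT,
)

_DX_RE = re.compile(r"^V?[0-9]+$")
_DX_RE_WITH_E = re.compile(r"^[VE]?[0-9]+$")


def normalize_code(raw: object, *, allow_e: bool = False) -> str:
    """Normalize a diagnosis/procedure code string.

    Uppercases, strips whitespace and removes the decimal point, so
    ``"730.07" -> "73007"`` and ``"V49.75" -> "V4975"``.  Idempotent.
    V-codes are accepted; E-codes (external cause) are rejected unless
    ``allow_e`` is set, since no phenotype here uses them.

    Raises
    ------
    CodeValidationError
        If the input is empty or contains characters other than digits
        and a single leading V (or E), or more than one decimal point.
    """
    s = str(raw).strip().upper()
    if not s:
        raise CodeValidationError("empty code string")
    if s.count(".") > 1:
        raise CodeValidationError(f"malformed code {raw!r}: multiple decimal points")
    s = s.replace(".", "")
    if s.startswith("E") and not allow_e:
        raise CodeValidationError(f"E-codes are not supported here: {raw!r}")
    pattern = _DX_RE_WITH_E if allow_e else _DX_RE
    if not pattern.fullmatch(s):
        raise CodeValidationError(f"malformed code {raw!r}")
    return s


@dataclass(frozen=True)
class DiagnosisCodeRule:
    """One matchable code pattern.

    ``condition`` holds companion rules of which at least one must match
    some code in the same record scope for this rule to fire (used for
    785.4 gangrene, which requires a diabetic peripheral-circulatory or
    extremity-atherosclerosis companion code).
    """

    pattern: str
    system: CodingSystem
    match_mode: MatchMode
    category: str
    specificity: Specificity = Specificity.NA
    condition: tuple["DiagnosisCodeRule", ...] = ()

    def __post_init__(self) -> None:
        if not _DX_RE_WITH_E.fullmatch(self.pattern):
            raise CodeValidationError(
                f"rule pattern {self.pattern!r} is not a normalized code"
            )

    @property
    def infection_category(self) -> InfectionCategory:
        return InfectionCategory(self.category)

    def matches(self, code: str, scope_codes: Iterable[str] = ()) -> bool:
        """Pure predicate: does ``code`` satisfy this rule within ``scope_codes``?"""
        if self.match_mode is MatchMode.EXACT:
            hit = code == self.pattern
        else:
            hit = code.startswith(self.pattern)
        if not hit:
            return False
        if self.condition:
            return any(
                c.matches(sc) for sc in scope_codes for c in self.condition
            )
        return True


def match_rule(
    rule: DiagnosisCodeRule, code: str, scope_codes: Iterable[str] = ()
) -> bool:
    """Functional alias for :meth:`DiagnosisCodeRule.matches`."""
    return rule.matches(code, scope_codes)


@dataclass
class CodeRegistry:
    """All code rules, grouped by purpose.

    Purposes: ``infection`` (the two-tier foot-infection phenotype),
    ``current_amputation`` (ICD-9 procedure 84.11-84.17),
    ``past_amputation`` (aftercare diagnoses V49.71-77/V52.1 plus CPT-4
    amputation/prosthesis codes), ``comorbidity`` (diabetes-complication
    sets) and ``treatment_cpt`` (vascular imaging, debridement, I&D).
    """

    rules: dict[str, tuple[DiagnosisCodeRule, ...]]
    source: Optional[str] = None

    def rules_for(self, purpose: str) -> tuple[DiagnosisCodeRule, ...]:
        return self.rules.get(purpose, ())

    def infection_rules(
        self, tier: Optional[Specificity] = None
    ) -> tuple[DiagnosisCodeRule, ...]:
        rules = self.rules_for(PURPOSE_INFECTION)
        if tier is None:
            return rules
        return tuple(r for r in rules if r.specificity is tier)

    def comorbidity_conditions(self) -> tuple[str, ...]:
        """Distinct comorbidity labels, in table order."""
        seen: list[str] = []
        for r in self.rules_for(PURPOSE_COMORBIDITY):
            if r.category not in seen:
                seen.append(r.category)
        return tuple(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodeRegistry):
            return NotImplemented
        return {k: set(v) for k, v in self.rules.items()} == {
            k: set(v) for k, v in other.rules.items()
        }


def categories_present(
    scope_codes: Iterable[str],
    registry: CodeRegistry,
    tier: Optional[Specificity] = None,
) -> set[InfectionCategory]:
    """Infection categories with at least one matching rule of the given tier.

    ``scope_codes`` must already be normalized; the whole set is the
    companion scope for conditional rules.
    """
    scope = frozenset(scope_codes)
    out: set[InfectionCategory] = set()
    for rule in registry.infection_rules(tier):
        cat = rule.infection_category
        if cat in out:
            continue
        if any(rule.matches(c, scope) for c in scope):
            out.add(cat)
    return out


# ---------------------------------------------------------------------------
# loading / writing code tables

_TABLE_COLUMNS = [
    "pattern",
    "system",
    "match_mode",
    "category",
    "specificity",
    "purpose",
    "condition_group",
]
_COND_COLUMNS = ["condition_group", "pattern", "system", "match_mode"]


def default_table_paths() -> tuple[Path, Path]:
    """Paths of the shipped default code tables (codes, condition groups)."""
    data = resources.files("dfi") / "data"
    return Path(str(data / "codes.csv")), Path(str(data / "condition_groups.csv"))


def _parse_enum(enum_cls, value: str, context: str):
    try:
        return enum_cls(str(value).strip())
    except ValueError:
        raise RegistryError(
            f"unknown {enum_cls.__name__} {value!r} in {context}"
        ) from None


def load_registry(
    codes_path: Optional[Path | str] = None,
    condition_groups_path: Optional[Path | str] = None,
) -> CodeRegistry:
    """Load a :class:`CodeRegistry` from CSV code tables.

    With no arguments, loads the shipped defaults.  The main table has
    columns ``pattern,system,match_mode,category,specificity,purpose,
    condition_group``; companion-condition groups live in a second CSV
    ``condition_group,pattern,system,match_mode``.  ``#`` lines are
    comments.

    Raises
    ------
    RegistryError
        On duplicate (pattern, system, purpose) rows, unknown enum
        labels, unresolvable condition groups, an empty infection tier,
        or infection rules whose category is not one of the six ranked
        categories.
    """
    if codes_path is None or condition_groups_path is None:
        d_codes, d_cond = default_table_paths()
        codes_path = codes_path or d_codes
        condition_groups_path = condition_groups_path or d_cond

    codes_df = pd.read_csv(codes_path, comment="#", dtype=str, keep_default_na=False)
    cond_df = pd.read_csv(
        condition_groups_path, comment="#", dtype=str, keep_default_na=False
    )
    for col in _TABLE_COLUMNS:
        if col not in codes_df.columns:
            raise RegistryError(f"code table missing column {col!r}")
    for col in _COND_COLUMNS:
        if col not in cond_df.columns:
            raise RegistryError(f"condition-group table missing column {col!r}")

    groups: dict[str, list[DiagnosisCodeRule]] = {}
    for _, row in cond_df.iterrows():
        rule = DiagnosisCodeRule(
            pattern=normalize_code(row["pattern"]),
            system=_parse_enum(CodingSystem, row["system"], "condition groups"),
            match_mode=_parse_enum(MatchMode, row["match_mode"], "condition groups"),
            category="CONDITION",
        )
        groups.setdefault(str(row["condition_group"]).strip(), []).append(rule)

    rules: dict[str, list[DiagnosisCodeRule]] = {p: [] for p in PURPOSES}
    seen: set[tuple[str, CodingSystem, str]] = set()
    for idx, row in codes_df.iterrows():
        purpose = str(row["purpose"]).strip()
        if purpose not in PURPOSES:
            raise RegistryError(f"unknown purpose {purpose!r} (row {idx})")
        system = _parse_enum(CodingSystem, row["system"], f"row {idx}")
        pattern = normalize_code(row["pattern"])
        key = (pattern, system, purpose)
        if key in seen:
            raise RegistryError(
                f"duplicate rule for pattern {pattern!r}, system {system.value}, "
                f"purpose {purpose!r}"
            )
        seen.add(key)
        category = str(row["category"]).strip()
        specificity = _parse_enum(Specificity, row["specificity"] or "NA", f"row {idx}")
        if purpose == PURPOSE_INFECTION:
            cat_enum = _parse_enum(InfectionCategory, category, f"row {idx}")
            if cat_enum.severity_rank is None:
                raise RegistryError(
                    f"infection rule {pattern!r} has unranked category {category!r}"
                )
            if specificity is Specificity.NA:
                raise RegistryError(
                    f"infection rule {pattern!r} must be SPECIFIC or MODERATE"
                )
        cond_name = str(row["condition_group"]).strip()
        condition: tuple[DiagnosisCodeRule, ...] = ()
        if cond_name:
            if cond_name not in groups:
                raise RegistryError(f"undefined condition group {cond_name!r}")
            condition = tuple(groups[cond_name])
        rules[purpose].append(
            DiagnosisCodeRule(
                pattern=pattern,
                system=system,
                match_mode=_parse_enum(MatchMode, row["match_mode"], f"row {idx}"),
                category=category,
                specificity=specificity,
                condition=condition,
            )
        )

    if not any(
        r.specificity is Specificity.SPECIFIC for r in rules[PURPOSE_INFECTION]
    ):
        raise RegistryError("code table defines no SPECIFIC infection rules")

    return CodeRegistry(
        rules={p: tuple(v) for p, v in rules.items()}, source=str(codes_path)
    )


def write_registry(
    registry: CodeRegistry, codes_path: Path | str, condition_groups_path: Path | str
) -> None:
    """Write a registry back to the two-CSV code-table format (round-trips)."""
    rows = []
    cond_rows = []
    cond_names: dict[tuple[DiagnosisCodeRule, ...], str] = {}
    for purpose in PURPOSES:
        for r in registry.rules_for(purpose):
            cond_name = ""
            if r.condition:
                if r.condition not in cond_names:
                    cond_names[r.condition] = f"group_{len(cond_names) + 1}"
                    for c in r.condition:
                        cond_rows.append(
                            {
                                "condition_group": cond_names[r.condition],
                                "pattern": c.pattern,
                                "system": c.system.value,
                                "match_mode": c.match_mode.value,
                            }
                        )
                cond_name = cond_names[r.condition]
            rows.append(
                {
                    "pattern": r.pattern,
                    "system": r.system.value,
                    "match_mode": r.match_mode.value,
                    "category": r.category,
                    "specificity": r.specificity.value,
                    "purpose": purpose,
                    "condition_group": cond_name,
                }
            )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(codes_path, index=False)
    pd.DataFrame(cond_rows, columns=_COND_COLUMNS).to_csv(
        condition_groups_path, index=False
    )
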