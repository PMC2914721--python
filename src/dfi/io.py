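"""Claims bundle: the seven-table input schema, validation, and CSV round-trip.

A :class:`ClaimsBundle` is the canonical in-memory container for one
administrative-claims extract: patients, inpatient stays with positioned
diagnoses and ICD-9 procedures, and outpatient visits with diagnoses and
CPT-4 procedures.  CSV is the interchange format (claims data has no
binary community standard); all dates are ISO-8601 and all codes are
stored normalized (decimal point removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["ClaimsBundle", "BundleValidationError", "read_bundle", "write_bundle", "SCHEMAS"]

# table name -> (required columns, date columns)
SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    "patients": (
        ["patient_id", "sex", "birth_date", "race", "death_date"],
        ["birth_date", "death_date"],
    ),
    "stays": (
        ["stay_id", "patient_id", "admit_date", "discharge_date", "care_setting"],
        ["admit_date", "discharge_date"],
    ),
    "stay_dx": (["stay_id", "position", "icd9_code"], []),
    "stay_proc": (["stay_id", "icd9_proc_code"], []),
    "visits": (
        ["visit_id", "patient_id", "visit_date", "care_setting"],
        ["visit_date"],
    ),
    "visit_dx": (["visit_id", "position", "icd9_code"], []),
    "visit_proc": (["visit_id", "cpt_code"], []),
}

_SORT_KEYS: dict[str, list[str]] = {
    "patients": ["patient_id"],
    "stays": ["stay_id"],
    "stay_dx": ["stay_id", "position", "icd9_code"],
    "stay_proc": ["stay_id", "icd9_proc_code"],
    "visits": ["visit_id"],
    "visit_dx": ["visit_id", "position", "icd9_code"],
    "visit_proc": ["visit_id", "cpt_code"],
}

_CODE_COLUMNS = {"icd9_code", "icd9_proc_code", "cpt_code"}


class BundleValidationError(ValueError):
    """Schema or referential-integrity failure; carries every violation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "claims bundle validation failed:\n  " + "\n  ".join(violations)
        )


@dataclass
class ClaimsBundle:
    patients: pd.DataFrame
    stays: pd.DataFrame
    stay_dx: pd.DataFrame
    stay_proc: pd.DataFrame
    visits: pd.DataFrame
    visit_dx: pd.DataFrame
    visit_proc: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @classmethod
    def empty(cls) -> "ClaimsBundle":
        tables = {}
        for name, (cols, datecols) in SCHEMAS.items():
            df = pd.DataFrame(columns=cols)
            for c in datecols:
                df[c] = pd.to_datetime(df[c])
            tables[name] = df
        return cls(**tables)

    def sorted(self) -> "ClaimsBundle":
        """Copy with rows in canonical order (for determinism checks)."""
        tables = {
            name: self.table(name)
            .sort_values(_SORT_KEYS[name], kind="mergesort")
            .reset_index(drop=True)
            for name in SCHEMAS
        }
        return ClaimsBundle(**tables, provenance=dict(self.provenance))

    def equals(self, other: "ClaimsBundle") -> bool:
        a, b = self.sorted(), other.sorted()
        return all(a.table(n).equals(b.table(n)) for n in SCHEMAS)

    def validate(self) -> None:
        """Raise :class:`BundleValidationError` listing every violation."""
        problems: list[str] = []
        for name, (cols, datecols) in SCHEMAS.items():
            df = self.table(name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                problems.append(f"{name}: missing columns {missing}")
                continue
            for c in datecols:
                if not pd.api.types.is_datetime64_any_dtype(df[c]):
                    problems.append(f"{name}.{c}: not parsed as dates")
        if problems:
            raise BundleValidationError(problems)

        def orphan(child: str, col: str, parent: str, pcol: str) -> None:
            cdf, pdf = self.table(child), self.table(parent)
            if cdf.empty:
                return
            bad = ~cdf[col].isin(set(pdf[pcol]))
            for idx in cdf.index[bad]:
                problems.append(
                    f"{child} row {idx}: {col}={cdf.at[idx, col]!r} not in {parent}"
                )

        orphan("stays", "patient_id", "patients", "patient_id")
        orphan("stay_dx", "stay_id", "stays", "stay_id")
        orphan("stay_proc", "stay_id", "stays", "stay_id")
        orphan("visits", "patient_id", "patients", "patient_id")
        orphan("visit_dx", "visit_id", "visits", "visit_id")
        orphan("visit_proc", "visit_id", "visits", "visit_id")

        bad_dates = self.stays["discharge_date"] < self.stays["admit_date"]
        for idx in self.stays.index[bad_dates.fillna(False)]:
            problems.append(f"stays row {idx}: discharge_date before admit_date")

        if problems:
            raise BundleValidationError(problems)


def read_bundle(directory: Path | str) -> ClaimsBundle:
    """Read and validate a claims bundle from a directory of CSV files.

    Raises
    ------
    BundleValidationError
        Listing every missing file, unparseable date, orphan row and
        schema violation found.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    problems: list[str] = []
    for name, (cols, datecols) in SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            problems.append(f"missing file: {path.name}")
            continue
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            problems.append(f"{name}.csv: missing columns {missing}")
            continue
        for c in datecols:
            raw = df[c].replace("", pd.NA)
            parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
            bad = raw.notna() & parsed.isna()
            for idx in df.index[bad]:
                problems.append(
                    f"{name}.csv row {idx}: unparseable date {df.at[idx, c]!r} in {c}"
                )
            df[c] = parsed
        if "position" in df.columns:
            df["position"] = pd.to_numeric(df["position"], errors="coerce").astype(
                "Int64"
            )
        tables[name] = df
    if problems:
        raise BundleValidationError(problems)
    bundle = ClaimsBundle(
        **tables,
        provenance={
            "directory": str(directory),
            "row_counts": {n: len(t) for n, t in tables.items()},
            "schema_version": 1,
        },
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: ClaimsBundle, directory: Path | str) -> None:
    """Write a bundle to CSV files in canonical row order (round-trips)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    b = bundle.sorted()
    for name, (cols, datecols) in SCHEMAS.items():
        df = b.table(name).copy()
        for c in datecols:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
            df[c] = df[c].fillna("")
        df[cols].to_csv(directory / f"{name}.csv", index=False)
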