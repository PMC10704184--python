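"""Patient records, stratum keys, and batch CSV input/output."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scheme import CategoryScheme, VocabularyError, categorize_age


class ValidationError(ValueError):
    """Raised for records that violate the metadata contract."""


#: Scheme variable name -> PatientRecord attribute holding the raw value.
_VARIABLE_FIELDS = {
    "race": "race",
    "sex_at_birth": "sex_at_birth",
    "ethnicity": "ethnicity",
    "covid_status": "covid_status",
    "site": "site_id",
}

#: Required columns of the batch CSV dialect; ``modalities`` is ``;``-separated.
BATCH_COLUMNS = (
    "patient_id", "age", "race", "sex_at_birth", "ethnicity", "covid_status", "modalities",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographic and modality metadata within an intake batch.

    ``None`` marks a missing demographic value; the modality set must be
    non-empty (a patient with no images has nothing to sequester).
    """

    patient_id: str
    age_years: float | None
    race: str | None
    sex_at_birth: str | None
    ethnicity: str | None
    covid_status: str | None
    modalities: frozenset[str]
    site_id: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id or not str(self.patient_id).strip():
            raise ValidationError("patient_id must be non-empty")
        object.__setattr__(self, "modalities", frozenset(self.modalities))
        if not self.modalities:
            raise ValidationError(f"patient {self.patient_id!r} has an empty modality set")
        age = self.age_years
        if age is not None:
            if isinstance(age, float) and math.isnan(age):
                object.__setattr__(self, "age_years", None)
            elif not (0 <= float(age) < 140):
                raise ValidationError(
                    f"patient {self.patient_id!r} has age {age} outside [0, 140)"
                )


@dataclass(frozen=True)
class StratumKey:
    """One category per scheme variable, in scheme order.

    Two patients belong to the same stratum exactly when their keys compare
    equal; keys are hashable and usable directly as grouping keys.
    """

    variables: tuple[str, ...]
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.variables) != len(self.values):
            raise ValidationError("stratum key variables/values length mismatch")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.variables, self.values))

    def content(self) -> tuple[tuple[str, str], ...]:
        """Order-independent identity: (variable, category) pairs sorted by variable."""
        return tuple(sorted(zip(self.variables, self.values)))

    def __str__(self) -> str:  # compact CSV-friendly form
        return "|".join(self.values)


def normalize_record(
    raw: PatientRecord, scheme: CategoryScheme, primary_modality: str
) -> StratumKey:
    """Categorize a raw record into its stratum key under ``scheme``.

    Blank demographic values map to the scheme's missing label; non-blank
    values are matched case-insensitively after trimming.  The caller supplies
    the patient's primary modality (see
    :func:`stratseq.engine.resolve_primary_modality`), which must be one of
    the patient's own modalities.
    """
    if primary_modality not in raw.modalities:
        raise ValidationError(
            f"primary modality {primary_modality!r} not among patient "
            f"{raw.patient_id!r} modalities {sorted(raw.modalities)}"
        )
    values: list[str] = []
    for name in scheme.variable_names:
        try:
            if name == "age_group":
                values.append(categorize_age(raw.age_years, scheme))
            elif name == "modality":
                values.append(scheme.normalize_value("modality", primary_modality))
            elif name in _VARIABLE_FIELDS:
                values.append(scheme.normalize_value(name, getattr(raw, _VARIABLE_FIELDS[name])))
            else:
                raise ValidationError(
                    f"scheme variable {name!r} has no corresponding patient field"
                )
        except VocabularyError as exc:
            raise VocabularyError(f"patient {raw.patient_id!r}: {exc}") from None
    return StratumKey(variables=scheme.variable_names, values=tuple(values))


# -- batch CSV dialect -------------------------------------------------------


def _cell(value: object) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_batch_csv(path: str | Path) -> list[PatientRecord]:
    """Read a patient metadata batch.

    Required columns: ``patient_id, age, race, sex_at_birth, ethnicity,
    covid_status, modalities`` (``modalities`` is a ``;``-separated list).
    Blank cells are missing values.  An optional ``site_id`` column is
    carried through.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in BATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"batch file {path} is missing required column(s): {', '.join(missing)}"
        )
    has_site = "site_id" in df.columns
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        age_raw = _cell(row.age)
        try:
            age = float(age_raw) if age_raw is not None else None
        except ValueError:
            raise ValidationError(
                f"{path} line {i}: age {age_raw!r} is not a number"
            ) from None
        mods = frozenset(m.strip() for m in str(row.modalities).split(";") if m.strip())
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id).strip(),
                    age_years=age,
                    race=_cell(row.race),
                    sex_at_birth=_cell(row.sex_at_birth),
                    ethnicity=_cell(row.ethnicity),
                    covid_status=_cell(row.covid_status),
                    modalities=mods,
                    site_id=_cell(row.site_id) if has_site else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from None
    return records


def write_batch_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records in the batch CSV dialect (lossless round-trip)."""
    rows = []
    any_site = any(r.site_id for r in records)
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age": "" if r.age_years is None else _format_age(r.age_years),
            "race": r.race or "",
            "sex_at_birth": r.sex_at_birth or "",
            "ethnicity": r.ethnicity or "",
            "covid_status": r.covid_status or "",
            "modalities": ";".join(sorted(r.modalities)),
        }
        if any_site:
            row["site_id"] = r.site_id or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _format_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else f"{age:.6g}"
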