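"""Category schemes for multi-variable stratification.

A :class:`CategoryScheme` fixes the ordered list of stratification variables
and, for each variable, the closed vocabulary of category labels.  The default
scheme covers six variables — age group, race, sex at birth, ethnicity,
COVID-19 status and primary image modality — with 9, 7, 4, 3, 3 and 4
categories respectively (9072 strata in total).  Age is binned into the CDC
COVID-19 surveillance age groups; race, sex and ethnicity follow the NIH
reporting categories; blank demographic entries map to a dedicated
"Not reported" category so that missingness itself is balanced.
"""

from __future__ import annotations

import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class SchemeError(ValueError):
    """Raised for invalid scheme definitions."""


class VocabularyError(SchemeError):
    """Raised when a non-blank raw value is not in a variable's vocabulary."""


class AgeRangeError(SchemeError):
    """Raised for an age outside the supported [0, 140) range."""


MISSING_LABEL = "Not reported"

#: Age bin edges (years); bins are half-open [lo, hi) and cover [0, 140).
AGE_BIN_EDGES: tuple[float, ...] = (0.0, 18.0, 30.0, 40.0, 50.0, 65.0, 75.0, 85.0, 140.0)

RACE_LABELS = (
    "American Indian or Alaska Native",
    "Asian",
    "Black or African American",
    "Native Hawaiian or other Pacific Islander",
    "White",
    MISSING_LABEL,
    "Other",
)
SEX_LABELS = ("Female", "Male", "Other", MISSING_LABEL)
ETHNICITY_LABELS = ("Hispanic or Latino", "Not Hispanic or Latino", MISSING_LABEL)
COVID_LABELS = ("No", MISSING_LABEL, "Yes")
MODALITY_LABELS = ("CR", "CT", "DX", "MR")

#: Variables that do not carry a missing-value category.  A patient with no
#: recorded modality is a validation error, not a stratum.
_NO_MISSING = frozenset({"modality", "site"})


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def age_bin_label(lo: float, hi: float) -> str:
    """Render an age bin in interval notation, e.g. ``[50, 65)``."""
    return f"[{_format_number(lo)}, {_format_number(hi)})"


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered stratification variables and their category vocabularies.

    Parameters
    ----------
    variables
        Ordered ``(variable_name, category_labels)`` pairs.  Stratum keys list
        one category per variable in this order.
    age_bins
        Half-open ``[lo, hi)`` intervals; must be contiguous and cover
        ``[0, 140)``.  The ``age_group`` variable's labels are these bins in
        interval notation plus the missing label.
    missing_label
        Category used for blank or absent demographic values.
    open_fraction
        Target fraction of each stratum assigned to the open commons.
    """

    variables: tuple[tuple[str, tuple[str, ...]], ...]
    age_bins: tuple[tuple[float, float], ...]
    missing_label: str = MISSING_LABEL
    open_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.variables:
            raise SchemeError("scheme must define at least one variable")
        if not (0.0 < self.open_fraction < 1.0):
            raise SchemeError(f"open_fraction must be in (0, 1), got {self.open_fraction}")
        names = [name for name, _ in self.variables]
        if len(set(names)) != len(names):
            raise SchemeError(f"duplicate variable names in scheme: {names}")
        for name, cats in self.variables:
            if not cats:
                raise SchemeError(f"variable {name!r} has no categories")
            if len(set(cats)) != len(cats):
                raise SchemeError(f"variable {name!r} has duplicate categories")
            if name not in _NO_MISSING and self.missing_label not in cats:
                raise SchemeError(
                    f"variable {name!r} must include the missing-value category "
                    f"{self.missing_label!r}"
                )
        # Age bins: contiguous, non-overlapping, covering [0, 140).
        if "age_group" in names:
            if not self.age_bins:
                raise SchemeError("scheme with an age_group variable needs age_bins")
            lo0 = self.age_bins[0][0]
            hi_last = self.age_bins[-1][1]
            if lo0 != 0.0 or hi_last != 140.0:
                raise SchemeError("age bins must cover [0, 140)")
            for (lo, hi), (lo2, _) in zip(self.age_bins, self.age_bins[1:]):
                if hi != lo2:
                    raise SchemeError(f"age bins not contiguous at {hi} vs {lo2}")
            for lo, hi in self.age_bins:
                if not lo < hi:
                    raise SchemeError(f"empty age bin [{lo}, {hi})")
            expected = tuple(age_bin_label(lo, hi) for lo, hi in self.age_bins)
            actual = self.categories("age_group")
            if tuple(actual[: len(expected)]) != expected:
                raise SchemeError(
                    "age_group categories must list the age bins in interval "
                    f"notation: expected {expected}, got {actual}"
                )

    # -- lookup helpers -----------------------------------------------------

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.variables)

    def categories(self, variable: str) -> tuple[str, ...]:
        for name, cats in self.variables:
            if name == variable:
                return cats
        raise KeyError(f"no variable {variable!r} in scheme")

    def normalize_value(self, variable: str, raw: object) -> str:
        """Map a raw metadata value onto the variable's vocabulary.

        Blank / absent values (``None``, ``NaN``, empty or whitespace string)
        map to the missing label.  Non-blank values are matched
        case-insensitively after trimming whitespace; anything that does not
        match is a :class:`VocabularyError` — silent coercion would corrupt
        the balance bookkeeping.
        """
        if raw is None:
            value = ""
        elif isinstance(raw, float) and math.isnan(raw):
            value = ""
        else:
            value = str(raw).strip()
        if not value:
            if variable in _NO_MISSING:
                raise VocabularyError(f"variable {variable!r} does not allow blank values")
            return self.missing_label
        lookup = {c.strip().casefold(): c for c in self.categories(variable)}
        try:
            return lookup[value.casefold()]
        except KeyError:
            raise VocabularyError(
                f"value {value!r} is not a recognised category of {variable!r}; "
                f"expected one of {list(self.categories(variable))}"
            ) from None

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [[name, list(cats)] for name, cats in self.variables],
            "age_bins": [list(b) for b in self.age_bins],
            "missing_label": self.missing_label,
            "open_fraction": self.open_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CategoryScheme":
        return cls(
            variables=tuple((name, tuple(cats)) for name, cats in d["variables"]),
            age_bins=tuple(tuple(b) for b in d.get("age_bins", ())),
            missing_label=d.get("missing_label", MISSING_LABEL),
            open_fraction=d.get("open_fraction", 0.8),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoryScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_scheme(
    open_fraction: float = 0.8,
    include_site: bool = False,
    site_labels: Sequence[str] = (),
) -> CategoryScheme:
    """The default six-variable scheme (9 × 7 × 4 × 3 × 3 × 4 = 9072 strata).

    ``include_site`` prepends an optional clinical-site variable; it is off by
    default because single-site batches carry no site information to balance.
    """
    age_bins = tuple(zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:]))
    age_labels = tuple(age_bin_label(lo, hi) for lo, hi in age_bins) + (MISSING_LABEL,)
    variables: list[tuple[str, tuple[str, ...]]] = [
        ("age_group", age_labels),
        ("race", RACE_LABELS),
        ("sex_at_birth", SEX_LABELS),
        ("ethnicity", ETHNICITY_LABELS),
        ("covid_status", COVID_LABELS),
        ("modality", MODALITY_LABELS),
    ]
    if include_site:
        if not site_labels:
            raise SchemeError("include_site=True requires site_labels")
        variables.insert(0, ("site", tuple(site_labels)))
    return CategoryScheme(variables=tuple(variables), age_bins=age_bins,
                          open_fraction=open_fraction)


def load_scheme(source: str | Path) -> CategoryScheme:
    """Load a scheme from a JSON file, or by built-in name (``"default"``/``"table1"``)."""
    if str(source) in ("default", "table1"):
        return default_scheme()
    return CategoryScheme.from_json(source)


def categorize_age(age_years: float | None, scheme: CategoryScheme) -> str:
    """Bin an age in years into the scheme's half-open age groups.

    Missing ages (``None``/NaN) map to the missing label.  Ages outside
    ``[0, 140)`` raise :class:`AgeRangeError` — out-of-range ages indicate
    corrupt metadata and are never silently binned.
    """
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return scheme.missing_label
    age = float(age_years)
    lo = scheme.age_bins[0][0]
    hi = scheme.age_bins[-1][1]
    if not (lo <= age < hi):
        raise AgeRangeError(f"age {age} outside supported range [{lo}, {hi})")
    edges = [b[0] for b in scheme.age_bins]
    i = bisect_right(edges, age) - 1
    return age_bin_label(*scheme.age_bins[i])


def count_strata(scheme: CategoryScheme) -> int:
    """Total number of possible strata: the product of per-variable category counts."""
    total = 1
    for _, cats in scheme.variables:
        total *= len(cats)
    return total
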