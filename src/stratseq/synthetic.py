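"""Synthetic patient cohorts with configurable marginal demographics.

The default target reproduces the marginal category counts of a 5000-patient
single-site COVID-era intake batch (the reference cohort used throughout the
test suite): e.g. 2533 Female, 2397 COVID-positive, 17 American Indian or
Alaska Native, per-modality availability CR 2049 / CT 910 / DX 2596 / MR 27,
including "Not reported" rates and multi-modality patients.

Demographic variables are drawn independently by default (only the marginals
of the reference cohort are known); an optional conditional table lets users
impose pairwise dependence to probe sensitivity to joint structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import PatientRecord
from .scheme import MISSING_LABEL

#: Reference marginal counts for the 5000-patient demonstration cohort.
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "age_group": {
        "[0, 18)": 74,
        "[18, 30)": 393,
        "[30, 40)": 529,
        "[40, 50)": 687,
        "[50, 65)": 1434,
        "[65, 75)": 909,
        "[75, 85)": 597,
        "[85, 140)": 284,
        MISSING_LABEL: 93,
    },
    "race": {
        "American Indian or Alaska Native": 17,
        "Asian": 294,
        "Black or African American": 1386,
        "Native Hawaiian or other Pacific Islander": 15,
        "White": 2568,
        MISSING_LABEL: 554,
        "Other": 166,
    },
    "sex_at_birth": {
        "Female": 2533,
        "Male": 2464,
        "Other": 0,
        MISSING_LABEL: 3,
    },
    "ethnicity": {
        "Hispanic or Latino": 499,
        "Not Hispanic or Latino": 4443,
        MISSING_LABEL: 58,
    },
    "covid_status": {
        "No": 2602,
        MISSING_LABEL: 1,
        "Yes": 2397,
    },
}

#: Patient-level modality availability counts (multi-modality: do not sum to 5000).
TABLE1_MODALITY_COUNTS: dict[str, int] = {"CR": 2049, "CT": 910, "DX": 2596, "MR": 27}

TABLE1_N = 5000

#: Half-open [lo, hi) age intervals keyed by bin label, for drawing raw ages.
_AGE_BIN_RANGES = {
    "[0, 18)": (0.0, 18.0),
    "[18, 30)": (18.0, 30.0),
    "[30, 40)": (30.0, 40.0),
    "[40, 50)": (40.0, 50.0),
    "[50, 65)": (50.0, 65.0),
    "[65, 75)": (65.0, 75.0),
    "[75, 85)": (75.0, 85.0),
    "[85, 140)": (85.0, 140.0),
}

_RECORD_FIELDS = {
    "race": "race",
    "sex_at_birth": "sex_at_birth",
    "ethnicity": "ethnicity",
    "covid_status": "covid_status",
}


class CohortSpecError(ValueError):
    """Raised for inconsistent cohort specifications."""


@dataclass(frozen=True)
class CohortSpec:
    """Target marginal distributions for a synthetic cohort.

    ``demographic_probs`` maps variable -> {category label: probability}
    (each variable sums to 1).  ``modality_probs`` are per-modality inclusion
    probabilities; they need not sum to 1 because patients can hold several
    modalities.  ``conditional`` optionally maps a child variable to
    ``(parent_variable, {parent_label: {child_label: p}})`` for pairwise
    dependence; variables absent from it are drawn independently.
    """

    n_patients: int = TABLE1_N
    demographic_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            var: {c: n / TABLE1_N for c, n in counts.items()}
            for var, counts in TABLE1_COUNTS.items()
        }
    )
    modality_probs: Mapping[str, float] = field(
        default_factory=lambda: {m: n / TABLE1_N for m, n in TABLE1_MODALITY_COUNTS.items()}
    )
    conditional: Mapping[str, tuple[str, Mapping[str, Mapping[str, float]]]] | None = None
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise CohortSpecError("n_patients must be positive")
        for var, probs in self.demographic_probs.items():
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise CohortSpecError(
                    f"probabilities for {var!r} sum to {total}, expected 1"
                )
            if any(p < 0 for p in probs.values()):
                raise CohortSpecError(f"negative probability in {var!r}")
        if not self.modality_probs:
            raise CohortSpecError("at least one modality is required")
        for m, p in self.modality_probs.items():
            if not (0.0 < p <= 1.0):
                raise CohortSpecError(
                    f"modality inclusion probability for {m!r} must be in (0, 1], got {p}"
                )

    def target_counts(self) -> dict[str, dict[str, int]]:
        """Per-variable integral target counts (probability × n), validated integral."""
        out: dict[str, dict[str, int]] = {}
        for var, probs in self.demographic_probs.items():
            counts = {}
            for c, p in probs.items():
                x = p * self.n_patients
                if abs(x - round(x)) > 1e-6:
                    raise CohortSpecError(
                        f"target count for {var}={c!r} is non-integral ({x}); "
                        "exact-marginal generation needs integral counts"
                    )
                counts[c] = int(round(x))
            if sum(counts.values()) != self.n_patients:
                raise CohortSpecError(
                    f"target counts for {var!r} sum to {sum(counts.values())}, "
                    f"expected {self.n_patients}"
                )
            out[var] = counts
        return out

    def target_modality_counts(self) -> dict[str, int]:
        out = {}
        for m, p in self.modality_probs.items():
            x = p * self.n_patients
            if abs(x - round(x)) > 1e-6:
                raise CohortSpecError(f"modality count for {m!r} is non-integral ({x})")
            out[m] = int(round(x))
        return out


def table1_spec(n_patients: int = TABLE1_N, **kwargs) -> CohortSpec:
    """The default spec: reference-cohort marginals at the given size."""
    return CohortSpec(n_patients=n_patients, **kwargs)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _records_from_labels(
    labels: Mapping[str, np.ndarray],
    modality_matrix: np.ndarray,
    modality_names: Sequence[str],
    rng: np.random.Generator,
    id_prefix: str,
) -> list[PatientRecord]:
    n = modality_matrix.shape[0]
    ages = np.full(n, np.nan)
    age_labels = labels["age_group"]
    for lab, (lo, hi) in _AGE_BIN_RANGES.items():
        mask = age_labels == lab
        m = int(mask.sum())
        if m:
            ages[mask] = rng.uniform(lo, hi, size=m)
    width = max(5, len(str(n)))
    records = []
    for i in range(n):
        mods = frozenset(
            modality_names[j] for j in range(len(modality_names)) if modality_matrix[i, j]
        )
        fields = {
            attr: (None if labels[var][i] == MISSING_LABEL else str(labels[var][i]))
            for var, attr in _RECORD_FIELDS.items()
        }
        records.append(
            PatientRecord(
                patient_id=f"{id_prefix}-{i:0{width}d}",
                age_years=None if math.isnan(ages[i]) else float(ages[i]),
                modalities=mods,
                **fields,
            )
        )
    return records


def _repair_empty_modalities(
    matrix: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Give every patient ≥1 modality while preserving per-modality column sums.

    Each empty patient receives one modality transferred from a randomly
    chosen patient holding two or more, so column totals are untouched.
    Feasible whenever total inclusions ≥ number of patients.
    """
    if matrix.sum() < matrix.shape[0]:
        raise CohortSpecError(
            "exact modality counts sum to fewer than n_patients; every patient "
            "needs at least one modality"
        )
    empties = list(np.flatnonzero(matrix.sum(axis=1) == 0))
    rng.shuffle(empties)
    row_sums = matrix.sum(axis=1)
    for i in empties:
        donors = np.flatnonzero(row_sums >= 2)
        donor = int(donors[rng.integers(len(donors))])
        held = np.flatnonzero(matrix[donor])
        j = int(held[rng.integers(len(held))])
        matrix[donor, j] = False
        matrix[i, j] = True
        row_sums[donor] -= 1
        row_sums[i] += 1
    return matrix


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> list[PatientRecord]:
    """Draw a cohort with the spec's marginal probabilities.

    Demographic fields are sampled independently per variable (or via the
    conditional table when provided); ages are uniform within the sampled bin;
    modality sets come from independent per-modality inclusion, re-drawn until
    non-empty.  Fully reproducible from the seed.
    """
    rng = _as_rng(seed)
    n = spec.n_patients
    labels: dict[str, np.ndarray] = {}
    conditional = spec.conditional or {}
    # Independent variables first so conditional parents are available.
    order = [v for v in spec.demographic_probs if v not in conditional]
    order += [v for v in spec.demographic_probs if v in conditional]
    for var in order:
        if var in conditional:
            parent, table = conditional[var]
            if parent not in labels:
                raise CohortSpecError(
                    f"conditional parent {parent!r} of {var!r} is not a generated variable"
                )
            out = np.empty(n, dtype=object)
            for plab, dist in table.items():
                mask = labels[parent] == plab
                m = int(mask.sum())
                if m:
                    cats = list(dist)
                    p = np.array([dist[c] for c in cats], dtype=float)
                    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                        raise CohortSpecError(
                            f"conditional distribution of {var!r} given "
                            f"{parent}={plab!r} sums to {p.sum()}"
                        )
                    out[mask] = rng.choice(cats, size=m, p=p)
            if any(v is None for v in out):
                raise CohortSpecError(
                    f"conditional table for {var!r} does not cover all "
                    f"realized values of {parent!r}"
                )
            labels[var] = out.astype(str)
        else:
            probs = spec.demographic_probs[var]
            cats = list(probs)
            p = np.array([probs[c] for c in cats], dtype=float)
            labels[var] = rng.choice(cats, size=n, p=p.clip(0) / p.clip(0).sum())

    mod_names = list(spec.modality_probs)
    p_mod = np.array([spec.modality_probs[m] for m in mod_names])
    matrix = rng.random((n, len(mod_names))) < p_mod
    empty = np.flatnonzero(~matrix.any(axis=1))
    while empty.size:
        matrix[empty] = rng.random((empty.size, len(mod_names))) < p_mod
        empty = empty[~matrix[empty].any(axis=1)]
    return _records_from_labels(labels, matrix, mod_names, rng, spec.id_prefix)


def exact_marginal_cohort(
    spec: CohortSpec, seed: int | np.random.Generator | None = None
) -> list[PatientRecord]:
    """Build a cohort whose marginal counts match the spec's targets exactly.

    Each demographic variable's labels are laid out with exactly the target
    multiplicity and independently permuted; each modality is granted to
    exactly its target number of patients, with empty modality sets repaired
    by transfers from multi-modality patients (column totals preserved).
    Intended for fixtures that need reference counts verbatim.
    """
    rng = _as_rng(seed)
    n = spec.n_patients
    labels: dict[str, np.ndarray] = {}
    for var, counts in spec.target_counts().items():
        col = np.repeat(list(counts), list(counts.values()))
        rng.shuffle(col)
        labels[var] = col

    mod_names = list(spec.modality_probs)
    mod_counts = spec.target_modality_counts()
    matrix = np.zeros((n, len(mod_names)), dtype=bool)
    for j, m in enumerate(mod_names):
        chosen = rng.permutation(n)[: mod_counts[m]]
        matrix[chosen, j] = True
    matrix = _repair_empty_modalities(matrix, rng)
    return _records_from_labels(labels, matrix, mod_names, rng, spec.id_prefix)
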