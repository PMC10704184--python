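"""The sequestration engine.

Incoming patients are first checked against the assignment registry (a patient
seen in an earlier batch keeps its arm), the remainder are grouped into strata
— one stratum per unique combination of categorized variables — and each
stratum is split at random into ~80% open and ~20% sequestered.

Counting rule.  A stratum of size ``m`` sends ``floor(f*m) + Bernoulli(frac(f*m))``
patients to the open arm, so the expected open fraction equals ``f`` for every
stratum size, including singletons.  A deterministic round would systematically
over-assign small strata.

RNG discipline.  ``sequester_batch`` derives one independent substream per
stratum, keyed by the stratum's *content* (the sorted (variable, category)
pairs) together with the master seed.  Assignments are therefore reproducible
and invariant to patient order and to the order of scheme variables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import PatientRecord, StratumKey, ValidationError, normalize_record
from .registry import AssignmentRegistry
from .scheme import CategoryScheme

logger = logging.getLogger(__name__)

SOURCE_CARRYOVER = "registry_carryover"
SOURCE_NEW = "new_split"


@dataclass(frozen=True)
class Assignment:
    patient_id: str
    arm: str
    stratum: StratumKey | None
    source: str


@dataclass(frozen=True)
class BatchAssignment:
    """The outcome of splitting one intake batch: one row per patient."""

    assignments: tuple[Assignment, ...]
    batch_label: str
    seed: int | None
    open_fraction: float

    @property
    def open_ids(self) -> list[str]:
        return [a.patient_id for a in self.assignments if a.arm == "open"]

    @property
    def sequestered_ids(self) -> list[str]:
        return [a.patient_id for a in self.assignments if a.arm == "sequestered"]

    def arm_of(self, patient_id: str) -> str:
        for a in self.assignments:
            if a.patient_id == patient_id:
                return a.arm
        raise KeyError(patient_id)

    def realized_open_fraction(self) -> float:
        return len(self.open_ids) / len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [a.patient_id for a in self.assignments],
                "arm": [a.arm for a in self.assignments],
                "stratum": ["" if a.stratum is None else str(a.stratum)
                            for a in self.assignments],
                "source": [a.source for a in self.assignments],
            }
        )


def resolve_primary_modality(batch: Sequence[PatientRecord]) -> dict[str, str]:
    """Assign each patient a single "primary" modality for stratification.

    A modality's prevalence is the number of patients in the batch possessing
    it; a multi-modality patient's primary is their possessed modality of
    highest batch prevalence, so the patient is stratified once and any less
    prevalent modalities ride along.  Prevalence ties break by lexicographic
    modality code.
    """
    if not batch:
        raise ValidationError("cannot resolve modalities for an empty batch")
    prevalence: dict[str, int] = {}
    for p in batch:
        for m in p.modalities:
            prevalence[m] = prevalence.get(m, 0) + 1
    return {
        p.patient_id: min(p.modalities, key=lambda m: (-prevalence[m], m))
        for p in batch
    }


def split_stratum(
    members: Sequence[str], open_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Randomly split one stratum into (open, sequestered) member lists.

    Of ``m`` members, ``floor(f*m) + Bernoulli(frac(f*m))`` go to the open arm,
    selected uniformly without replacement; the two lists partition ``members``.
    """
    if not members:
        raise ValidationError("cannot split an empty stratum")
    if not (0.0 < open_fraction < 1.0):
        raise ValidationError(f"open_fraction must be in (0, 1), got {open_fraction}")
    m = len(members)
    x = open_fraction * m
    k = int(math.floor(x))
    frac = x - k
    if frac > 0 and rng.random() < frac:
        k += 1
    perm = rng.permutation(m)
    open_members = [members[i] for i in sorted(perm[:k])]
    seq_members = [members[i] for i in sorted(perm[k:])]
    return open_members, seq_members


def _stratum_rng(seed: int, key: StratumKey) -> np.random.Generator:
    """Independent substream keyed by (master seed, stratum content)."""
    payload = json.dumps([int(seed), key.content()], separators=(",", ":")).encode()
    digest = hashlib.sha256(payload).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(w) for w in words]))


def stratify_batch(
    batch: Sequence[PatientRecord], scheme: CategoryScheme
) -> dict[str, StratumKey]:
    """Map patient_id -> stratum key (primary-modality resolution + normalization)."""
    primaries = resolve_primary_modality(batch)
    return {
        p.patient_id: normalize_record(p, scheme, primaries[p.patient_id])
        for p in batch
    }


def sequester_batch(
    batch: Sequence[PatientRecord],
    registry: AssignmentRegistry,
    scheme: CategoryScheme,
    seed: int,
    batch_label: str = "batch",
    open_fraction: float | None = None,
    timestamp: str | None = None,
) -> BatchAssignment:
    """Assign every patient in an intake batch to the open or sequestered commons.

    Patients already in the registry keep their recorded arm
    (``registry_carryover``); the remainder are grouped by stratum and split
    with :func:`split_stratum`.  The registry is extended in place with the
    new assignments.  Identical (batch, registry, scheme, seed) reproduce the
    identical assignment.
    """
    of = scheme.open_fraction if open_fraction is None else open_fraction
    ids = [p.patient_id for p in batch]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), set()
        for pid in ids:
            (dupes if pid in seen else seen).add(pid)
        raise ValidationError(f"duplicate patient_id(s) within batch: {sorted(dupes)}")

    keys = stratify_batch(batch, scheme)
    carryover: dict[str, str] = {}
    groups: dict[StratumKey, list[str]] = {}
    for p in batch:
        if p.patient_id in registry:
            carryover[p.patient_id] = registry.arm_of(p.patient_id)
        else:
            groups.setdefault(keys[p.patient_id], []).append(p.patient_id)

    new_arm: dict[str, str] = {}
    for key in sorted(groups, key=lambda k: k.content()):
        members = sorted(groups[key])
        rng = _stratum_rng(seed, key)
        open_members, seq_members = split_stratum(members, of, rng)
        for pid in open_members:
            new_arm[pid] = "open"
        for pid in seq_members:
            new_arm[pid] = "sequestered"

    registry.record_many(new_arm, batch_label=batch_label, timestamp=timestamp)

    assignments = tuple(
        Assignment(
            patient_id=p.patient_id,
            arm=carryover.get(p.patient_id, new_arm.get(p.patient_id, "")),
            stratum=keys[p.patient_id],
            source=SOURCE_CARRYOVER if p.patient_id in carryover else SOURCE_NEW,
        )
        for p in batch
    )
    result = BatchAssignment(assignments, batch_label, int(seed), of)
    logger.info(
        "batch %s: %d patients, %d carryover, %d strata instantiated, "
        "realized open fraction %.4f",
        batch_label, len(batch), len(carryover), len(groups),
        result.realized_open_fraction(),
    )
    return result


def naive_split(
    batch: Sequence[PatientRecord],
    open_fraction: float,
    rng: np.random.Generator | int,
    batch_label: str = "batch",
) -> BatchAssignment:
    """Baseline: the whole batch as a single stratum, no registry interaction.

    Uses the same counting rule as :func:`split_stratum`, so the stratified and
    naive samplers differ only in stratification.  Evaluation-only.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    members = sorted(p.patient_id for p in batch)
    open_members, _ = split_stratum(members, open_fraction, rng)
    open_set = set(open_members)
    assignments = tuple(
        Assignment(
            patient_id=p.patient_id,
            arm="open" if p.patient_id in open_set else "sequestered",
            stratum=None,
            source=SOURCE_NEW,
        )
        for p in batch
    )
    return BatchAssignment(assignments, batch_label, None, open_fraction)
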