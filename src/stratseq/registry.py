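"""Persistent assignment registry: patient ID -> arm, across intake batches.

The registry is what makes sequestration longitudinal: a patient assigned to
one commons stays there in every later batch, so all images from longitudinal
studies of that patient live in exactly one commons.  Arms are immutable once
recorded.  The on-disk form is an append-friendly CSV written atomically
(write-temp-then-rename) so a crashed run never half-records a batch.
"""

from __future__ import annotations

import csv
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Mapping

ARMS = ("open", "sequestered")

_FIELDS = ("patient_id", "arm", "batch_label", "timestamp")


class RegistryError(ValueError):
    """Raised on arm conflicts or malformed registry files."""


@dataclass(frozen=True)
class RegistryEntry:
    arm: str
    batch_label: str
    timestamp: str


@dataclass
class AssignmentRegistry:
    """Map patient_id -> (arm, batch label, ISO timestamp)."""

    _entries: dict[str, RegistryEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def arm_of(self, patient_id: str) -> str:
        return self._entries[patient_id].arm

    def entry(self, patient_id: str) -> RegistryEntry:
        return self._entries[patient_id]

    def record(
        self,
        patient_id: str,
        arm: str,
        batch_label: str = "",
        timestamp: str | None = None,
    ) -> None:
        """Record an assignment; re-recording with a different arm is an error."""
        if arm not in ARMS:
            raise RegistryError(f"unknown arm {arm!r}; expected one of {ARMS}")
        existing = self._entries.get(patient_id)
        if existing is not None:
            if existing.arm != arm:
                raise RegistryError(
                    f"patient {patient_id!r} already assigned to "
                    f"{existing.arm!r}; arms are immutable"
                )
            return  # idempotent re-record keeps original provenance
        if timestamp is None:
            timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self._entries[patient_id] = RegistryEntry(arm, batch_label, timestamp)

    def record_many(
        self, assignments: Mapping[str, str] | Iterable[tuple[str, str]],
        batch_label: str = "", timestamp: str | None = None,
    ) -> None:
        items = assignments.items() if isinstance(assignments, Mapping) else assignments
        for pid, arm in items:
            self.record(pid, arm, batch_label, timestamp)

    # -- persistence ---------------------------------------------------------

    @classmethod
    def load(cls, path: str | Path) -> "AssignmentRegistry":
        reg = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not set(_FIELDS) <= set(reader.fieldnames):
                raise RegistryError(
                    f"registry {path} must have columns {', '.join(_FIELDS)}"
                )
            for row in reader:
                reg.record(row["patient_id"], row["arm"], row["batch_label"],
                           row["timestamp"])
        return reg

    def save(self, path: str | Path) -> None:
        """Write the whole registry atomically (temp file + rename)."""
        path = Path(path)
        fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
        try:
            with os.fdopen(fd, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(_FIELDS)
                for pid in sorted(self._entries):
                    e = self._entries[pid]
                    writer.writerow([pid, e.arm, e.batch_label, e.timestamp])
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
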