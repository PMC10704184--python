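"""Sequester two overlapping intake batches with longitudinal consistency.

Splits a first batch ~80:20 by stratified sampling, then a second batch that
shares patients with the first.  Returning patients keep their original arm
(registry carry-over), so all longitudinal data of a patient stay in one
commons.
"""

from stratseq import (
    AssignmentRegistry,
    default_scheme,
    generate_cohort,
    sequester_batch,
    table1_spec,
)

scheme = default_scheme()
cohort = generate_cohort(table1_spec(n_patients=1200), seed=42)
batch1, batch2 = cohort[:800], cohort[500:]  # 300 patients overlap

registry = AssignmentRegistry()
a1 = sequester_batch(batch1, registry, scheme, seed=7, batch_label="2021-Q3")
a2 = sequester_batch(batch2, registry, scheme, seed=8, batch_label="2021-Q4")

print(f"batch 1: {len(a1.open_ids)} open / {len(a1.sequestered_ids)} sequestered "
      f"(realized open fraction {a1.realized_open_fraction():.3f})")
carry = [a for a in a2.assignments if a.source == "registry_carryover"]
print(f"batch 2: {len(a2.open_ids)} open / {len(a2.sequestered_ids)} sequestered; "
      f"{len(carry)} returning patients kept their arm")

arms1 = {a.patient_id: a.arm for a in a1.assignments}
flips = sum(1 for a in a2.assignments
            if a.patient_id in arms1 and a.arm != arms1[a.patient_id])
print(f"arm flips across batches: {flips} (always 0 — arms are immutable)")
print(f"registry now tracks {len(registry)} patients across both batches")
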