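# Methods

## Model and procedure

`stratseq` implements multi-dimensional stratified sequestration: a batch of
patient records is partitioned into an open and a sequestered commons so that
the joint distribution of categorical demographic variables is preserved on
both sides.

1. **Longitudinal check.** Patient IDs are compared against a persistent
   registry of all previous assignments. A returning patient keeps their
   recorded arm and bypasses splitting entirely; arms are immutable once
   recorded. The registry stores only `(patient_id, arm, batch label,
   timestamp)` — demographics are deliberately not persisted, so cross-batch
   demographic inconsistencies cannot be detected from the registry and are
   not reconciled; sequestration integrity outranks metadata hygiene.
2. **Primary modality.** A modality's prevalence is the number of batch
   patients possessing it. A multi-modality patient's primary is their
   possessed modality of highest prevalence (ties broken by lexicographic
   modality code), so each patient is stratified exactly once and the less
   prevalent modalities ride along.
3. **Stratification.** Each remaining patient is categorized on every scheme
   variable; patients sharing all categories form one stratum. The default
   scheme (age group 9, race 7, sex at birth 4, ethnicity 3, COVID-19 status
   3, modality 4) admits 9072 strata; an optional clinical-site variable can
   be prepended (off by default — a single-site batch carries no site signal
   to balance). Blank demographic entries map to a "Not reported" category so
   that missingness itself is balanced; unknown non-blank values are
   validation errors, never coerced.
4. **Within-stratum split.** A stratum of size *m* sends
   `floor(f·m) + Bernoulli(frac(f·m))` members (uniformly chosen) to the open
   arm. This randomized rounding makes the expected open fraction exactly *f*
   for every stratum size; deterministic rounding would systematically
   over-assign strata of size 1–4 at *f* = 0.8.

### Randomness and reproducibility

`sequester_batch` derives one substream per stratum from the master seed and
the stratum's *content* (sorted (variable, category) pairs), and sorts members
by patient ID before selection. Assignments are therefore invariant to the
order of patients in the batch and to the order of scheme variables, and
reproducible from `(batch, registry, scheme, seed)`.

The multi-trial evaluator `run_trials` instead derives one stream per
`(master seed, sampler, trial)` and applies the same counting rule to all
strata vectorized within a trial. The distribution of assignments is
identical to the per-stratum-stream layout; only the stream bookkeeping
differs, chosen for throughput (2000 trials × 5000 patients run in seconds).
Consequently a `run_trials` trial does not bit-reproduce a `sequester_batch`
call at the same seed; both are individually seed-reproducible.

## Evaluation framework

For a subcategory with input count `N_T` and realized open-arm count
`N_Open`, the scaled difference from expectation is
`d = |f·N_T − N_Open| / (f·N_T)`; the sequestered arm uses `1 − f` and the
sequestered count. Re-splitting the same input over many trials yields a
per-subcategory distribution of `d` for each sampler.

- **Baseline.** The naive sampler treats the whole batch as a single stratum
  under the identical counting rule, so the two samplers differ *only* in
  stratification. With 0.8 × 5000 integral, the naive open total is exactly
  4000 and naive subcategory counts are hypergeometric.
- **Test.** One-tailed Mann–Whitney U per subcategory (alternative:
  stratified `d` stochastically smaller), midranks for ties. Both samples
  ≤ 10: exact enumeration of the permutation distribution (also the oracle
  path in tests). Larger samples: normal approximation with tie-corrected
  variance and continuity correction (scipy). At 10-vs-10 on continuous data
  the two paths agree within 0.005; with heavy ties in tiny samples the
  approximation is poorer, which is why the exact path owns that regime. If
  every value in both samples ties, p = 1 is reported with a degeneracy
  warning.
- **Multiplicity.** Holm–Bonferroni step-down (statsmodels) across all
  testable subcategories; the i-th smallest of m p-values is tested against
  α/(m−i+1) — equivalently, each p against α divided by its rank with the
  smallest p ranked m. Zero-count subcategories are N/A and excluded.
- **Prevalence summaries.** Per trial, a subcategory's prevalence in an arm
  is its patient count divided by the arm total; modality prevalences count
  possession and may sum over 100%. Means and sample SDs are taken across
  trials.

## Synthetic cohorts

The generator emulates a 5000-patient single-site COVID-era intake batch via
its published marginal counts (2533 Female, 2397 COVID-positive, 17 American
Indian or Alaska Native, …; modality availability CR 2049 / CT 910 / DX 2596 /
MR 27). Two modes:

- `generate_cohort`: i.i.d. draws per variable (ages uniform within the
  sampled bin; modality sets by independent inclusion, re-drawn until
  non-empty). An optional conditional table imposes pairwise dependence for
  sensitivity studies.
- `exact_marginal_cohort`: every marginal count matched verbatim by
  independent per-variable permutation; exact per-modality counts are
  reconciled with the ≥ 1-modality invariant by transferring one modality
  from a random multi-modality patient to each empty one (column totals
  preserved). Used wherever reference counts must hold exactly.

**What the defaults do not model.** The joint demographic distribution of the
reference cohort is not public, so variables are independent by default. Real
cohorts are correlated (race × ethnicity, CR × DX), which concentrates
patients into fewer strata than independence does. Results that depend only
on marginals and on stratum sparsity transfer; results sensitive to the
stratum-size profile (see the near-universal-category caveat below) are
conservative under independence. Also note the non-empty redraw conditions
the sampled modality law on non-emptiness, inflating realized availability by
1/P(≥ 1 modality) ≈ 1.3 at default probabilities; use the exact-marginal mode
when modality counts matter.

## Behaviour at the extremes

- **Rare subcategories** (counts ≤ 27) land almost entirely in singleton
  strata, where the split degenerates to an independent 80:20 draw per
  patient — statistically indistinguishable from naive randomization. Their
  Mann–Whitney comparisons are expected non-significant.
- **Near-universal categories.** For a category covering ~89% of the batch
  spread across hundreds of strata, the summed rounding variance
  Σ frac(f·m_s)(1−frac(f·m_s)) (≈ 85 for "Not Hispanic or Latino" on the
  default cohort) can *exceed* the naive hypergeometric variance (≈ 79), so
  stratified sampling is slightly worse there under independent marginals.
  Correlated real-world demographics, with fewer and larger strata, shrink
  the rounding term; this is the regime where the method's advantage is
  weakest either way.

## Numerical and design choices

- Age bins are half-open `[lo, hi)` covering `[0, 140)`; ages outside are
  validation errors (fail fast on corrupt metadata), never silently binned.
- Vocabulary matching trims whitespace and is case-insensitive; the first
  listed spelling is canonical.
- Registry files are written atomically (temp file + rename) so a crashed run
  never half-records a batch.
- Modality-prevalence ties break lexicographically; deterministic and
  documented rather than random.
- Scaled differences are scored on the open arm by default; an `arm` switch
  selects the sequestered arm (complementary expectation).
- Histogram figures share Freedman–Diaconis bins between samplers per
  subcategory so widths are visually comparable.
- Comparison tables report full-precision p-values; a formatter floors the
  display at "p < 0.01" and stars Holm-significant rows.
- Trial counts default to 2000; the balance-comparison examples and tests use
  500, where the significance pattern is already stable. The acceptance
  script runs 2000 trials for prevalence means and 25 for counting testable
  comparisons (the count is trial-invariant for ≥ 2 trials).

## Limitations

- Balance is enforced and evaluated per marginal subcategory and per joint
  stratum; no multi-way balance diagnostic beyond that is computed.
- Longitudinal carry-over can drift the realized open fraction over many
  batches if returning patients are unbalanced; the realized fraction is
  logged but not corrected.
- No task-based sampling from the sequestered commons, no minimization-style
  adaptive allocation, and no image/DICOM handling — modality availability is
  taken from metadata.
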