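"""Compare stratified sequestration against naive randomization.

Re-splits the 5000-patient reference cohort 500 times with each sampler,
summarises how well each demographic subcategory's prevalence is preserved in
the open arm, and tests per subcategory whether the stratified scaled
difference from expectation |f*N_T - N_Open| / (f*N_T) is stochastically
smaller than the naive one (one-tailed Mann-Whitney U, Holm-corrected).
"""

from stratseq import (
    compare_samplers,
    default_scheme,
    exact_marginal_cohort,
    prevalence_summary,
    run_trials,
    table1_spec,
)
from stratseq.reporting import format_comparison_table, format_prevalence_table

scheme = default_scheme()
batch = exact_marginal_cohort(table1_spec(), seed=1)

ensemble = run_trials(batch, scheme, "stratified", n_trials=500, master_seed=11)
summary = format_prevalence_table(prevalence_summary(ensemble))
print("Prevalence preservation (stratified, 500 trials; mean % (SD)):")
print(summary.to_string(index=False))

report = compare_samplers(batch, scheme, n_trials=500, master_seed=11)
print(f"\nStratified vs naive ({report.n_comparisons} testable comparisons, "
      f"alpha={report.alpha}; '**' = significant after Holm):")
print(format_comparison_table(report).to_string(index=False))

print("\nWell-populated subcategories are significantly better balanced under "
      "stratification; rare ones (counts <= 27) live in singleton strata "
      "where stratified assignment degenerates to a per-patient 80:20 draw.")
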