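"""Which design parameters drive success?  Logistic-regression assessment.

Simulated records for the 1:1_1f and dil:mt schemes at several population
sizes are fitted with the canonical Model 1: success ~ cross + h + s + af +
N + the population-genetically motivated interactions.  Each variable is
then tested with a likelihood-ratio test of the full model against the
model lacking it (and its interactions), with Nagelkerke's R2 measuring the
improvement.  Crossing scheme and population size should dominate.
"""

from secoer import ExperimentDesign, generate_panel, generate_recmap
from secoer.experiment import records_to_frame, run_many
from secoer.models import (fit_logistic, model_spec, predict_success,
                           prepare_records, standardize_covariates,
                           variable_lrt_table)

panel = generate_panel(seed=31)
recmap = generate_recmap(panel.chrom_length, 100, 0.5, seed=32)

records = []
for scheme in ("1:1_1f", "dil:mt"):
    for N in (300, 1200, 4800):
        design = ExperimentDesign(scheme, N=N, generations=60, replicates=5)
        records.extend(run_many(design, panel, recmap, n_sims=40,
                                master_seed=33 + N))

df = prepare_records(records_to_frame(records))
df, scale = standardize_covariates(df)
spec = model_spec(1, "B")
fit = fit_logistic(df, spec, scale_params=scale)
print(f"n={fit.n}, log-likelihood={fit.llf:.1f}, converged={fit.converged}")

print("\nper-variable LRT (full vs model lacking the variable + interactions):")
print(variable_lrt_table(df, spec).round(3).to_string(index=False))

p, lo, hi = predict_success(fit, {"cross": "1:1_1f", "h": 0.5, "s": 0.085,
                                  "af": 0.5, "N": 1200})
print(f"\npredicted success-B for 1:1_1f, additive target, N=1,200: "
      f"{p:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print("variables with a large chi2 / Nagelkerke R2 drive success; small "
      "batches (40 sims/design here) give noisy rankings, so treat this as "
      "a template for full-scale record sets")
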