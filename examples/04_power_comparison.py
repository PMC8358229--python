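"""Compare the power of two crossing schemes at two population sizes.

Runs small batches of complete experiments for the simple 1:1_1f cross and
the dilution-with-multiple-targets scheme (dil:mt) and prints success-B
power with Wilson confidence intervals.  The simple cross wins, and both
gain from a larger census -- the central design message for secondary E&R.
(30-50 simulations per design keep this example quick; the acceptance
script runs the full batches.)
"""

from secoer import ExperimentDesign, estimate_power, generate_panel, generate_recmap
from secoer.experiment import run_many, tie_summary

panel = generate_panel(seed=21)
recmap = generate_recmap(panel.chrom_length, 100, 0.5, seed=22)

all_records = []
for scheme in ("1:1_1f", "dil:mt"):
    for N in (300, 1200):
        design = ExperimentDesign(scheme, N=N, generations=60, replicates=5)
        recs = run_many(design, panel, recmap, n_sims=30, master_seed=23 + N)
        all_records.extend(recs)
        p, lo, hi = estimate_power(recs, "B")
        print(f"{scheme:8s} N={N:5d}: success-B power {p:.2f} "
              f"(95% CI {lo:.2f}-{hi:.2f})")

print("\ntop-statistic tie counts (more ties = broader LD signature):")
print(tie_summary(all_records))
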