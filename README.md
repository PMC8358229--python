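# secoer — power and resolution of secondary evolve-and-resequence designs

Evolve-and-resequence (E&R) experiments evolve replicated lab populations
under a selection regime and sequence them as pools to find selected loci.
In sexual organisms like *Drosophila*, linkage disequilibrium leaves broad
candidate blocks instead of single SNPs. A *secondary* E&R re-exposes
material from the primary experiment to the same regime: the true target
should rise again, and the extra recombination separates it from
hitchhikers. Before committing years of fly work, one wants to know which
design can actually localize the causative SNP.

`secoer` is a simulation toolkit for that question, aimed at experimental
population geneticists planning such follow-ups. It provides:

- a synthetic founder-haplotype generator (power-law site-frequency
  spectrum, block-mosaic LD, piecewise recombination map) emulating ~100
  sequenced inbred *D. simulans* lines on one chromosome arm;
- a fast diploid Wright–Fisher forward simulator over founder haplotypes
  (fitness 1 : 1+hs : 1+s per selected locus, fitness-proportional mating,
  Poisson crossovers on the genetic map, no male recombination by default);
- crossing-scheme constructors — inbred line crosses (1:1 with one or two
  targets, 1:few, 1:many) and "dilution" schemes where 50% of an evolved
  primary population is replaced by ancestral genotypes (dil:st, dil:mt),
  including the embedded primary E&R, χ² scan and 1 Mb window selection;
- Pool-Seq emulation (binomial resampling to read depth 80) with
  PoPoolation2 sync-format I/O;
- the detection machinery: Cochran–Mantel–Haenszel tests across replicate
  strata, dense ranking, success-A / success-B classification and
  resolution ECDFs;
- logistic-regression assessment of which design parameters drive success
  (likelihood-ratio tests, Type-II term tests, Nagelkerke's R²,
  separation handling, inverse-logit predictions with CIs).

A simulation is **success-A** when the true target has the highest CMH
statistic, and **success-B** when it lies within 100 SNPs of the top
signal; **power** is the proportion of successful simulations and
**resolution** the distribution of target–to–top-SNP distances.

## Worked example

```python
from secoer import ExperimentDesign, estimate_power, generate_panel, generate_recmap
from secoer.experiment import run_many

panel  = generate_panel(seed=21)                                  # 100 lines x 5,000 SNPs, 23.5 Mb
recmap = generate_recmap(panel.chrom_length, 100, 0.5, seed=22)   # 0.5 Morgan female map

for scheme in ("1:1_1f", "dil:mt"):
    for N in (300, 1200):
        design = ExperimentDesign(scheme, N=N, generations=60, replicates=5)
        recs = run_many(design, panel, recmap, n_sims=30, master_seed=23 + N)
        p, lo, hi = estimate_power(recs, "B")
        print(f"{scheme:8s} N={N:5d}: success-B power {p:.2f} (95% CI {lo:.2f}-{hi:.2f})")
```

prints (exact numbers depend only on the seeds):

```
1:1_1f   N=  300: success-B power 1.00 (95% CI 0.89-1.00)
1:1_1f   N= 1200: success-B power 1.00 (95% CI 0.89-1.00)
dil:mt   N=  300: success-B power 0.83 (95% CI 0.66-0.93)
dil:mt   N= 1200: success-B power 0.80 (95% CI 0.63-0.90)
```

The simple two-line cross localizes the target more reliably than the
dilution scheme at either census. At this desk scale (5,000 SNPs, so the
100-SNP success window is relatively generous) powers sit higher than in a
full-size experiment; the orderings, not the absolute values, carry the
design message. `examples/` contains five short narrative scripts
(founder generation, selection trajectories, a hand-built CMH scan, the
power comparison above, and the logistic design models).

There is also a thin CLI:

```bash
secoer generate-panel --n-hap 100 --n-snps 5000 --seed 1 --out founders.tsv
secoer run --config designs.yaml --out records.tsv --seed 42
secoer power records.tsv --success B
secoer resolution records.tsv
secoer fit-models records.tsv --model 1
```

where `designs.yaml` lists design rows
(`{scheme: "1:1_1f", N: 1200, generations: 60, replicates: 5, n_sims: 200}`).

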