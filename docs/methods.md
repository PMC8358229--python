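# Methods

`secoer` simulates *secondary* evolve-and-resequence (E&R) experiments —
follow-up experimental-evolution studies that re-expose material from a
primary E&R to the same selection regime in order to validate a putative
selection target and fine-map it through additional recombination — and
quantifies how design choices (crossing scheme, census size, duration,
replication) and population-genetic parameters (selection coefficient s,
dominance h, starting frequency) shape the probability of pinpointing the
causative SNP.

## Forward simulation model

Populations are diploid with discrete, non-overlapping generations and a
constant census N. Haplotypes descend from a panel of phased founder
haplotypes; there is no mutation, so all variation is standing variation and
alleles that fix or are lost stay absorbed.

**Fitness.** A selected SNP contributes genotype fitness 1 : 1 + h·s :
1 + s for 0/1/2 derived copies. With several targets the per-locus factors
multiply (the conventional w-mode of haplotype-based E&R simulators); an
additive combiner (1 + Σ contributions, floored at 0) is available via
`SimulationConfig(fitness_combiner="additive")`. h = 0.5 is codominant,
h = 1 dominant; fully recessive targets (h = 0) are excluded by default
because they respond too weakly to truncation-free lab selection to be
detectable in a primary E&R.

**Reproduction.** The population carries ⌊N/2⌋ females. For each offspring
a mother is drawn from the females and a father from the males, both with
probability proportional to fitness and with replacement (fecundity
selection). The maternal gamete recombines; the paternal gamete is an
intact haplotype by default (Drosophila males are achiasmatic;
`male_recombination=True` switches this off-default behaviour on).

**Recombination.** Crossover counts per meiosis are Poisson with mean equal
to the total map length in Morgans (no interference); positions are placed
along the genetic map — i.e., with density proportional to the local
cM/Mb rate — and converted to bp through the piecewise map. The default map
is 0.5 Morgans over a 23.5 Mb arm (≈2.1 cM/Mb), the female map scale of a
*D. simulans* chromosome arm.

**Representation.** Each haplotype is stored as a run-length mosaic of
founder-haplotype segments (breakpoint positions + founder indices) rather
than a dense allele vector. Meiosis merges two segment tracks with the
sampled crossover cuts; per-generation cost scales with N × (segments per
haplotype, ≈1 + map-length·generations ≈ 30 after 60 generations) instead
of N × SNPs. Allele frequencies decoded from the tracks are exact, and a
dense matrix can always be reconstructed (`Population.haplotype_matrix`),
which the test suite uses to cross-check the two representations. Numba
kernels implement the track operations; all randomness stays in NumPy
generator streams, so results are bit-reproducible for a given seed.

## Synthetic founder panel

The real input of such a study — ~100 sequenced inbred founder lines on one
chromosome arm — is replaced by a parametric generator so that nothing needs
downloading:

- **Site-frequency spectrum.** Each SNP's target derived-allele count c is
  drawn with P(c) ∝ c^(−α) (α = 1 by default), the neutral-equilibrium
  shape; most variants are rare, mean derived frequency ≈ 0.19 at the
  defaults.
- **Linkage disequilibrium.** Every haplotype is a Markov block-mosaic over
  12 prototype labels with mean block length 100 kb; at each SNP a subset
  of prototypes is greedily assigned the derived allele to approximate the
  target count. Nearby SNPs therefore share a prototype partition and are
  correlated; distant SNPs are nearly independent. The LD calibration is
  qualitative — no published pairwise-LD decay of the real panel is
  matched — so resolution numbers should be read as desk-scale, not
  empirical, values.
- Monomorphic columns are dropped at construction: only segregating
  biallelic SNPs are ever tested.

Defaults (100 haplotypes, 5,000 SNPs, 23.5 Mb, 0.5 Morgan) are the
desk-scale study conditions; the real study's ~0.5–1 M SNPs are reachable
through the same parameters but are not a default. Because success-B allows
100 SNPs between target and top signal, the *relative* leniency of that
window is larger at 5,000 SNPs than at 500,000 — desk-scale powers are
therefore upper bounds on full-scale powers, and only directional and
threshold claims are asserted.

## Crossing schemes

- **1:1 (versions 1f, 2f, 1f1nf).** The inbred focal line carrying the
  target is crossed 50:50 with one inbred nonfocal line per replicate, a
  different (non-carrier) line in each replicate; a focal-private SNP
  starts at exactly 0.5. Version 2f adds a second target on the focal
  haplotype, 1f1nf on exactly one nonfocal haplotype; the additional s is
  drawn U(0.07, s_focal) and its dominance is fixed by the architecture
  label.
- **1:few / 1:many.** The focal line at 50% plus a fixed pool of 5 (each
  10%) or 99 nonfocal lines, identical across replicates. Line counts are
  apportioned with largest-remainder rounding so the census is exact.
- **dil:st / dil:mt.** A primary E&R is simulated first: an outbred base
  population (each haplotype drawn uniformly from the founder panel),
  N = 300, 60 generations, one replicate, with 1 (dil:st) or 16 (dil:mt)
  targets whose starting frequencies are drawn from a Beta(2, 18)
  (mean 0.1 — the stand-in for the empirical starting-frequency
  distribution of detected selected alleles) and matched to panel SNPs
  within ±0.02. The 16 dil:mt targets stand for distinct mapped selection
  peaks — separate selected haplotype blocks — so they are kept at least
  one block length (1 Mb) apart; two targets inside one block would be one
  peak, not two, and in repulsion linkage they would deterministically drag
  each other out. Every SNP is then tested with the two-sided Pearson χ²
  on depth-rescaled counts, and a 1 Mb window (the reported median selected
  haplotype block length) is centred on the top SNP, clipped at chromosome
  ends. Each secondary replicate is an independent dilution draw: half the
  secondary census sampled from the evolved population without replacement
  (with replacement when the secondary census exceeds the primary's 300 —
  the expansion any larger secondary experiment implies), half fresh
  ancestral genotypes. Secondary testing and ranking are restricted to the
  window.

Design grids mirror the study table: N ∈ {300; 1,200; 4,800; 19,200},
20/60 generations, 5/30 replicates, with arbitrary values allowed.

## Detection and classification

Allele counts at generations 0 and 60 are resampled to a uniform read depth
of 80 by per-SNP binomial draws (Pool-Seq emulation; no sequencing-error
model, so frequencies 0/1 give deterministic counts). Each SNP forms one
2×2 table (timepoint × allele) per replicate; replicates are the strata of
a Cochran–Mantel–Haenszel test without continuity correction, so the
single-stratum statistic equals (n−1)/n times the Pearson χ². Strata with a
zero marginal contribute nothing; SNPs degenerate in every stratum are
untestable and excluded from ranking. The secondary-E&R scan is one-sided
for frequency *increases*: SNPs whose pooled deviation points downward keep
statistic 0, so a sweeping-out allele cannot top the ranking.

SNPs are dense-ranked (ties share a rank, no gaps). A simulation is
**success-A** if the focal target attains the maximum statistic and
**success-B** if it lies within 100 SNPs (position-order steps among tested
SNPs) of the top-ranked SNP; **resolution** is the ECDF of those distances
among successful runs. Ties at the maximum are broken toward the tied SNP
nearest the focal (then lower position) — an optimistic rule — and the tie
count is reported so sensitivity to the rule is measurable; `tie_rule`
accepts "lowest" and "random" alternatives. In dil:mt the analysis focal is
the in-window target closest to the top CMH SNP; a simulation whose window
contains no true target is scored a failure (`window_miss`), with its
covariates taken from the target nearest the window centre.

**Focal loss** is the event that the focal allele is extinct in every
replicate at the final generation, measured on true population
frequencies. For dil:st the focal is the single true target whether or not
it lies in the window; for dil:mt a window-miss simulation has no analysis
focal, so it counts as a failure but never as a focal loss — the two
failure modes are kept distinct.

## Design assessment

Success is modelled with binomial GLMs (logit link; statsmodels IRLS,
deviance tolerance 1e-8, ≤100 iterations). Three canonical models cover
(1) 1:1_1f vs dil:mt across population sizes, (2) the 1:1 architecture
variants across population sizes (no starting-frequency covariate — it is
always 50%), and (3) all five schemes at N = 300. s and the mean focal
starting frequency are multiplied by 100 and z-transformed; cross,
architecture, h and N are treatment-coded categoricals (first level
reference). Variables are tested by LRT of the full model against the
nested model lacking the variable and all its interactions (at the
canonical codings this removes 8/12/2/9/1 parameters for
cross/N/af/h/s in Model 1); per-term Type-II tests use the
marginality-respecting reduced sets, and Nagelkerke's R² quantifies each
variable's improvement (computed full-vs-reduced for the same drop).
Complete separation is flagged (|coefficient| > 15 on the logit scale,
single-response cells reported) and handled by appending one
pseudo-observation with the missing response to the separated cell.

## Numerical and bookkeeping choices

- One master seed spawns per-design and per-simulation child streams
  (`numpy.random.SeedSequence`), so any single simulation is reproducible
  in isolation and results are independent of execution order and thread
  count.
- Segment-track capacity grows geometrically on overflow with a
  deterministic retry (all random draws are fixed before the kernel runs).
- Largest-remainder rounding for line proportions; window clipping (not
  shifting) at chromosome ends; dil:mt af covariate recorded post-dilution,
  pre-selection.
- The CMH null-calibration check uses zero-generation data (both timepoints
  resampled from the same frequencies) restricted to frequencies in
  [0.1, 0.9]: with depth-80 counts this is the validity regime of the χ²
  approximation, and with no drift between timepoints the test's sampling
  null holds exactly. With generations of drift in between, the CMH test is
  anticonservative by construction — a property of the method, not a bug.

## What the tests do and do not show

The suite verifies the machinery against independent oracles (closed-form
χ², the (n−1)/n CMH identity, scipy/statsmodels cross-checks, the
deterministic selection recursion, neutral-drift variance p(1−p)/2N,
Poisson crossover counts, logistic parameter recovery) and reproduces the
study's directional findings at desk scale: the simple 1:1 cross beats
dilution at N ≥ 1,200, more replicates and larger N raise power, 1:1_1f
exceeds 75% success-B power at N = 4,800 and 50% at N = 1,200, and
dilution schemes lose the focal allele in ≲1% of simulations. Absolute
power values are *not* comparable to the full-scale study: the synthetic
panel's SNP density, its qualitative LD calibration, and 100–200
simulations per design (vs 2,000) all differ. Real-data effects that are
deliberately out of scope: sequencing error and depth heterogeneity,
mutation, migration, epistasis/pleiotropy, polygenic architectures, and
X-vs-autosome differences.

## Problem sizes used by the default suite

Simulation batches are 100–200 per design on the 5,000-SNP panel (the
package's desk-scale default), with the heaviest batch the 100 simulations
of 1:1_1f at N = 4,800 × 60 generations × 5 replicates. The focal-loss
rate sits below 1%, so it is measured on 400 dilution simulations
(200 dil:st + 200 dil:mt) — 200 would resolve it only to 0.5% steps. The
acceptance script (`scripts/acceptance.py`) re-runs the three headline
quantities at exactly these sizes.
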