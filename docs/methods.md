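# Methods

## The population model

A four-way RIL (FW-RIL) line descends from a double cross
(P1 × P2) × (P3 × P4) followed by single-seed-descent selfing. The
simulator tracks founder origin per haplotype through every meiosis:

- **Map function.** Crossovers fall as a Poisson process at rate 1 per
  100 cM with no interference, i.e. the Haldane map function
  `r = (1 − e^(−2d/100))/2` links cM distance to recombination fraction.
  No interference is the simplest self-consistent choice; nothing in the
  analysis depends on the interference model.
- **Selfing.** Five generations of selfing are simulated meiosis by
  meiosis (default `n_selfing_generations = 5`, matching a typical
  multi-year SSD program; configurable). Closed-form RIL expansions are
  used only as test oracles, never in the generator.
- **Forced homozygosity.** After the last selfing generation, residual
  heterozygosity is resolved by drawing one more meiotic gamete and
  doubling it. Marginally this is a fair coin per heterozygous locus, but
  it respects linkage: two completely linked loci can never fix to
  different founders. (Independent per-locus coin flips would violate
  that invariant.) The exact two-locus consequences of this scheme are
  enumerated by the Markov-chain oracle in `tests/test_simdata.py`, and
  the simulator is required to match it to Monte-Carlo error.
- **Founder SNPs.** Founder haplotypes are i.i.d. Bernoulli(0.5) per
  founder and marker, which keeps expected MAF at 0.5 and makes roughly
  1/8 of markers monomorphic (all founders sharing an allele) — these are
  dropped by the scans exactly as uninformative chip markers would be.
- **Seeding.** One master seed; all streams are spawned from a numpy
  `SeedSequence`, so every run is bit-reproducible (asserted in the test
  suite by byte-comparing pipeline CSVs).

## The phenotype model

Phenotypes are the split-block ANOVA model read forward:

```
x_eijr = mu + E_e + R_r + D_j + sum_q [a_i(q) + ad_i(q),j]
         + GE_ei + GDE_eij + eps_eijr
```

with environment effects `E_e`, replicate-block effects `R_r`, density
effects `D_j`, QTL founder-allele effects `a_i` and allele × density
interactions `ad_ij`, and independent Gaussian GE, GDE and residual terms.
Defaults (grand mean 14 nodes, env effects ±1.4, density effects ±0.6,
residual SD 1.5, GE variance 0.8, GDE variance 0.9, three QTL with allele
effects up to 1.5 nodes, two with ±0.4-node density interactions) were
chosen once so that the simulated per-treatment means (≈12–15 nodes) and
SDs (≈1.8–2.3) sit inside the spans reported for real FW-RIL soybean MSNN
data (means 11.77–16.68, SD 1.73–3.22). The generator draws the QTL
genotype from the founder label at the marker nearest the QTL position.

What the generator does *not* emulate: segregation distortion, missing or
erroneous genotype calls, non-Gaussian residuals, spatial field trends,
and real marker-density variation. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to those artefacts.

## ANOVA, variance components, heritability

The field design is a split block: within each replicate block the two
densities are main plots (error stratum block × density, `RD_jr`) and the
genotypes subplots. On balanced data the sums of squares come from the
closed-form marginal-mean projections; the joint analysis nests blocks in
environments. Unbalanced inputs are routed to sequential (type-I) least
squares via statsmodels with a warning — the design itself is balanced, so
this path only serves damaged data. The density F test uses the
main-block error; genotype and its interactions use the subplot residual.

Variance components are method-of-moments from expected mean squares
(e.g. single environment `s2_GD = (MS_GD − MS_res)/r`); negative estimates
are truncated at zero and logged. REML is deliberately out of scope: the
EMS path is auditable and reproduces the published single-environment
heritabilities exactly.

Heritability (broad sense, line-mean basis):

- single environment: `h2 = s2_G / (s2_G + s2_GD/d + s2/(d·r))`
- joint: `h2 = s2_G / (s2_G + s2_GD/d + s2_GDE/(d·e) + s2/(e·d·r))`

The joint formula carries **no** `s2_GE/e` term, matching the form the
study states; because reasonable practice would include it, a
GE-inclusive variant is available via `heritability(..., include_ge=True)`.
We implement the stated formula as primary and take no position on which
variant produced the published joint value.

Skewness is the adjusted Fisher–Pearson coefficient and kurtosis the
excess form (Gaussian ⇒ 0), matching the near-zero published values;
constant groups get an explicit undefined flag rather than silent zeros.

## Response to density

`RD = x_D2 − b(x_D1 − mean(x_D1))` with `b = C_D1D2/V_D1` computed from
sample (n−1) moments over line means within one environment (the n−1
convention cancels in the slope). RD is exactly the intercept-plus-
residual of the OLS regression of x_D2 on x_D1. Lines missing either
density in an environment are dropped (complete case, counted). If
`V_D1 < 1e-12` the slope is undefined and RD falls back to `x_D2` with a
warning (the covariance is then 0 too, so the adjustment vanishes).

## Founder posteriors and genome scans

The hidden state at each position is the founder of origin (1–4) of the
line's homozygous chromosome. Emissions compare the observed allele with
each founder's allele with a mismatch floor of 1e-3 (genotyping error);
founder-coded input yields exact point masses; missing data is uniform.
Transitions over a gap use the selfed-RIL expansion `r* = 2r/(1+2r)` of
the Haldane single-meiosis fraction — an approximation for the four-way
pedigree (the exact expansion differs slightly at large distances), whose
effect is quantified against the simulator's Markov oracle in the tests.
Between grid points a founder change moves to each alternative with
probability `r*/3`. Posteriors come from a standard normalized
forward–backward pass per chromosome on the union of the 1-cM grid and
the marker positions.

The IM scan is a Haley–Knott-style least-squares fit of the trait on the
four posterior dosage columns per position (the dosages sum to 1, so the
fit absorbs the intercept). `LOD = (n/2) log10(RSS0/RSS1)` against the
intercept-only fit; `PVE = 100(1 − RSS1/RSS0)`; effects are reported as
deviations of the coefficients from their unweighted mean (sum-to-zero
convention), which at a fully informative marker equal the founder
class-mean deviations exactly. Degenerate positions (dosage rank ≤ 1, or
no RSS reduction) report LOD 0 and are flagged. Full-likelihood EM
mixtures were not used: for near-homozygous RILs the regression scan is
standard and the accuracy difference is negligible.

The ICIM-style scan selects background marker cofactors (3-df founder
dosage blocks) by forward–backward stepwise partial F tests
(`alpha_in = 0.001`, `alpha_out = 0.002`, at most n/10 cofactors — the
originating software does not publish its settings, so these are chosen
conservatively and exposed), then rescans the trait adjusted by the
selected cofactors lying outside ±10 cM (different chromosome, or
distance > window) of each evaluation point; a cofactor never adjusts its
own region. With no cofactors selected the result is identical to IM.

QTL calling: maximal runs with LOD ≥ 3 (the fixed threshold used
throughout; no permutation thresholds), leftmost argmax as peak, and the
flanking-marker interval containing the peak as the reported physical
support (bp endpoints inclusive as printed in such tables). Calls whose
marker intervals overlap on a chromosome share a sequence number; NN and
RD traits keep separate per-chromosome counters with cross-references
(`qlNN-6-1 (qlRDNN-6-1)` style). Region merging by interval *overlap* is
the default; exact-identity merging is available via `merge="identity"`.

## QTL × density decomposition

Given hard allele classes at the peak (posterior max ≥ 0.7, otherwise
excluded and counted), the decomposition follows the moment formulas:
`G_i`, `D_j`, `GD_ij` from marginal and cell means, `s2_G = Σ f_i G_i²`,
`s2_D = (1/d) Σ D_j²`, `s2_GD = Σ f_ij GD_ij²`, `s2_p` the mean squared
deviation, `PVE_A`/`PVE_AD` their percentage shares. The interaction
share's numerator is `s2_GD` — the allele × density interaction variance,
consistent with the decomposition it accompanies. Frequencies `f_i, f_ij`
are the observed class proportions (an equal-frequency override exists
for strict-formula checks). In a balanced two-density design
`Σ_j GD_ij = 0`, so the interaction column under D2 is exactly minus the
D1 column — asserted, since published tables show the same pairing.

## Association stand-in and LD

Multi-locus GWAS methods (mrMLM family) are *not* reimplemented — their
internals are cited, not defined, in the source material. The stand-in is
a clearly labeled single-marker regression scan with the same thresholds
(MAF > 0.05, LOD ≥ 3) and a method label per record so multi-method
support logic stays exercisable. No kinship/structure correction: an
FW-RIL has known pedigree and no population structure. Under two-class
reduction the scan's LOD is identical to the IM scan's, which ties the
two modules together in the tests. LD decay is binned pairwise r² on
allele indicators with interpolated threshold crossing; both the LD-based
window motivation and the fixed 100-kb flank are exposed as constants
rather than derived, since they are not mutually consistent in the source
material.

## Report rules

Stability (default): a QTL/QTN is stable when it is detected with ≥2
values in at least one support dimension (methods, densities incl. RD,
environments); a strict all-dimensions rule is available. The published
phrasing reads as a conjunction, but the accompanying tables satisfy only
some dimensions per entry, so repetition-in-any-dimension is the default
and both rules are explicit. Candidates: linkage — stable AND PVE > 10%
AND interval < 600 kb; association — (≥2 methods OR ≥2 environments OR
co-located with a linkage interval) AND r² > 10%. Co-location: a QTN bp
inside a QTL's marker interval, endpoints inclusive. Windows extend
candidate intervals by 100 kb each side, clamped at zero; coordinates are
0-based half-open internally and 1-based inclusive when printed. Gene
intersection stops at positional overlap — expression and pathway
filtering are out of scope.

## Problem sizes

The bundled analysis runs 144 lines × 4 chromosomes × 26 markers
(4-cM spacing, 125 kb/cM so a single marker interval is 500 kb and the
<600 kb candidate rule has both outcomes), 5 environments × 2 densities ×
3 replicates — a deliberately scaled-down genome with the study's design
structure. The simulation-based tests use 100-seed power runs, 200-seed
null runs, and n = 2000–5000 line draws for the frequency and Markov
checks. The whole suite runs in well under a minute.

## Known limitations

- The HMM transition is the two-way selfed-RIL expansion, not the exact
  four-way one; posterior accuracy is data-limited near true double
  crossovers (single-marker founder islands are genuinely ambiguous in
  SNP data and are excluded from the accuracy checks).
- EMS variance components can go negative on noisy data (truncated, logged).
- The single-marker association scan is a stand-in, not a reimplementation
  of multi-locus GWAS; its records exist to exercise the reporting logic.
- No VCF ingestion beyond what the CSV schemas cover; no map estimation,
  segregation-distortion filtering, or real-chip error models.
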