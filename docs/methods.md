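# Methods

This note documents the models, estimators and numerical choices behind
`afrostruct`, in the spirit of the methods documentation of simulation and
population-genetics packages.

## Scope and data model

The package implements the analysis chain used to characterize continental
population structure from modest SNP-array panels — the setting in which a
few thousand post-QC autosomal SNPs across tens of population samples are
used to ask whether a target population (here, a South-East African
Bantu-speaker analogue, "Mozambique") carries a major genetic component not
shared with related populations.  The chain is: genotype QC → PCA →
model-based ancestry estimation with cross-validated choice of the number
of components K → FST between inferred components and between population
samples → Patterson's f3 admixture tests with block-jackknife Z-scores →
a resampling-based power analysis of the f3 test → a complete-linkage FST
dendrogram and inverse-distance-weighted ancestry maps.

The central container is `GenotypeMatrix`: an individuals × SNPs dosage
matrix over {0, 1, 2, missing} plus sample metadata (population label,
optional lon/lat) and variant metadata (chromosome, id, position, alleles).
A dosage counts copies of allele1 — the counted allele — and every
statistic in the package uses this one polarity convention; f-statistics
are notoriously sensitive to silent polarity flips, so the convention is
enforced at the container boundary.

## Synthetic data generator

Working data sets in this field are assembled by merging many genotyping
efforts and are rarely redistributable as a single accession, so a
first-class simulator stands in for the working data set.  It is a
Balding–Nichols admixture generator:

* Ancestral allele frequencies are Uniform(0.05, 0.95) per SNP.  This
  avoids monomorphic sites and mimics array ascertainment toward common
  variants; it does not attempt a realistic site-frequency spectrum.
* Component allele frequencies derive from the ancestral frequency by
  Balding–Nichols draws, `Beta(p(1-F)/F, (1-p)(1-F)/F)`, which have mean
  `p` and variance `F·p(1-p)`.
* Genotypes follow the standard admixture model: each of an individual's
  two allele copies independently picks component k with probability
  `q_ik`, then is the counted allele with probability `P_kj`.
* Missingness is applied completely at random; duplicates and parent–child
  pairs can be injected to exercise kinship QC (the child receives one
  allele transmitted from the parent per SNP, the other drawn from the
  population's own admixture model).

### Calibration of component divergence

The default scenario carries six components (Khoisan, Pygmies, East-1,
East-2, NC-West, NC-East) whose pairwise divergences are calibrated to a
15-entry reference matrix of pairwise component FST values, with the
NC-East/NC-West pair by far the closest (0.042).

Two calibrations are implemented:

* **Star model** (`fit_drifts`): independent per-component drifts fitted by
  least squares under `E[FST_ab] = (F_a + F_b)/2`.  Fifteen equations and
  six unknowns leave substantial residuals (max |residual| 0.039): the
  target matrix is strongly non-additive — the pair of high-drift
  hunter-gatherer components is mutually close (0.102), which no assignment
  of per-component drifts can reproduce.  The fit reports its residuals.
* **Tree model** (`fit_component_tree`, used by `default_scenario`):
  nested Balding–Nichols draws down a rooted 6-leaf tree, one drift per
  branch.  Cumulative drift satisfies `1 - f_child = (1 - f_parent)(1 - F_branch)`
  and the expected pairwise FST between leaves is
  `(f_a + f_b - 2 f_m) / (2 (1 - f_m))` with `f_m` the cumulative drift at
  the most recent common ancestor.  The topology
  `((((NC-East,NC-West),(Pygmies,Khoisan)),East-1),East-2)` was selected by
  exhaustively fitting all 945 rooted binary topologies and keeping the
  best; branch drifts come from bounded least squares
  (`scipy.optimize.least_squares`, bounds [1e-4, 0.5]).  Max |residual|
  0.0098; the correlation between realized component FST (at 1,747 SNPs)
  and the calibration targets is ≈ 0.98.

The tree calibration is the package's deliberate design choice: a star
model cannot reproduce the calibration matrix even approximately, and
shared internal branches are also the biologically natural reading of the
component relationships (the two Niger-Congo components share most of
their history).

### Default panel

Fifteen population samples of 25 diploids each (375 individuals, matching
the per-population sampling depth of typical merged survey panels),
spanning pure components, two-way and three-way mixtures, and a
Mozambique-like sample that is 97% NC-East; each sample carries rough
sampling coordinates for the interpolation maps.  1,747 SNPs on one
chromosome; missing rate 0.005 (post-QC data are nearly complete).  All
draws flow from a single `numpy.random.default_rng` seed; generation is
bit-reproducible.

The resampled admixed targets of the power analysis mix *allele copies*:
each copy derives from the donor with probability alpha, else from the
second source, and is then Bernoulli at that source's empirical frequency.
Allele-level mixing matches the intended admixture proportion in
expectation at every SNP and every alpha; the alternative
(whole-individual mixing) would make realized alpha lumpy at small target
sizes.  The default target sample size equals the donor sample size,
keeping estimator noise comparable to a real target.

### What the simulator does not model

No linkage disequilibrium (sites are exchangeable given the component
frequencies), no realistic allele-frequency spectrum, no ascertainment
toward any particular panel, no sex chromosomes, no genotyping error
model.  Green tests therefore demonstrate correctness of the estimators
and the qualitative behaviour of the chain under the calibrated divergence
structure — not robustness to LD (the 100-SNP jackknife blocks exist
precisely to absorb LD in real data) or to array artefacts.

## QC chain

* **Call rate**: SNPs below the SNP threshold are dropped first, then
  individuals below the sample threshold computed on surviving SNPs.
  Defaults 0.9 (per-dataset stage) and 0.98 (post-merge stage) — exposed
  as two sequential calls.  The stage is idempotent at realistic
  missingness; at extreme missingness removing individuals can re-expose
  SNPs (a property of any one-pass filter).
* **LD pruning**: greedy within sliding windows (200 SNPs, step 25, never
  crossing a chromosome): while any retained pair in the window has
  squared Pearson dosage correlation (pairwise-complete observations)
  above 0.4, the lower-MAF member of the worst pair is removed (ties:
  later map position).  Zero-variance SNPs count as uncorrelated.
  After completion no within-window pair exceeds the cutoff — verified by
  brute force in the tests.
* **Kinship**: the KING-robust within-pair estimator,
  `phi = (N_het_both - 2·N_opposite_hom) / (N_het_i + N_het_j)` over
  jointly non-missing SNPs; robust to population structure because it
  never consults panel allele frequencies.  Pairs with phi > 0.0884
  (= 2^(-7/2), the standard second/third-degree boundary) are flagged;
  removal is iterative — the individual in the most flagged pairs goes
  first (ties: lower call rate, then later sample index).  Pairs sharing
  fewer than 100 SNPs are flagged `insufficient_overlap` instead of
  estimated.
* **Outgroup admixture**: given an ancestry matrix Q from a low-K fit that
  includes an outgroup reference (the intended use is K=4 with a European
  reference), individuals with more than 10% outgroup ancestry are
  dropped.

## Ancestry model

The admixture likelihood treats genotypes as Binomial(2, f_ij) with
`f_ij = Σ_k q_ik p_kj`.  Fitting is by multiplicative EM updates of Q and P
from the same per-iteration posterior expectations — the classic EM for
this model.  EM is monotone in the log-likelihood; the fit records the
full trace and the tests assert monotonicity.  P is clamped to
[1e-6, 1-1e-6] each iteration to keep the likelihood finite.  Plain EM
converges to the same stationary points as quasi-Newton accelerations of
the same likelihood; it is slower per unit of convergence but easier to
verify, and speed is not binding at this panel size.  Missing genotypes
are excluded from the likelihood (never imputed); PCA, by contrast,
mean-imputes per SNP, centres, scales by `sqrt(p(1-p))` and takes the SVD.

K is chosen by held-out genotype prediction: non-missing entries are
randomly partitioned into folds (the same folds for every K, so errors are
comparable); per fold the model is refit with those entries masked (best
of several seeded restarts by training likelihood) and scored by the mean
squared difference between the masked dosage and the predicted dosage
`2·Σ_k q_ik p_kj`; the chosen K minimizes the mean error.  Entry-level
(not individual-level) masking mirrors the cross-validation design of the
standard ancestry-estimation software.  EM tolerance during CV is an
absolute log-likelihood gain of 1e-2 with a 300-iteration cap — the error
curve is insensitive to tighter tolerances at this data size, and the cap
keeps a full K=2..10 sweep within minutes.

FST between fitted components treats P rows as population frequency
parameters: Hudson-form numerator `(p_a - p_b)²` and denominator
`p_a(1-p_b) + p_b(1-p_a)`, ratio of averages over SNPs, with sites fixed
identically in both components excluded.  No sample-size correction is
applied — component frequencies are parameters, not sample frequencies.

## f3 admixture test

For a trio (Target; A, B), the per-SNP contribution is
`(c-a)(c-b) - ĥ_c/(2 n_c)` with c, a, b sample allele frequencies, `n_c`
the target's genotyped diploid count at the SNP and
`ĥ_c = c(1-c)·2n_c/(2n_c-1)` the unbiased target heterozygosity; the
correction removes the upward-noise bias of `(c-a)(c-b)` at finite target
size.  A switch disables the correction for population-parameter tests
(used in the closed-form unit tests).  SNPs with any missing frequency or
`n_c < 2` are excluded.

The estimate is the mean contribution; its standard error comes from a
delete-one-block jackknife over consecutive blocks of 100 SNPs in map
order (the window length the field's standard implementation uses), with
the weighted form (block-size weights) handling the ragged final block;
an unweighted variant is exposed.  Significance follows the conventional
one-sided rule Z < -3.  The all-trios scan reports every
(target; unordered pair) combination — `P(P-1)(P-2)/2` tests for P
populations — with per-target counts of negative and significant
statistics.

The power analysis resamples, for each alpha in {0.05, …, 0.95} (19
values) and each of 100 replicates, a synthetic target mixing a donor and
a partner population in proportion alpha : 1-alpha, then runs
f3(target; donor, partner) and tabulates how often Z < -3.  One partner
therefore costs exactly 1,900 tests.  Power decreases as alpha → 1 (the
target degenerates into pure donor); the tests assert monotonicity of the
aggregated power curve.

## Population distances and maps

Pairwise FST between population samples is Weir & Cockerham's θ for two
populations: per-SNP among-population (a), between-individual (b) and
within-individual (c) variance components from sample sizes, allele
frequencies and observed heterozygosity, combined as the ratio of sums
`Σa / Σ(a+b+c)` across SNPs.  Ratio-of-averages (rather than averaging
per-SNP ratios) is the standard lower-variance choice; negative per-SNP
components are retained for unbiasedness.  Sites monomorphic across both
samples, or with fewer than two genotyped individuals in either, are
excluded.  For two Balding–Nichols populations at drift F each, θ is an
(essentially unbiased) estimator of F — the calibration the acceptance
checks exercise at F = 0.042.

The population tree is complete-linkage agglomerative clustering on the
raw FST matrix (merge height = maximum member-pair distance; ties broken
by lexicographically smallest leader-label pair).  Complete linkage never
inverts heights, so the dendrogram is ultrametric; it is written as Newick
with branch length = parent height - child height.  The implementation is
the package's own (n ≤ 35 populations; O(n³) is negligible) so that
tie-breaking is deterministic; scipy's complete linkage serves as an
independent oracle for merge heights in the tests.

Ancestry maps are plain inverse-distance-weighted interpolation of mean
per-population component proportions onto a regular lon/lat grid: node
value `Σ w_i v_i / Σ w_i` with `w_i = d_i^-3` and great-circle distances
on a spherical Earth (radius 6,371 km; a planar approximation would
distort at continental scale).  A node within 1e-9 km of a sample point
takes that point's value.  IDW weights are convex, so interpolated values
are bounded by the input range.  The package outputs numeric grids only —
rendering is out of scope.

## Pipeline

`run_pipeline` executes the stages in fixed order (simulate/load → QC →
PCA → admixture CV → component FST → f3 scan → f3 power → FST tree →
ancestry maps), writing plain files (PLINK, TSV, Newick, JSON) so any
stage can be rerun in isolation, plus a machine-readable manifest and a
summary.  The master seed fans out to per-stage seeds via
`numpy.random.SeedSequence([master_seed, stage_index])`; stages are
mutually seed-independent and reruns are byte-identical.

## File formats

PLINK text (.ped/.map) and PLINK 1 binary (.bed/.bim/.fam, SNP-major
2-bit encoding: 00 = hom allele1, 10 = het, 11 = hom allele2, 01 =
missing, each variant padded to a byte boundary; file size
`3 + n_variants · ceil(n_samples/4)` bytes).  Binary round trips are exact.
The .ped format itself carries no counted-allele designation: the reader
takes allele1 from the allele order of the first heterozygote (the writer
emits heterozygotes as "a1 a2"), so text round trips are exact whenever a
column contains at least one heterozygote; a column observed only as
homozygous-allele2 is inherently ambiguous in the format.  The
text→binary→text composition is always the identity.  Positions are
1-based; chromosomes are strings.  VCF, PLINK 2, multiallelic sites and
phased data are out of scope.

## Problem sizes used by the test suite and acceptance script

Simulated checks run at the panel's native size (1,747 SNPs; 375
individuals for the default scenario; 25–100 diploids per population in
focused checks), with 10 replicates for FST calibration, 200/100
replicates for the f3 null/power calibration, and a K = 2..10 CV sweep at
5 folds × 2 restarts.  Estimator-vs-oracle equivalence checks use small
instances (≤ 20 × 350) where brute-force recomputation is exact.

## Known limitations

* The EM fit finds local optima; CV uses a small number of restarts and
  the best training likelihood.  Label switching across runs is resolved
  by Hungarian assignment on Q correlations when fits are compared.
* The component-FST formula for fitted components is a parameter-level
  Hudson form; the formula used by the original ancestry-estimation
  software is undocumented, so agreement is approximate by construction.
* Jackknife blocks are defined over the SNPs actually used by a test
  (after missing-data exclusion), in map order.
* The f3 power analysis, like the design it follows, treats the donor and
  partner frequencies as fixed when resampling targets; donor-sample noise
  is shared across replicates.
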