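# Methods

## The analysis model

`poolscan` analyses Pool-seq experiments: each sequenced library is a DNA
pool built from equimolar contributions of a few dozen individuals, so that
at a biallelic SNP the fraction of reads carrying the alternate allele
estimates the population frequency of that allele. The package covers the
post-calling half of a selection-signature study on hatchery broodstock
nuclei — groups of breeder fish managed as closed reproductive units, whose
offspring pools are compared to find genomic regions of unusually high
differentiation.

### Site filters

From a called variant table the pipeline retains biallelic single-base
substitutions with site quality strictly greater than 100 and mean per-pool
total depth of at least 40, the depth averaged arithmetically across all
pools at the site (quality strict, depth non-strict — the boundary
semantics are asserted in tests). Each removed site is attributed to the
first criterion it fails (shape, then quality, then depth), so the
per-criterion counts sum to the number removed.

### Per-SNP and global F_ST

Differentiation between two pools at marker *k* with alternate-allele
frequencies *p1*, *p2* (*q* = 1 − *p*) uses the pooled-frequency estimator

    N_k = p1(q2 − q1) + p2(q1 − q2),   D_k = p1 q2 + p2 q1,   F_ST(k) = N_k / D_k.

Algebraically N_k = (p1 − p2)² and D_k = p1 + p2 − 2 p1 p2, which gives the
closed form used as an independent oracle in the tests and proves
0 ≤ F_ST ≤ 1 wherever D_k > 0. D_k = 0 exactly when both pools are fixed
for the same allele; such SNPs carry no information and are excluded from
summaries as *undefined* rather than counted as zero.

Two global summaries exist in the literature for this estimator and both
are computed for every comparison:

* **mean of ratios** — the arithmetic mean of defined per-SNP values; this
  is the quantity averaged inside scan windows (mF_ST);
* **ratio of sums** — ΣN_k / ΣD_k.

They differ systematically. Under pure drift from a common founder
frequency *p0*, E[N_k] = 2 p0 q0 F and E[D_k] = 2 p0 q0 with
F = 1 − (1 − 1/(2N_e))^t, so the ratio-of-sums estimator is the one whose
expectation equals the Wright–Fisher fixation index; the mean of ratios
carries a Jensen-type bias (measured ≈ −12% relative at F ≈ 0.1 with
founder frequencies uniform on [0.05, 0.95]). Drift-calibration checks
therefore use the ratio-of-sums form; windowed scans use per-SNP means, as
is conventional.

Frequencies are taken directly as alt/(ref+alt) read-count ratios. No
pool-size or depth correction is applied, so read-sampling noise inflates
both global estimates relative to the true population F_ST (by roughly
1/(2 n_fish) + E[pq]/depth at the default 30 fish and 60× depth); windowed
outlier calling is unaffected because the inflation is shared by all
windows of a comparison.

### Windowed scan and outlier calling

Per-SNP F_ST values are averaged in 500-kb windows with 50% overlap
(step 250 kb). Windows are 0-based half-open, anchored at 0 on each
chromosome, stepping while the start is inside the chromosome; the trailing
windows are truncated to their true span (configurable off). SNP positions
are compared directly against window coordinates, so a SNP at exactly a
250-kb boundary belongs to both windows that meet there; membership is by
point position only.

The outlier threshold is the 99th percentile (numpy's linear-interpolation
definition, fixed so results are bit-stable) of mF_ST over all windows with
at least one defined SNP, computed by default *before* the SNP-count rule
(the other order is available). A window is retained iff its mF_ST is
strictly above the threshold **and** it contains strictly more than
`min_snps` SNPs (default 200, i.e. ≥ 201). Retained windows that overlap or
are book-ended merge into outlier regions; a region's `total_snps` sums its
source windows' counts, so a SNP shared by two overlapping retained windows
is counted twice there.

### PCA

Pools are observations, complete-case per-site frequencies are variables;
sites missing in any pool are dropped and counted. Columns are centered,
not scaled, and scores come from the SVD of the centered matrix — the model
of a centered, unscaled `prcomp`. With *n* pools at most *n* − 1
components are informative. The sign of each component is fixed by making
its largest-magnitude loading positive (first such site on ties), so
results are deterministic under site and pool reordering.

### Region annotation

Gene–region intersection reports a gene whenever its interval overlaps a
region by ≥ 1 bp under the half-open convention, strand ignored — the
default semantics of standard interval-intersection tools. Impact tallies
consume a precomputed variant-impact table (one row per predicted
consequence; the four-level HIGH/MODERATE/LOW/MODIFIER severity
vocabulary). Because one SNP can carry several consequence records
(overlapping genes, alternative transcripts), tallies count records by
default; `unique_positions=True` collapses to the most severe class per
position.

## The synthetic-data generator

The generator emulates the hatchery design the analysis assumes: several
nuclei founded from one base population, drifting independently, sequenced
as pools. Per SNP and pool the model has three sampling layers:

1. **nucleus frequency** — a Wright–Fisher binomial trajectory over
   2 N_e allele copies per generation from a founder frequency drawn
   uniformly on [0.05, 0.95] (configurable; the range avoids immediately
   monomorphic founders while covering the spectrum);
2. **pool composition** — 2 × fish_per_pool allele copies drawn binomially
   from the nucleus frequency (exactly equimolar contributions, no
   fish-level dispersion beyond binomial sampling);
3. **sequencing** — Poisson total depth, binomial alternate reads at the
   pool frequency, and an optional symmetric base-flip error rate
   (default 0: called SNPs are treated as clean input).

Defaults are the emulated study conditions: 3 nuclei with the first
sequenced as three replicate pools (A1/A2/A3, B, C), 30 fish per pool, 60×
mean depth, 3 chromosomes of 10 Mb carrying 6,000 SNPs (≈ 100 SNPs per
500-kb window), N_e = 100 diploids and 20 generations of separation.
Census sizes of real broodstock nuclei (on the order of one to three
hundred breeders) bound N_e from above but effective sizes and separation
times are not observable from the published design, so both are explicit
parameters; N_e = 100 / t = 20 gives a drift-level differentiation
(F ≈ 0.095) in the range reported between real nuclei.

**Planted selection.** A planted locus applies the deterministic update
p′ = p(1+s) / (p(1+s) + 1 − p) before each generation's binomial draw in
the target nucleus. The update is applied to every SNP within
`sweep_radius_bp` (default 250 kb) of the planted position, emulating the
hitchhiking footprint of a hard sweep. This radius is part of the model,
not a tuning knob: windowed scans detect swept *regions*, and an isolated
selected SNP among ≥ 50 unlinked neutral SNPs shifts its window mean by
only ~(1 − F̄)/n — an order of magnitude less than the 99th-percentile
offset — so single-site selection is undetectable by construction in any
window-mean scan.

**What the generator does not model:** linkage disequilibrium between
neutral SNPs (sites are independent given the sweep structure), sequencing
error by default, mapping artifacts, indels, multi-allelic sites, variable
SNP density along the genome, and gene-annotation realism (genes are tiled
at uniform density with alternating strand; impact classes are drawn i.i.d.
with VEP-like proportions ≈ 97.2/2.0/0.8/0.07% for
MODIFIER/LOW/MODERATE/HIGH). Passing tests therefore demonstrate the
correctness of the estimators and the scan logic and the internal
consistency of the sampling model — not robustness to alignment artifacts
or LD structure in real data.

`infinite_depth=True` bypasses the pool and read layers and reports exact
nucleus frequencies over a fixed large depth; truth checks (e.g. per-pool
fixed-allele proportions against the simulator's absorption record) use
this mode so equality can be exact.

## Numerical choices and degenerate inputs

* Frequencies at zero-depth entries are missing (NaN), never 0; they are
  skipped and counted in every downstream statistic.
* Pool combination sums raw read counts (depth-weighted); an unweighted
  mean-of-frequencies mode exists for comparison since published analyses
  rarely state which was used.
* Percentile: numpy linear interpolation; "above" is strict, so a
  degenerate distribution (all windows equal) retains nothing.
* An empty variant file reads as an empty table; an all-filtered table is a
  valid empty result; statistics that would be 0/0 raise
  `UndefinedResultError` instead of returning a value.
* The fixed-allele proportion counts exact 0/1 frequencies among sites with
  defined frequency in that pool, over the shared called-SNP set.
* Window/region coordinates are 0-based half-open everywhere internally;
  VCF/GFF3 positions are converted on read and write.

## Problem sizes

Test and demonstration runs use 3 × 10 Mb chromosomes with 2,000–6,000
SNPs, 50-replicate batches for calibration and recovery rates, and
100k-point grids for estimator oracles. These sizes put Monte-Carlo
standard errors well below the effect sizes being checked while keeping any
single batch in the seconds-to-a-couple-of-minutes range; all simulation
layers are vectorised over SNPs so larger runs scale linearly.

## Known limitations

* The F_ST estimator is the study's pooled-frequency form; no unbiased
  Pool-seq estimator (e.g. with finite-pool correction terms) is provided,
  so absolute global values are depth- and pool-size-dependent.
* Outlier calling is empirical-percentile only; no permutation or
  simulation-based significance.
* Two-pool comparisons only; no multi-population statistics.
* The planted-sweep model is deterministic selection plus drift; it does
  not simulate partial or soft sweeps, and the sweep footprint has a hard
  edge at the configured radius.
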