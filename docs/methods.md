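# Methods

`ovipop` implements the analysis chain used to trace ancestry and
introgression in SNP-array genotypes of structured livestock populations
(the motivating system is domestic sheep and its wild mouflon relatives):
quality control and LD pruning, diversity statistics, genetic distances
and trees, supervised ordination, ancestry-informative-marker panels,
model-based ancestry estimation, and normalized f4 introgression
profiles. This note records the models, the defaults and why, the
numerical choices, and what the bundled simulator does and does not
emulate.

## Data model and QC

Genotypes are diploid allele-B dosages in {0, 1, 2} with a single missing
sentinel; all statistics use pairwise-complete observations unless stated.
PLINK .bed/.bim/.fam (v1.0 SNP-major) and .ped/.map are read and written
natively; in the text dialect, allele letters are re-inferred from the
genotypes in sorted order, so round-trip identity requires both alleles to
be observed (the binary dialect round-trips unconditionally).

Missingness filtering removes SNPs with more than `max_rate` (default
0.10) missing calls first, then recomputes sample rates and removes
samples above the same threshold — the order used by the PLINK toolchain.
LD pruning follows `--indep-pairwise` semantics (default 50-SNP windows,
step 50, r² > 0.03): r² is the squared Pearson correlation of dosages
over pairwise-complete individuals (composite LD, no phasing);
monomorphic SNPs get r² = 0 and are never pruned for LD. Within a
violating pair the SNP with the higher missing rate is dropped, ties
dropping the later SNP in map order — deterministic by construction.

## Diversity

Observed heterozygosity is the fraction of heterozygous calls among
non-missing calls per individual, averaged per breed. Runs of
homozygosity use a deterministic maximal-run scan rather than a
sliding-window hit-rate heuristic: a candidate run grows SNP by SNP and
is closed by an inter-SNP gap > 250 kb or by a second heterozygous or
second missing call; a closed run is reported iff it spans ≥ 1 Mb,
contains ≥ 31 SNPs, and exceeds one SNP per 100 kb average density.
Reported segments are trimmed to start and end on a homozygous call
(spending the single het/missing allowance on a boundary would only blur
it) and are non-overlapping within an individual-chromosome. Coordinates
are the first and last SNP positions, 1-based inclusive. F_ROH is the
summed segment length divided by the total autosome length, default
2,452.06 Mb (sheep).

## Distances and trees

The allele-sharing distance between two individuals is
1 − (shared alleles)/(2 × SNPs) over pairwise-complete SNPs, with shared
alleles per SNP equal to 2 − |gᵢ − gⱼ|; pairs overlapping at fewer than
100 SNPs (configurable) are an error rather than a noisy number.
Reynolds' coancestry distance between populations uses the ratio-of-sums
form, Σ(p_A − p_B)² / Σ(p_A + p_B − 2 p_A p_B), accumulating both sums
over loci before dividing so that shared monomorphic loci are harmless;
an all-zero denominator returns 0 by continuity. Neighbor joining is the
classical Saitou–Nei agglomeration with a deterministic tie-break (merge
the pair whose smallest-leaf labels sort first) and negative branch
lengths clamped to zero with the deficit logged. Distance matrices export
as TSV, PHYLIP and NEXUS TAXA+DISTANCES blocks; the NEXUS export exists
so split networks (neighbor-net) can be drawn in external software.

## Ordination

PCA standardizes dosages PLINK-style: center 2p̂, scale √(2p̂(1−p̂)), with
p̂ estimated **only from the fit subset**; missing dosages are imputed to
the fit mean, and SNPs monomorphic within the fit subset are dropped from
the model. Loadings are top-k right singular vectors; each loading's sign
is fixed by making its largest-magnitude entry positive. Supervised PCA
(svPCA) is exactly this machinery with a deliberately restricted fit
subset — e.g. everyone except heavily drifted isolates — after which all
individuals, fit or not, are projected with the model's centering and
scaling. Geographic svPCA restricts the fit to breeds at the geographic
extremes of a study area so PC1 aligns with the cline. Projection is
affine, so an equal admixture of two fit populations scores at the
midpoint of their centroids.

## AIM panels and ancestry estimation

Per-SNP FST between two populations is the Weir–Cockerham two-population
estimator computed from pooled allele frequencies and allele counts
(random union of gametes; no within-individual heterozygosity term, since
the module consumes frequency tables). Negative per-SNP estimates are
kept and compared against thresholds as-is. For multi-locus summaries,
`fst_overall` returns the ratio of summed variance components (the
weighted mean PLINK prints); the per-SNP mean-of-ratios is biased low and
is not used as a summary.

An AIM panel is the deterministic set of SNPs passing every FST
inequality of its rule (e.g. FST(source, reference) > 0.5 and
FST(other-source, source) > 0.5 and FST(other-source, reference) < 0.1)
and every per-population non-missing-count floor.

Ancestry proportions maximize the binomial admixture likelihood
Σᵢⱼ [g ln μ + (2−g) ln(1−μ)], μ = Σ_c q_ic p_cj, by EM — the same
likelihood ADMIXTURE and Structure's admixture model target, optimized
deterministically given a seed instead of by MCMC. Supervised mode
estimates cluster frequencies P once from labelled reference individuals
and holds them fixed; unsupervised mode updates Q and P jointly from the
best of 5 Dirichlet(1) random starts. Missing genotypes are skipped in
the likelihood; P is clamped to [1e-6, 1−1e-6]; convergence is
|Δlog-lik| < 1e-6 or 2,000 iterations (non-convergence returns the
result with a flag). The log-likelihood is non-decreasing every
iteration up to the clamping tolerance. Runs are flagged degenerate when
two clusters are statistically indistinguishable: in supervised mode,
multi-locus FST between their reference frequencies below 0.005 (within
sampling noise); in unsupervised mode, collapsed frequency rows.

## f4 and the normalized ratio f4n

For sources (src1, src2), reference ref and test population X,
f4 = mean over usable SNPs of (f_src1 − f_src2)(f_ref − f_X). The
normalization divides by the same mean with X replaced by src2:

    f4n(X) = mean[(f_src1 − f_src2)(f_ref − f_X)]
           / mean[(f_src1 − f_src2)(f_ref − f_src2)]

so X = src2 scores exactly 1, X = ref exactly 0, and under a simple
admixture graph f4n estimates the admixture fraction of src2 in X
relative to ref. The confidence interval is f4n ± 2 × SD from a
delete-one-block jackknife of the ratio over contiguous SNP blocks
(default 100 blocks; SNPs must arrive in genome order), the standard
choice for f-statistics under local LD.

Two properties worth knowing. First, with a finite source sample the
denominator contains the squared sampling noise of f̂_src2 (it appears in
both factors), which attenuates f4n multiplicatively by roughly
Var(drift)/(Var(drift) + p(1−p)/2n); with 25 diploids and the default
simulation graph this is a few percent of the estimate. The estimator
deliberately mirrors the plain frequency-product form used in the field
rather than a moment-corrected variant. Second, the self-tests X = src2
and X = ref are exact identities, unaffected by that bias.

## The simulator

`ovipop.simulate` draws structured genotypes under the Balding–Nichols
model: ancestral frequencies uniform on [0.05, 0.95], each population's
frequency Beta(p(1−F)/F, (1−p)(1−F)/F) around its parent's (mean p,
variance F·p(1−p)); admixture nodes mix source frequencies with declared
proportions and individuals draw genotypes Binomial(2, Σ α_c p_c).
Missing calls are masked at a configurable rate; SNP positions are
uniform within configurable chromosomes; homozygous runs can be
implanted for ROH fixtures; array ascertainment is emulated by an MAF
floor within named discovery populations. Outputs are bit-identical for
a fixed seed.

The generator reproduces the features the statistics consume — drift
structure, admixture fractions, clines, inbred isolates, missingness,
ascertainment — and deliberately omits linkage disequilibrium,
recombination maps, selection and phased haplotypes. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to LD (the jackknife block structure is exercised
but not stressed) or to array-specific artifacts beyond the MAF-floor
mechanism.

Preset study conditions, used by the test suite and the acceptance
script:

* `paper_like_config` — two wild-source outgroups (F ≈ 0.27 cumulative
  drift), a reference group at the root of the domestic radiation, an
  8-population cline whose wild-source ancestry rises 0 → 0.20, and two
  bottlenecked isolates (F = 0.30–0.35); 5,000 SNPs and 1% missingness by
  default, 20,000 SNPs where the cline must be resolved (the size of a
  typical LD-pruned array panel).
* `two_source_graph_config` — the four-population calibration graph for
  f4/f4n, 25 diploids per population and 5,000 SNPs.
* `isolate_contrast_config` — two tight regional clusters (three nearly
  undifferentiated breeds each, F = 0.001 within, 0.2 to the root) plus a
  private-drift isolate (F = 0.3, 10 individuals); the configuration in
  which an all-samples PCA devotes PC2 to the isolate while the
  remaining breeds' geometry is insensitive to excluding it.

## Design choices made where the design was open

* Declared-F1 and visually identified outlier samples are handled as a
  configured exclusion list, not an algorithm — outlier status came from
  tree topology inspection, which is not mechanizable faithfully.
* The ROH caller enforces the stated run constraints directly instead of
  reimplementing a sliding-window heuristic, so every reported segment
  re-validates against the rules; segment counts can differ slightly
  from heuristic callers near boundaries.
* svPCA uses loading-projection (standardize with the model's center and
  scale, multiply onto loadings); fit individuals reproduce their fit
  scores by construction.
* The jackknife is used for the f4n interval because a plain SD across
  SNPs ignores local correlation; the block count (100) only affects
  interval width, never the point estimate.
* Subsampling per breed, EM restarts and the simulator all take explicit
  seeds; there is no hidden global random state.

## Known limitations

* No VCF ingestion, genotype imputation, sex-chromosome handling,
  ROH-island detection, Tracy–Widom eigenvalue tests, split-network
  construction, or migration-edge tree fitting (distance matrices export
  to NEXUS for external neighbor-net drawing instead).
* The ped/map reader infers alleles from observed genotypes, so a SNP
  whose B allele is never observed reads back with dosage polarity
  collapsed to the observed allele.
* f4n inherits the small finite-sample attenuation described above; with
  very small source panels the estimate should be read with its interval,
  not as a point.
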