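# Methods

This note documents the models, estimators and numerical conventions behind
svepop, the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Data model

Genotypes are diploid, biallelic, unphased, stored as dosages of a per-locus
reference allele A1 (0, 1, 2, or missing). PED carries no reference allele,
so on import A1 is the first non-missing allele encountered at the locus,
with a lexicographic tie-break when that genotype is heterozygous; the
convention is deterministic and idempotent (reading a file the package wrote
is a fixed point). Every statistic in the package is invariant to swapping
A1/A2 (checked by tests), so the convention never affects results.
Positions are 1-based base pairs; all windowing uses half-open intervals
[start, end). Sample metadata joins on exact id; genotyped samples without
metadata are dropped with a warning rather than an error, since merged
multi-source panels rarely overlap perfectly.

## Synthetic panels

The generator emulates a national SNP survey with weak, geographically
organized structure. Ancestral frequencies are uniform on the configured MAF
range (default [0.05, 0.5], mirroring the usual MAF ≥ 0.05 ascertainment of
genotyping arrays). Differentiation follows the Balding–Nichols model:
region frequencies are Beta(p(1−f)/f, (1−p)(1−f)/f) draws around the
ancestral p with f = `f_region`, province frequencies are drawn the same way
around their region with f = `f_province`. f equals the expected F_ST of the
level, which is what makes closed-loop recovery tests possible. Defaults
(f_region = 0.004, f_province = 0.003, six provinces in three regions over a
ten-degree latitude band, ~100 samples per province) put the simulated
differentiation in the 10⁻³–10⁻² range typical of within-country European
structure.

In clinal mode each sample's expected frequency mixes its province frequency
(weight 1 − w) with a blend of two gradient frequency vectors weighted by a
normalized latitude; the latitude weight is the first component of the true
ancestry matrix `true_Q`, so its correlation with latitude is exactly 1 by
construction. Genotypes are Binomial(2, freq); coordinates are province
centroids plus isotropic Gaussian jitter (converted at 111.195 km per degree
of latitude, cos(lat)-scaled for longitude). Artifact injection overlays
per-platform missingness, near-duplicate individuals (genotype copies with
independent missingness), batch SNPs whose frequency is shifted on one
platform (clipped to [0.01, 0.99]) and random null case/control labels.
Platforms are assigned cyclically in sample order.

What the generator does **not** emulate: linkage disequilibrium between loci
(loci are independent given frequencies; LD-module tests construct
haplotype-level LD directly), genotype-calling error structure, family
relatedness beyond exact duplicates, and realistic coastline geography.
Passing recovery tests therefore demonstrates correctness of the estimators
under their sampling assumptions, not robustness to LD or call artifacts.

## Quality control

Filter order is fixed: sample call rate → SNP call rate → exact HWE within
each declared population → MAF on the whole retained dataset. The order is a
package convention (thresholds alone do not determine results); it is chosen
so that sample-level problems cannot masquerade as locus-level ones.
Defaults: 0.99 per sample (0.97 is the conventional relaxation for chips
with lower call rates), 0.95 per SNP, HWE p < 10⁻⁷, MAF 0.05.

The HWE test is the exact conditional test (sum of probabilities of all
heterozygote counts, given the allele counts, that are no more probable than
the observed count) rather than the asymptotic chi-square, because 10⁻⁷
thresholds live deep in the tail where the asymptotic test is unreliable.
The implementation is validated against full enumeration for every table
with ≤ 30 allele copies.

Near-duplicate removal links pairs with IBS distance below 0.05 and keeps,
within each connected component, the sample with the highest call rate (ties
by input order). Two-group concordance filtering removes SNPs whose 1-df
allele-count chi-square between platforms (or cases and controls) falls
below a threshold (10⁻¹⁰ and 0.1 respectively by convention); monomorphic
SNPs are never removed by it. LD pruning is greedy within sliding windows
(default 50 SNPs, step 5, composite genotype r² > 0.5 removes the
later-positioned SNP), a widely used convention exposed in config.

## IBS and MDS

The IBS distance between samples i and j is 1 − mean over pairwise-complete
loci of (1 − |dᵢ − dⱼ|/2). Missing data are handled pairwise-complete rather
than by imputation; a pair with no overlapping loci is an error. Classical
scaling double-centers the squared distances and eigendecomposes; variance
explained per axis is λₖ divided by the sum of **positive** eigenvalues.
Negative eigenvalues (non-Euclidean input, which IBS matrices are) are
excluded from both coordinates and the denominator; this reads "sum of all
eigenvalues" as "all retained axes" and is stated here because the
alternative (including negative terms) changes the reported proportions.

Comparing IBS distributions between two populations uses the Mann–Whitney U
statistic on the two sets of within-population pairwise distances. Pairwise
values sharing an individual are dependent, so the null distribution is
built by permuting individual labels and rebuilding both sets (default
10,000 permutations). The two-sided empirical p uses the symmetric statistic
|U − μ| with p = (1 + #{perm ≥ obs}) / (n_perm + 1); an exact mode
enumerates all label assignments for small groups.

## F_ST

The estimator is Weir & Cockerham's (1984) θ̂ for diploids with observed
heterozygosity: per-locus components a (among populations), b (among
individuals within populations), c (within individuals), combined as the
ratio of sums over loci. Loci monomorphic across all populations are
skipped. Negative estimates are reported as-is — truncation at zero would
bias the estimator upward precisely in the near-zero regime that fine-scale
structure studies occupy. Significance uses one-sided upper permutation
p-values, p = (1 + #{θ_perm ≥ θ̂}) / (n_perm + 1), permuting individual
labels (default 5,000 permutations). An AMOVA-style alternative would give
near-identical values for biallelic diploid data; θ̂ was chosen because it is
fully specified in the open literature and directly comparable to the
generator's drift parameter.

The hierarchical decomposition is a nested ANOVA on allele indicators with
three strata: among regions, among provinces within regions, and among
allele copies within provinces (provinces are treated as random-mating
pools, i.e. the individual level is collapsed — adequate when within-
population inbreeding is negligible, as here). Unequal-size coefficients
follow the standard expected-mean-square formulas. F_CT = σ²ₐ/σ²_tot,
F_SC = σ²_b/(σ²_b + σ²_c), F_ST = (σ²ₐ + σ²_b)/σ²_tot, summed over loci, so
(1 − F_ST) = (1 − F_CT)(1 − F_SC) holds algebraically. Permutation schemes:
whole provinces among regions for F_CT; individuals among provinces within
their region for F_SC.

Frequency- and LD-based population comparisons first downsample every
population to a common size (default 115) so that sample size does not
drive the statistics.

## Frequency scans and λ

Between-group scans use the 2×2 allele-count chi-square without continuity
correction (standard GWAS practice), on non-missing genotypes only; SNPs
monomorphic in the combined groups get χ² = 0, p = 1 and a flag that
excludes them from λ. The overdispersion factor sorts the m statistics,
keeps the smallest ⌊0.9 m⌋, pairs rank i with the χ²₁ quantile at
(i − 0.5)/m, and reports the ratio of means. Two conventions are worth
stating: expected order statistics are approximated by quantiles (the
difference is O(1/m), negligible at genome scale), and each retained
observed order statistic is paired with the same-rank quantile of the
*full* distribution rather than a re-normalized truncated one. λ = 1 means
the two groups are samples of one population; the acceptance suite verifies
1.00 ± 0.02 on a 50,000-SNP null panel of 2 × 115 diploids.

Nearest-gene annotation reports the minimal bp gap (0 inside the gene),
omits genes beyond 200 kb, and lists both genes on an exact tie with the
lower-start gene as primary. Interval-enrichment counts compare observed
significant SNPs inside intervals with the genome-wide significant fraction
via an exact binomial tail; the output carries an explicit caveat flag
because adjacent SNPs are correlated through LD and the binomial p is
anti-conservative.

## Linkage disequilibrium

Two-locus haplotype frequencies come from the standard EM over unphased
diploids: every genotype pair except the double heterozygote determines its
haplotypes; the double-het count is split between coupling and repulsion
phases by their current expected proportions. Initialization is at linkage
equilibrium with a single start (the two-locus likelihood is well behaved in
practice; a multi-start option exists for pathological inputs); iteration
stops when the log-likelihood gain drops below 10⁻⁸, and monotonicity of the
log-likelihood is asserted on every run. D′ is D normalized by its maximum
attainable magnitude given the allele frequencies, reported in [0, 1].

Pair sampling draws n index SNPs uniformly without replacement and pairs
each with every same-chromosome SNP within 500 kb; mutual-neighbor
duplicates are removed. Decay profiles report median D′ in windows
[s, s + 40 kb) anchored at multiples of 10 kb (the window/step sizes are the
field convention; the anchoring is a package choice). Paired population
comparisons use the Wilcoxon signed-rank test with zero differences dropped:
an exact distribution computed by dynamic programming over doubled midranks
when ≤ 25 non-zero differences remain (this handles ties exactly, which
off-the-shelf exact implementations refuse), otherwise the normal
approximation with tie-corrected variance.

## Spatial statistics

Geographic distances are haversine great circles on a sphere of radius
6371.0088 km (IUGG mean). The Mantel test correlates upper-triangle entries
and permutes one matrix's rows and columns jointly; p is one-sided upper.
Inbreeding coefficients use the small-sample-corrected expected homozygosity
1 − 2p(1−p)·2n/(2n−1) per locus from whole-sample frequencies, giving
F = (O_hom − E_hom)/(L − E_hom) per individual over its non-missing
polymorphic loci. Regional distributions are compared with the tie-corrected
Kruskal–Wallis test.

Grid statistics cover the sample bounding box with a regular lat/lon grid
(default spacing 25 km — the smoothing radius makes results insensitive to
spacing) and evaluate, per grid point, the samples within 150 km: the median
of a per-sample value (inbreeding, ancestry) when at least 20 members are
present, or the Pearson correlation between genetic and geographic pairwise
distances when at least 40 members are present. The 40 is read as a
sample count (≥ 780 pairs), and the local correlation is a plain Pearson r
without a permutation p — both conventions noted because the alternatives
(40 pairs; Mantel r per cell) are defensible.

## Admixture and ΔK

The admixture model: each of an individual's two allele copies at locus l
originates in cluster k with probability q_ik and is A1 with probability
f_kl, so the dosage is Binomial(2, Σₖ q_ik f_kl). Q and F are estimated by
EM (the classic maximum-likelihood admixture formulation); missing genotypes
are skipped in the likelihood. The likelihood is multimodal for K ≥ 2, so
the fit runs several random restarts (default 3) and keeps the best; F is
clipped to [10⁻⁶, 1 − 10⁻⁶] each iteration to keep logarithms finite, a
numerical guard with negligible bias. K = 1 is closed-form (sample
frequencies). Cluster labels are identifiable only up to permutation; all
recovery comparisons align clusters by the error-minimizing permutation.
Plain EM approaches the optimum slowly near convergence: ancestry recovery
to MAE < 0.05 on a clearly separated two-population panel needs on the order
of 500–1000 iterations, which is the package's default operating point for
desk-scale panels (hundreds of samples, thousands of SNPs).

A Bayesian MCMC treatment of the same likelihood family (Dirichlet priors,
burn-in) is deliberately out of scope; the ΔK selection statistic consumes
final log-likelihoods from replicate runs of any tool. For interior K,
ΔK = |L̄(K+1) − 2 L̄(K) + L̄(K−1)| / sd(L(K)); it requires at least three
consecutive K values and two replicates per K with positive sd.

## Barriers

Pairwise F_ST is first regressed (OLS with intercept) on great-circle
distance between population centroids; the residuals isolate genetic change
not explained by geography. Monmonier's maximum-difference algorithm then
runs on a Delaunay triangulation of the centroids, each edge weighted by its
endpoint pair's residual: a barrier starts across the globally
maximum-weight unused edge and grows from both ends, at each step crossing
the heavier of the two remaining edges of the triangle just entered,
stopping at the convex hull or at an already-crossed edge. Ties break by
sorted population-pair index, and no edge is ever crossed twice, so barriers
always terminate and the output is invariant to uniform scaling of the
residuals. Only the residual-distance variant is the default (raw-F_ST mode
is available behind a flag).

## Pipeline and reproducibility

The pipeline executes qc → ibs/mds → fst → frequency scan → ld → spatial →
admixture → barrier, writing every table as TSV plus a JSON manifest with
versions, thresholds and per-stage seeds. A master seed spawns per-stage
seeds through numpy's `SeedSequence`, so any stage can be re-run in
isolation; reruns with the same config are bit-identical for deterministic
stages. Permutation counts default to 5,000 (F_ST) and 10,000
(Mann–Whitney); `--fast` scales them down for smoke runs. Stage failure
halts the run with the stage name, persisting partial outputs and the
manifest.

## Problem sizes used in the test suite

The statistical checks run at desk scale chosen to make each property
measurable with margin: 50,000 SNPs × 230 samples for λ calibration; 20,000
SNPs × 400 samples × 10 seeds per drift level for θ recovery (15% relative
tolerance reflects the sampling sd of the mean across seeds); 5,000 SNPs ×
300 samples with 5,000 permutations for the significance floor; 99
permutations × 200–300 replicates for the null-uniformity (KS) checks;
5,000 SNPs × 200 samples for ancestry recovery. The pipeline smoke test
uses a deliberately small panel (400 SNPs, 120 samples) since it checks
plumbing, not statistics.

## Known limitations

- The generator's independent-loci assumption means LD-dependent behaviour
  (pruning effectiveness, interval-enrichment calibration) is exercised only
  on constructed examples.
- The hierarchical decomposition collapses the individual level within
  provinces; with substantial within-population inbreeding F_SC would absorb
  part of it.
- The exact Mann–Whitney and Mantel modes enumerate assignments and are
  usable only for a handful of individuals; large-sample inference is
  permutation-based.
- Plain EM for admixture converges slowly near the optimum; quasi-Newton
  acceleration is a natural extension for panels beyond desk scale.
- Barrier significance is not propagated; the underlying pairwise F_ST
  permutation p-values are exported instead.
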