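# Methods notes

## The problem and the data model

The pipeline detects and genotypes polymorphic chromosomal inversions from
diploid biallelic SNP genotypes when the reference assembly is too
fragmented for breakpoint or LD-based methods. The only positional
information used is the placement of contigs on a genetic map: each contig
gets one averaged centimorgan position per linkage group, every SNP
inherits its contig's position, and all detection operates on 1-cM
non-overlapping windows (half-open intervals `[w, w+1)`, window index
`floor(cM)` — a convention chosen so windows partition the map with no
double counting).

Genotypes are stored as alternate-allele counts 0/1/2 with −1 for missing;
phase is never used (heterozygosity only needs the value 1).

### Filters

* SNP filter: biallelic, mapping quality ≥ 30, MAF ≥ 0.05, mean allele
  depth within [5, 35] (bounds inclusive; the rule is "extreme depth
  removed"), and contig present on the map.
* Map-marker filter: within each contig, markers on a non-modal linkage
  group are dropped (modal-LG ties go to the smaller LG id); markers more
  than 2 cM from the contig's average position are then trimmed
  *greedily* — drop the most deviant marker, recompute the mean, repeat
  until all survivors are within 2 cM. A single non-iterative pass against
  the initial mean would let one extreme outlier drag the mean far enough
  to disqualify every marker of an otherwise consistent contig; greedy
  trimming removes exactly the outliers (e.g. markers at 10.0, 10.5,
  30.0 cM keep {10.0, 10.5}, mean 10.25).
* Boundary transfer: for each inversion the widest anchored interval is
  adopted (min cM over left anchors, max over right). Two regions carry
  hand-set windows to avoid overlap with neighbouring inversions
  (LGC14.3: 12–34.66 cM; LGC12.3: 46–50.09 cM).

## Heterozygosity-split segmentation

Observation unit: per-contig pairs (k heterozygous, n genotyped SNPs).
Contigs are the natural block on a fragmented map and carry the
between-block overdispersion that the beta-binomial dispersion ρ
(intraclass correlation) absorbs; a plain binomial would anti-conservatively
sharpen every likelihood-ratio test.

The fit maximises the beta-binomial likelihood in the (μ, ρ)
parameterisation (beta mean μ, intraclass correlation ρ) by L-BFGS-B with
analytic gradients; bounds μ ∈ [1e-6, 1−1e-6], ρ ∈ [1e-6, 0.995]; ρ → 0
recovers the binomial. Split models (two means, shared ρ) are warm-started
at the no-split optimum, which guarantees LL₁ ≥ LL₀ numerically.

Candidate boundaries are the 1-cM window edges with at least one contig on
each side; ties in likelihood go to the smallest cM position. The LRT uses
1 df (one extra mean; ρ is re-estimated under each model, with "the same
dispersion" read as shared between the two segments of one split model).
Acceptance threshold p < 0.01; recursion depth 3, so a linkage group yields
1–8 segments. Segments tile `[lg_start, lg_end]` (defaults 0 to the ceiling
of the last contig position).

The split-cluster permutation test counts accepted split positions per 1-cM
window (a split at integer boundary c is counted in window c−1, its left
window), takes the variance of 3-cM sliding sums as the statistic, and
redistributes the total count multinomially (uniform) over marker-bearing
windows, 10,000 replicates by default. Empirical p-values use the +1
correction, so p = 1/(reps+1) is the smallest attainable value and zero
splits return p = 1 with a degenerate flag. BH correction is applied across
all (linkage group × genetic group) tests of one run.

Calibration: with ~40 contigs per segment the per-candidate LRT fires at
roughly 1.0–1.3% under the null at the 1% threshold (mild small-sample
inflation); the best-of-all-candidates rule is a maximum over correlated
tests compared to a single-test reference, so the per-linkage-group
false-split rate is a few percent, not 1%. The group-level permutation
test, not any single split, carries the detection decision.

## Window PCA and orientation

Per window, genotypes are mean-imputed per SNP (so an all-missing
individual scores ≈ 0), centred and scaled to unit variance; monomorphic
SNPs are dropped before scaling, and fully monomorphic windows are flagged
and skipped. PC sign is arbitrary, so PC1 profiles are chained left to
right: a window negatively Pearson-correlated with its already-oriented
predecessor is negated; zero-variance pairs leave the sign unchanged with a
flag. The chain is idempotent. Only PC1 carries detection; PC2 is kept for
complex (three-arrangement) regions.

Region PCAs store their centring/scaling vectors and loadings so outgroup
individuals can be projected onto the fitted axes without refitting
(projection stops interspecific divergence from dominating the axes).
Colinear control PCAs exclude every inversion ± a 2-cM buffer and raise an
explicit "mostly covered" error when nothing informative remains, mirroring
the exclusion of linkage groups that are nearly all inversion.

## Karyotyping

K-means with 100 random starts keeps the start with the highest
between-group sum of squares (equivalently the lowest within-group sum of
squares, since the total is fixed — scikit-learn's best-inertia rule). The
silhouette (Euclidean, on the same score space as the clustering) selects
K ∈ {2,3} on PC1 for simple regions and K ∈ {2..9} on (PC1, PC2) for
complex regions; K values whose best partition contains a cluster of size
< 2 are skipped, ties go to the smaller K.

Labelling: for K = 3 the PC1-extreme clusters are the homokaryotypes and
the crab-richest of them is RR (ties → lower mean PC1; with no crab
samples at all, the lower-PC1 rule applies with a warning). For K = 2 the
second cluster is RA rather than AA when its mean region heterozygosity
exceeds the RR cluster's by more than 50% relative (heterokaryotypes carry
two diverged haplotypes); the threshold is configurable and the choice is
recorded. For complex regions the three mutually most distant cluster
centroids in (PC1, PC2) are the homokaryotype vertices — the automatic
analogue of reading the "triforce" by eye — RR is the crab-richest vertex,
A1A1 the vertex furthest from RR on PC1, and every inner cluster is named
by its two nearest vertices. Manual label overrides are supported through
an explicit table and always warn; nothing is adjusted silently.

Identifiability: when arrangement frequencies do not differ between
ecotypes the crab anchoring of "R" is undefined, so simulation-based
recovery is scored up to a global R↔A polarity flip of the region. This is
a property of the naming convention, not of the genotyping.

## Association ladder

Response: per individual, the count of A alleles out of 2 (A1 and A2 both
count toward A). Binomial GLMs with logit link are fitted at the individual
level. The ladder follows the ΔAIC > 2 rules exactly: an ecotype effect
requires AIC_Null − AIC_Eco > 2; Eco then beats Int only when
AIC_Int − AIC_Eco > 2 and loses only when AIC_Eco − AIC_Int > 2; inside the
±2 band the simpler model is reported with an `ambiguous` flag (the source
rules are silent on the tie band). Without an ecotype effect, Null and Int
are compared the same way. With a single shared location the location term
drops (Null = intercept only) and Int is not fitted.

Pseudo-R² is 1 − residual deviance / null deviance, clipped to [0, 1] and 0
by construction when Null wins. (The reciprocal orientation sometimes seen
in print, 1 − null/fitted, goes negative for any improving model; the
standard orientation is used here.) The p-value comes from the deviance
drop of the focal term: ecotype (1 df) when Null or Eco is best, the
interaction (#locations − 1 df) when Int is best. BH correction is applied
within each contrast family across regions (`run_contrasts` exposes the
family choice).

Because the reported p follows model selection (the interaction term when
Int wins), the mixed family of reported p-values is post-selection and the
naive rule "BH-adjusted reported p ≤ 0.05" rejects more often than the
nominal level on pure-null regions. The BH guarantee holds for a fixed term
family; `AssociationResult.p_eco` therefore always carries the 1-df ecotype
main-effect p so FDR-controlled screening for ecotype-associated inversions
can be done on a single consistent family, while `p_raw` reports the
best-model focal term for interpretation.

Degenerate strata (an ecotype×location cell fixed for one arrangement)
produce separation; the fit is stabilised with a small Haldane-style
continuity adjustment (0.25 allele pulled toward the centre per individual
in the degenerate cell) and flagged `separation_adjusted`. Units of
analysis are alleles (2 per individual); within-individual dependence is
ignored, as the count formulation implies.

## The simulator

What it emulates: (a) geographic structure — per-location allele
frequencies are Balding–Nichols beta draws around a global frequency with
variance set by a single F_ST knob; global frequencies are Beta(α, α) with
α = θ/(1−2θ) so the expected background heterozygosity is θ (the realised
within-location value is θ(1−F_ST), exposed as
`effective_background_het`); (b) inversions — each arrangement carries its
own haplotype; a fraction *d* of region SNPs are fixed differences between
arrangements (*d* is the one knob for inversion age/divergence), the rest
share the background frequency; three-arrangement regions split the fixed
differences into three equal pattern groups (R-specific, A1-specific,
A2-specific) so every pair of arrangements differs at ~2d/3 of region SNPs
and the six-cluster PCA geometry emerges; (c) karyotypes — two arrangement
copies drawn independently from the population's arrangement frequencies
(Hardy–Weinberg); (d) missingness — uniform at random.

Closed-form oracle: inside a region the expected per-SNP heterozygosity is
`d_pair + (1 − d)·θ_eff`, where `d_pair` is the fraction of region SNPs at
which the two carried arrangements differ (d for simple heterokaryotypes,
2d/3 for complex ones, 0 for homokaryotypes). Hence young-inversion
homokaryotypes have *reduced* heterozygosity `(1−d)·θ_eff` and
heterokaryotypes elevated heterozygosity, which is exactly the signal the
split scan detects.

What it does not emulate: linkage disequilibrium in the colinear background
(SNPs are independent; the permutation nulls assume exchangeability across
windows, so LD realism is out of scope), coalescent haplotype structure or
gene flux within arrangements, selection, and non-random missingness.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness to LD, reference bias
or structured missingness in real data.

Default study conditions: one 30-cM linkage group, 5 contigs and 40 SNPs
per cM, two locations × two ecotypes × 20 snails, θ = 0.2, F_ST = 0.05,
5% missing, one inversion at [5, 15] cM with d = 0.6 and frequency 0.5 —
small enough for desk-scale replication, large enough for every stage to
have power.

## Problem sizes used in verification

Chosen as the package's own desk-scale study design: segment-bound fuzzing
uses 1,000 profiles (10% dense 12-level staircases that saturate the
three split levels); cluster-count checks use n = 120 at d = 0.8;
change-point recovery uses 50 replicates of n = 40 at d = 0.6; type-I
control uses 200 colinear replicates (~29 candidate boundaries each);
karyotype recovery uses 8 replicates per cell of the d ∈ {0.5, 0.8} ×
freq ∈ {0.2, 0.5, 0.8} grid at n = 80; the no-effect arm of the model
ladder uses 1,000 replicates (the 90% bar needs ~1% Monte-Carlo error to
resolve, since the true Null-selection rate under four locations is ≈ 91%);
effect and interaction arms use 100 and 50 replicates; FDR behaviour uses
20 replicates of 19 regions with 3 true effects.

## Known limitations

* The χ²₁ reference for the best-of-candidates split is anti-conservative
  at the linkage-group level (see calibration note); detection authority
  rests with the permutation cluster test.
* Binary segmentation cannot recover alternating-mean patterns whose
  single best split shows no contrast; monotone or isolated steps are the
  designed use case.
* K-means on PC1 assumes roughly equidistant karyotype clusters; strongly
  unbalanced cluster sizes can shift the silhouette toward K = 2, in which
  case the heterozygosity rule decides RA vs AA.
* The ancestral-arrangement call is a nearest-centroid heuristic on
  projected scores and is only as good as the outgroup sample size.
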