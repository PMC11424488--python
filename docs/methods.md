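# Methods

This note documents the models, numerical choices and limitations of
`tumordiv`. It is the package's own account of its science; every empirical
statement here is computed by the test suite or by `scripts/acceptance.py`.

## Copy-number model

A biopsy is modelled as a fraction ρ ∈ (0, 1] of tumor cells with integer
total copy number n per 500-kb bin, mixed with diploid normal cells. The
observed signal is the log2 ratio of normalized coverage,

r = log2((ρ·n + 2(1−ρ)) / (ρ·ψ + 2(1−ρ))),

with ψ the tumor ploidy, plus iid Gaussian noise per bin, then median-centred
(the same normalization low-pass pipelines apply). B-allele frequencies are
not modelled; all copy numbers are total.

**Identifiability.** Median-centring applies a constant shift to r, which the
mixture equation absorbs into ψ: the fitted ploidy is defined relative to
the median bin's copy number, not the generating ψ. For majority-diploid
genomes the two coincide. Lattice ambiguity is intrinsic: for a single
sample, several (ρ, ψ) pairs can map every segment mean onto integers,
especially at low purity or when a genome-doubled lattice fits noise
slightly better. Ties in the single-sample search break toward ψ nearest 2
and then the highest purity; a flat profile is reported with ψ from the best
grid cell and the purity flagged unidentifiable.

**Multi-sample search.** `fit_participant` sums each candidate ψ's
best-purity goodness across a participant's samples, adds a weak ploidy
parsimony penalty (0.01 per ploidy unit, enough to reject spurious doubled
lattices but far below the separation between genuine solutions), picks the
shared ψ, and refines each sample within ±0.3 of it. On the default noisy
study conditions this recovers bin-exact copy number in roughly 80–90% of
samples where single-sample fits recover far fewer; with no noise, recovery
is exact (this is the round-trip acceptance check). The per-sample search
with a participant context instead augments goodness with a concordance
penalty toward the context's median rounded ploidy; this is a documented
stand-in, since the original multi-sample procedure is described only in
non-public supplementary material.

**Segmentation.** Penalized least-squares piecewise-constant fitting by exact
dynamic programming per chromosome, breakpoints shared across samples in
multi-sample mode. The penalty γ (15 tissue, 10 cfDNA) is expressed in units
of per-sample noise variance: each profile is standardized by a MAD-of-first-
differences noise estimate before the fit, matching the convention of the
R `pcf`/`multipcf` implementations the field uses. Noise-free input makes
the estimate zero; the fit then falls back to a vanishing penalty, which
splits exactly at true steps and nowhere else. The dynamic program is
validated against exhaustive enumeration of all breakpoint subsets on
profiles of up to 12 bins, plus the 40-bin noise-free step case.

**Derived quantities.** PGA counts bins off the rounded baseline ploidy,
with sex-chromosome bins compared to round(ψ/2) (male cohort). Focal
amplifications require z > 3 (z computed from the sample's bin-level log2
mean and SD — the bin/segment choice is not pinned by the source text;
bin-level chosen) over more than 3 and fewer than 20 bins, strict on both
ends. Arm status compares the arm's median bin copy number to the baseline.
The cfDNA fragment filter keeps insert sizes in [90, 150] inclusive.

## Minimum-event distance and phylogenies

An event adds or subtracts one copy over a contiguous run of bins; copy
number is floored at zero and zero is absorbing (an amplification cannot
rescue a lost segment, and events may span absorbed bins without effect).
The distance from profile p to q is the minimum number of events, computed
by a dynamic program over deletion/amplification coverage profiles: there
is always an optimal solution with all deletions before all amplifications,
the number of events equals the total positive increment of the two coverage
functions along the genome, and absorbed positions leave their coverage
unconstrained. The DP state is the (deletion, amplification) coverage pair;
transitions are separable min-plus transforms, so each position costs
O(U·V) with U, V bounded by the maximum copy numbers. Distances are computed
per chromosome and summed (events never span chromosome boundaries). The DP
is validated exhaustively against breadth-first search over event sequences
for all profile pairs of length 3 with copy number ≤ 4 and for sampled
sources at lengths 4–6 (the all-pairs space at length 6, ~2.4×10⁸ pairs, is
not enumerable in reasonable time; sources are sampled and all 15 625
targets checked per source).

Zero-absorption makes the distance asymmetric; the neighbor-joining matrix
uses the mean of the two directions when both are finite, else the finite
one. Trees include an artificial diploid root taxon (copy number 2, 1 on
sex chromosomes), are rooted on the edge leading to it with the full pendant
length kept on the tree side, and branch event counts are branch lengths
rounded half-up with negative lengths clamped to zero. Total events sum all
branches; subclonal events sum branches strictly below the tumor MRCA;
subclonality is their ratio (undefined for event-free trees). Samples with
PGA < 0.01 are excluded; fewer than two qualifying samples yield no tree.
Neighbor joining can split shared events between the root pendant and the
truncal branch, so simulated event totals are only guaranteed within ±1 per
branch — the tolerance the recovery checks use.

**Sidedness.** The left/right trait (right = 1, left = 0, other = 0.5,
parsed from location labels) is tested for phylogenetic signal with Pagel's
λ: the Brownian trait covariance between two tips is the depth of their
MRCA, off-diagonal entries are scaled by λ ∈ [0, 1], and μ and σ² are
profiled out analytically. The λ maximum-likelihood estimate uses a bounded
scalar optimizer cross-checked against the endpoints, with a likelihood
ratio test against λ = 0 (χ², 1 df). The diploid root is pruned before the
covariance is formed; the covariance diagonal carries a 10⁻⁶ jitter against
zero-length-branch degeneracy. A constant trait has no estimable signal and
is reported as failed rather than given a value. The ML estimate is required
to match a dense λ-grid maximization within 0.01. λ > 0.8 is classified
side-clustered ("strong"), λ < 0.2 side-mixed.

## Variant rules

The multisample cascade applies its six rules in a fixed order and logs the
first failure per record, so survivors of the full cascade are a subset of
survivors of any prefix. VAF-ratio clauses are strict (>, "ten times
greater"). The clonality sentence is ambiguous; the default reads clonal ⇔
VAF > 0.05 in *all* tumor samples (truncal interpretation), with the
alternative reading (`rule="any"`) behind a switch. Clonality is refused for
participants with fewer than three tumor samples. Multiplicity assumes a
clonal mutation (cancer cell fraction 1): m = VAF·(ρ·CN + 2(1−ρ))/ρ, m is
linear in VAF and equals VAF·CN at ρ = 1; homozygosity at m > CN − 0.5.
SSAR flagging measures the window between primary and secondary alignment
start positions and requires the same chromosome. Calling engines,
annotation and dN/dS are upstream tools, out of scope; the VCF reader maps
GT:DP:AD:GQ and site FILTER flags onto the internal records.

## Morphology

Slide scoring ranks tumor patterns (3/4/5) by pixel area. The conversion of
a segmentation map to a primary + secondary score is not fully specified in
public sources; the package uses a 5% secondary floor (a second pattern
below 5% of tumor area does not alter the score), a standard pathology
convention. ISUP 2014: 3+3→1, 3+4→2, 4+3→3, total 8→4, total 9–10→5.
Continuous Gleason is the tumor-pixel-weighted mean pattern, in [3, 5].

The Morisita-Horn overlap M = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y) is used as
the Morisita variant (bounded [0, 1], scale-invariant, symmetric). Quadrats:
Voronoi cells of k-means centroids over all cell coordinates
(k = max(10, ⌈n/100⌉), fixed seed; nearest-centroid assignment is exactly
Voronoi membership), a 50×50 rectangular grid over the cell bounding box, or
50×50 pixel-area quadrats on the label raster. Gleason Morisita is defined 0
when primary = secondary. Quadrat counts only carry information when the
expected count per quadrat is well above 1; with the 50×50 grid this needs
on the order of 10⁵ cells per slide, which is the realistic density of a
whole-slide section and what the synthetic slides provide where the grid
mode is exercised. Patient aggregation: grade group is the tumor-area-
weighted mean of slide grade groups rounded down (so patient grade group 5
requires every cancer slide to be grade group 5), Gleason Morisita is the
median across cancer slides (the mean is also reported), continuous Gleason
the area-weighted mean. Non-cancer slides are excluded.

## Outcome statistics

Burden metrics (mPGA, max PGA, lossness, total and subclonal events) enter
models as natural logs; subclonality as e^x ("exponent" read as the natural
exponential); everything else raw. Spearman divergence splits at the upper
tertile, other metrics at the median; quantiles use linear interpolation,
median ties go to the lower group, the tertile boundary value to the upper
group. Continuous covariates are rescaled so the 5th and 95th percentiles
map to 0 and 1 (values outside the band map outside [0, 1]; zero spread is
an error), making a Cox HR the hazard increase across that band. The
univariate screen fits each metric continuous and binary and admits Wald
P < 0.1, preferring the continuous form when both qualify. Cox fits use
lifelines (Efron tie handling); non-convergence and collinearity raise with
diagnostics. Mixed models use a random intercept per participant with a
Wald z test on the gradient (the Satterthwaite t of lmerTest is not
available in statsmodels; at the cohort sizes involved the difference is
immaterial and the recovery checks pass at their stated tolerances). The
per-arm scan emits a model only beyond 10 observations of the direction and
adjusts P values by Benjamini–Hochberg within each dependent variable.

## Synthetic study conditions

Defaults, fixed once: 400 bins over four autosomes plus chrX (80 bins each,
split into p/q arms), a two-subclone tree (one truncal loss, one private
gain and one private loss, each a single contiguous event of 5% of the
genome), 3–6 samples per participant alternating between subclones, purity
uniform on [0.3, 0.8] (realistic needle-biopsy cellularity), ploidy 2,
log2-ratio noise SD 0.1 (typical low-pass residual scale). Cell slides are
uniform point patterns on the unit square with 10% immune and 20% stromal
cells by default; pattern layouts are half-plane (segregated), fine
checkerboard (interleaved, 100×100 so both patterns mix within any quadrat
scheme in use) or a tunable blend. Variant tables draw binomial read counts
at the VAF implied by multiplicity, purity and copy number, with subclonal
sites present in a strict subset of samples. Survival is exponential with
hazard ∝ exp(β·x) and independent exponential censoring.

What the generators do not emulate: GC/mappability artifacts, wavy bins and
outlier bins in real low-pass data; segmentation-error correlation across
samples; non-uniform cell density, tissue folds and classifier error in real
slides; subclonal cancer-cell fractions below 1 in the variant model; and
non-proportional hazards. Passing tests therefore demonstrate correctness
of the rules and estimators under the stated models, not robustness to
those artifacts.

## Problem sizes

The test suite and acceptance script run at deliberately desk-scale sizes,
chosen as the smallest where each check is statistically meaningful: 3–12
participants × 3–6 samples × 400 bins for cohort work; exhaustive BFS at
profile length 3 and sampled lengths 4–6; 150 replicates for the null screen
rate; n = 500 for Cox recovery; 50 replicates at n = 300 for log-rank power;
50 slides of 6 000 cells for the quadrat-robustness property and 80 000
cells where a single dense-grid slide is needed.
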