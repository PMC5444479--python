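# Methods

This note documents the models, numerical choices and limitations of
`seedmqtl`. It is written for users deciding whether the pipeline's
assumptions fit their data and for maintainers changing defaults.

## Population model and genotype probabilities

The pipeline targets biparental recombinant inbred lines produced by
selfing (single-seed descent). Genotypes at a locus are modelled as the
two parental homozygotes, `AA` (first parent, Col-0-type in the
motivating design) and `BB` (second parent, C24-type). Residual
heterozygotes — an F10 population carries about (½)⁹ ≈ 0.2% — are
treated as missing observations rather than as a third hidden state.
This keeps the RIL transition matrix exactly two-state at negligible
information loss; the expected-dosage regression then handles partial
information naturally.

Conditional genotype probabilities are computed per chromosome by a
forward–backward pass over a grid containing every marker plus 1 cM
steps (`ScanConfig.step_cm`). Between adjacent grid positions at map
distance d, the meiotic recombination fraction is the inverse Kosambi
map function r = ½ tanh(2d) (Haldane r = ½(1−e^(−2d)) available via
`map_function="haldane"`), and the generation-accumulated probability of
observing a recombinant genotype between the positions is the
Haldane–Waddington fixation value R = 2r/(1+2r). Emissions use a
symmetric genotyping-error model: the observed call equals the true
homozygote with probability 1−ε, the other with probability ε
(ε = 10⁻⁴ by default); heterozygous and missing calls are
uninformative. Forward and backward vectors are renormalized at every
step, so no log-space arithmetic is needed at these chromosome lengths.
The posterior is exact: tests compare it to brute-force enumeration
over all hidden-state sequences at 10⁻¹⁰.

## Scans and thresholds

`scan_hk` regresses the trait on the expected dosage
x = P(BB) − P(AA) ∈ [−1, 1] at each grid point and converts the fit to
LOD = (n/2) log₁₀(RSS₀/RSS₁). For a single added regressor this equals
−(n/2) log₁₀(1−ρ²) with ρ the (residual) correlation, which is how the
scan, the permutation engine and the covariate scans are vectorized
(one matrix product per scan). Traits with zero variance return a flat
zero curve with a warning; fewer than 10 informative individuals is an
error.

`scan_cim` forward-selects `cim_covariates` (default 5) marker dosages
by greedy RSS reduction, then excludes any covariate within half the
window (default 20 cM window, so ±10 cM, same chromosome) from the
local model at each scan position. Grid positions sharing an
active-covariate set are fitted together. The comparison model is the
covariate-only fit, so CIM LOD is the gain of the tested position over
the selected background.

Permutation thresholds shuffle trait values against intact genotypes
and take the type-7 (linear-interpolation) quantile of the
per-permutation genome-wide maximum LOD at 1−α (α = 0.05, 10 000
permutations in the study configuration; tests and examples scale the
permutation count down — the quantity estimated is the same). All
permutations derive from the stage-named child generators of
`rng_for(seed, stage)`, so a single seed reproduces every threshold.

1.5-LOD support intervals take the contiguous grid region around the
apex (ties broken leftmost) with LOD ≥ apex − Δ, then expand both ends
outward to the nearest true markers; chromosome ends cap the expansion.
A flat curve yields the whole chromosome with a warning.

## Two-QTL scans and penalties

`scan_two` evaluates all position pairs on a coarser grid (default
2.5 cM) against the full model (two dosages plus their product) and the
additive model. The genotype-only Gram blocks of every pairwise design
are assembled from five matrix products and pseudo-inverted once;
each trait or permutation then costs only the right-hand sides. This is
what makes 3000 two-dimensional permutations tractable. LOD_int =
LOD_full − LOD_add is clipped at 0 (the models nest; small negative
values are numerical noise), and LOD_fv1 = LOD_full minus the better
single-QTL LOD of the pair.

`derive_penalties` follows the standard penalized-LOD construction:
main = (1−α) quantile of permuted single-scan maxima; heavy = (1−α)
quantile of permuted max LOD_int; light = (1−α) quantile of permuted
max LOD_fv1 minus the main penalty, clipped into [0, heavy]. The light
penalty is a difference of quantiles and therefore not monotone in α;
only main and heavy carry that guarantee.

## Stepwise multiple-QTL search

The search state is (QTL grid positions, interaction pairs). The
penalized LOD charges `main` per QTL; interactions are charged per
connected component of the QTL–interaction graph: one interaction at
the light penalty, the rest at heavy. Forward moves consider (i) the
best additive QTL anywhere (via a covariate-residualized scan), (ii)
any new interaction between model QTLs, and (iii) a new QTL added
jointly with an interaction to an existing QTL — move (iii) is what
finds masking epistasis, whose modifier locus has no marginal effect.
The forward phase runs to the model cap (10 QTLs, 5 interactions),
recording the best pLOD model visited; the backward phase deletes
elements one at a time down to the empty model, again recording; the
best model overall is position-refined by one-dimensional re-scans
(two sweeps) and refitted. New QTLs must sit ≥ 10 cM from model QTLs on
the same chromosome, which prevents rank-degenerate designs on the
1 cM grid. An empty model is returned when no move achieves positive
pLOD.

The final fit reports per-QTL additive effects as regression
coefficients on the ±1 dosage — i.e. (BB−AA)/2 contrasts in trait
units — per-QTL R² as type-III drops 100·(RSS_without − RSS_full)/TSS,
per-QTL LOD as drop-one LODs, and support intervals from drop-one LOD
profiles along each QTL's chromosome. Under linkage the per-QTL R²
need not sum to the combined R²; each is individually ≤ combined.

## Hotspot test

Every QTL apex is assigned to the nearest marker on its chromosome
(midpoint ties to the lower-cM marker). The null re-places each trait's
QTLs uniformly at random on distinct markers (without replacement
within a trait — a trait cannot map twice to one marker; a
with-replacement variant exists behind the `distinct` flag), traits
independent, and records the maximum per-marker total; the threshold is
the smallest integer c with empirical P(max ≤ c) ≥ q (q = 0.95, 10 000
replicates). The null depends on the per-trait count vector only
through weak moments: alternative partitions consistent with the same
totals shift the threshold by at most one count (tested). An analytic
cross-check treats the per-marker count as Poisson with mean
(total QTLs)/(markers) and brackets the quantile between a union-bound
lower construction and an independence-approximation value; at the
study scale (786 QTLs, 138 markers) both the simulation and the bracket
give 15. Hotspots are annotated with member traits and the medians of
the member QTLs' support-interval bounds (cM and, via anchors, bp).

## Preprocessing

Order of operations: (1) divide by seed weight, (2) divide by
internal-standard intensity, (3) per trait, divide by the
measurement-day median rescaled to the grand median (a per-batch
variant via `group_by="batch"`), (4) outlier removal at
median ± 4·SD (sample SD, n−1; applied once, not iterated; a constant
trait has SD 0 and passes through), (5) Box–Cox power transform with λ
maximizing the profile likelihood on the fixed grid [−2, 2] step 0.01
(λ = 0 → log; traits with non-positive values receive a documented
positive shift first), (6) presence filter keeping traits observed in
strictly more than 85% of samples (complete traits always survive a
threshold of 1.0). Sample-level corrections run before trait-level
statistics so outlier bounds and transforms see comparable values;
whether outlier removal precedes the transform is recorded in the audit
so both variants can be compared. Samples with zero/missing seed weight
or internal standard are excluded and logged. Protein content uses the
same group-median correction plus concentration × buffer volume /
seed count.

## Multivariate analyses

Correlations are pairwise-complete Pearson with two-sided p-values and
Benjamini–Hochberg adjustment (step-up; q_(i) = min_{j≥i} p_(j)·m/j),
cross-checked against both a brute-force implementation and
statsmodels. The sign split is reported both over all pairs and over
FDR-significant pairs, since either convention is defensible. PCA
centers each trait and divides by the square root of its standard
deviation (Pareto scaling), imputes missing values by trait means
(deterministic; at most 20% missing per trait), and uses the SVD;
variance fractions are eigenvalue shares. PC scores are exported as
ordinary mapping traits. The Mantel test correlates off-diagonal
simple-matching similarity structures with row/column permutations and
the (b+1)/(n+1) p-value estimator (scikit-bio backend). The
reciprocal-subset check is a two-way fixed-effects ANOVA (type-II sums
of squares), falling back to main effects when a cell is empty. The
four-group epistasis display drops heterozygous/missing calls,
median-divides only when the median is positive (dividing by a
negative median would flip orderings), and letters groups by Tukey HSD
with a compact-letter-display insertion algorithm; groups under 4
members are omitted with a note.

## Candidate genes

Support intervals map to physical windows [bp(lo_marker),
bp(hi_marker)] (1-based inclusive); genes count as in-window on any
overlap, since support intervals are conservative outer bounds. A gene
is a *direct* candidate when linked to a reaction with the query
metabolite as substrate or product, *indirect* when it belongs to any
pathway containing the metabolite (union over pathways — the natural
reading when a metabolite sits in several), with direct taking
precedence. Currency metabolites (water, ATP-like entries) are excluded
from direct matching via a configurable stop-list; otherwise every
window would yield direct hits. TF shortlists order by seed-expression
flag, then family, then position.

## Synthetic data

The generator emulates the study conditions: 393 lines, F10 by
single-seed descent (9 selfings after a fully heterozygous F1), 138
markers evenly spaced at 3.4 cM over five chromosomes with ~1 Mbp per
3.4 cM physical anchors, genotyping error 10⁻³ and 2% missing calls
(values chosen as typical for SNP/SSR genotyping of the period), 311
traits. Meiosis is marker-skeleton: a gamete picks a starting haplotype
and switches between adjacent markers with probability r from the
inverse map function — no interference beyond the map function and no
continuous crossover process, which is adequate because the analysis
only ever sees marker and pseudo-marker positions. Closed forms follow:
heterozygosity halves per selfing generation, and the simulator's
adjacent-marker recombinant fraction matches R = 2r/(1+2r) within
Monte-Carlo error (both tested at n = 50 000).

Traits are built on a log-intensity scale: shared block latent factors
(correlated trait blocks), additive effects a·x with x ∈ {−1, 0, +1}
and a = √(R²·total variance) at unit dosage variance, masking or
synergistic interaction terms (masking: the second locus acts only in
the AA class of the first), additive batch offsets, Gaussian noise,
and injected 8-SD outliers. `to_raw_intensities` exponentiates and
multiplies by seed weight, internal-standard intensity and day factors,
producing exactly the multiplicative nuisance structure the
normalization stage removes. `study_architecture` scatters per-trait
QTLs with explained variances spanning ~0.5–78%, plants a master locus
(the median marker of chromosome 4) driving 40% of traits, a few
masking pairs, batch effects and rare outliers. Reciprocal-cross labels
carry no phenotypic effect by default (an option plants one for ANOVA
power checks).

What the generator does not emulate: chromatographic artifacts,
intensity-dependent (non-MCAR) missingness, segregation distortion,
interference-aware crossover placement, and non-Gaussian trait noise.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
failure mode of real GC-MS data.

## Problem sizes used in validation

The validation suite runs the full study geometry (393 lines, 138
markers, 1 cM grid) but scales stochastic repetitions to what the
estimands need: 10 000 hotspot replicates (the study setting), 1000
permutations per trait for type-I calibration over 500 null traits,
500-permutation thresholds and 200 two-QTL-scan permutations inside the
100-replicate recovery study (penalties are derived once per study —
they are properties of the genotype architecture, not of a replicate),
and 10 end-to-end runs of the 311-trait master-locus analysis with
200-permutation thresholds. Closed-form genetic checks use n = 50 000
lines.

## Known limitations

- Two-state HMM only: no X-chromosome handling, no intercross (F2)
  three-genotype support, no kinship/mixed-model correction.
- Haley–Knott regression is an approximation to full-likelihood
  interval mapping; with low missingness and dense markers the
  difference is negligible, but it can overstate LOD under heavy
  missing data.
- The stepwise search is greedy per move; with the forward/backward
  sweep and paired-interaction moves it recovers the planted
  architectures reliably, but it does not enumerate all models and can
  in principle miss configurations a full search would find.
- `scan_two` grid resolution (2.5 cM) and the position-refinement sweep
  count (2) are config-exposed compromises; the study's original
  choices for these are not documented anywhere, so defaults were set
  by convergence behavior on synthetic data.
- Candidate classification is only as good as the pathway tables
  supplied; the shipped generator writes schema-compatible fixtures,
  not real database contents.
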