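# Methods

This note records the models, conventions and design choices behind
`amfgen`, in the order the pipeline runs.

## Read filtering and clustering

A read is retained iff its length is ≥ `min_length` (default 170 bp)
**and** its expected error count EE = Σᵢ 10^(−Qᵢ/10) is ≤ `max_ee`
(default 1.0, inclusive: "more than one expected error" is a strict
comparison). Qualities are Phred+33 only; there is no +64 support.
Reads are used as-is — the length rule filters, it does not truncate.

Dereplication groups byte-identical sequences across samples, keeping
per-sample counts; output is ordered by total abundance descending with
lexicographic tie-breaks, which fixes the clustering result. Unique
sequences with **global** abundance < 3 (singletons and doubletons over
the whole dataset, not per sample) are removed as PCR/sequencing
artifacts — the convention of abundance-based denoisers; the per-sample
reading would also delete genuine low-depth observations of common
sequences.

Clustering is greedy abundance-sorted centroid clustering: each unique
sequence joins the first existing centroid (in creation order) whose
pairwise identity reaches the threshold (default 0.97), else founds a
new cluster. Identity is matching columns over **all** alignment
columns of a full global (Needleman–Wunsch) alignment, terminal gaps
included, with match +1 / mismatch −1 / gap −2. Co-optimal alignments
are resolved by the aligner's first result. No chimera detection and no
k-mer prefilter heuristics: at study scale (~10² unique sequences after
rare-sequence removal) the quadratic scan is exact and fast enough.

## OTU-table construction

Order is fixed: taxonomy filter → control subtraction → depth filter →
host subset; the chain is idempotent on its own output.

* Taxonomy: an OTU is *retained* iff some reference hit has alignment
  length ≥ 200 bp **and** identity ≥ 90% (the removal clause is stated
  in the negative in common usage and is logically ambiguous; the
  conjunctive retention rule is the standard reading and both cutoffs
  are configurable). The best qualifying hit (identity, then length,
  then subject id) becomes the OTU's assignment.
* Negative controls: for each OTU the counts in all control samples are
  **summed** and that sum subtracted from every other sample, flooring
  at zero — the conservative (maximal-removal) aggregation; controls
  are then dropped.
* Depth: samples under 1000 reads are removed, then all-zero OTU
  columns.
* Host subset: only samples from species flagged as AMF hosts; a rerun
  with all hosts is one flag away (`mycorrhizal_only=False`).

## Rarefaction

`rarefy_once` draws a multivariate hypergeometric subsample (without
replacement). Mean/SD richness per unit come from iterated draws
(default 500) at a common depth defaulting to the minimum unit total —
for gamma diversity the units are mesocosm-aggregated counts, so the
depth is the minimum *mesocosm* total (configurable). Each unit's
stream is keyed by its id from the top-level seed, so results are
reproducible and invariant to row order. The closed form
E[S] = Σⱼ (1 − C(N−Nⱼ, n)/C(N, n)) (evaluated in log-gamma space) is
kept in the package as the independent oracle the Monte-Carlo estimator
is tested against.

## Partner generalism

D_k (effective partner number) uses reads pooled by plant species over
the **whole experiment** — the statistic describes how a fungus spreads
its associations across the available flora, not within one pot; Hill
orders 0 and 2 are available through `hill_number(q=...)`, q=1 is the
default and is base-invariant. Raw counts are used (not rarefied): the
Hill number depends on shares, and pooling across ~900 samples makes
depth artifacts negligible at this scale. The mesocosm score divides
the read-share-weighted mean of D_k by realized plant richness at
harvest, correcting for mortality-driven differences in how many host
species a pot still contains. OTUs with zero reads (possible after
subsetting) get D = 0 with a warning rather than an error.

## Root diameter

Per species: all measured locations and individuals are pooled within
each root order (1st–3rd), and the species mean is the unweighted mean
of the order means (not length-weighted; pooling before averaging —
the per-individual-first variant differs only under unbalanced sampling
and is available via the same table by pre-aggregating). Mesocosm mean
diameter averages over harvested plants, so a twice-planted species
counts twice. The packaged species trait table is **synthetic** (built
in `synthetic_root_measurements`, labelled as such): per-species
order-level diameters constructed mean-preservingly so the
equal-species-weighted provenance means are 0.302 mm (exotic) and
0.317 mm (native).

## Mixed models and selection

Candidate sets are all subsets of the maximal fixed structure that
respect marginality (an interaction implies its lower-order terms);
pinned design covariates can be forced into every candidate. Gaussian
LMMs are fit by **maximum likelihood** (not REML) through statsmodels'
MixedLM so AIC is comparable across fixed structures — the prerequisite
for all-subsets selection. Crossed random intercepts (plant species ×
mesocosm-in-community) use the single-group variance-components
construction. df counts fixed coefficients + variance components +
residual variance; AIC = −2ℓ + 2·df. Selection: restrict to candidates
with delta-AIC < 2 (strict) of the minimum and take the lowest df, ties
broken by AIC then deterministic candidate order. Non-converged or
singular fits are excluded from selection with a warning.

The mesocosm gamma model includes a random intercept over realized
plant-richness levels — a literal implementation of treating richness
at harvest as a grouping factor; it is statistically unusual (an
ordered covariate as a factor) and a fixed-term variant is a one-line
change in the spec of the call.

Zero-inflated beta regression (for family relative abundances in
[0, 1)) is a two-part fixed-effects model fit by joint MLE with scipy:
logistic zero part (intercept-only), beta positive part with logit mean
link and a single log-precision parameter; standard errors come from
the numerical Hessian. Responses exactly 1 are rejected with advice to
apply the (n−1+0.5)/n shrinkage to the boundary values. Random terms
are not supported in this family — the package's beta models are
population-average fits. Model diagnostics are simulation-based
residual checks (simulate from the fitted model, compare residual
quantiles and dispersion); they are reported, never gating.

## The synthetic experiment generator

The generator's defaults are the study conditions: 20 communities × 8
replicates (160 mesocosms), 8 species per community drawn from a
39-species pool (4 non-mycorrhizal), exotic proportion in
{0, .25, .5, .75, 1} crossed with home/away soil and herbivore
addition/exclusion (2 replicates per combination), independent 25%
plant mortality (with one guaranteed survivor per pot), one root sample
per surviving plant, and lognormal read depths (median 15 000, σ = 1,
clipped to [300, 170 000]) so that depths span ~10³–1.7×10⁵ and a small
tail is removed by the depth filter.

Counts: OTU base abundances are lognormal with σ = 2.5; per-OTU host
affinities are Dirichlet draws over the species pool — concentration 5
for generalists (near-uniform partner use) and 0.15 for specialists
(mass on a few hosts). Occupancy of OTU k in a plant of species s is

    min(0.95, base_occupancy · (K·u_k)^0.8 · S·a_{k,s}) · thin(p)

with u_k the OTU's relative base abundance (an abundance–occupancy
coupling: regionally abundant fungi are also widespread) and
thin(p) = min(1, exp(β_rich·p + β_gen·p·1[generalist])) the
exotic-proportion effect: specialists are thinned by exp(−0.3·p) while
generalists are exempt (never boosted above baseline). Conditional on
occupancy, expected composition is base × affinity with generalist
weights tilted by exp(+0.5·p), and counts are Dirichlet-multinomial
(concentration 50) at the sampled depth. Generalist flags (20% of OTUs)
go to the two top-abundance OTUs plus evenly spaced mid-abundance
ranks, reproducing the observed dominance structure in which a couple
of widespread generalists hold over half the reads while most OTUs are
low-dominance and specialists collectively retain a movable share.

Calibration (done by direct simulation while fixing the defaults): the
expected top-2 OTU read share is ≈ 0.55, per-plant observed richness
runs ≈ 10 at 0% exotic down to ≈ 8.5 at 100%, and the realized
generalist-share shift is ≈ +0.5–0.6 logit from p = 0 to 1. A strictly
uniform occupancy thinning was rejected during design because
composition renormalisation then *lowers* the generalist read share as
richness falls, contradicting the effect structure the generator must
emulate; the generalist exemption realizes both stated effect
directions simultaneously.

What the generator does **not** emulate: sequence-level community
structure in the FASTQ renderer (reads are exact copies of random
250-mers plus i.i.d. substitution errors — no chimeras, indels,
quality-by-cycle decay or primer artifacts), soil chemistry or
herbivore dynamics (treatments are inert placeholders), aboveground
biomass, phylogenetic signal in host affinity, and any true effect of
root diameter on fungal composition (diameter enters the models as a
covariate with no generated effect). Passing tests therefore show the
*statistics* behave correctly under the study's design and effect
directions, not that the generator reproduces field data.

## Problem sizes in tests and acceptance

Monte-Carlo checks use sizes chosen to keep the whole suite and the
acceptance script in the low minutes on one CPU while leaving
comfortable statistical margins: the rarefaction oracle runs 20 random
tables at 10 000 iterations; sign recovery runs 20 (tests) or 30
(acceptance) replicate experiments at full default scale with 100
rarefaction iterations per replicate (the estimator's Monte-Carlo noise
at 100 iterations is far below the between-mesocosm variance that
limits the slope estimate); clustering and selection oracles run 50 and
200 random instances. When the empirical Monte-Carlo SE of a
rarefaction check degenerates to zero (richness constant across draws),
the theoretical SE from the closed-form presence probabilities is used
instead.

## Known limitations

* Greedy clustering reproduces the convention, not any specific tool's
  heuristics; results can differ from k-mer-accelerated implementations
  near the threshold.
* MixedLM occasionally reports non-convergence on near-singular random
  structures; such candidates are dropped from selection rather than
  papered over.
* The zero-inflated beta family has no random effects and an
  intercept-only zero part.
* The FASTQ truth-recovery contract is exact only at zero read error;
  with errors enabled the pipeline still runs but recovery is
  approximate by design.
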