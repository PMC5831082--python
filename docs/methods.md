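# Methods

This note documents the models, priors, numerical choices and known
limitations behind `microdyn`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Sample QC

Ecological outliers are screened per body site. For every site with at
least 4 samples, each sample's median Bray–Curtis dissimilarity
(`1 − 2·Σmin(x,y)/(Σx+Σy)`) to all other same-site samples is computed in a
single pass (previously flagged samples are not removed before computing
other samples' medians); a sample is flagged when its median exceeds the
upper inner fence `Q3 + 1.5·IQR` of the site's medians. Quartiles use
linear interpolation between order statistics (numpy's default, "type 7");
the fence value depends on this choice, which is therefore fixed and
documented rather than configurable.

## Pre-fit transform pipeline

Feature series entering the GP are processed in a fixed order:
arcsine-square-root transform (variance stabilization for fractions; inputs
outside [0,1] by more than 1e-9 are errors, within tolerance clamped), then
an iterative two-sided Grubbs outlier test at significance 0.05 (the most
extreme point is removed while its G statistic exceeds the t-based critical
value; at most 10% of points — but at least one — may be removed, a guard
against runaway deletion on heavy-tailed series), then standardization to
zero mean and unit *sample* (n−1) variance. Standardization is idempotent
and affine-invariant; the (n−1) convention matches common GP preprocessing.

## Strain niche association

Strain divergence is the Kimura two-parameter distance; gap and IUPAC
ambiguity positions are excluded pairwise, and saturation (non-positive log
arguments) is an explicit error rather than a clamped value.

The directed site dissimilarity is a silhouette-style construction: with
`ā(u)` the mean distance over unordered strain pairs within site u and
`b̄(u,v)` the mean distance from strains of u to strains of v,

    D(u, v) = (b̄(u,v) − ā(u)) / max(b̄(u,v), ā(u)),

defined as 0 when all involved distances vanish. **This formula is a
reconstruction**: it is the minimal asymmetric silhouette-like comparison
of within-site cohesion against cross-site separation evaluated over
directed site pairs, and it should be validated qualitatively (orderings of
species by score), not against published numerical values. The
niche-association score A is the maximum D(u, v) over directed pairs of
sites holding at least 5 strains each; all argmax pairs are reported, and A
is checked in tests for permutation invariance, monotonicity in cross-site
divergence, and agreement with a brute-force evaluation.

Reference-genome coverage is `1 − UniFrac G` with G operationalized as the
asymmetric (strain-normalized) unique fraction: the summed length of
branches whose descendant leaves are exclusively strains, divided by the
summed length of branches ancestral to at least one strain leaf; the root
edge carries no information and is excluded. The implementation traverses
a dendropy tree and is tested against an independent recursion over
nested-tuple topologies, including degenerate star trees (coverage 0) and
zero-length-sibling trees (coverage 1).

## Core-pathway classification

All thresholds live in one `CorenessConfig`:

| parameter | default | meaning |
|---|---|---|
| detection threshold | 1e-4 | strict `>` for "detected" in a sample |
| prevalence threshold | 0.75 | `>=` fraction of subject-unique samples |
| human-associated genus rule | 5 subjects at > 1e-3 | genus detection bar |
| attribution rule | > 50% copies in > 25% samples | unclassified filter |
| enrichment threshold | < 10% | of non-human genera *and* pangenomes |
| site-enrichment ratio | Q1 > 2·Q3 | focal site vs other body areas |

"At least 75%" is implemented as `>= 0.75` (the boundary case — exactly 75
of 100 samples — is a core candidate; tested explicitly). Subject-unique
samples are the lowest-visit sample per (subject, site), first technical
replicate kept by stable input order. The attribution filter reads a
per-sample unclassified-copy-fraction table as an *input* (emulating
stratified profiler output) and is evaluated per site over that site's
subject-unique samples. The body-area map defaults to the six targeted
sites in four areas (oral: buccal mucosa, supragingival plaque, tongue
dorsum; nasal; gut; vaginal); site enrichment only requires separation from
sites of *other* areas, so oral sites are not required to separate from one
another. Levels nest by construction (supercore ⊆ multicore ⊆ core), and a
sweep over prevalence ∈ {0.6, 0.75, 0.9} × detection ∈ {1e-5, 1e-4, 1e-3}
is tested to run without failure with monotone counts.

The essential-gene summary compares classes with two-sided Wilcoxon
*rank-sum* tests: the essential and non-essential families are independent
groups of unequal size, so a paired signed-rank test is not applicable.
The co-occurrence screen binarizes at 0.1% relative abundance, applies
two-sided Fisher's exact tests per unordered pair (constant features are
skipped with a reason), and controls FDR with Benjamini–Hochberg within the
screened pair set.

## Gaussian-process variance decomposition

### Model

Samples are indexed by subject `s`, time `t` (months; days are converted by
12/365.25), and specimen (shared by technical replicates). The covariance
is a sum of components, all gated by subject identity except technical
noise:

    K[i,j] = U·1[sᵢ=sⱼ] + T·exp(−|Δt|/l)·1[sᵢ=sⱼ] + B·1[specᵢ=specⱼ] + N·1[i=j]

**The component structure is a reconstruction** from the described
behaviour of each term: biological noise is tied to specimen identity so
that technical replicates differ only by N — the unique structure under
which replicates separate the two fast-varying components. Candidate
models may also include a squared-exponential term
`exp(−Δt²/2l²)·1[sᵢ=sⱼ]` and a seasonal term
`exp(−2·sin²(πΔt/12)/l²)·1[sᵢ=sⱼ]` with the period fixed at 12 months.
Biological noise is assumed not to covary across specimens collected the
same day. All processes are stationary; a Gaussian likelihood is used
throughout, which is why only prevalent features (≥ 75% within-site
prevalence, with a rescue for ≥ 2% mean-when-present abundance in ≥ 50
samples) should be fitted — zero-inflated likelihoods are out of scope.

Because every non-diagonal component is subject-gated, K is block diagonal
by subject; the likelihood evaluator groups subjects by block size and runs
one batched Cholesky per group (~100 µs per evaluation at 300 samples),
with the dense-matrix path retained as the reference in tests.

### Priors and fitting

Constrained fits impose `U+T+B+N = 1` with a Dirichlet(1, 1, 1, 1) prior
and sample in additive-log-ratio coordinates (technical noise as
reference); the lengthscale carries a gamma prior (shape 3.1, mean 10
months, i.e. scale 10/3.1) and is sampled as log l. The lengthscale prior
keeps l away from both the replicate limit and the study span, which is
what makes T identifiable next to B and U. Selection-stage (unconstrained)
fits give each included component a positive magnitude with a
half-normal(sd 1) prior and each time-varying component its own
lengthscale with the same gamma prior.

The sampler is adaptive scalar Metropolis-within-Gibbs with diminishing
adaptation (per-coordinate proposal scales tuned toward 44% acceptance at
rate t^(−1/2)), started from independent prior draws. Defaults are 10
chains × 200 retained draws after 30 burn-in iterations, thinning every
other sweep; model-selection fits default to 5 chains × 150 after 20
burn-in. Desk-scale tests and the acceptance script use 4 chains × 100.
Convergence is monitored with split-chain R̂ (checked against arviz), with
R̂ < 1.1 the conventional bar; all draws are reproducible from the seed.

### Evidence

Marginal likelihoods are estimated by a truncated harmonic mean of the
un-normalized posterior. A plain harmonic mean over posterior draws is
inconsistent — its bias is the log-volume of the region the draws cover —
so the estimator restricts the harmonic mean to an explicit high-posterior
ellipsoid and divides out its volume: draws below the 5th percentile of
log-posterior are discarded, an ellipsoid A is fit to the retained cloud
(mean, covariance, Mahalanobis radius at the retained median), and

    1/Ẑ = (1 / (M·vol(A))) · Σ_{θᵢ∈A} 1/p(θᵢ),

a consistent instrumental-region estimator. Fewer than 50 retained draws
is an error ("evidence unstable"). The estimator works in the transformed
sampling space, where the stored log density is the exact target including
Jacobians. On conjugate normal–normal problems with analytic evidence it
is accurate to well under 2 bits at 2,000 draws (measured in the test
suite and the acceptance script). Evidence differences are reported as
log₂ Bayes factors ("bits") against the better model.

### Greedy model selection

The search starts from the technical-only null. Each iteration fits every
candidate that adds one covariance component (each candidate nests the
current model) and accepts a candidate when the evidence against the
current model exceeds six bits. Acceptance is **parsimony-first**: among
decisively better candidates, the one adding the fewest parameters wins
(plain variance components add one parameter; OU/SE/periodic add a
magnitude and a lengthscale), ties broken by bits. Without this rule the
OU component — which degenerates to biological noise as l → 0 and to
inter-individual differences as l → ∞ — absorbs both simpler components
whenever either is present. A consequence, measured in the tests: on
near-pure OU data the OU candidate dominates the first step (tens of bits
against the null), but once B and U are admitted its residual gain is a
few bits and it enters the final model only for some realizations. This
mirrors the documented difficulty of separating time-varying covariance
families at ≤ 3 visits per subject.

### Ternary summary and uncertainty

Constrained fits are summarized by the posterior mean of
`(U, T, B)/(U+T+B)` (technical noise normalized out). The s.e.m. of each
coordinate is the standard deviation of per-chain posterior means divided
by √(chains), maximized over coordinates; fits with max s.e.m. > 0.2 are
flagged low-confidence. Draws with `U+T+B = 0` would be excluded with a
warning (unreachable under the logistic parameterization, kept as a
guard).

### Identifiability, measured

Under the reference design (90 subjects, ≤ 3 visits, 1–12-month gaps, 15%
replicates, N = 0.05):

* the **even mixture** is recovered within ±0.15 per ternary coordinate on
  average over seeds (single-feature scatter is larger — mixtures of all
  three components carry the greatest uncertainty);
* **pure inter-individual** variance is the most identifiable vertex
  (recovered weight ≈ 0.98); pure biological noise ≈ 0.8; **pure
  time-varying** variance recovers ≈ 0.73 — the posterior cannot exclude a
  biological-noise share because B is pinned only by the ~40 replicate
  pairs while OU covariance at Δt → 0 is unobserved below the 1-month
  minimum gap. This is a property of the design, not of the sampler (the
  full-length MCMC posterior is unchanged);
* **U/T mixtures** show a systematic signed bias toward T: estimates
  should be read as biased away from the inter-individual corner whenever
  time-varying dynamics are present;
* the **OU sensitivity window**: simulations with true lengthscales 0.1,
  3, 12, 24 and 100 months attribute plurality weight to T only inside
  roughly 3–24 months, with weight shifting to B below and U above. At
  exactly 3 months the T/B split is near even — the window edge;
* **without technical replicates** B and N are not separable: the
  posterior of B/(B+N) reverts to its uniform prior (mean ½, variance
  1/12) and B, N are negatively correlated along the ridge (analytically
  ≈ −0.6 under the Dirichlet prior — not −1, because the prior is uniform
  on the undetermined split). With replicates the split concentrates near
  truth.

## Synthetic data

The generators are pure functions of (spec, seed) and define the study
conditions: 90 subjects with exactly `visits_per_subject` (default 3)
visits, inter-visit gaps uniform in 1–12 months drawn in whole days so
metadata round-trips exactly, 15% technical-replicate rate, truth mixture
defaulting to 5% technical noise with the remainder split evenly and OU
lengthscale 6 months.

The community generator covers the six targeted sites at 25 subjects per
site (a desk-scale stand-in for the cohort) with a steep lognormal
rank-abundance background, per-sample lognormal noise, and Bernoulli
zero-inflation (rate 0.3) applied to the sub-dominant tail only — dropout
of a site-dominant species would make ordinary samples indistinguishable
from genuine outliers. All planted structure holds by construction, not
merely in expectation: human-associated genera are forced above 10⁻³ in
five designated subjects, rare genera capped at three subjects, the
co-occurring pair forced present in six subjects and absent in three, and
the per-site outlier sample gets a permuted *background* profile (planted
rows untouched so their guarantees survive). Pathway tables plant a
supercore, a two-area multicore, a gut-only core, a stool-enriched, a
range-filtered, an attribution-filtered, and a human-enriched pathway
against ten low-prevalence background pathways, with matching annotation,
pangenome and attribution tables (genus universe: 8 planted human genera,
20 table-resident environmental genera that are human-associated by the
detection rule, 20 annotation-only non-human genera).

Strain clades evolve a 500-bp root sequence by independent-site
substitution with transition/transversion ratio 2 (so K2P assumptions hold
exactly): per-site ancestors at half the between-site divergence (default
0.5 substitutions/site), haplotypes at half the within-site divergence
(default 0.01). The null sets every site's ancestor to the root.

What the generators do *not* emulate: compositional coupling between
features, phylogenetically realistic tree shapes, abundance-dependent
dropout, batch effects, or read-level error. Passing tests therefore
demonstrate correctness of the statistics and recoverability under the
stated design, not robustness to those real-data complications.

## Problem sizes

Desk-scale sizes used by the default test run and the acceptance script
(chosen once for a single-CPU workflow): recovery checks use 6 seeds per
mixture in tests and 20 seeds for the even mixture in the acceptance
script, 3–6 seeds per vertex/lengthscale, reduced MCMC of 4 chains × 100
draws; evidence calibration uses 20 conjugate problems × 2,000 draws;
oracle-equivalence batteries use 1,000 random cases for scalar statistics
and 200–300 for the matrix/tree/full-procedure checks; the demo runs the
complete pipeline on one community and one GP feature.

## Known limitations

* The D(u, v) and covariance formulas are reconstructions (flagged above).
* Gaussian likelihood only; rare, zero-inflated features need different
  likelihoods and are filtered out rather than modelled.
* One population-level lengthscale; per-subject temporal parameters are
  not identifiable at ≤ 3 visits.
* The harmonic-mean evidence, even stabilized, is a single-sample-run
  estimator; bits differences within ~1 of a threshold should not be
  over-read.
* Coreness operates on provided annotation/attribution tables; it does not
  recompute pathway quantification or parse annotation databases.
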