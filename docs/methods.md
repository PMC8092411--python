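# Methods

This note records the models, numerical choices and calibrations behind
`stressrec`, in the order the pipeline runs them.

## Synthetic study conditions

The generator (`stressrec.synthetic`) is the package's definition of the
study it analyzes: a pulsed-stress recovery experiment sampled at days 0, 1,
2, 4, 6, 8 and 10 with three replicates per day.

**Temporal archetypes.** Six canonical response shapes are defined on
normalized time u = day/max(day): an early spike-decay (peak ≈ day 1), a
slower spike-decay (peak ≈ day 2–4), a mid-recovery rise, a late dip, an
early-down/late-overshoot curve, and a late monotone rise. Each raw curve
starts at its baseline value at u = 0, so anchoring fold changes at day 0
preserves the intended shape; the set is roughly balanced between up- and
down-responses, which keeps the total-count composition of simulated
libraries stable across days (see *Normalization*, below). Curves are
z-scored across days (mean 0, population sd 1). Distinctness is enforced as
pairwise Pearson r < 0.8 — near-duplicate shapes are rejected, while
mirror-like anticorrelated shapes are allowed because correlation-based
similarity separates them perfectly. For k < 6 the subset is chosen greedily
to maximize the minimum pairwise |r|-dissimilarity, so small sets are also
weakly correlated in magnitude.

**Transcripts.** Feature i at day d has mean
μ_i · 2^(β·A_i·h_a(i)(d)), where h is the day-0-anchored archetype curve
scaled to unit peak, β = 2 is the peak |log2FC| (responses up to 4-fold
either way), and A_i is a per-feature amplitude factor, lognormal with
sd 0.35 clipped to [0.5, 2] — real deregulated genes span a fold-change
spectrum rather than one fixed effect, and without this spread per-day
cross-omics correlations degenerate on days where all called features share
one planted value. The clip exists because an unbounded amplitude tail
occasionally lets a single abundant feature dominate the library and
destabilize CPM baselines. Counts are negative binomial with
Var = μ + φμ²; φ = 0.01 (biological CV 0.1), the standard figure for
replicates of a clonal cell line. Baselines μ_i are lognormal around
2⁷ CPM-scale counts (log2 sd 1.2). A fraction 0.85 of features is null
(flat), matching the ~15% peak deregulation rate of the motivating design.

**Proteins.** Proteins share the transcript feature namespace. A coupled
protein's log2 intensity follows the transcript program convolved with a
causal exponential lag kernel exp(−Δd/τ), τ = 1 day, renormalized over the
available past samples, attenuated by 0.6 and multiplied by a per-feature
translational modulation factor ~ N(1, 1.0); 30% of proteins are fully
decoupled (translationally buffered). Residual noise is N(0, 0.5²) on the
log2 scale. These three knobs (attenuation, modulation sd, decoupled
fraction) were calibrated once by Monte Carlo over 20 seeds so that the
default per-day correlation between transcript and protein fold changes
among truth-positive features lies in [0.2, 0.6] (realized per-day means
≈ 0.41–0.50) and the realized band of per-day correlations brackets the
moderate-coupling regime of r ≈ 0.22–0.34 reported for comparable
multi-omics time courses. Coupling is monotone in attenuation, which the
tests verify over three settings.

**Supernatant and viable cells.** The stressed viability curve is an
interpolated anchor series dipping to 50% of baseline at day 2 and
overshooting baseline from day 6 (day-0 density 5·10⁵ cells/mL, 10 mL).
Exchange is planted as per-interval rates (nmol per 10⁶ cells per hour):
glucose is consumed throughout with decreasing magnitude; lactate flips from
consumption on day 0–1 to release peaking in the interval ending on day 4.
Concentrations are produced by integrating these rates against the
trapezoidal viable-cell integral, so the downstream estimator recovers the
planted rates exactly — a deliberate closed loop that makes the rate
arithmetic testable to machine precision. The unstressed variant grows
monotonically with constant-sign rates.

**Dependency cohorts.** The target gene's CERES-like scores are
N(−1, 0.2²) for dependent lines and N(0, 0.2²) for independent lines
(dependent fraction 0.3 of 200 lines over 5 tissues); dependency
probability is a logistic map of the score centred at −0.5. Sixty signature
genes are shifted by ±δ (δ = 1.5 expression sd, random sign per gene) in
dependent lines; a 150-tumor cohort with 20% planted dependent tumors
carries the same shift pattern.

All generators draw from child streams of a single `SeedSequence`, so every
artifact is reproducible from one integer seed.

**What the generator does not emulate.** Gene–gene correlation beyond the
planted archetypes, abundance-dependent dispersion trends, batch effects,
missing values (common in proteomics), compositional normalization
pathologies beyond simple library drift, and tissue-specific expression
programs in the dependency cohort. Passing tests therefore demonstrate
correctness of the machinery and recoverability under idealized noise, not
performance on real data.

## Differential analysis

Transcripts are normalized to log2(CPM + 0.5); intensity omics to per-sample
median-centered log2. CPM is deliberately simple; the generator's balanced
archetype set keeps library composition drift small (|Δ| ≲ 0.2 log2), which
is the regime where CPM is adequate. The moderated t shrinks the pooled
per-feature variance toward a scaled inverse-chi-square prior whose
parameters (d₀, s₀²) are fitted by matching the mean and variance of
log s² to their theoretical values under the model (trigamma-inverse
solved by Newton iteration). When the observed spread of sample variances
does not exceed chi-square sampling noise, d₀ → ∞ and the test reduces to a
z-test with the common variance — the correct limit for the generator,
whose dispersion is shared across features. BH adjustment is applied per
omic per day because deregulation counts are reported per day; it is
implemented directly (vectorized step-up) so that it agrees bitwise with an
independent quadratic-time reference. Calls require q ≤ 0.05 and, for
transcripts only, |log2FC| ≥ 1 (the "fold change > 2" convention). The
direction test on an annotation set is a two-sided Fisher exact test on
{up, down} × {in-set, background} among called features; empty margins
return p = 1 with the odds ratio flagged undefined.

## Temporal network

Day-courses (per-day log2FC with day 0 included as 0, or per-day mean log
level) are z-scored per feature with the population sd; constant profiles
cannot be z-scored and are dropped with a report. Similarity is the Pearson
correlation of z-scored profiles; the distance √(2(1−s)) is the Euclidean
distance between normalized profiles. The edge set is MST ∪ kNN (default
k = 5): the MST guarantees connectivity (required by the random-walk
model), kNN supplies local density. Edge weights are max(s, 10⁻⁶), so MST
bridges across anticorrelated regions carry positive but negligible weight.
A constant shift is added to distances before the MST computation only so
that zero distances (identical profiles) register as edges; a constant
shift cannot change the MST edge set.

## Markov Stability clustering

The exact objective r(t,H) = trace[Hᵀ(Π e^{−tL} − ππᵀ)H] is evaluated via
the symmetrized Laplacian eigendecomposition (dense; capped at n ≤ 2000).
The linearized objective is the default for optimization; at t = 1 it
equals Newman–Girvan modularity exactly, which the tests assert to 10⁻¹²,
and it deviates from the exact objective by O(t²) as t → 0. Optimization is
Louvain-style: greedy node moves with first-improvement tie-breaking in a
shuffled order, aggregation, repeat; after the hierarchy converges a final
node-level refinement sweep runs on the original graph, because aggregation
can lock individual nodes inside super-nodes. Best-of-restarts (default
20–50) with deterministic child seeds per restart; on all random graphs
with n ≤ 8 the optimizer attains the exhaustively enumerated optimum.

The scan covers t ∈ [10⁻², 10²] on 50 log-spaced points. Robust selection
takes the longest contiguous run of Markov times with a constant cluster
count and mean restart VI ≤ 0.05·ln n (VI in nats, computed from the
contingency of cluster proportions), breaking ties toward larger t and
returning the run's central partition; single-cluster plateaus are ignored
when an informative plateau exists, and if no plateau qualifies the
maximum-stability partition is returned flagged as a fallback. On planted
six-archetype studies (600 features, β = 2, three replicates, default
noise) this recovers six clusters with ARI ≥ 0.9 in ≥ 9 of 10 seeds; the
known failure mode is a tie between the six-cluster plateau and the very
coarse plateau at the upper grid edge, which the larger-t tie rule then
prefers.

## Single-sample enrichment

Per sample, features are ranked by expression descending (ties broken by
feature id for determinism) and a KS running sum adds 1/|hits| at set
members and subtracts 1/(n−|hits|) elsewhere; the score is the signed
maximum deviation. With α > 0 member increments are weighted by rank^α and
renormalized (α = 0 by default). Scores are rank-based and hence invariant
to monotone transforms within a sample. For display, each set's scores are
divided by their maximum magnitude across samples, bounding the matrix in
[−1, 1]; all-zero rows stay zero. This is a deliberate stand-in for
kernel-density single-sample enrichment: it reproduces temporal enrichment
patterns at the figure level but does not replicate any specific tool's
score values.

## Exchange rates

rate over [t₁,t₂] = (C(t₂)−C(t₁))·V / ∫N dt, with the viable-cell integral
by trapezoid between measured densities, expressed in nmol per 10⁶ cells
per hour; negative = consumption. No medium-change correction is applied by
default (the feeding schedule is a property of the experiment, not the
data); per-cell-per-hour normalization is this package's convention.

## Dependency signatures

Extreme-group selection takes the n_top most-negative dependency scores and
greedily matches the bottom group to the top group's tissue histogram from
the least-negative end, reporting shortfalls and filling them from the
global pool. The signature is the top-`size` genes by |moderated t| with
q ≤ 0.05 between the groups (ties broken by lexicographic gene id; the
screened target gene itself is excluded), with direction = sign of the
dependent-minus-independent mean difference; if fewer genes pass, all
passing genes are returned flagged short. Projection z-scores each
signature gene across the tumor cohort and counts sign agreements; a tumor
is dependent when the agreeing fraction strictly exceeds 0.8. Sign
agreement was chosen over correlation or nearest-centroid because it makes
the ">80% of the signature" semantics exact and is insensitive to
expression scale; constant genes in the cohort are dropped as carrying no
sign information. Defaults (61 top lines, 60 matched lines, 56-gene
signature) mirror the scale of the skin-cancer use case; 40- and 58-gene
variants are a parameter, not separate code paths.

## Problem sizes

Tests and the acceptance script run at desk scale: 600-feature transcript
studies (10 seeds) for cluster recovery, 500-feature studies (20 seeds) for
coupling calibration, 200-line/5000-gene/150-tumor cohorts (10 seeds) for
dependency recovery, and n ≤ 8 graphs for exhaustive enumeration. These
sizes were chosen so the full suite completes in a few minutes while
keeping Monte-Carlo standard errors well below the tested margins.

## Known limitations

- CPM normalization is biased under strongly unbalanced deregulation; the
  pipeline does not implement trimmed-mean or median-of-ratios size factors.
- The moderated t uses a single global variance prior (no abundance trend),
  which is slightly anticonservative for low-count features when dispersion
  varies with abundance.
- The plateau-selection rule treats a grid-edge plateau like any other; very
  coarse partitions that are stable at the top of the Markov-time range can
  win ties against interior structure.
- Exact stability is dense-only (n ≤ 2000); no sparse matrix-exponential
  action is provided.
- The enrichment score has no permutation null; it is a descriptive
  per-sample statistic.
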