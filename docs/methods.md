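# Methods

This note documents the models and conventions implemented in `pwconsensus`,
the choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Symbol namespace and significance conventions

All resources and measurements are harmonized to one uppercase gene-symbol
namespace (syntactic normalization; an optional alias table resolves
non-canonical names). No online identifier lookup is performed.

Proteome-style layers (phosphoprotein, protein) call a molecule significant
at timepoint *t* when |log2FC(t)| ≥ log2(1.5), i.e. at least 1.5-fold up *or*
down versus the 0 h baseline. The rule is two-sided because down-regulation
is as informative as up-regulation for consensus membership and clustering.
Transcript layers are expected to carry significance flags from a dedicated
differential-expression pipeline (e.g. ANOVA at controlled FDR); when a
transcript table has no flags the fold-change rule is applied as a fallback
with a logged warning. Missing values are disallowed throughout: the spline
and state-space stages require complete series.

## Downstream / upstream analyses

TF identity is defined operationally as membership among the keys of the
TF→target table. Pathway membership is plain set intersection — no
enrichment statistic is computed, because a handful of phosphoproteins
cannot support one and the subsequent consensus intersection already
controls false positives.

Upstream traversal runs per pathway on that pathway's own topology
(breadth-first against edge direction, depth ≤ `order`, default 10), and the
per-pathway results are unioned. Topologies are deliberately *not* merged
into one supergraph: merging would let traversal jump between pathways
through shared hub proteins and inflate the regulator set. Edge signs
(activation/inhibition) are ignored for reachability and retained only for
reporting. Seed TFs are excluded from their own regulator set, keeping the
TF and protein layers distinct.

## Static consensus graphs

Consensus proteins and TFs are the terminals of a Steiner-tree
2-approximation on the PPI graph: all-pairs shortest paths between terminals
(metric closure), minimum spanning tree of the closure, expansion of closure
edges into their underlying paths, a second MST on the expanded subgraph,
then iterative pruning of non-terminal leaves. The approximation guarantee
is weight ≤ 2·(1 − 1/|terminals|)·OPT.

Numerical conventions:

* Edge length is 1 − confidence score, so high-confidence interactions are
  preferred; an unweighted mode (all lengths 1) is available via
  `weighted=False`.
* Shortest-path ties are broken by the lexicographically smallest node
  sequence and MST ties by sorted (weight, u, v) edge key, making graph
  construction fully deterministic.
* Terminals absent from the PPI are dropped with a warning; terminals in
  different PPI components yield a forest (one tree per component group)
  rather than an error, since real consensus sets can be disconnected.

TF→target edges are added only between consensus TFs and consensus genes
(not to all known targets of a TF) — the completion step decorates the
consensus network, it does not re-open it. Feedback edges run gene → protein
between nodes of the same symbol, encoding that the transcript feeds the
protein pool.

## Dynamic consensus network

The measured grids (default 0, 1, 4, 8, 13, 18, 24 h) are too sparse for
state-space estimation, so each consensus molecule's course is first fitted
with a cubic smoothing spline — smoothing parameter chosen by generalized
cross-validation, reflecting the assumption that signaling changes gradually
between samples — and evaluated on `n_grid` = 50 equally spaced points
spanning the measured interval. With only 4 measured points the exact cubic
interpolant is used (GCV needs ≥ 5 knots). Each densified series is
standardized to zero mean and unit variance so that molecules measured on
different platforms contribute on a common scale; constant series are
rejected.

The model is a linear feedback state-space system over the P observed
molecules (proteins and transcripts share one observation vector; layer tags
are kept for reporting):

    x_t = A x_{t−1} + B y_{t−1} + w_t,   w_t ~ N(0, I_K)
    y_t = C x_t + D y_{t−1} + v_t,       v_t ~ N(0, diag(1/v))

The first observation is conditioned on rather than modeled. Rows of A, B,
C, D carry zero-mean normal priors with one precision hyperparameter per
row; all precision hyperparameters (including the observation precisions v)
are re-estimated at every EM iteration from the current posterior moments
(empirical Bayes), starting from 1. Hidden-state posteriors come from Kalman
filter / RTS smoother recursions with the hidden noise fixed to the identity
for identifiability. Convergence is declared when the maximum relative
change of all hyperparameters drops below `tol` (default 1e-3, up to 100
iterations); a non-converged fit is returned with `converged=False` and a
warning — on data with no real dynamics the prior precisions drift upward
indefinitely and hitting the iteration cap there is expected and harmless.
With K = 0 the model reduces to a Bayesian ridge VAR(1), y_t = D y_{t−1} + v_t.

K is selected (when not fixed) from the singular values of a block-Hankel
matrix of lagged autocovariances of the observed series: the smallest K
whose cumulative singular-value mass reaches 0.90, capped at 5. An all-zero
Hankel gives K = 0.

**Edge scores.** D is the network: D[j,i] is the influence of molecule i on
molecule j one grid step later. The z-score of an edge is the posterior mean
of the coefficient divided by the *sampling standard error of that posterior
mean* (for a row fit, cov = v_i Σ_i M Σ_i with Σ_i the posterior covariance
and M the predictor second-moment matrix). Under data with no true
interactions this statistic is standard normal for any prior precision, so
thresholding |z| at Φ⁻¹(1 − α/2) makes α exactly the probability of an edge
appearing by chance — the semantics the default α = 0.15 is meant to carry.
The naive alternative (posterior mean over posterior sd) loses this
calibration, because empirical-Bayes shrinkage deflates mean and sd together
and the prior precisions grow without bound under the null. Retained edges
are signed by the coefficient (activation if positive); self-loops are
reported — self-activation is a real and interpretable outcome here.

## Time-profile clustering

Fuzzy c-means with the standard alternating updates; fuzzifier m defaults
to 2.0 (the common choice for expression profiles; exposed as a parameter).
Input rows are standardized per molecule so shape, not magnitude, drives the
partition. Each run uses the best of 10 seeded restarts by final objective;
a profile coinciding with a centroid is hard-assigned to it. The objective
is non-increasing within a run and asserted as such in the tests.

The cluster count rule scans candidate c (default 2..8), computes the
minimum pairwise centroid distance d_min(c), and returns the last candidate
before the first *collapse* — a relative drop of d_min by more than 0.5 from
one candidate to the next. The rationale: as long as c does not exceed the
number of genuinely distinct profile shapes, centroids occupy distinct
shapes and d_min falls slowly; one step beyond, two centroids split the same
shape and d_min crashes. On data with no collapse in range the largest
candidate is returned.

## Time-course integration

For each measured phosphoprotein p and timepoint where p is significant, the
pathways containing p define p's TFs and their target genes; intersecting
with the consensus transcripts of that timepoint and uniting over time gives
p's downstream consensus transcripts. Those significant on the proteome
layer at any timepoint become matched transcript/protein pairs with both
log2FC series attached; a Pearson correlation per pair is reported as a
purely descriptive summary of co-movement (no test is attached to it).

## Synthetic fixtures

The generator emulates the qualitative structure of a growth-factor
stimulation study: a planted phosphorylation cascade X0 → K0 → TF0 whose
kinase crosses the 1.5-fold threshold from the first post-baseline
timepoint, immediate target genes switching on at 1 h and delayed targets at
8 h (signs alternate within each group), and planted proteins following
their transcripts with a 4 h lag. Response curves are logistic rises with a
slow exponential decay (τ = 40 h), so they are smooth enough for spline
densification and stay above threshold through 24 h. All other molecules are
i.i.d. Gaussian noise on the log2FC scale (default sd 0.2). Decoy pathways,
decoy TFs and random PPI edges are drawn from symbol pools disjoint from the
planted cascade, which is what makes the noiseless ground truth exact.

What passing tests on these fixtures shows: every set-algebraic step, the
graph algorithms, the estimators and the orchestration behave as specified,
and the planted structure is recovered exactly in the noiseless limit. What
it does not show: robustness to realistic measurement error (correlated
noise, platform-specific biases, missing values), to incomplete or wrong
pathway annotations, or to the identifier-mapping ambiguities of real
databases — none of which the generator models.

Problem sizes used in the shipped checks were chosen to keep the whole suite
fast on a laptop: null calibration uses 20 datasets of 10 molecules × 50
grid points; parameter recovery uses 5 molecules × 200 points over 20 seeds;
the Steiner bound is verified against exhaustive optima on 200 random graphs
of ≤ 12 nodes with ≤ 5 terminals.

## Known limitations

* The dynamic model is linear and first-order on the dense grid; oscillatory
  or high-frequency components are not identifiable at this time resolution
  and are out of scope.
* Identities are gene-symbol level throughout; phosphosite-level resolution
  is collapsed.
* Pathway collections from several sources are kept as-is, so partly
  redundant pathways are counted separately in pathway-hit tallies.
* The Steiner construction is an approximation; optimality is only
  guaranteed within the factor 2·(1 − 1/|terminals|).
* The chance-edge calibration of the dynamic threshold is exact under the
  null model of independent Gaussian observations; densification introduces
  smoothing-induced autocorrelation on real data, so α should be read as a
  screening level, not a family-wise error rate.
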