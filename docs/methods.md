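# Methods

This note documents the models implemented in `macrodiv`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and known limitations.

## Time trees and derived vectors

All analyses operate on rooted, strictly bifurcating, ultrametric
chronograms with branch durations in time units (My by convention).
Polytomies are rejected rather than resolved with zero-length branches,
because every likelihood below assumes a binary reconstructed process.
Ultrametricity is checked to a relative tolerance of 1e-6 of the tree
depth (configurable); trees inside the tolerance are re-normalised by
extending tip branches to the mean root-to-tip depth, so numerically
ragged chronograms read from text round cleanly. Ages are measured
backward from the present (tips at 0, crown split at the tree depth).

From a tree with n tips we take the branching times
x₂ > x₃ > … > xₙ (internal-node ages; x₂ is the crown age) and the
internode intervals gₖ = xₖ − xₖ₊₁ (g_n runs to the present), the
duration during which the reconstructed tree has exactly k lineages.
Tied node ages, which can occur in degenerate synthetic input, are kept
as zero-length intervals; the likelihoods treat them as distinct events.

## Gamma, CR and MCCR

With Tᵢ = Σ_{k=2..i} k·gₖ and T = Tₙ,

    gamma = [ mean_{i=2..n-1}(Tᵢ) − T/2 ] / [ T · sqrt(1/(12(n−2))) ].

Gamma is invariant to rescaling time and is asymptotically standard normal
under a completely sampled constant-rate pure-birth process, so the CR
test is one-tailed normal (deceleration, P = Φ(gamma)); a two-tailed
variant exists behind a flag. We verified the calibration by simulation:
at n = 100 the empirical type-I error at the 5% level is ~0.055.

The MCCR test corrects for incomplete sampling: B pure-birth trees are
simulated at the clade's true richness N (rate 1; gamma is scale-free),
each uniformly pruned to the sampled tip count, and the empirical
0.05-quantile of the pruned-gamma sample is the corrected critical value.
The quantile is the order statistic of rank ceil(0.05·B); P-values use the
add-one convention (1 + #{null ≤ observed})/(B + 1), which cannot return
0. When the observed input is a sample of trees (a posterior), the
headline comparison uses the sample mean gamma, with the median and range
reported alongside. B defaults to 5000.

Non-random sampling is modelled as an interpolated removal scheme: each
tip removal is, with probability α, a "diversified" removal (one member of
the shallowest remaining cherry — the most redundant tip), otherwise
uniform. α = 0 is random sampling and α = 1 retains a maximally
diversified subset. The literature method this emulates is not specified
precisely enough to copy, so this scheme is an explicit interpretation,
pluggable by design; printed α values from the original analyses are
therefore not comparable numbers.

## Birth-death likelihood (BDL) suite

Six models are fitted to branching times and compared by AIC = −2lnL + 2k.
The labelled-history constant Σ_{k=2..n−1} ln k is included in every
pure-birth-family lnL: it is shared across models (AIC differences are
unaffected) and matches the sign conventions of the classic printed
tables, where lnL for a few-hundred-tip tree is positive. Parameter
counts are 1 (pureBirth), 2 (bd, DDL, DDX), 3 (yule2rate), 5 (yule3rate)
— shift times count as free parameters.

* pureBirth: lnL = C + (n−2)·ln λ − λT, with the closed-form MLE
  λ̂ = (n−2)/T (cross-checked against a numeric optimiser in the tests).
* bd (Nee conditioned-on-crown-survival, net rate r = λ−μ, extinction
  fraction a = μ/λ):
  lnL = C + (n−2)ln r + n·ln(1−a) + r·Σ_{i≥3}xᵢ − 2Σ_{i≥2}ln(e^{rxᵢ}−a),
  computed in log space (ln(e^{rx}−a) = rx + log1p(−a·e^{−rx})). Fitting
  is Nelder–Mead on (ln r, logit a) from two starts, with the a = 0
  boundary (where the rate MLE is closed-form) always evaluated; at a = 0
  the likelihood equals pureBirth exactly.
* DDL / DDX (density dependence): per-lineage-count rates
  λₖ = r₁(1 − k/K) and λₖ = r₁·k^(−x);
  lnL = Σ_{k<n} ln(k·λₖ) − Σ_k k·λₖ·gₖ. For a fixed shape (K or x) the
  rate MLE is closed-form, so fitting is a 1-D profile search (24-point
  grid + bounded refinement; K on (n, 10⁴n] log-scale, x on [0, 8]).
* yule2rate / yule3rate: piecewise pure birth with shifts only at observed
  branching times; a branching event exactly at a shift age belongs to the
  older segment. Per-segment rate MLEs are closed-form
  (events_j / Σ k·duration_j), so fitting profiles exhaustively over all
  admissible shift placements (every segment must keep at least one
  event), vectorised with prefix sums.

ΔAIC significance: the observed best-RC-minus-best-RV AIC difference is
compared with a null built by simulating B pure-birth trees at the clade's
richness, pruning to the sampled size, and refitting the whole suite;
P = (1 + #{null ≥ observed})/(B + 1). The null is invariant to the
simulation rate (scale freedom), which the tests verify.

A property of the exhaustive multi-rate profile worth knowing: yule3rate
can always place its two shifts around a single branching event, and the
resulting "spike" regime gains roughly ln n in lnL on any tree — so on
complete constant-rate trees the rate-variable models usually win the raw
AIC comparison. That is precisely why the Monte-Carlo ΔAIC test exists
(the same inflation is present in the null), and why the package's
specificity guarantees are stated for the smooth rate-variable models
(DDL/DDX/bd) rather than for the multi-rate profiles. Relatedly, the
changepoint MLE resolves the shift position only to within a branching
event or two: at a 10-fold rate drop (n = 100) the fitted shift falls
between the two branching times bracketing the truth in ~75% of runs
(~89% within one extra event); at a 50-fold drop this rises above 90%.
The recovery tests assert those measured resolutions.

## Among-clade shifts on richness backbones

The backbone likelihood decomposes per regime into reconstructed-process
factors: each observed split at age t contributes
ln λ·p₁(t) = ln r + ln(1−a) + rt − 2ln(e^{rt}−a); each piece is
conditioned on survival of its stem (ln(1−a) − ln(e^{rt_s}−a); the basal
piece carries one such factor per crown lineage it retains); and each
terminal of stem age t with richness n contributes the geometric
ln P(n|t) = ln(1−β) + (n−1)ln β with β = (e^{rt}−1)/(e^{rt}−ε). With every
richness equal to 1 and a single regime this reduces exactly to the bd
likelihood plus per-tip survival terms (asserted to 1e-8); the geometric
sums to 1 over n ≥ 1. A single labelled-history constant for the whole
backbone is shared by every shift configuration, so stepwise AIC
comparisons are unaffected by it.

The stepwise search starts from one regime, proposes a shift on every
branch (the shifted regime takes the branch and everything below it; the
donor regime keeps the rest), refits only the two affected regimes (ML by
multi-start Nelder–Mead on (ln r, logit ε), with piece-level caching), and
accepts the best proposal while the AIC improves by at least a threshold.
The threshold defaults to 4 AIC units — the original studies do not state
their cutoff, so it is configurable. k = 2 per regime + 1 per shift
placement. Clade ages attached to richness are stem ages, matching how
`collapse_to_backbone` builds terminals (terminal branch = stem lineage).
Shifts on both crown branches simultaneously would leave the basal regime
empty and are not proposed. When a shifted clade is one of the two crown
lineages, a shift on its sister complement describes the same bipartition
with the same likelihood; recovery experiments count either placement.

## BiSSE

Along each branch (age increasing tip-to-root) the standard coupled ODEs
for Eᵢ (probability of leaving no sampled descendant) and Dᵢ (density of
the observed subtree) are integrated; at nodes
Dᵢ = D_left,i · D_right,i · λᵢ with per-node rescaling (log accumulated);
at the root, states are combined with D-proportional weights by default
(equal weights and an explicit prior are options — the root treatment of
the historical implementations is not documented, so none of the
package's guarantees depend on it). No sampling-fraction correction is
applied: the model assumes the tree is completely sampled, and applying it
to an incompletely sampled tree inherits that approximation.

Integration is fixed-step classic RK4, 40 steps per branch by default,
with E carried alongside D (E depends only on age on an ultrametric,
fully extant-sampled tree; at joins the children's E are averaged). The
sweep is compiled with numba when available and falls back to pure Python
otherwise. Accuracy: halving the step changes lnL by < 1e-5 on the test
tree; the state-independent factorisation identity (BiSSE = single-state
birth–death density × Mk likelihood) holds to 1e-6 at 120 steps against a
closed-form + pruning oracle. Data impossible under the parameters (both
states observed with q01 = q10 = 0) return −inf.

Fitting is Nelder–Mead on log-rates (6 free parameters unconstrained; 5
with λ₀ = λ₁ tied). The unconstrained fit is warm-started from the
constrained optimum, so lnL_u ≥ lnL_c holds by construction and the LRT
statistic 2(lnL_u − lnL_c) is never materially negative (a deficit beyond
1e-6 raises). The test against χ²(1) is calibrated: simulated equal-rate
data (n = 50) reject at ~5%.

## Ancestral states

The Mk engine uses Felsenstein pruning with P(t) = expm(Qt) and per-node
rescaling; the default model is the 1-parameter symmetric Mk ("Mk1",
uniform root prior), for up to 7 states; asymmetric models are out of
scope. The rate is fitted by bounded 1-D ML on a log scale. Marginal
reconstructions use the standard inside/outside two-pass algorithm; each
internal node's vector is normalised and keyed by the tip set it subtends.
Pruning equals brute-force enumeration over interior states on small
trees to 1e-10 (property-tested).

Stochastic mapping samples, per tree and draw, a rate from a prior
(gamma(shape, scale) by default, or fixed) and then joint node states from
their exact conditional distribution given the tips (root from π·D, then
children from P[parent,·]·D). Marginal posterior probabilities are draw
frequencies aggregated over the trees containing each node, where node
identity across trees is the exact subtended tip set, and the count of
containing trees is reported per node. The historical prior-elicitation
MCMC for the mapping priors is replaced by this explicit configurable
prior — a deliberate, documented divergence. With a fixed rate on a single
tree the MPPs converge to the ML marginals (tested within Monte-Carlo
error). Only node states are sampled, not full character histories along
branches: dwell times and transition counts are not reported.

## Simulators: what they emulate, and what they do not

All generators grow trees forward from two crown lineages and condition on
the number of extant tips; with k lineages the next event waits an
Exponential(k·rate) time, and the tree is observed just before the
(n+1)-th tip would appear, so the final interval is a complete draw and
the complete-sampling gamma null is N(0,1) (the general-sampling
alternative of stopping exactly at the n-th birth would truncate the last
interval; the present convention is the one under which the package's
calibration properties are stated and verified). Fixed seeds give
byte-identical Newick; the rate acts as a pure time scale (the tree at
rate λ equals the rate-1 tree with durations divided by λ, same seed).

Birth–death and BiSSE trees are conditioned on n survivors by rejection
(default cap 10⁵ attempts), requiring both crown lineages to survive so
that the observed crown age matches the simulated one; extinct lineages
are pruned. Piecewise-rate trees take shift times measured forward from
the crown split — when conditioning on n the final depth is random, so a
shift cannot be pinned to an age before the present in advance; the
realised shift ages are attached to the returned tree for recovery
checks. Mk characters evolve by exact transition-matrix sampling down the
tree.

These generators emulate clean reconstructed chronograms with known
rates. They do not emulate: phylogenetic estimation error or calibration
uncertainty (no posterior spread around node ages), non-ultrametric or
polytomous summaries, fossil/extinct sampling, diversity-dependence
across clades, or correlated characters. Passing tests therefore show
that the estimators recover the truth of the generating models at the
stated sizes — not that a real chronogram, with its dating error and
non-random sampling, satisfies those assumptions.

## Problem sizes used in the test suite

Monte-Carlo test sizes were chosen to make each check statistically
decisive at its stated threshold: the three MCCR reference values use the
full B = 5000; gamma type-I calibration uses 2000 trees of 100 tips; the
ΔAIC-uniformity check uses 50 trials of B = 120 at n = 40; BiSSE LRT
calibration uses 200 replicates at n = 50; shift-recovery experiments use
100–200 replicates; MEDUSA recovery uses 60 13-terminal backbones. All
seeds are fixed in the tests, so the suite is deterministic.

## Known limitations

* The multi-rate Yule profiles overfit micro-intervals (see above); raw
  AIC ranks involving yule2rate/yule3rate should always be read against
  the Monte-Carlo null.
* MEDUSA-style ε estimates are weakly identified on small backbones; the
  per-regime ε frequently sits near a boundary. A fixed-ε variant is
  available (`fit(fixed_eps=...)`).
* BiSSE here has no sampling-fraction correction and assumes binary,
  fully observed tip states.
* The diversified-subsampling α scale is an interpretation, not a
  reproduction, of the cited non-random-sampling method.
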