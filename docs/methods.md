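# Methods

## The measurement model

The package studies one question: can study bias plus per-test error alone
produce power-law (PL) degree distributions in observed, aggregated
protein–protein interaction networks?  Two complementary formalizations are
implemented.

**Closed-form aggregated AP-MS testing** (`ppibias.analytic`).  A ground
truth G is an Erdős–Rényi graph on n proteins with edge probability p.
Protein u is selected b(u) times as bait; each selection tests all pairs
{u, v}.  A test of a true edge is positive with probability 1 − FNR, of a
non-edge with probability FPR, and a pair is observed if it is positive at
least once.  Hence

    Pr[{u,v} observed] = p·(1 − FNR^(b(u)+b(v))) + (1−p)·(1 − (1−FPR)^(b(u)+b(v))),

with the convention 0⁰ = 1 so that a never-tested pair is never observed.
For small FPR and p (both O(1/n)) the expected degree of v is bounded between
(1−p)·FPR·(n−1)·b(v) and the same plus the uniform constant
A = p·n + (1−p)·FPR·B, B = Σ b(u): expected degrees track the bait-usage
distribution up to an additive offset.  If b is PL-distributed, the expected
degrees are too — even at p = 0 (empty interactome).

The bait-usage surrogate (`powerlaw_bait_usage`) is i.i.d.: zero with probability
0.24 (the empirical fraction of never-baited proteins in large catalogs),
otherwise a discrete PL with exponent 3.13 and cutoff 1, matching the fitted
exponent of real bait-usage counts.  Its mean is
0.76·ζ(2.13)/ζ(3.13) ≈ 0.99.

**Iterative biased measurement** (`ppibias.simulate`).  Experiments are run
sequentially.  Experiment i samples n_bait baits without replacement with
probability ∝ deg_{i−1}(u) + δ, where deg_{i−1} is the degree in the
*currently observed* network — the feedback loop that models study bias —
and δ = 0.01 is a baseline weight so unstudied proteins remain reachable.
Preys are uniform in AP-MS mode and degree-biased in Y2H mode (both roles
are actively chosen in Y2H).  Every ordered bait × prey pair (self-pairs
skipped) receives one Bernoulli test; symmetric counters a (tested) and
b (positive) accumulate, and the observed edge set after each experiment is
{uv : b_uv > 0 ∧ b_uv/a_uv > γ} with strict inequality, γ ∈ [0, 1).
Weighted sampling without replacement is implemented with exponential race
keys (key_i = E_i / w_i, E_i ~ Exp(1)), which is distributionally identical
to sequential draw-and-renormalize.

## Power-law inference

`ppibias.powerlaw` implements the standard discrete fitting recipe: for each
candidate cutoff k_min (every distinct data value whose tail keeps at least
two observations and two distinct values), the exponent is the discrete MLE
maximizing −n_tail·ln ζ(α, k_min) − α·Σ ln k_i, found by golden-section
search on (1.01, 6.0] — the log-likelihood is concave in α, so the search is
exact to machine precision.  The winning cutoff minimizes the KS distance
between the empirical tail CDF and the fitted Hurwitz-zeta CDF; ties go to
the smallest cutoff (larger tails, deterministic).  Zeros are excluded
before fitting (isolated nodes carry no tail information); their fraction is
reported separately.  Excluding the largest distinct value from the
candidate set avoids a degenerate single-support-point tail whose MLE is
pushed to the search boundary.  The Hurwitz zeta is evaluated with
`scipy.special.zeta` (double precision, far below the 1e−10 relative error
the printed constants require).  All fits agree with the independent
`igraph.power_law_fit` implementation to ~1e−8 on common inputs (tested).

Goodness of fit is the semi-parametric bootstrap: each of 100 replicates
draws |data| values — from the fitted tail with probability n_tail/|data|,
otherwise uniformly from the empirical body below k_min — and is re-fitted;
the p-value is the fraction of replicate KS distances at least as large as
the observed one, computed over the replicates whose re-fit succeeded.  A
result is invalid when more than 10% of replicates fail, and the PL is
"plausible" when the test is valid and p ≥ 0.1 (the field's convention; the
threshold is inclusive).

## Synthetic study catalogs

`synthetic_catalog` emulates the descriptive statistics of real catalogs
without any download: per-protein research-interest weights from the
zero-inflated PL family above; long-tailed study sizes (bait counts from a
discrete PL with exponent 2.5, capped at a tenth of the proteome — most
studies are tiny); a log-uniform bait/prey size balance on [0.02, 1]
spanning symmetric to highly asymmetric designs; interest-proportional bait
selection; and the per-test error model against a supplied ground truth.
What it does *not* emulate: cell-line expression restriction, abundance- or
mass-dependent detectability, matrix-vs-spoke expansion of n-ary complexes,
and indirect bias pathways (annotation databases); passing tests therefore
show that the *mechanisms* behave as specified, not that real catalogs are
quantitatively reproduced.

## Numerical and design choices

* **One-shot exemplifier.** Sampling all ~1.4·10⁸ pairs at n ≈ 17,000 is
  avoided by grouping proteins into bait-usage classes: the edge probability
  is constant within a class pair, so the number of edges is one binomial
  draw, assigned to uniformly sampled member pairs (distinct indices drawn by
  rejection; triangular decoding within a class).  Cost is near-linear in n
  plus the realized edge count, and the mean degree matches the exact
  enumeration Σ p_uv (tested to 3 Monte-Carlo standard errors).
* **Simulator backends.** The public counters are a sparse symmetric map;
  `simulate()` switches to dense numpy count matrices for integer-labelled
  graphs up to n = 4000 and updates the γ rule incrementally on the touched
  pairs only.  Both paths produce bit-identical results for the same seed
  (tested).
* **ΔSOD.** Two variants ship: the plain form (Σd_BA − Σd_ER)/Σd_ER and a
  range-normalized form dividing by max(Σd_BA, Σd_ER), which is guaranteed
  to lie in [−1, 1]; they always share sign.  The plain form is the default;
  it is undefined when Σd_ER = 0, in which case callers are pointed to the
  normalized variant.
* **EMD** is computed between normalized degree PMFs (networks of different
  sizes must be comparable), via `scipy.stats.wasserstein_distance`.
* **K-NN ties** are broken deterministically: distance, then BA before ER,
  then insertion index.
* **BA sizing.** To match an ER edge count m_ER, the BA edges-per-step is
  m_BA = round(n/2 − √(n²/4 − m_ER)); the grown graph has exactly
  m_BA + m_BA·(n − m_BA − 1) edges.  Rounding m_BA by up to 1/2 moves the
  final edge count by up to ~n/2 (0.4% at n = 1000, m_ER = 4000).
* **Randomness.** Every stochastic operation takes an explicit seed or
  `numpy.random.Generator`; there is no global state, and all derived seeds
  stay below 2³¹.

## Problem sizes used in the shipped checks

The end-to-end checks run at "desk scale", chosen so the full suite stays
comfortable on one CPU: the analytic exemplification at the full n = 16,777
with 10 seeds; fit calibration with 200 null datasets of n = 1000 and 100
bootstrap replicates each; ER rejection at n = 2000 over 50 seeds; and the
tipping-point grid at n = 1000 nodes, 2000 edges, 10 networks per arm,
5 seeds over the 9-point FPR ladder {0} ∪ {0.4·2⁻⁷ … 0.4}.  The number of
experiments per simulated campaign in the tipping check is 1200: campaigns
must be long enough that the error-free measured reference covers its
ground truth well (with the long-tailed study-size model, 1200 experiments
test ≈ 12% of all pairs), mirroring the density of real aggregated
reference networks; much shorter campaigns leave all measured networks
almost empty and the ensemble comparison is then dominated by sampling
noise rather than topology.  The full-scale grid (two methods × 5 FNRs ×
9 FPRs × 2 γ = 180 cells, 50 networks per arm) is expressible through the
same `GridConfig` and is checked for cardinality, not executed, in the test
suite.

## Known limitations

* The analytic bait-usage surrogate has its PL tail from k_min = 1; real
  bait-usage histograms are heavier in the body (fitted cutoffs around 8).
  Finite-n fits of degree sequences generated from the surrogate therefore
  land their KS-selected cutoff near the additive-offset bulk and estimate
  tail exponents well above 3.13 (≈3.6 at FPR = 1/1700 — matching the
  published exemplification — and ≈4.6 at FPR = 1/n); the bait-usage
  exponent itself is only recovered asymptotically in the far tail of the
  expected degrees.
* ΔSOD's plain form is unbounded above; comparisons across FPR values use
  the sign and trend, not the magnitude.  Against a *simulated* error-free
  reference (unlike a real aggregated one), ΔSOD saturates near zero beyond
  the tipping point — both ensembles become equally noise-dominated and
  equidistant — so the informative signature is the rise from the strongly
  negative FPR = 0 floor and the sign change, not monotonicity across the
  whole FPR ladder.
* On heavily tied discrete data (a power law with cutoff 1 puts ~85% of the
  mass on k = 1) the KS-based bootstrap is mildly conservative in its low
  tail: under the null, p-values below 0.1 occur slightly less often than
  10% of the time.  This makes plausibility verdicts err on the side of
  *accepting* the power law, which is the conservative direction for this
  package's argument.
* `read_mitab_lite` interprets the minimal robust column subset
  (identifiers, detection method, publication, experimental roles) and keeps
  identifier strings verbatim; cross-database identifier reconciliation is
  out of scope.
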