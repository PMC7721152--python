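# Methods

## Model

Every experimental group is a binomial experiment over one observed answer
dichotomy ("option A" vs "option B").  Under direct questioning (DQ) the
option-A ("agree") probability equals the prevalence π of the sensitive
attribute.  Under the crosswise design with randomization probability
p — the known prevalence of the non-sensitive companion statement — the
processing tree gives the option-A ("exactly one statement") probability

    λ(π) = π(1 − p) + (1 − π)p = p + π(1 − 2p),

so λ is confined to the band [min(p, 1 − p), max(p, 1 − p)] and the design
is uninformative at p = 0.5 (the package rejects it).  The extended
crosswise model (ECWM) is two crosswise groups with complementary
probabilities p and 1 − p sharing one π; the joint model for the pair has
two observed frequencies and one parameter, hence one degree of freedom.

All likelihoods are product-binomial kernels (binomial coefficients are
omitted; they cancel in every likelihood-ratio statistic computed here).
The convention 0·ln 0 = 0 applies; a boundary λ contradicting observed
counts gives −∞ rather than an exception.

## Estimation

*Per group (closed form).*  π̂ = λ̂ for DQ; π̂ = (λ̂ − p)/(1 − 2p) for
crosswise, with delta-method SE √(λ̂(1 − λ̂)/(n(1 − 2p)²)).  Sampling noise
can push λ̂ outside the design band and hence π̂ outside [0, 1]; the raw
value is always reported, with a clipped companion and a `truncated` flag,
because out-of-range estimates are diagnostic information, never silently
discarded.

*Pooled (EM).*  The shared π of a multi-group crosswise dataset is fitted
by expectation maximization: the E-step attributes expected carrier counts
per group (among option-A responders `count_a·π(1−p)/λ`, among the rest
`(n−count_a)·πp/(1−λ)`), the M-step sets π to total expected carriers over
total n.  Defaults: tolerance 10⁻¹⁰ on successive π, at most 10⁴
iterations, start at 0.5 — cheap and robust for a unimodal one-parameter
likelihood.  Plain EM converges only linearly and becomes very slow when
the maximum sits at or near a parameter boundary, so each double EM step is
followed by an Aitken Δ² extrapolation, accepted whenever it stays in
[0, 1] and does not decrease the likelihood.  Agreement with direct bounded
1-D maximization of the log likelihood to |Δπ| < 10⁻⁶ is asserted in the
test suite on randomized datasets.  Non-convergence raises an error
carrying the full iteration trace.

*Standard errors.*  From the inverse observed Fisher information
I(π) = Σ_g n_g (1 − 2p_g)²/(λ_g(1 − λ_g)) (slope 1 instead of 1 − 2p for a
direct group).  For a complementary-p pair split equally, this information
is identical to a single CWM group of the same total n — the extension's
fit test is free in efficiency terms; the identity is asserted to 10⁻¹².
Confidence intervals are Wald 95% (π̂ ± 1.96·SE) clipped to [0, 1]: the
simplest interval consistent with the reported standard errors.

## Inference

All model tests are nested likelihood-ratio comparisons, asymptotically
χ² with one df per restriction:

- *Goodness of fit* (ECWM pair): G² = 2[ℓ_saturated − ℓ_pooled], where the
  saturated model fixes each group's option-A probability at c/n.  An
  equivalent cell formula 2Σ obs·ln(obs/exp) is kept as an independent
  oracle in the tests.
- *Equality of prevalences* across two datasets: the restricted shared-π
  fit uses bounded Brent maximization over [0, 1] (tolerance 10⁻¹⁰) rather
  than EM, since the mixed DQ + crosswise likelihood is still unimodal in
  one parameter; EM equivalence on all-crosswise data is tested.
- *Fixed-constant tests* (e.g. π = 0): when the constant assigns zero
  probability to an observed answer the statistic is reported as +∞ with a
  boundary flag — never as a large finite surrogate.  A DQ dataset with
  affirmative answers tested against π = 0 is the canonical case: the pure
  binomial likelihood diverges, and any finite printed value for such a
  test implies an unstated small lower bound on π (a bound near 10⁻⁸
  reproduces magnitudes around 1.5·10³ at the bundled data's size).  The
  package deliberately does not adopt such a constant.
- Negative statistics beyond −10⁻⁸ raise; values in (−10⁻⁸, 0) are clipped
  to 0.  p-values are χ² upper tails; p(G² = 0) = 1.
- *Contingency analyses* (dropout, demographics): Pearson χ² without
  continuity correction (Yates' correction would be inconsistent with the
  reproduced value on the bundled table) and Cramér's V =
  √(χ²/(N(min(r,c) − 1))).  No multiple-testing adjustment anywhere.

## Power

Variances are design-based and evaluated at each arm's assumed prevalence
(not at a pooled null): direct π(1 − π)/n, crosswise λ(1 − λ)/(n(1 − 2p)²),
ECWM pair the inverse summed information.  Power of the two-sided Wald test
of π_a = π_b is Φ(z_eff − z_{1−α/2}) + Φ(−z_eff − z_{1−α/2}) with
z_eff = |π_a − π_b|/√(var_a + var_b); it reduces to α at zero effect.
`required_total_n` allocates the total 2:1 between the indirect and the
direct arm by default — the standard compensation for the randomization-
induced variance inflation — splits a multi-group arm near-equally
(floor/ceil), and returns a locally minimal N (N passes, N − 1 fails),
found by bisection plus a downward walk to absorb integer-allocation
rounding.

## Simulator

`simulate_study` draws, per respondent: carrier status ~ Bernoulli(π_true),
non-sensitive statement ~ Bernoulli(p) (drawn, but unused, for direct
groups and non-adherent respondents, keeping the record layout uniform),
then a response mechanism from a single uniform draw — careless with
probability c, option preference with probability d (optionally restricted
to carriers or non-carriers; out-of-scope respondents fall back to
adherent), else adherent.  Careless respondents answer by a fair coin;
preference respondents deterministically pick the target option; adherent
respondents follow the tree (crosswise: option A iff carrier XOR
statement).  The careless-then-preference order with disjoint rates keeps
the marginal biased answer probability exactly

    λ′ = c/2 + d·1[target = A] + (1 − c − d)λ   (scope "all"),

which `bias_implied_estimates` inverts per group.  Two consequences drive
the test design: a fair coin preserves the complementarity λ₂ = 1 − λ₁, so
careless responding biases the pooled estimate toward 50%
(E[π̂] = (1 − c)π + c/2) while remaining invisible to the fit test; an
option preference breaks complementarity and is what the fit test detects.

Randomness: one master seed; per-group substreams are seeded by
(seed, crc32(label)), so output is reproducible and independent of group
order.  `replicate_counts` is a vectorized count-level path drawing group
counts directly as Binomial(n, λ′) — exactly the marginal law of
aggregating respondent records, since mechanisms are iid per respondent —
used for Monte-Carlo calibration studies where respondent records are not
needed.

What the simulator does not model: social-desirability lying under direct
questioning (the quantity the design comparison is meant to expose, not a
specified generative mechanism), respondent-level heterogeneity in p
(imperfect knowledge of the non-sensitive fact), and any non-iid answer
dependence.  Passing calibration tests therefore show the machinery is
correct under the stated mechanisms, not that real surveys satisfy them.

## Reconstructed study inputs

The bundled fixture carries the answer counts of a published two-arm survey
(ECWM p = .158/.842 with n = 455/456; DQ with n = 450), recovered from the
printed prevalence estimates by exhaustive search over integer counts
(`reconstruct_count`): a count matches if its closed-form estimate, rounded
half-away-from-zero to two decimals in percent, equals the printed value.
Published tables occasionally round an intermediate proportion before the
final division, which can shift the last printed digit by one; when no
count matches exactly, a unique candidate within 0.01 percentage points is
accepted.  That fallback is exercised by the p = .158 group: 140/455 gives
21.8848% at full precision (21.88 rounded), while the printed 21.89 arises
from a four-decimal intermediate rounding of λ̂.  All three reconstructed
counts are cross-validated simultaneously against the printed standard
errors, fit statistic, comparison statistics, and power.  The
dropout-by-condition table [[42, 507], [56, 1024]] is likewise the unique
integer table consistent with the printed marginals and dropout rates.

## Problem sizes in the test suite

Deterministic reproductions run on the study-sized counts (n ≤ 1361) and
complete in milliseconds.  Monte-Carlo calibration uses the study's group
sizes (455 + 456) with 5000 replicates for type-I error, 1000 for
parameter recovery, 2000 for the bias studies, and 10⁴ for the power
check — via the count-level fast path, these are seconds-scale.

## Known limitations

- Asymptotic inference only: no exact small-sample tests, no Bayesian
  estimation, no covariate extensions of the crosswise model.
- Wald intervals degenerate at boundary estimates; the boundary flag is the
  signal to distrust them there.
- `required_total_n` optimizes only the total n at a fixed allocation
  ratio; it does not search over randomization probabilities.
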