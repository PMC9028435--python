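# Methods

## Evidence representation

All reasoning happens on the two-hypothesis frame {positive, negative}.  A
source's state of knowledge is a normalized mass triple (α, β, θ): belief in
positive, belief in negative, and mass on "either" (uncertainty), with
α, β, θ ≥ 0 and α + β + θ = 1.  Plausibility of the positive status is
α + θ = 1 − β.  θ = 0 recovers ordinary complementary probabilities
("Bayesian" evidence); (0, 0, 1) is the vacuous triple and the identity of
both conjunctive combination rules.

Numerical conventions: triples are validated with an absolute mass-sum
tolerance of 1e-9 — sums within tolerance are renormalized, anything beyond
is rejected; tiny negative masses from floating-point cancellation (within
1e-9 of zero) are clamped to zero before validation.  Dempster combination
of totally conflicting evidence (conflict K = 1) raises a dedicated error
rather than returning a sentinel, since the rule's denominator vanishes.

## Evidence sources

**Gene expression.**  A logistic responsibility function
r₊(x) = expit(c₀ + c₁x) estimated per gene by maximum likelihood
(statsmodels `Logit`; Newton iterations, no regularization — perfectly
separable data is reported as an error with the diverging direction, never
silently ridged).  Beliefs are capped responsibilities α = α̂·r₊,
β = β̂·r₋; with caps strictly below one, θ ≥ 1 − max(α̂, β̂) > 0 for every
finite x, so expression alone never eliminates uncertainty.  The β̂ cap is
kept as a separate configurable constant defaulting to β̂ = α̂, preserving
the symmetric scaled form.  Default caps are 0.9.

**IHC.**  A fixed evidence triple per categorical status.  Defaults:
(+) → (0.85, 0, 0.15), (−) → (0, 0.85, 0.15), unknown → (0, 0, 1).  These
are conservative reconstructions chosen by this package, not published
constants, with two properties: the opposing belief is zero, and θ = 0.15
is small enough that capped expression evidence can weaken but never invert
an IHC call into the opposite definite call (verified as a cohort-level
test).  All entries are config-overridable.

## Fusion pipeline

Per receptor: E_gene ⊕D E_cogene, then ⊕Y E_IHC.  The Dempster step merges
the two correlated-but-distinct expression channels sharply; the Yager step
merges expression with IHC softly, so expression-vs-IHC contradiction ends
up as uncertainty rather than as a confident overruling of the assay.
Because Yager's rule is not associative, this order is part of the
contract and the three input triples are retained as provenance on every
call.  A missing expression value contributes vacuous evidence, leaving the
rest of the fusion untouched.

The two receptor evidences merge by the OR-rule
α_H = α_ER + α_PGR − α_ER·α_PGR, β_H = β_ER·β_PGR (θ_H by complement, which
is algebraically β₁θ₂ + θ₁β₂ + θ₁θ₂ ≥ 0): the mass-function counterpart of
the clinical "positive if either receptor is positive".  Two sub-threshold
positive receptors (e.g. α = 0.4 each) can jointly cross the border
(α_H = 0.64).

**Decision rule.**  pos iff α > t, neg iff β > t, else inconclusive, with
t = 0.5 by default and t restricted to [0.5, 1) so at most one belief can
exceed it.  The inequality is strict: border evidence stays inconclusive.
The defining texts use "exceeds 0.5" and "≥ 0.5" in different places; the
strict reading is adopted here as the conservative choice, and the geometry
module assigns regions identically so the algebraic and ternary views can
never disagree.

## Ternary geometry

Corner convention (fixed, not configurable, so plots stay comparable):
β = 1 at (0, 0), α = 1 at (1, 0), θ = 1 at (1/2, √3/2); a triple projects
to x = α + θ/2, y = θ·√3/2, which is invertible on the triangle.  Constant-α
loci project to straight segments, so the decision borders α = t and β = t
are straight lines; the regions are the positive and negative corner
triangles and the inconclusive kite between them.  Rendering (matplotlib)
dual-codes samples — position from the fused evidence, color from a second
classifier, open circles for samples with unknown IHC — and the projected
coordinates can be exported as TSV for downstream checks.

## ODDS baseline

A deliberately simple stand-in for the conventional score-based
comparator: per receptor, score = w_g·(c₀ + c₁x_gene) +
w_c·(c₀′ + c₁′x_cogene) + offset(IHC status), i.e. weighted per-gene
log-odds plus an additive IHC shift; neg below t_neg, pos above t_pos,
inconclusive between; a crisp three-valued OR across receptors.  The
original score formulas are defined in prior work that is not reproduced
here; every constant (weights 1.0/0.5, offsets ±2, thresholds ∓1) is a
placeholder and configurable.  The module exists so the comparison
machinery (cross-tabulation, κ, divergence subsets) operates on a
structurally faithful baseline, not to reproduce the baseline's published
operating point.

## Agreement statistics

The 3×3 cross-tabulation is ordered neg / inc / pos with the baseline in
rows.  Cohen's κ = (p_o − p_e)/(1 − p_e) is computed unweighted from the
table; it matches both a brute-force implementation from the raw call lists
and scikit-learn's independent implementation in tests.  Percentages are
kept at full precision internally and rounded to one decimal only for
display.  Divergence subsets: "adding information" = baseline-inconclusive
but fusion-positive; "increasing safety" = baseline-positive but
fusion-inconclusive; everything else off-diagonal is reported as "other".

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, per
sample: latent ER and PGR positivity (Bernoulli, prevalences 0.70 / 0.60,
associated with odds ratio 4 — receptor statuses co-occur in real cohorts,
and the PGR co-gene *is* ER expression, so independence would make that
channel vacuous); class-conditional Gaussian expression (ER gene 12 vs 8,
common SD 2; co-gene correlated 0.6 within class; PGR gene 10.5 vs 7.5);
IHC = latent status flipped with probability 0.15 (the reported
misclassification range is 10–20 %) and masked to unknown with probability
0.05.  Identical spec + seed gives bit-identical cohorts.

With equal class SDs the latent posterior log-odds is exactly linear in
expression — slope (μ₊ − μ₋)/σ², intercept log(p/(1−p)) − (μ₊² − μ₋²)/(2σ²)
— so the logistic responsibility model is correctly specified and parameter
recovery has a closed-form target (slope 1, intercept −10 at prevalence
0.5 with the defaults).  `recovery_experiment` fits against the *latent*
labels: that isolates the estimator.  Fitting against noisy IHC labels
instead attenuates the slope toward zero; that bias is a property of label
noise, not of the fitter, and cohort-level model fitting in the pipeline
does use the noisy labels (as any real application must).

What the synthetic cohorts do **not** emulate: microarray normalization and
batch effects, heavy-tailed or multimodal within-class expression,
informative missingness of IHC, and the real cohort's class-conditional
distributions (published only graphically).  Passing tests therefore
establish internal correctness and the direction of the fusion benefit
under the assumed generative model — not clinical performance.

## Problem sizes used in the test suite

Chosen to make the statistical assertions stable: algebra invariants on
10⁴ random Dirichlet triples plus an exhaustive 0.1-mass grid against
brute-force focal-set oracles; parameter recovery at n = 2000 (asserted
within 3 standard errors, fixed seed); the end-to-end comparison — fused
calls versus IHC-alone accuracy on decided samples — at n = 5000 with 15 %
IHC error; rate-concentration checks at n = 10⁴–4·10⁴.

## Known limitations

- The belief caps and IHC evidence constants shipped as defaults are this
  package's conservative choices; real deployments must calibrate them.
- The ODDS baseline is a reconstruction; κ values against it on synthetic
  data say nothing about the published baseline's agreement.
- Only two hypotheses per frame are supported; richer frames (and the
  PCR5 / Dubois–Prade / discounted rules that become interesting there) are
  out of scope.
- One co-gene per receptor; the Yager step's non-associativity means
  extending to more sources requires an explicit order or a different rule.
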