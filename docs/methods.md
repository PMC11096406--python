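# Methods

`burnskin` re-creates, as a tested pipeline, a uniaxial-tension analysis of
full-thickness burn human skin: specimens are pulled to rupture at one of
three grip speeds (0.3, 2.0 or 8.0 mm/s), five material parameters are
extracted per specimen, and two statistical stages ask whether any of them
depends on the loading rate. Because the underlying specimens are not
publicly available, the package ships a synthetic-cohort generator that
emulates the cohort's reported distributional structure; every result the
tests and the acceptance script state is computed on those synthetic
cohorts.

## Constitutive model

The stress–strain response is described by the Veronda–Westmann isotropic,
incompressible hyperelastic law,

Ψ(Ī₁, Ī₂) = (μ/γ)(e^{γ(Ī₁−3)} − 1) − μ(Ī₂ − 3),

with stiffness scale μ (MPa) and strain-stiffening exponent γ (–). Under
uniaxial kinematics with principal stretch λ = 1 + ε_N, Ī₁ = λ² + 2/λ and
Ī₂ = 2λ + 1/λ², the nominal stress along the loading axis is

σ_N = 2μ(1 − λ⁻³)(λ e^{γ(Ī₁−3)} − 1),

which is exactly dΨ/dλ (verified numerically to 1e−6 relative over
λ ∈ [1.01, 3], μ ∈ {0.1, 0.32, 1}, γ ∈ {0, 0.07, 0.5}). Two analytic
details worth knowing:

- **γ = 0 limit.** The energy's μ/γ prefactor is handled by the series
  limit μ(Ī₁ − Ī₂); the stress expression is already regular at γ = 0.
- **Flat toe.** This parameterization has zero initial tangent modulus:
  σ_N = 6με² + O(ε³) at small strain. The toe-region flatness is a feature
  of the model family, and the test suite asserts the quadratic onset
  rather than a linear one.

## Curve processing

Nominal measures are σ_N = F/A₀ and ε_N = ΔL/L₀ with the undeformed gauge
geometry. The failure peak is the global stress maximum; when the maximum
extends over a contiguous plateau the last plateau index is used (so a
degenerate constant curve retains its full area), while non-contiguous
ties keep the first peak. Ultimate tensile (UT) stress and strain are read
at that index; toughness is the trapezoidal integral of stress over strain
from the origin to the peak, excluding any post-peak tail — the choice
makes the property well defined on noisy rupture tails and is invariant to
appending post-peak points. Raw signals are not smoothed; an optional
cleaning step drops non-monotone displacement points with a warning.

## Parameter estimation

(μ, γ) are estimated per specimen by bounded nonlinear least squares
(trust-region reflective) on the unweighted nominal-stress residuals of
the peak-truncated curve, with the analytic Jacobian. Bounds are
μ ∈ (10⁻⁶, 10³) MPa and γ ∈ [0, 50]; γ < 0 is excluded because it destroys
the convexity of the exponential term. Initialization uses the secant
slope over the first 10% of strain divided by 6 for μ₀ (a deliberate,
bounded heuristic — see the toe-region note above) and γ₀ = 0.05;
noiseless curves are recovered to 1e−6 relative and the fit is idempotent
on its own predictions. Residuals are scaled by max(1, max|σ|) — which
does not move the minimizer — and clipped at 1e100 purely so that
far-tail synthetic specimens cannot overflow the solver. R² is computed
on nominal stress. A small plugin interface (`HyperelasticLaw`) exposes
the same fitting machinery to alternative uniaxial laws.

## Synthetic cohorts

The generator draws, per specimen, (μ, γ, rupture strain) independently
from lognormal laws calibrated by median and quartiles:
location = ln(median), scale = ln(q75/q25)/(2·z₀.₇₅). The default
triplets are the pooled burn-skin values μ: 0.32 [0.17, 0.66] MPa,
γ: 0.07 [0.01, 0.12], rupture strain: 1.69 [1.27, 2.47]. The lognormal
family was chosen because all five parameters are strictly positive and
strongly right-skewed; quartile calibration avoids assuming moments.
γ's triplet is not log-symmetric, so its calibrated law matches the
median and the quartile *ratio* only — a documented approximation that
gives γ a very heavy right tail (log-scale ≈ 1.84).

UT stress and toughness are **not** sampled: each specimen's curve is the
Veronda–Westmann stress on an even strain grid [0, rupture strain]
(100 points by default), so those two properties emerge through the
physical coupling of stiffness, stiffening and failure strain. Multiplicative
Gaussian noise with CV 0.03 (a typical load-cell signal-proportional error)
perturbs the stress, floored at 10⁻⁴ MPa; with the noise off the curves
are exactly the constitutive law. Curves are converted to force and
displacement through ASTM D638 Type V gauge dimensions (L₀ = 7.62 mm,
A₀ = 3.18 mm × 2.1 mm, the cohort's mean thickness).

Defaults reproduce the screened cohort sizes (95, 92, 102) and rates; the
loading-rate label has **no** effect on the generating law by default
(`rate_effect = 0`), encoding the rate-independence null. A scalar
`rate_effect = r` shifts the log-location of every parameter of class k
by k·r·scale (classes ordered by rate) for power and direction studies.
One master seed drives everything; per-stage seeds are derived by hashing
stage names, so identical configuration gives byte-identical artifacts.

**What the generator does not emulate:** anisotropy and Langer-line
orientation, viscoelastic (truly rate-dependent) mechanisms, anatomical
location effects, machine compliance, and — importantly — any dependence
*between* μ, γ and rupture strain. Real tissue almost certainly couples
them (stiffer, more strain-stiffening specimens tend to rupture earlier).
One visible consequence: with independent draws and γ's heavy tail, the
*emergent* median UT stress of a large cohort sits near 2.4 MPa rather
than at the value the law gives at the median parameters (≈ 1.7 MPa,
matching the reported real-data median of 1.73 MPa). Passing tests on
these cohorts therefore validate the pipeline's statistical behavior, not
the joint distribution of real burn-skin parameters.

## Outlier screen

A specimen is removed when any of its five parameters falls outside
[Q1 − 3·IQR, Q3 + 3·IQR], with linear-interpolation quantiles computed
once on the pooled cohort (single pass; fences are not recomputed after
removal; boundary values are kept). Because the parameters are bounded
below by zero and right-skewed, removals occur almost exclusively above
the upper fence. A per-rate-group fence scope is available behind a flag
and is the appropriate setting when a large between-rate effect is
injected, since pooled fences would then flag an entire shifted class.

## Univariate decision tree

Each parameter is compared between each pair of rates at α = 0.01:
Shapiro–Wilk on both groups; if both retain normality, a two-sided F-test
routes to the pooled- or unequal-variance t-test; otherwise the two-sample
Kolmogorov–Smirnov test routes to the Wilcoxon rank-sum test (same
shapes) or the unequal-variance t-test (different shapes). The terminal
p ≤ α concludes "not equal". The rank-sum test uses the exact null for
groups of ≤ 25 without ties, else the tie- and continuity-corrected
normal approximation; at the study's n ≈ 95 this terminal is slightly
conservative, and the tree's measured null rejection rate is ≈ 0.6–0.8%
at the nominal 1%. No multiple-testing correction is applied — decisions
are reported per pair, as they are interpreted. Cohen's d (pooled-SD,
absolute) accompanies every comparison.

Minimum sample size inverts the exact noncentral-t power of the
two-sample t-test (noncentrality d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2) by
bracketed bisection; the configuration d = 0.4, α = 0.05, power = 0.85,
allocation ratio 1, **one-tailed** yields 91 per group. The one-tailed
setting is the documented default because it is the configuration that
reproduces that published figure; tails are an explicit parameter.

## Multivariate classification

A multinomial logistic model predicts the rate class from the five
standardized features under leave-one-out cross-validation;
standardization uses each training fold's mean/SD, so the held-out sample
never leaks into the scaling. The model carries an L2 ridge of 10⁻⁶
(sklearn C = 10⁶), which guarantees a unique optimum under separation or
collinearity without materially changing dense-data fits — and makes
predictions invariant to duplicated feature columns.

From the LOOCV confusion matrix the package computes accuracy, the
multiclass (R_k) Matthews correlation coefficient (zero denominator ⇒ 0),
and the pair-counting Fowlkes–Mallows and Adjusted Rand indices; all
three agreement indices are implemented directly from the contingency
table and are cross-checked in tests against brute-force pair enumeration
and sklearn's vector-based implementations. Feature "contribution" is the
normalized mean absolute standardized coefficient per feature (a
permutation-importance variant is available); it summarizes coefficient
magnitudes and is not a latent-factor model.

## Problem sizes and determinism

The acceptance script uses 20 null cohorts of 95/92/102 specimens for the
classification averages, 2000 replicate pairs (n = 95 vs 92) for the
type-I-error estimate, and a 10,000-specimen cohort for the emergent
UT-stress median; the full script completes in well under a minute on one
core. All randomness flows from a single integer seed through named-stage
seed derivation; reruns are byte-identical.

## Known limitations

- The generator's independence assumption across (μ, γ, rupture strain)
  is a simplification with measurable consequences (see above).
- The decision tree's terminal tests inherit the finite-sample
  conservatism of the continuity-corrected rank-sum approximation.
- The pooled outlier screen assumes roughly exchangeable rate groups; use
  the per-rate scope when that is not plausible.
- True-stress conversion, optical strain measurement and machine
  compliance correction are out of scope.
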