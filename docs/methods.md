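# Methods

## Utility scales and chaining

Utilities are handled internally on the canonical [0, 1] fraction scale of
each session's anchor pair; 0–100 is presentation. The common scale is
anchored at Well = 100 and Dead = 0. States worse than dead are not
representable: both assessment parts bottom out at Dead, and negative
utilities are never elicited, so all values are clamped to [0, 100].

The HCV-viremic transplant state is assessed against a chained anchor pair
(transplant with an HCV-unexposed kidney as best, Dead as worst). The
elicited fraction r is returned to the common scale by the chained product
u = r · u(transplant). Normalization is applied per patient, per method,
before any aggregation. Because the anchor's utility multiplies a fraction
in [0, 1], a chained utility can never exceed its anchor's — a package-wide
invariant the tests enforce.

The SG utility u implies a maximum acceptable probability of immediate
death of 100 − u: at the indifference gamble the respondent accepts a
(100 − u)% chance of death in exchange for the best anchor otherwise.

## Adaptive titration

SG and TTO sessions maintain a bracket (low, high) ⊂ [0, 1] around the
indifference point. Answer semantics follow expected utility: the gamble's
expected value at best-anchor probability p is p on the fraction scale, so
choosing the gamble (or trading years down) implies the respondent's value
lies below the probe, which becomes the new upper bound; choosing the sure
state (or staying) makes the probe the new lower bound. Ties at the
threshold resolve to the sure/stay option.

Probes follow a ping-pong ladder (0.95, 0.05, 0.85, 0.15, 0.75, 0.25 by
default), served in order but skipping any rung not strictly inside the
current bracket; when none remain the session bisects the bracket until
its width is at most the resolution (default 0.005, i.e. 0.5 points on the
0–100 scale). A response that reverses the expected ladder pattern
automatically pushes the remaining rungs outside the bracket, so bisection
begins at the first reversal without special-casing. The question cap
(default 14 = 6 ladder rungs + ⌈log2(1/0.005)⌉ bisections) is a
configuration invariant, and the worst case over an exhaustive threshold
grid is 13 questions. The elicited fraction is the final bracket midpoint,
so a noise-free threshold respondent is always recovered within the
resolution; the test suite verifies this exhaustively over a 0.005-spaced
grid for SG and TTO.

Because every probe lies strictly inside the current bracket, every answer
shrinks the bracket and is self-consistent by construction; repeated-probe
consistency checks (and hence inconsistency flags) are not part of this
design. Full transcripts (question, response, bracket after each answer)
are recorded and exportable as JSON lines.

**TTO horizons and the month grid.** The horizon is the patient's remaining
life expectancy from a period life table (CSV columns `age,sex,ex`),
rounded to the nearest whole year with a floor of 1. Offers are posed in
whole months (horizon × 12 grid): at typical horizons this keeps the offer
granularity at or below the 0.5-point utility resolution, and the session
terminates early if no interior month remains in the bracket (short
horizons then limit precision to half a month). The bundled life table is
**synthetic** — linear declines of 0.8 years of expectancy per year of
age, female above male — intended for tests and demos; any real period
life table with the same columns can be substituted, subject to the
validation rules (contiguous ages, strictly decreasing expectancy).

**VAS** is a single thermometer placement, not adaptive, per standard
feeling-thermometer semantics.

## Simulated respondents

A respondent carries latent state utilities on [0, 1] (Well fixed at 1,
Dead at 0), an additive per-method bias clamped to [0, 1], and an optional
per-question Gaussian perturbation of the comparison threshold (seeded,
reproducible). Additive bias is the simplest mechanism that yields the
well-documented SG > TTO/VAS elevation of risk-averse respondents; a
probability-weighting hook would be the natural extension. In a chained
session the respondent's target is the latent target utility divided by
the latent utility of the chained anchor state (clamped to [0, 1]); a zero
anchor latent is rejected as degenerate. Noise perturbs the threshold per
question rather than the final utility, mirroring choice-model convention.

## Synthetic cohorts and calibration

The generator reproduces the study's marginal structure for n = 63
patients: exact counts for race (44/19), gender (33/30), education
(10/25/11/5/9/3) and prior transplant (9); ages from a [21, 80]-truncated
normal matched to mean 57.8/SD 12.3; per-race dialysis vintage (means
7.3/2.79 years; the per-race SDs are not published, so 8.8/3.0 were chosen
to pool near the published overall 8.1); knowledge scores on the 10-point
item grid; and per-(state, method) latent utility marginals matched to the
published mean/SD pairs. Arms are assigned by seeded permuted-block
randomization (blocks of 4; block size 0 selects simple randomization).
The mismatched arm flips race and keeps gender. All outputs are
deterministic given (calibration, seed).

**Truncated-normal moment matching.** `calibrate_truncated_normal` solves
the two truncated-moment equations by nested root-finding (mu for the
mean at fixed sigma, then sigma for the SD) to 1e-6. Two infeasibility
regimes are detected: the Bhatia–Davis bound (no [0, 100]-supported
distribution can have variance above (100 − m)(m − 0)), and the family
frontier — as sigma → ∞ a truncated normal tends to an exponentially
tilted uniform, capping the attainable SD at a given mean (≈16.8 at mean
82.5, ≈10.9 at 89, ≈21.7 at 75.5). Several published (mean, SD) pairs lie
beyond that frontier (real utility data are bimodal-ish, with mass at 100
and a long tail, which a truncated normal cannot imitate). The cohort
generator therefore uses a relaxed fit that matches the **mean exactly**
and takes the largest attainable SD; realized utility SDs are accordingly
smaller than the published ones, while all mean-level round trips are
unaffected. Moments are computed by peak-recentred Gauss–Legendre
quadrature, which stays accurate in the deep-tail/tilt regime where naive
truncated-moment formulas lose all precision.

**Shared-rank coupling.** A single uniform rank per patient is mapped
through every (state, method) marginal's quantile function, so a patient's
latent utilities are comonotone — the published tables give no joint
distribution, and the shared rank preserves every marginal while inducing
realistic positive within-patient dependence. A useful consequence for the
chained round trip: the chained normalized utility equals
min(latent HCV, latent transplant) up to elicitation resolution, and under
the calibrated marginals the HCV quantile never exceeds the transplant
quantile, so the chained grand mean reproduces the HCV target mean.

**Knowledge scores.** Pre-test scores are drawn from a truncated normal
matched to mean 79.0/SD 17.3 and rounded to the 10-point grid. Because the
scale is capped at 100, adding an unadjusted N(10, 13.8) change draw would
realize a mean change of only ~6 points after clamping. The change-draw
parameters are therefore calibrated against the exact discrete pre-score
distribution (binned normal integration over the 11 grid levels) so that
the realized clamped-and-rounded change matches mean 10.0 and SD 13.8;
both moments are attainable (the calibrated draw is ≈ N(19.6, 19.0)). An
optional arm-effect parameter shifts the matched arm's change mean and
defaults to 0, matching the published absence of an arm effect.

## Statistics

* **Rank-sum (Mann-Whitney)** and **signed-rank (paired Wilcoxon)** tests
  use midranks for ties; exact p-values by full enumeration when total
  n ≤ 12 (rank-sum) or nonzero-difference n ≤ 15 (signed-rank) — caps at
  which enumeration stays well under a second — otherwise the
  tie-corrected normal approximation with continuity correction. Zeros are
  dropped before signed ranking (conventional). Results carry their
  exact-vs-approximate provenance. Exactness is verified in tests against
  independent brute-force enumeration and against scipy in tie-free cases.
* **Cronbach alpha** uses the standard k/(k−1)(1 − Σ item variances /
  total variance) with sample (n−1) variances; zero total variance is an
  error.
* **Power**: the smallest integer per-arm n whose two-sided two-sample t
  test reaches the target power under the noncentral-t distribution
  (df = 2n − 2, ncp = (δ/σ)√(n/2)), floored at 2. With δ = σ it returns
  17; with δ = 12 and σ = 16.3 it returns 30 — the published design n,
  whose assumed SD is not stated and was back-solved to ≈16.3 and kept as
  a fixture constant, not presented as the authors' input.
* **Ranking proportions** count strict within-patient orderings
  (HCV-viremic below hemodialysis) with missing pairs excluded and
  reported; percents round to the nearest integer in prose-style output
  and to one decimal in table-style output, matching the two reporting
  conventions.
* **Summary tables** mirror the published layouts: mean (SD) per
  (method, state) or per knowledge test, overall and per stratum
  (arm or race), with a rank-sum p per row. The change-score row is
  emitted in both stratifications, since the published arm-level p for it
  is reported ambiguously.

## What the simulations do and do not show

Passing round trips demonstrate that the elicitation engines, chaining,
normalization and calibration are mutually consistent at the published
mean level — not that real patients behave like threshold respondents.
Real response data feature intransitivities, scale clumping (multiples of
5/10), and heavier tails than the truncated-normal latents; the published
patient-level p-values, Cronbach alphas (.990/.994) and stratified
subgroup means cannot be recomputed without the raw data and are not
reproduction targets. Monte-Carlo problem sizes (500 replicate cohorts of
63; 10,000 replicates for the power simulation) were chosen so Monte-Carlo
standard errors sit well below the half-point elicitation resolution.

## Numerical choices

Bracket arithmetic is plain binary floating point; termination compares
width ≤ resolution exactly, and TTO probes are snapped to the month grid
with round-half-to-even. Life-expectancy rounding is half-up with a
1-year floor. Exact-test p-values compare enumerated statistics with a
1e-9 slack to absorb midrank float noise. Truncated-normal root-finding
brackets expand geometrically to cover the tilt regime (mu ≈ θσ² far
outside the support). Seeds below 2³¹ derive all randomness through
`numpy.random.default_rng`.
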