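# Methods

## Stimulus model

Every stimulus is a parabolic approach path in the observer's sagittal plane.
A path is fixed by its flight duration *D* (s), horizontal range *L* (m) and
gravitational acceleration *g* (m/s², default 9.8): the vertex height is
*h = gD²/8*, the launch angle atan(4h/L), and launch and arrival are at eye
height.  The nine conditions use the (L, D) pairs of the experimental design:
seven experimental durations 0.7–1.3 s in 0.1-s steps (condition 4, D = 1 s,
is the reference) plus two controls (8, 9) that match the initial distance of
conditions 3 and 5 while lasting exactly 1 s.  g = 9.8 was back-derived from
the design's printed launch velocities (v_y0 = gD/2 = 4.90 m/s at D = 1) and
is configurable.

The same spatial curve y(x) = 4hx(L−x)/L² is traversed by three laws of
motion, all taking exactly *D* seconds:

* **gravitational** — constant horizontal velocity L/D, vertical free flight
  with v_y0 = gD/2;
* **constant vertical** — |v_y| = 2h/D throughout; horizontal position follows
  from inverting y(x) on the correct branch, so v_x = (2h/D)·(L/4h)/√(1−y/h)
  diverges at the vertex.  Analytic queries within 10⁻⁶ s of D/2 are
  evaluated at the window edge and flagged `capped`; in frame-sampled series
  the vertex sample's v_x is replaced by the one-frame central difference at
  the sampling rate;
* **constant tangential** — arc-length reparameterization at speed S/D, with
  the closed-form parabola arc length
  S = L²/(8h)·(a√(1+a²) + asinh(a)), a = 4h/L.  The arc-length equation
  s(x) = (S/D)·t is inverted by Newton's method with a bisection-bracketed
  fallback to |Δs| < 10⁻¹⁰·S (no scheme is prescribed by the design, so a
  guarded Newton was chosen for its quadratic convergence on this monotone,
  smooth function).

Frame sampling (default 75 Hz) always includes t = D as a final sample so the
endpoint invariants are testable.  Coordinates: x from launch toward the
observer, y above eye level; the seated observer's 13° backrest tilt is
treated as display-only and ignored in world geometry.

Note on the design table's constant-tangential columns: the printed initial
velocities for that law (e.g. 2.81/3.70 m/s for the reference) sit ~1% above
the tangent-at-launch analytic values (2.78/3.67).  They are consistent with
first-frame finite differences of a sampled trajectory; this package reports
the analytic values.

## Observer geometry and optic variables

The observer's cyclopean eye sits at eye height, 0.5 m beyond the arrival
point; the fixation cross is 13.8 m ahead and 3.2 m above the eyes (fixation
line elevation 0.2279 rad).  For a ball of radius r = 0.045 m at distance d:

* dilation θ = 2·atan(r/d) — the full subtended angle (the precise meaning of
  "dilation" is not fixed by the source; this is the natural choice and the θ
  used by the flight-time estimator);
* elevation γ = atan(y/u) − atan(3.2/13.8), u the horizontal eye–ball
  distance — sagittal-plane sightline elevation relative to the fixation
  line, positive above it;
* disparity δ = 2·atan(ipd/2d) − 2·atan(ipd/2d_fix) — vergence-angle
  difference between ball and cross.  The inter-pupillary distance is not
  part of the printed design; the default 0.063 m is a standard adult value
  and configurable;
* radial velocity v_r = −dd/dt.

Rates are available analytically (propagating the law's velocities) and as
central finite differences of the frame-sampled series (one-sided at the
endpoints), which is what a 75-Hz display actually shows.  The two agree to
<10⁻³ rad/s through the first ~60% of the flight; during the final approach
the rates themselves blow up as the ball passes close to the eyes, and
agreement is relative (~1%).  Constant-vertical series flag the frames whose
difference stencil straddles the mid-trajectory singularity.

The discriminability index DI = |γ̇_comp − γ̇_ref|/|γ̇_ref| compares each
comparison condition against the same-law reference at matched locations.
The headline statistic uses the start of motion and the ascending
fixation-line crossing; the descending crossing is computed and reported but
excluded from the headline minimum, and rates enter in magnitude so sign
conventions cannot flip the index.  Fixation-line crossings are the two roots
of γ(t) = 0, bracketed by the vertex time D/2 (all three laws have
time-symmetric speed profiles) and refined to |γ| < 10⁻⁹ rad; a path whose
peak elevation stays below the line reports absent crossings rather than
erroring.

The optical flight-duration estimator T = s/(v_rθ + tan(γ)·s·γ̇) uses the
ball diameter s = 2r and, by default, γ measured from the horizontal eye line
(the convention of the model it derives from); measuring from the fixation
line is available via a flag.  Whether the estimator is exact for these
stimuli is not asserted anywhere — tests record its discrepancy against the
true flight duration rather than assuming one.

### Known reconstruction discrepancies

The original stimulus equations are not available, so the geometry above is
reconstructed from projectile physics plus the printed design values.  Two
printed quantities are not exactly reproduced:

* the upper end of the maximum-elevation range: the reconstruction gives
  0.383 rad for condition 7 against a printed 0.37 (the lower end, 0.29 rad,
  reproduces to within 0.005);
* the DI floor: the reconstruction's minimum is 8.91% (condition 5,
  constant-vertical, ascending crossing) against a stated floor of 9% — it
  rounds to 9% but does not strictly exceed it.  The corresponding acceptance
  test asserts the strict bound and is expected to fail by this margin; the
  geometry was deliberately not adjusted to force it.

## Synthetic observer cohort

There is no observer model in the source study (it analyzes humans); the
generator here is the exact generative dual of the logistic analysis so that
parameter recovery is well defined.  The probability of judging the
comparison longer is

P = λ/2 + (1−λ)·logistic[(w_D(D−PSE_law) + w_H·κ·(H−H_ref))/σ_law],
σ_law = JND_law/log 3,

so a logit fit on duration recovers PSE and JND exactly in expectation.  The
distance weight w_H lets an observer respond from initial horizontal distance
H; κ (≈0.106 s/m, the slope of D on H across conditions 1–7) normalizes the
distance cue so duration- and distance-responders are indistinguishable on
the experimental conditions and separable only through the duration-matched
controls — exactly the contrast the control GLMM tests.  Lapses default to 0
(the analysis model has no lapse term); a nonzero λ is available to
stress-test fitting.

Cohort defaults are the study conditions: 15 subjects, per-law mean JNDs
(0.076, 0.101, 0.091) s and PSEs (1.006, 1.014, 1.021) s for constant
tangential / constant vertical / gravitational.  Between-subject SDs
(JND: 0.030/0.046/0.036 s; PSE: 0.027/0.033/0.020 s) are back-derived from
the reported 95% confidence intervals at n = 15 (halfwidth·√n/t₀.₉₇₅,₁₄).
Each subject draws a standardized bivariate pair (u₀, u₁) shifting the
per-law PSEs and JNDs coherently; JND draws are truncated at a 0.02-s floor
so every generated observer discriminates.  Response times are lognormal
(median ≈ 1.2 s) with a 3% contamination rate outside the [0, 10] s window
and a 0.5% inattention rate — these exist purely to exercise the exclusion
rules, not as a model of response-time psychology.  What the generator does
not emulate: sensory noise on the optic variables themselves, lapse/criterion
drift over the session, sequential effects, or order biases — so passing
recovery tests certifies the statistical pipeline, not the perceptual realism
of the cohort.

## Statistical pipeline

* Trial filtering: responses with rt < 0 s (pre-emptive), rt > 10 s, or an
  attention flag (including missing responses) are excluded; the fraction is
  reported.
* Per-subject psychometric model: binomial GLM, logit link, aggregated per
  duration (statsmodels).  PSE = −η₀/η₁, JND = log 3/η₁, Weber fraction
  JND/T_ref with T_ref = 1 s.  Non-converged, separated, or non-positive
  slope fits are flagged and excluded downstream.  Putative-cue re-fits
  (initial tangential speed, dilation rate, elevation rate at the start,
  crossings, or destination, each normalized so the reference maps to 1)
  instead use JND = log 3/|η₁| since those cues are anti-correlated with
  duration.
* Outlier rule: JND outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with type-7 (linear
  interpolation) quartiles — the convention is not fixed by the rule's name,
  so the numpy default is used and stated.
* RM-ANOVA: one-way within-subject F over the three laws (statsmodels
  AnovaRM), df = (k−1, (k−1)(n−1)), no sphericity correction (noted in the
  output metadata); Shapiro–Wilk p-values accompany it as a normality check.
  Holm step-down adjusted paired t-tests as post hocs.
* GLMM: binomial-logit mixed models fitted by Laplace-approximated maximum
  likelihood, implemented in `paradur.glmm` (no maximum-likelihood binomial
  GLMM exists in the scientific Python stack).  Per group the penalized
  Bernoulli log-likelihood is maximized by Newton's method (it is strictly
  concave), the Gaussian curvature correction applied at the mode, and fixed
  effects plus the Cholesky factor of the random-effect covariance maximized
  jointly by L-BFGS-B (ftol 10⁻¹², gtol 10⁻⁸; log-SDs bounded in
  [log 10⁻³, log 50]).  The implementation matches lme4's glmer to 3–4
  significant figures on fixed effects, random-effect SDs and log-likelihood,
  and collapses onto the pooled GLM in the zero-variance limit.  Baseline law
  is constant tangential velocity; per-law PSE/JND follow from the composite
  intercepts/slopes and do not depend on the baseline choice.
* Bootstrap: parametric — new random effects and binomial responses drawn
  from the fitted model, refit warm-started at the original solution,
  percentile 95% intervals of the per-law JND/PSE differences; failed refits
  dropped and counted.  B = 1000 by default; the analysis drivers use
  B = 200, which already gives percentile endpoints stable to ~1 ms.
* BIC selection: the nested pool crosses {random intercept, random
  intercept+slope} × {with, without duration×law interactions} (the source
  never enumerates its pool); BIC = −2·loglik + k·log N with N the Bernoulli
  trial count, ties broken to the first candidate.
* Control GLMM: logit P = β₀ + u₀ + β₁H + β₂C + β₃HC on conditions 3, 5
  (C = 0) and 8, 9 (C = 1), random intercept only.  Duration-only responding
  implies β₃ = −β₁, distance-only β₃ = 0, mixtures in between.

## Problem sizes and seeds

Analyses run at the study design size: 15 subjects × 405 trials (3 laws × 9
conditions × 15 replications).  The recovery check simulates 20 such cohorts
end-to-end; unit tests use smaller cohorts (4–10 subjects, 4–12
replications) chosen to keep every property identifiable.  All randomness —
schedule shuffles, cohort draws, responses, bootstrap — flows through
explicit integer seeds recorded in the run configuration, and identical
configurations reproduce outputs byte for byte.

## Limitations

* The pipeline certifies internal consistency (generative model ↔ analysis)
  and geometric reconstruction, not the original human data: the deposited
  raw data are not packaged, so the study's coefficient tables are reproduced
  in structure and derivation, not in value.
* Per-subject GLMs are weakly identified for observers much steeper than the
  0.1-s duration grid (JND ≲ 0.03 s): slope estimates can run away on
  near-separated data.  Such fits are flagged by a |η₁| < 10³ sanity bound,
  and the IQR rule and the partially pooling GLMM temper their influence.
* No VR rendering, no eye movements, no air drag: world geometry only.
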