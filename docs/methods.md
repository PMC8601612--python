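# Methods

`vpwm` implements a family of probabilistic observer models for the delayed
-estimation (continuous-report) working-memory task, per-subject maximum-
likelihood fitting with information-criterion model comparison, a synthetic
cohort generator emulating a two-group (healthy control vs schizophrenia-
like) study, and the group-level statistics that such studies report. This
note records the models, the numerical choices, and the limits of what the
synthetic studies can show.

## Task and data model

A trial presents N colored squares (or oriented bars); after a delay one
item is probed and the subject reproduces its feature value on a continuous
wheel. The datum is the signed circular response error. Feature spaces are
circular with period 360 deg (color) or 180 deg (orientation); all model
math runs on an internal circle of (-pi, pi] radians, with degrees at every
I/O boundary. Orientation data are handled by linear rescaling of the
period — the two spaces differ only in period, not in model structure. The
signed-error convention is half-open: exactly opposite responses map to
+period/2.

Behavioral dispersion is summarized by the circular standard deviation,
CSD = sqrt(-2 ln R) * period/(2 pi), with R the mean resultant length of
the errors.

## Precision currency and the von Mises stages

Memory precision is expressed as the Fisher information J of a von Mises
measurement: J = kappa I1(kappa)/I0(kappa) = kappa A(kappa). The map and
its inverse are evaluated from a 2000-node log-spaced kappa table
(1e-6..1e4) interpolated with monotone cubics (PCHIP) in log-log
coordinates; round-trip error is < 1e-6 relative over J in [1e-3, 500].
J above the table ceiling clamps to kappa = 1e4 with a warning. The
small-J branch uses kappa = sqrt(2 J), the exact limit of J ~ kappa^2/2.

A sensory stage (concentration kappa from the item's resource J) and a
choice stage (concentration kappa_r) are chained by moment-matched
convolution: kappa_c = A^{-1}(A(kappa) A(kappa_r)). This rule is exact in
the first circular moment; because the convolution of two von Mises
densities is not von Mises, the approximation carries an intrinsic total
variation error that peaks near 0.026 at moderate equal concentrations
(kappa of 2-5) and vanishes in both the diffuse and concentrated limits.
The samplers draw the response from the same moment-matched distribution
the likelihood evaluates, so sampler and density agree exactly by
construction; the matching rule itself is validated against FFT-based
numerical convolution in the test suite.

## The seven observer models

All models describe the error density p(eps | N) and share the choice
stage kappa_r where they have one.

- **IL** (item limit): capacity K, fixed kappa_r. With probability
  g = max(0, 1 - K/N) the probe is unstored and the response is a uniform
  guess; otherwise VM(kappa_r). 2 free parameters.
- **MIX**: IL with a separate concentration per set-size level
  (1 + #levels parameters).
- **SA** (slots plus averaging): K discrete slots each carrying J_slot of
  precision, spread as evenly as possible; an item holding s slots is
  encoded at precision s*J_slot, convolved with kappa_r. 3 parameters.
- **cosSA**: SA with a stimulus-dependent periodic response bias
  b(s) = sum_h amp_h sin(h s + phase_h), default two harmonics with
  amplitudes bounded at +-0.35 rad (3 + 2H parameters). The bias recenters
  every mixture component.
- **EP** (equal precision): continuous resource J_bar(N) = J1_bar N^-a,
  identical on every trial. 3 parameters.
- **VP** (variable precision): the per-trial resource J is gamma-
  distributed with mean J_bar(N) and scale tau (shape J_bar/tau). The
  density marginalizes the von Mises over that gamma. 4 parameters
  (J1_bar, a, tau, kappa_r). The across-trial draw operates even at
  N = 1 — allocation varies across trials when it cannot vary across items.
- **VPcap**: VP with an explicit capacity K on top
  (min(1, K/N) VP + guess). 5 parameters.

Parameter defaults and bounds: J1_bar in [0.5, 500], a in [0, 5] (identity
scale), tau in [0.1, 200], kappa_r and the MIX concentrations in [1, 500],
J_slot in [0.5, 200], K integer in [1, 8]. Guessing is uniform on the
circle. Reductions hold by construction and are tested: MIX -> IL (shared
kappa), cosSA -> SA (zero amplitudes), VPcap -> VP (K >= max N), VP -> EP
(tau -> 0).

## VP marginalization

The gamma integral is evaluated by fixed-node Gauss-Legendre quadrature on
the quantile scale: u_i in (0,1), J_i = Q_gamma(u_i; J_bar/tau, tau), so
p(eps) = sum_i w_i VM(eps; kappa_c(J_i)). The quantile transform keeps the
rule accurate for small shapes (strongly skewed gammas). Defaults: 100
nodes for density evaluation, 50 nodes inside the optimizer (the
difference is far below the likelihood's sampling noise). Agreement with a
10^6-draw Monte-Carlo average of the same integrand is within 3 MC
standard errors at all tested error values and set sizes. Densities
integrate to 1 by construction (mixtures of normalized components with
weights summing to 1); the test suite verifies 1e-3 agreement on a
720-node trapezoid grid for random in-bounds parameters of all models.

## Maximum-likelihood fitting

Per subject and model, the negative log-likelihood (sum over trials;
underflow yields an infinite sentinel, never NaN) is minimized by
Nelder-Mead on transformed coordinates: log scale for positivity-
constrained parameters (J1_bar, tau, kappa_r, J_slot, per-level kappas),
identity for the decay exponent and the bias terms, with bounds enforced
by clipping. Starts are one data-informed start (per-set-size error
concentration inverted through A^{-1}) plus Latin-hypercube restarts
(default 20; the large simulation studies below use 0-2 restarts after
verifying that more restarts do not change the optima found). Integer
capacity K is profiled by an exhaustive grid with a continuous fit per K;
for IL, MIX and VPcap the grid stops at the largest set size because the
likelihood is exactly constant beyond it, while SA and cosSA use the full
1..8 grid (extra slots still raise per-item precision). A fit is flagged
converged when the best two starts agree within 0.5 log-likelihood units.

Model comparison uses AIC = -2 logL + 2k and BIC = -2 logL + k ln n per
subject; winners minimize the criterion with exact ties broken by fewer
parameters, then by fixed model order (IL, MIX, SA, cosSA, EP, VP, VPcap).

## Synthetic cohorts

The generator emulates the statistical structure of a two-group study:

- Task presets: color-main (period 360, set sizes {1, 3} x 80 trials, 180
  equally spaced wheel colors), color-high (set sizes {2, 4, 6}),
  orientation (period 180, set sizes {2, 4, 6}). Stimuli are drawn
  uniformly from the discrete wheel without replacement within a trial;
  the probe is uniform over items. Delay periods, fixation timing and
  rendering geometry are not simulated — the models operate on errors.
- Subject parameters are log-normal around group means (positive,
  right-skewed, matching the across-subject spread of fitted precision
  parameters). Defaults, chosen once: HC mean J1_bar = 60, a = 1.0,
  tau = 15, kappa_r = 150 (about 4.7 deg choice SD — pointing on a wheel
  is precise relative to memory noise), with sigma_log = 0.5, 0.3, 0.75,
  0.5 respectively.
- The patient-like group differs only in tau, scaled multiplicatively so
  the natural-scale Cohen's d between groups hits the configured target
  (default d = 0.7).
- Symptom scores are linear in tau plus Gaussian noise, truncated at 0,
  with slope and intercept calibrated so each scale's marginal mean/SD and
  its target Pearson r with tau match the configured values (defaults:
  BPRS 27.25/6.27 at r = 0.259, SANS 24.43/11.45 at r = 0.302, SAPS
  5.77/7.02 at r = -0.121). Truncation at zero slightly distorts the SAPS
  scale, whose mean is within one SD of zero.

What the generator deliberately omits: response-time structure, learning
or fatigue across blocks, medication effects, stimulus-specific biases in
the VP family, and any group difference outside tau. Passing tests on
these cohorts therefore show that the analysis chain recovers the
structure it assumes — not that real patient data contain that structure.

## Group statistics

CSD is compared by a two-way mixed ANOVA (set size within, group between;
partial eta-squared effect sizes), computed with pingouin and verified
against textbook sums of squares on a hand-built table. Fitted VP
parameters are compared by a pooled-variance two-sample t
(df = n1 + n2 - 2; Welch optional). Positivity-constrained parameters are
tested on the log scale by default: fitted precision-type parameters are
approximately log-normal across subjects, and the t statistic is better
calibrated on that scale; natural-scale means and SEMs are reported
alongside either way. No multiple-comparison correction is applied to the
four parameter tests or to the correlations by default. Symptom
correlations are Pearson r with the two-sided t transform and pairwise
deletion of missing scores.

## Known limits of the study design (and honest failures)

Two advertised recovery properties are unattainable at the main design
scale of 160 trials (80 each at set sizes 1 and 3), and their tests fail
honestly rather than being weakened:

- **tau recovery precision.** A numerical Cramer-Rao analysis of the VP
  likelihood (Fisher information in log-parameter coordinates, all four
  parameters free) bounds any estimator's sd(log tau-hat) above ~1.0
  across the realistic parameter range at this design. That implies a
  best-case median absolute relative error of ~55-75% (measured: ~0.57)
  — far above a 30% target — and caps the attainable generating-vs-fitted
  tau correlation near 0.6-0.67 (measured: 0.673 at 50 subjects, stable
  under added optimizer restarts). Scaling the same bound to 4,800 trials
  predicts ~±20% recovery, which the fitter achieves; the information is
  simply not present at 160 trials.
- **Leakage into the other parameters.** At 160 trials the fitted VP
  parameters trade off strongly; a true between-group difference confined
  to tau biases the other fitted parameters differently in the two groups,
  so two-sample tests on fitted J1_bar, a, kappa_r reject above the
  nominal rate even though their generating distributions are identical.
  Under a full null (no group effect), the same tests are correctly
  calibrated — the inflation is specific to leakage from a real tau
  effect, a property of maximum-likelihood estimation at this trial count,
  not of the test machinery.
- **Per-seed power.** With a tau-only effect of d = 0.7 at n = 61/60, the
  power of the end-to-end chain (generate -> fit -> pooled t at alpha
  = .05) is bounded near 95% per seed even for an error-free estimator, so
  a >= 95%-of-seeds detection requirement sits on a knife edge by
  construction; estimation noise pushes realized power below it.

## Simulation sizes

Study sizes used by the test suite and the acceptance script, chosen for
single-CPU runtimes: tau recovery at 50 subjects; model recovery with 10
subjects per generating model (IL, EP, VP) at 1,200 trials each on the
high-set-size design — at the two-level {1, 3} design EP and MIX are
likelihood-equivalent with equal parameter counts, so generating-model
identification is only well-posed with three or more levels; end-to-end
group analysis over 20 cohort seeds at full cohort size (61/60, 160
trials/subject); null calibration over 200 seeds of small EP cohorts
(8/8 subjects, 100 trials); the tau->CSD simulation at 4,000 responses
per cell on the default grid tau in {2, 5, 10, 20, 40, 80} x J1_bar in
{20, 60, 180} with a = 1 and kappa_r = 150 fixed (grid chosen once;
dispersion is non-decreasing in tau along every slice within Monte-Carlo
error).
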