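# Methods

## The model

`mctmm` models patient-reported hand-foot syndrome (HFS) severity under
oral capecitabine as a four-state continuous-time Markov chain over the
CTCAE-style grades 0-3, observed once per 3-week treatment cycle (the
questionnaire reports the cycle's maximum grade, treated as the grade at
the cycle end). All patients start asymptomatic, so the baseline state is
grade 0 with probability one.

**Stationary law (proportional odds).** At daily dose $D$ the three
cumulative probabilities share one linear predictor on the logit scale:

$$\mathrm{logit}\,P(\mathrm{Gr}\ge n) = \alpha_n +
\theta_{\mathrm{Dose}}(D - 3000\,\mathrm{mg}) + \eta^{(\alpha)}_i,
\qquad \alpha_{n+1} = \alpha_n + b_{n+1},\; b_{n+1} < 0 .$$

The ordered intercepts are parametrized through strictly negative
increments $b_2, b_3$ (estimated as $\log(-b)$ internally), which forces
the cumulative probabilities to decrease in $n$ for every subject and
covariate value. The dose effect is centred at the cohort median of
3000 mg/day, so $\alpha_n$ retains its interpretation at the typical dose.
Differencing the cumulative probabilities gives the grade distribution
$\pi(D, \eta_i)$; each entry is floored at $10^{-12}$ before rate
construction so the generator stays finite in saturated regimes.

**Kinetics (minimal CTMC).** Only adjacent-grade transitions carry rate.
All rates share a single time scale, the mean equilibration time MET
(in cycles), and are proportional to the destination grade's stationary
probability, normalized per adjacent pair:

$$K_{i\to j} = \frac{\pi_j}{\mathrm{MET}\,(\pi_i + \pi_j)},\qquad |i-j|=1,$$

so that $K_{i\to j} + K_{j\to i} = 1/\mathrm{MET}$ for every adjacent pair
— the property that makes MET literally the equilibration time constant of
each pair. The construction satisfies detailed balance
$\pi_i K_{i\to j} = \pi_j K_{j\to i}$ exactly, hence $\pi$ is the
stationary law of the chain. The normalization is a genuine design choice:
the alternative family $K_{i\to j} = \pi_j/\mathrm{MET}$ also satisfies
detailed balance with the same stationary law, but its exit rate from
grade 0 equals $\pi_1/\mathrm{MET}$, which collapses toward zero precisely
when high doses push probability mass to high grades — under that family a
virtual patient at 1250 mg/m² twice daily essentially never leaves grade 0
within six cycles, and the observed volume of grade transitions in real
cohorts (about half of grade-0 records transition away within one cycle)
cannot be generated at any plausible MET. The pairwise form reproduces
both, so it is the one implemented; note that MET is identifiable only
jointly with this normalization convention.

**Random effects.** Two independent normal subject-level effects:
$\eta^{(\alpha)}_i \sim N(0, \omega_\alpha^2)$ added to all three
cumulative logits, and $\eta^{(m)}_i \sim N(0, \omega_{\mathrm{MET}}^2)$
acting exponentially, $\mathrm{MET}_i = \mathrm{MET}\,e^{\eta^{(m)}_i}$.
Because the additive terms of the linear predictor commute, it is
immaterial whether $\eta^{(\alpha)}$ is added before or after covariate
centring.

**Likelihood.** Between observations the state distribution obeys
$\dot P = PQ$ with the piecewise-constant generator (dose changes only at
cycle boundaries; multi-cycle questionnaire gaps are propagated as the
ordered product of per-cycle matrix exponentials). At each observation the
state collapses to the observed grade (the Markov property), so one
subject's conditional likelihood is the product over consecutive
observation pairs of transition-matrix entries, starting from the grade-0
baseline. Matrix exponentials exploit reversibility:
$D^{1/2} Q D^{-1/2}$ with $D=\mathrm{diag}(\pi)$ is symmetric, so a single
batched symmetric eigendecomposition propagates every (subject, cycle,
quadrature-point) segment at once; `scipy.linalg.expm` is kept as the
public single-matrix path and as the cross-check oracle in the tests,
together with a high-accuracy ODE integration (`solve_ivp`, rtol 1e-10).

## Estimation

The marginal likelihood integrates the two random effects per subject.

* **Laplace (default).** Per-subject posterior modes are found by a damped
  Newton iteration, vectorized across subjects, restarted at $\eta=0$ for
  every outer iteration (reproducibility over warm-start speed). Gradients
  and Hessians use central finite differences (step $10^{-4}$) evaluated
  in one batched stencil call; the iteration stops at gradient norm
  $10^{-6}$ (a finite-difference-compatible reading of a tight inner
  tolerance) or 50 iterations, with per-subject backtracking on the
  (direction-preserving, length-capped) Newton step. The approximation is
  $\log\int L\,\phi \approx -f(\hat\eta) - \tfrac12\log\det\Omega -
  \tfrac12\log\det H$ with $H$ the curvature of the negative log
  posterior kernel at the mode; log-determinants use clipped eigenvalues
  so numerically rank-deficient curvature at extreme trial parameters
  degrades gracefully instead of poisoning the line search.
* **Adaptive Gauss-Hermite quadrature (oracle).** A 21-node-per-dimension
  tensor rule centred and scaled at the Laplace mode, evaluated by
  log-sum-exp. On a single subject it agrees with brute-force dense-grid
  integration to $<10^{-5}$, which is how it earns its role as the
  independent check of the Laplace path. At the published
  $\omega_\alpha = 1.12$ the *inherent* Laplace error is about 0.035 OFV
  units per subject (the intercept dimension is skewed), so Laplace and
  AGQ objective values on a 20-subject cohort typically differ by
  0.3-1.2 units — an approximation property, not an implementation defect.

The outer problem minimizes the OFV ($-2\log$ marginal likelihood) by
L-BFGS-B with finite-difference gradients on a transformed scale
($\log(-b)$, $\log \mathrm{MET}$, $\log\omega$ with a $10^{-3}$ floor, and
the dose slope in per-gram units for conditioning). Standard errors come
from the central-difference Hessian of the OFV at the estimates on the
natural scale, with the convention $\mathrm{SE} =
\sqrt{\mathrm{diag}(2H^{-1})}$ (the OFV is twice the negative
log-likelihood). Nested models are compared by the likelihood-ratio test
at $p \le 0.01$: one extra parameter must drop the OFV by at least 6.64
($\chi^2_{1,0.99}$); two-level categorical covariates use two degrees of
freedom. The non-parametric bootstrap resamples subjects with replacement
to the original size, refits each replicate from the original estimates
(standard practice, and the inner restart keeps replicates independent of
each other), and reports percentile 2.5/50/97.5 summaries; failed
replicates are excluded, counted, and flagged hard above 20%.

Subjects observed only at baseline contribute nothing (the baseline is
deterministic) and are dropped with a log message. Missing questionnaires
mid-sequence are bridged by the Markov property (piecewise-dose
propagation over the gap), never imputed. For the 25-of-56 discontinued
patients who keep returning questionnaires, dose is set to zero from the
discontinuation cycle onward.

## Synthetic cohorts

The generator emulates the observed 150-patient design: exact category
counts (39 male / 101 female; 71 colorectal / 67 breast / 12 other tumour
entities; 71 monotherapy), ages drawn normal (median 62, SD 13) clipped to
28-93, daily doses on the 1000-5000 mg grid in 500 mg steps with
combination-therapy patients drawn from the lower half and weights placing
the cohort median at 3000 mg, six cycles with one questionnaire each, 56
discontinuations of which 25 keep reporting (dose 0 afterwards, observed
through cycle 6) and 31 stop reporting (discontinuation cycle drawn from
{1,2,3} so the mean observed-cycles count lands near the 5.2 target).
Adherence groups are assigned 40/40/20% — an assumption, as the source
summary does not give the split — and, like age, sex, entity, and
monotherapy, carry no effect under the final model; they exist so the
covariate screen can be exercised against known-null effects. Grades are
then simulated from the model, and the resulting transition-count table is
dominated by its diagonal with roughly half of grade-0 records moving away
per cycle, the structure seen in the real cohort.

What the generator does *not* emulate: within-patient dose modifications
during treatment (real oncologists reduced and occasionally re-escalated
doses at their discretion; here the per-cycle dose is constant until
discontinuation), treatment-interruption time delays (the model has no
within-cycle time axis), adherence-driven exposure variation, and any
misclassification between reported and "true" grade. Passing
simulate-and-refit checks therefore demonstrates internal consistency of
model, simulator, and estimator under the stated design — not robustness
to those real-data features.

## Simulation studies

* **VPC.** 1000 replicates simulated on the observed design (same
  subjects, times, doses; no simulated dose adaptation), binned by cycle
  index; bands are empirical 2.5-97.5 percentiles of the per-cycle grade
  proportions, unsmoothed; proportions rather than counts (the standard
  choice for a categorical VPC).
* **Dose policy.** 1000 virtual patients with BSA ~ N(1.8, 0.2²) m²
  truncated to [1.2, 2.6] (assumed values — the source cohort recorded no
  BSA), starting dose 2 × 1250 mg/m² × BSA. Each cycle the full grade
  probability vector is propagated from the asymptomatic start; the modal
  grade (argmax, ties toward the lower grade) is the cycle's toxicity
  assessment and drives the label-style rule, expressed per (grade,
  occurrence count) as fractions of the *starting* dose: grade 2 at
  occurrences 1/2/3/4 → 100%/75%/50%/discontinuation recommended; grade 3
  at 1/2/3 → 75%/50%/discontinuation. Doses are never re-escalated;
  patients with a recommended discontinuation are kept at their last dose
  so both scenarios retain the same 1000 patients; the same seed gives
  both scenarios identical BSA and random-effect draws. A variant that
  collapses the state to the modal grade before each cycle is retained as
  a diagnostic, but it is degenerate (see the rate-normalization
  discussion) and not the default. Confidence intervals on the per-cycle
  median probabilities are order-statistic (binomial-rank) intervals.
  Because the BSA distribution is assumed, the printed transition counts
  of the source study are matched directionally, not numerically.
* **Individual prediction.** For each target cycle $k \ge 2$, random
  effects are re-estimated as the MAP (empirical Bayes) mode from
  observations before $k$ — the standard pharmacometric reading of a
  "Bayesian" update; full posterior sampling is out of scope. The grade
  distribution at $k$ is the single propagated distribution from the last
  observed grade at the recorded doses (deterministic and reproducible;
  simulation replicates would have the same modal grade in expectation),
  and the modal grade is compared with the observed one. PPV counts
  correct grade-$\ge2$ predictions among all grade-$\ge2$ predictions, NPV
  likewise for $\le1$; baseline is excluded, empty denominators are
  reported as missing, and both per-cycle and pooled values are reported
  (the source range is stated per cycle).

## Numerical and design choices

* Time unit: one 21-day cycle; observations at integer cycle times. A
  days-to-cycles converter exists for display only.
* Grade-probability floor $10^{-12}$ (not renormalized); transition
  probabilities are clipped below at $10^{-300}$ before logs, so a
  zero-probability transition cannot occur under floored probabilities.
* Random-effect excursions beyond ±20 are clipped inside the likelihood
  kernel only (the prior term keeps growing), which keeps transient
  optimizer iterates from overflowing the exponential map.
* Modal-grade ties break toward the lower grade (conservative assessment;
  ties are measure-zero anyway).
* Bootstrap and screen refits reuse the original estimates as starting
  values; headline fits start from a neutral point (all intercept-scale
  parameters at ±1, MET 1 cycle, slope $10^{-4}$/mg, both $\omega$ 0.5).
* Problem sizes in the shipped checks: the recovery experiment uses one
  150-patient cohort; the oracle comparison 20 subjects; the bootstrap
  calibration 40 subjects × 50 replicates; the dose-policy comparison
  1000 virtual patients; the VPC 1000 replicates. These match the source
  study's scales except the bootstrap (1000 replicates there), which is a
  calibration check here, not a precision claim.

## Known limitations

* $\omega_\alpha$ is weakly identified at this design (six occasions, one
  grade per cycle): its profile is nearly flat over a wide range — the
  source study reported the same (RSE 37%, bootstrap interval almost
  touching zero) — and simulate-and-refit estimates of variance components
  shrink accordingly.
* The Laplace approximation carries an irreducible per-subject bias at
  large $\omega_\alpha$ (see Estimation); quadrature is available via
  `method="agq"` where exactness matters more than speed.
* Estimates are conditional on the pairwise rate normalization; a
  different normalization rescales (and reshapes) MET.
* The conflation of "maximum grade during the cycle" with "grade at the
  cycle end" is inherited from the data-collection design and is a known
  approximation of the observation model.
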