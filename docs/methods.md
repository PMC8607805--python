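# Methods

## Model and assumptions

The model is an operational (coarse-grained) description of CD8+ T-cell
cytokine production under plate-immobilised stimulation.  Reactions follow
mass action except for two simplifications:

* **Rapid binding equilibrium.**  Receptor-ligand binding equilibrates in
  seconds to minutes while the readouts evolve over hours, so complexes are
  algebraic functions of dose: `C = pMHC^n/(K_A^n + pMHC^n) * TCR` for the
  TCR, and Hill occupancies `f_L = L/(K_D + L)` for CD70 and 4-1BBL.
  Plate-bound ligand doses are constant within a stimulation phase (the
  coating is not consumed on these time scales).
* **Population-averaged digital switch.**  Single cells respond
  digitally, with activation thresholds distributed across the population.
  With normally distributed thresholds (mean `mu`, SD `sigma`) the fraction
  of activated cells is `Phi((C - mu)/sigma) = 1/2 + 1/2 erf((C -
  mu)/(sqrt(2) sigma))`.  The printed form of such switch terms is
  typographically ambiguous between a `sqrt(2)*sigma` and a `2*sigma`
  denominator; the package defaults to the normal-CDF reading (`sqrt(2)`)
  because it is the one with a population interpretation, and retains the
  literal reading behind `VariantSpec(erf_denom="two")`.  The two differ
  only by a rescaling of `sigma`.

The model is deterministic and mean-field: it tracks the population-average
trajectory, not single-cell stochasticity (the erf already integrates over
cell-to-cell threshold variability).  Molecular signalling species
(TRAF/NF-kB/AP-1) are deliberately absent; the model's claims are about
input-output behaviour.

Adaptation arises from an incoherent feedforward loop: pMHC engagement
produces Signal and simultaneously destroys the TCR pool that produces it.
Cytokine is the time integral of Signal, so it is cumulative and
non-decreasing — an IFN-gamma-like readout.  IL-2, which is consumed by
activated cells, is outside the model's scope.

### Co-stimulation variants

`ModelVariant` enumerates where co-stimulation can integrate:

| variant | mechanism |
|---|---|
| `BASE` | none (k10, k11 ignored) |
| `THRESHOLD_MOD` | scales C inside the switch: threshold lowered (accepted) |
| `ALT1` | as `THRESHOLD_MOD` but CD70 term only |
| `ALT2` | scales the erf term of the switch output |
| `ALT3` | adds to the erf argument (dose-independent offset) |
| `ALT4_LITERAL` | Signal decay `k3*S*k10*f` (ligand-gated decay, literal reading) |
| `ALT4_ATTEN` | Signal decay `k3*S/(1 + k10*f)` (decay attenuation reading) |
| `ALT5` | scales cytokine production `k4 (1 + k10 f) S` |
| `ALT6` | adds ligand-driven production `k4 S + k10 f` |
| `EXPLORE_KA` | divides the apparent K_A by the modulation factor |
| `EXPLORE_TCR` | multiplies TCR resynthesis k1 by the modulation factor |

`ALT1`–`ALT6` carry only the CD70 term, as printed in their defining
equations.  The literal `ALT4` reading abolishes Signal decay in the
absence of ligand — no adaptation in the control arm — which is why the
attenuation reading is provided alongside; both are scored.

Two modulation conventions exist.  `LITERAL` uses ligand occupancy only;
under it, receptor downregulation has no functional consequence, which
contradicts the expression-dynamics mechanism the model exists to express.
`RECEPTOR_SCALED` (default) multiplies each occupancy by the current
surface receptor level: `1 + k10*CD27(t)*f_CD70 + k11*41BB(t)*f_41BBL`.

The switch production term is floored at zero: `ALT2` scales a signed erf
and could otherwise yield a negative signal-generation rate, which is
unphysical and would break state non-negativity.

GITR is represented by reusing the inducible-receptor (4-1BB) equations
with `gitr_like()` parameters (k7 x 0.3, k9 x 2): induced more slowly and
to a lower level, matching its weaker phenotype.

## Default parameters

No measured rate constants are available for this model; the defaults are
**calibration products of this package**, chosen once so that the accepted
model reproduces the screen's qualitative phenotypes, and should be treated
as a self-consistent reference set rather than biological measurements:

| parameter | default | unit | rationale |
|---|---|---|---|
| k1 | 0.05 | 1/h | slow TCR resynthesis (~20 h recovery): adaptation persists through transfer |
| k2 | 0.5 | 1/h | TCR downregulation: ~2 h decline at saturating occupancy |
| k3 | 0.5 | 1/h | Signal decay: ~2 h memory after the switch closes |
| k4 | 100 | conc/h | sets cytokine scale: saturating-dose output ~10^2-10^3 units, well above the 50 pg/ml exclusion level at `cytokine_scale=1` |
| k5 | 0.05 | 1/h | slow CD27 resynthesis: CD70-exposed cells stay CD27-low for hours |
| k6 | 0.4 | 1/h | CD70-driven CD27 loss (~3 h at 200 ng/well): fast, but CD27 outlives the base production window enough to amplify the early response |
| k7 | 0.3 | 1/h | Signal-driven 4-1BB synthesis: units of 4-1BB are defined by this rate |
| k8 | 0.2 | 1/h | ligand-driven 4-1BB downregulation, partially offset by synthesis |
| k9 | 0.05 | 1/h | slow constitutive 4-1BB decay: expression persists |
| k10 | 6 | — | CD27 co-stimulation strength: ~1.7x amplification at 8 h |
| k11 | 3 | — | 4-1BB co-stimulation strength: sustained late production |
| mu | 0.25 | complex units | threshold below the saturating complex level (C <= 1) but above the adapted level C* ~ 0.09 |
| sigma | 0.05 | complex units | 20% population CV: digital in time, graded across doses |
| K_A | 50 | ng/well | half-occupancy inside the 0-2,000 ng/well dose series |
| n | 1 | — | plain binding; with n = 2 the occupancy crosses the threshold within one 3-fold dilution and the simulated dose responses become step-like, unlike measured ELISA curves |
| K_D^CD27 | 50 | ng/well | 200 ng/well CD70 gives 80% occupancy |
| K_D^41BB | 100 | ng/well | 500 ng/well 4-1BBL gives 83% occupancy |

Initial conditions: TCR = CD27 = 1 (resting levels), Signal = Cytokine =
4-1BB = 0 — CD27 is constitutively expressed, 4-1BB absent on resting
cells.

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA, rtol 1e-6 / atol 1e-9 — the switch
makes the system stiff near `C ~ mu`.  Correctness is checked three ways:
against closed-form fixed points (resting state; `CD27* = k5/(k5 + k6 f)`
under saturating CD70; `41BB* = k7 S/k9` at clamped Signal, via the
`clamp_signal` diagnostic flag), against a fixed-step 4th-order
Runge-Kutta oracle at dt = 1e-3 h (agreement < 1e-4 relative), and by
self-convergence under tolerance refinement.  Tiny negative excursions
within solver tolerance are clipped to zero.

Two-phase (plate-transfer) protocols carry every cellular state across the
transfer and reset only the cumulative cytokine: medium replacement removes
secreted product, not surface receptors or signalling state.  Phase-1
output is the cytokine at the end of phase 1.

## Dose-response fitting

The bell function has a mirror parameterisation: for `n2 < 0` the roles of
`(emin, a)` and `(c1, c2)` swap and the low-dose asymptote is `a`.
Metrics are therefore orientation-independent: Emax is the maximum of the
fitted line over a 10,000-point log-spaced grid spanning the non-zero
doses, and the EC50 baseline is the curve's analytic `y(0)` limit, with
EC50 the lowest grid dose at which the line first reaches `y(0) + (Emax -
y(0))/2` on the rising limb.  `x = 0` is always evaluated by the analytic
limit, never as `(c/x)^n`.

Fitting is bounded least squares (TRF) with 12 multi-starts seeded from
log-spaced quantiles of the dose range and both signs of `n2`; starts are
explored with a capped iteration budget and the winner is polished to
tight tolerance.  Selection prefers, among candidates whose RSS is
statistically indistinguishable (within 1e-5 of the data's total sum of
squares), the fit whose smooth line least exceeds the observed maximum,
then lower RSS, then smaller `|n2|`.  The overshoot preference exists
because a 7-parameter bell can interpolate switch-like data exactly while
inventing a large peak between doses that no observation supports.  Flat
data are fit by the exact constant with EC50 undefined; fewer than 5
distinct non-zero doses refuse to fit; non-convergence of every start is
flagged, not raised.

EC50 values are excluded when the fitted Emax is below 50 pg/ml, where
assay noise makes the midpoint meaningless.  Normalisation divides each
extracted metric by its within-experiment mean across conditions (or by a
named standard condition), which removes per-experiment technical scale
while preserving all between-condition ratios.

## Synthetic data

The generator emulates the ELISA screen: 12 pMHC doses (2,000 ng/well with
3-fold serial dilutions plus 0), ligand arms (defaults: none, plus 7-dose
2-fold titrations of CD70 from 200, 4-1BBL from 500 and GITRL from 500
ng/well — 22 conditions), times 4/8/16/24 h, duplicate wells, 3
experiments.  Noise is layered on the ODE truth: mean-one multiplicative
lognormal per well (CV 0.15), a mean-one lognormal scale per experiment
(SD 0.25, donor/transduction variability), and an additive lognormal
detection background around 4 pg/ml.  All magnitudes are conventions of
this package — no error model is published for such screens — and all are
configurable; with every source at zero the records equal the simulation
exactly.  The truth sidecar records the generating parameters and each
curve's noiseless Emax and half-max crossing *at the design's dose grid*.

What the generator does **not** emulate: cytokine consumption (IL-2),
standard-curve/calibration error structure, plate-position effects,
pipetting covariance between neighbouring wells, and continuous-dose
information between the plated dilutions.  Passing pipeline tests on these
data therefore demonstrates internal consistency of model + analysis, not
fidelity to any particular laboratory's error structure.

## Model selection

Seven phenotype criteria operationalise the screen's qualitative
observations; each returns a verdict and a signed margin.  Defaults
(`PhenotypeConfig`): adaptation = post-8 h rate < 10% of the 0-8 h mean
rate; CD27 front-loading = >= 1.3x amplification at 8 h with at most 1.3x
further relative gain by 24 h and a decreasing production rate; 4-1BB
persistence = late Emax increment (E24 - E16) > 25% of the early one and
>= 1.5x amplification at 24 h; rescue = >= 2x phase-2 output when CD70 is
added to adapted cells; antigen dependence = zero-pMHC phase-2 output <=
5% of the saturating-dose output; CD70 pre-exposure penalty = phase-2 CD70
response <= 80% after phase-1 CD70; TCR direction = no ligand arm raises
surface TCR more than 0.01 above the no-costim trajectory.  The
quantitative thresholds are this package's choices; the phenomena they
encode are qualitative.

The TCR-direction criterion exists because TCR-expression modulation
(`EXPLORE_TCR`) can reproduce every cytokine phenotype — it fails only on
the direction of surface-TCR change, which measurements put at or below
the no-costim trajectory.  Without it, a cytokine-only scorecard cannot
exclude that variant; the package's `SCREEN_CRITERIA`/`TRANSFER_CRITERIA`
subsets let users reproduce that ablation (dropping the transfer criteria
leaves multiple variants passing, which is exactly the discriminative
value of the plate-transfer experiments).

Ranking refits each variant's co-stimulation strengths (k10, and k11 where
the variant has a 4-1BBL term) by coarse grid search maximising criteria
passed, with all shared kinetics fixed — variants fail on structure, not
on an unflattering strength choice.  For the affinity-modulation variant
the scorecard also records the CD70-induced EC50 fold-shift at 8 h,
computed through the bell-fit pipeline, documenting that this variant
shifts sensitivity while leaving rate and duration unexplained.  P1-P3 are
evaluated on simulated cytokine at the saturating dose directly (the
criteria are statements about the top of the dose response, where the
surface maximum is exact); bell fits are used where data-like curves are
analysed.

## Calibration

`ModelCalibrator` reduces a measurement table to per-(arm, time) Emax and
log10-EC50 targets — the screen's own summary statistics — averaging wells
per dose and then experiments.  Both the data side and the model side use
the same model-free extraction (grid maximum; interpolated half-max
crossing), so extraction bias cancels; EC50 targets are included by
default because Emax trajectories alone leave a nearly flat
(k1, k2, mu) direction that noise exploits.  Free parameters are fit in
log space (positivity) by TRF least squares with relative Emax residuals
and log-EC50 residuals.  Identifiability diagnostics flag flat objective
directions via the Jacobian's singular spectrum (ratios below 1e-3); with
only a single early time point this correctly implicates the Signal decay
rate k3.  Non-convergence raises an error carrying the best-so-far
parameters.

Recovery performance under the default conditions (five arms, duplicate
wells, three experiments, 10% multiplicative noise): k2, k3, k4 and mu
recover within ~20%; k1 is the weak direction — its ~20 h timescale barely
expresses itself within a 24 h screen, so its error varies several-fold
with the noise realisation and can exceed 25% on unlucky draws.  Noiseless
recovery is exact to optimizer precision.

## Problem sizes

Default test and acceptance runs use: 12-dose screens with 3-5 ligand
arms; 200 synthetic curves for fitter studies; 3 synthetic experiments for
recovery studies; the full 11-variant scorecard with a 4 x 4 (x3) strength
grid per variant.  These sizes make every analysis rerun from scratch in
minutes on a single CPU while keeping all comparisons well-conditioned.

## Known limitations

* The model is mean-field; latch-like positive feedback (Signal -> 4-1BB ->
  threshold) makes simulated dose responses near the ignition dose sharper
  than population-resolved biology would be, and the bell family cannot
  represent such quasi-discontinuous curves to arbitrary accuracy between
  sampled doses.
* Parameters are a calibrated reference set, not measurements; conclusions
  should be read as structural (which mechanisms can or cannot produce
  which phenotypes), not as quantitative rate estimates.
* EC50 estimates inherit the dose grid's resolution: with 3-fold
  dilutions, half-max crossings between doses carry an irreducible
  interpolation uncertainty.
* Cumulative-cytokine readouts only; consumed cytokines (IL-2) and
  co-stimulation of proliferation/survival are out of scope.
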