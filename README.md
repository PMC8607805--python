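# costimod

Operational modelling of TNFRSF co-stimulation of CD8+ T-cell cytokine
responses.

CD8+ T cells stimulated with plate-immobilised pMHC produce a burst of
cytokine and then *adapt*: TCR downregulation silences the response within
about 8 hours even though antigen is still present.  Co-stimulatory
receptors of the TNF receptor superfamily (CD27, 4-1BB, GITR) share
TRAF-based signalling yet have sharply different quantitative phenotypes:
CD27 amplifies the early response only (it is expressed on resting cells and
rapidly downregulated by its ligand CD70), whereas 4-1BB — absent on resting
cells and induced by TCR signalling — sustains cytokine production past the
adaptation point.  `costimod` implements an operational ODE model that
explains both phenotypes with a single shared mechanism, plus the
dose-response analysis used to quantify such screens.  It is written for
quantitative immunologists and systems biologists who want to simulate,
re-analyse, or extend this class of model.

## The model

State variables: surface TCR and CD27 (fractions of resting level),
integrated activation `Signal`, cumulative secreted `Cytokine`, and surface
4-1BB.  pMHC binding is at rapid equilibrium,

    C = pMHC^n / (K_A^n + pMHC^n) * TCR

and drives both TCR loss and a population-averaged digital switch,

    dTCR/dt      = k1 (1 - TCR) - k2 C
    dSignal/dt   = 1/2 + 1/2 erf((C - mu) / (sqrt(2) sigma)) - k3 Signal
    dCytokine/dt = k4 Signal

an incoherent feedforward loop: activation and adaptation from the same
input.  Receptor expression follows

    dCD27/dt = k5 (1 - CD27) - k6 f_CD70 CD27
    d41BB/dt = k7 Signal - k8 f_41BBL 41BB - k9 41BB

with `f_L = L / (K_D + L)` the ligand occupancies.  In the accepted model
co-stimulation lowers the activation threshold of the switch,

    erf argument:  ((1 + k10 CD27 f_CD70 + k11 41BB f_41BBL) C - mu) / (sqrt(2) sigma)

scaled by the *current* surface receptor level, so CD27 loss ends CD27
co-stimulation while the Signal -> 4-1BB feedback sustains 4-1BB
co-stimulation.  Six alternative integration points (scaling the switch
output, adding to its argument, gating Signal decay, scaling or offsetting
cytokine production), plus affinity- and TCR-expression-modulation variants,
are implemented for model selection; an executable scorecard of seven
phenotype criteria (adaptation, CD27 front-loading, 4-1BB persistence,
rescue of adapted cells, antigen dependence, CD70 pre-exposure penalty,
surface-TCR direction) identifies threshold modulation as the unique variant
consistent with all of them.

The analysis side fits each cytokine dose-response curve with the
bell-shaped function

    y(x) = Emin + [a + (b - a)/(1 + (c1/x)^n1) - Emin] / (1 + (c2/x)^n2)

and reads Emax and EC50 off a 10,000-point evaluation of the fitted line
(EC50 excluded when Emax < 50 pg/ml).  A synthetic-data module emulates the
ELISA screen (12 pMHC doses x ligand titrations x 4, 8, 16, 24 h, in
replicate across donors) with a configurable noise model, so the whole
pipeline — including parameter calibration by least squares on extracted
Emax/EC50 trajectories — runs without any external data.

## Worked example

```python
import numpy as np
from costimod import (ModelParameters, VariantSpec, LigandCondition,
                      simulate_screen, default_pmhc_grid, fit_bell,
                      extract_metrics, predict_synergy)

params = ModelParameters()          # calibrated defaults
spec = VariantSpec()                # THRESHOLD_MOD, receptor-scaled

surfaces = simulate_screen(
    params, spec, default_pmhc_grid(),
    [LigandCondition("none", 0.0), LigandCondition("CD70", 200.0),
     LigandCondition("4-1BBL", 500.0)],
)
for surf in surfaces:
    print(f"{surf.condition.ligand:>7}: Emax(4,8,16,24 h) =",
          np.round(surf.emax(), 1))

curve = surfaces[0].curve(8.0)
m = extract_metrics(fit_bell(surfaces[0].pmhc_doses, curve))
print(f"8 h no-costim: Emax = {m.emax:.1f} pg/ml, EC50 = {m.ec50:.1f} ng/well")

row = predict_synergy(params, pmhc_doses=[667.0]).iloc[0]
print(f"4-1BB at 16 h: {row.b41bb_16h_none:.2f} without vs "
      f"{row.b41bb_16h_cd70:.2f} with phase-1 CD70")
print(f"synergy index at 667 ng/well: {row.synergy_index:.1f}")
```

prints

```
   none: Emax(4,8,16,24 h) = [421.7 646.3 684.3 686. ]
   CD70: Emax(4,8,16,24 h) = [ 454.1 1152.4 1531.2 1559.6]
 4-1BBL: Emax(4,8,16,24 h) = [ 454.1 1207.3 2800.1 4400. ]
8 h no-costim: Emax = 645.8 pg/ml, EC50 = 22.8 ng/well
4-1BB at 16 h: 1.09 without vs 2.43 with phase-1 CD70
synergy index at 667 ng/well: 37.0
```

Reading the numbers: without co-stimulation cytokine output plateaus after
8 h (646 -> 686, adaptation); CD70 roughly doubles the early output but the
amplification stops growing (front-loaded); 4-1BBL keeps production going
(1207 -> 4400, persistence).  In the two-phase protocol, 16 h of CD70
co-stimulation more than doubles surface 4-1BB at transfer, and the synergy
index — the excess phase-2 cytokine from sequential CD27 -> 4-1BB engagement
beyond the sum of the single-receptor effects — is positive at every
activating dose.

A command line mirrors the library: `costimod simulate | screen | fit-dr |
gen-data | select-model | predict-synergy | calibrate` (see `costimod
--help`).

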