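"""Right-hand sides of the operational co-stimulation model.

The model couples an incoherent feedforward loop (pMHC engagement drives both
TCR downregulation and activation signalling) to a population-averaged digital
switch: the fraction of cells whose activation threshold is exceeded by the
current pMHC-TCR complex level C is ``1/2 + 1/2*erf(...)``, i.e. a normal CDF
in C.  Co-stimulatory receptors (CD27, constitutively expressed and
ligand-downregulated; 4-1BB, signal-induced) modulate this switch.  The
accepted model lowers the activation threshold in proportion to engaged
co-stimulatory receptor; the alternative variants integrate the same ligand
occupancy at other positions of the cascade and exist to be excluded.

States
------
``TCR``      surface TCR, fraction of the resting level (starts at 1)
``Signal``   integrated activation signal (starts at 0)
``Cytokine`` cumulative secreted cytokine, arbitrary units (starts at 0)
``CD27``     surface CD27, fraction of the resting level (starts at 1)
``B41BB``    surface 4-1BB, arbitrary units (starts at 0)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    CD70_ONLY_VARIANTS,
    ModelParameters,
    ModelVariant,
    ModulationMode,
    VariantSpec,
)

__all__ = [
    "ModelState",
    "StimulusPhase",
    "complex_occupancy",
    "switch_rate",
    "rhs",
    "resting_state",
    "STATE_NAMES",
]

STATE_NAMES = ("TCR", "Signal", "Cytokine", "CD27", "B41BB")

_SQRT2 = math.sqrt(2.0)
_LO = float(np.nextafter(0.0, 1.0))
_HI = float(np.nextafter(1.0, 0.0))


@dataclass
class ModelState:
    """One point of the model's state space."""

    TCR: float = 1.0
    Signal: float = 0.0
    Cytokine: float = 0.0
    CD27: float = 1.0
    B41BB: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.TCR, self.Signal, self.Cytokine, self.CD27, self.B41BB])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(*(float(v) for v in y))


def resting_state() -> ModelState:
    """Initial conditions of a resting T cell: full TCR and CD27, no signal,
    no secreted cytokine, no 4-1BB (4-1BB is absent on resting cells)."""
    return ModelState()


@dataclass(frozen=True)
class StimulusPhase:
    """Constant plate-immobilised ligand doses over one stimulation phase."""

    pMHC_dose: float = 0.0
    CD70_dose: float = 0.0
    L41BB_dose: float = 0.0
    duration: float = 24.0

    def __post_init__(self) -> None:
        for name in ("pMHC_dose", "CD70_dose", "L41BB_dose"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.duration > 0:
            raise ValueError("phase duration must be > 0")


def complex_occupancy(pMHC_dose: float, TCR: float, KA: float, n: float) -> float:
    """pMHC-TCR complex level under rapid binding equilibrium.

    ``C = pMHC^n / (KA^n + pMHC^n) * TCR`` — a Hill occupancy of the surface
    TCR pool.  Monotone non-decreasing in dose and in TCR; ``0 <= C <= TCR``.
    """
    if pMHC_dose < 0 or TCR < 0:
        raise ValueError("pMHC_dose and TCR must be >= 0")
    if not KA > 0:
        raise ValueError("KA must be > 0")
    if pMHC_dose == 0.0:
        return 0.0
    # evaluate in log-ratio form for numerical safety at extreme doses
    ln_r = n * (math.log(KA) - math.log(pMHC_dose))
    if ln_r > 700.0:
        return 0.0
    return TCR / (1.0 + math.exp(ln_r))


def switch_rate(
    C: float,
    mu: float,
    sigma: float,
    modulation_factor: float = 1.0,
    erf_denom: str = "sqrt2",
) -> float:
    """Population-averaged digital switch: fraction of cells activated.

    ``1/2 + 1/2 * erf((f*C - mu) / (sqrt(2)*sigma))`` where ``f`` is the
    co-stimulation modulation factor (1 without co-stimulation).  With the
    default ``sqrt2`` convention this equals the normal CDF
    ``Phi((f*C - mu)/sigma)``, i.e. thresholds are normally distributed across
    the population with mean ``mu`` and SD ``sigma``.  ``erf_denom="two"``
    uses the literal ``2*sigma`` denominator instead.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    if modulation_factor < 0:
        raise ValueError("modulation_factor must be >= 0")
    denom = (_SQRT2 if erf_denom == "sqrt2" else 2.0) * sigma
    v = 0.5 + 0.5 * math.erf((modulation_factor * C - mu) / denom)
    return min(max(v, _LO), _HI)


def _occupancies(phase: StimulusPhase, p: ModelParameters) -> tuple[float, float]:
    f_cd70 = phase.CD70_dose / (p.KD_CD27 + phase.CD70_dose)
    f_41bb = phase.L41BB_dose / (p.KD_41BB + phase.L41BB_dose)
    return f_cd70, f_41bb


def _ligand_weights(
    y: np.ndarray, phase: StimulusPhase, p: ModelParameters, spec: VariantSpec
) -> tuple[float, float]:
    """CD70 and 4-1BBL engagement terms entering the modulation factor."""
    f_cd70, f_41bb = _occupancies(phase, p)
    if spec.modulation_mode is ModulationMode.RECEPTOR_SCALED:
        return max(y[3], 0.0) * f_cd70, max(y[4], 0.0) * f_41bb
    return f_cd70, f_41bb


def rhs(
    y: np.ndarray | ModelState,
    params: ModelParameters,
    phase: StimulusPhase,
    spec: VariantSpec | ModelVariant = VariantSpec(),
    *,
    clamp_signal: bool = False,
) -> np.ndarray:
    """Time derivative of the model state for one variant.

    Parameters
    ----------
    y :
        State vector ``(TCR, Signal, Cytokine, CD27, B41BB)`` or a
        :class:`ModelState`.
    clamp_signal :
        Diagnostic switch: hold Signal constant (``dSignal/dt = 0``), used to
        probe the 4-1BB fixed point ``k7*Signal/k9`` at clamped drive.

    Notes
    -----
    The switch production term is floored at 0: variant ``ALT2`` scales the
    (signed) erf and could otherwise produce a negative signal-generation
    rate, which is unphysical and would break state non-negativity.
    """
    if isinstance(y, ModelState):
        y = y.to_array()
    if isinstance(spec, ModelVariant):
        spec = VariantSpec(variant=spec)
    p = params
    variant = spec.variant
    TCR, S, _, CD27, B = (float(v) for v in y)

    wC, wB = _ligand_weights(np.asarray(y, dtype=float), phase, p, spec)
    if variant in CD70_ONLY_VARIANTS:
        wB = 0.0  # printed alternatives carry only the CD70 term
    mod = 1.0 + p.k10 * wC + p.k11 * wB  # generic modulation factor

    KA_eff = p.KA
    k1_eff = p.k1
    if variant is ModelVariant.EXPLORE_KA:
        KA_eff = p.KA / mod
    elif variant is ModelVariant.EXPLORE_TCR:
        k1_eff = p.k1 * mod

    C = complex_occupancy(phase.pMHC_dose, max(TCR, 0.0), KA_eff, p.n)

    denom = (_SQRT2 if spec.erf_denom == "sqrt2" else 2.0) * p.sigma
    z = (C - p.mu) / denom

    if variant in (ModelVariant.THRESHOLD_MOD, ModelVariant.ALT1):
        production = switch_rate(C, p.mu, p.sigma, mod, spec.erf_denom)
    elif variant is ModelVariant.ALT2:
        production = 0.5 + 0.5 * mod * math.erf(z)
    elif variant is ModelVariant.ALT3:
        production = 0.5 + 0.5 * math.erf(z + p.k10 * wC)
    else:  # BASE, ALT4*, ALT5, ALT6, EXPLORE_*: unmodulated switch
        production = switch_rate(C, p.mu, p.sigma, 1.0, spec.erf_denom)
    production = max(production, 0.0)

    if variant is ModelVariant.ALT4_LITERAL:
        decay = p.k3 * S * p.k10 * wC
    elif variant is ModelVariant.ALT4_ATTEN:
        decay = p.k3 * S / (1.0 + p.k10 * wC)
    else:
        decay = p.k3 * S

    if variant is ModelVariant.ALT5:
        d_cyt = p.k4 * (1.0 + p.k10 * wC) * S
    elif variant is ModelVariant.ALT6:
        d_cyt = p.k4 * S + p.k10 * wC
    else:
        d_cyt = p.k4 * S

    f_cd70, f_41bb = _occupancies(phase, p)
    d_tcr = k1_eff * (1.0 - TCR) - p.k2 * C
    d_sig = 0.0 if clamp_signal else production - decay
    d_cd27 = p.k5 * (1.0 - CD27) - p.k6 * f_cd70 * CD27
    d_b = p.k7 * S - p.k8 * f_41bb * B - p.k9 * B
    return np.array([d_tcr, d_sig, d_cyt, d_cd27, d_b])
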