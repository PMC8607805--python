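"""Model parameters, variants and configuration I/O.

The operational model of TNFRSF co-stimulation is a five-state ODE system
(surface TCR, integrated Signal, cumulative Cytokine, surface CD27, surface
4-1BB) driven by plate-immobilised ligand doses.  All rate constants are per
hour; receptor levels are fractions of the resting level (TCR, CD27) or
arbitrary synthesis-rate units (4-1BB); doses are ng/well.

The default parameter values are calibration products of this package: they
were chosen once so that the accepted model reproduces the qualitative
phenotypes of the screen (cytokine adaptation by ~8 h without co-stimulation,
front-loaded CD27 amplification, persistent 4-1BB amplification).  They are
not measured constants.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ModelVariant",
    "ModulationMode",
    "VariantSpec",
    "load_config",
    "save_config",
    "gitr_like",
]


class ModelVariant(str, enum.Enum):
    """Where co-stimulation integrates into the signalling cascade.

    ``BASE`` has no co-stimulation.  ``THRESHOLD_MOD`` is the accepted model:
    receptor engagement lowers the activation threshold of the digital
    switch.  ``ALT1``–``ALT6`` are the six printed alternative integration
    points (CD70 term only); ``ALT4`` exists in two readings (see
    :mod:`costimod.model_core`).  ``EXPLORE_KA`` lets co-stimulation sharpen
    the pMHC–TCR interaction (scales the apparent affinity), ``EXPLORE_TCR``
    lets it boost TCR resynthesis.
    """

    BASE = "BASE"
    THRESHOLD_MOD = "THRESHOLD_MOD"
    ALT1 = "ALT1"
    ALT2 = "ALT2"
    ALT3 = "ALT3"
    ALT4_LITERAL = "ALT4_LITERAL"
    ALT4_ATTEN = "ALT4_ATTEN"
    ALT5 = "ALT5"
    ALT6 = "ALT6"
    EXPLORE_KA = "EXPLORE_KA"
    EXPLORE_TCR = "EXPLORE_TCR"


class ModulationMode(str, enum.Enum):
    """How ligand engagement enters the modulation factor.

    ``LITERAL``: occupancy only, exactly as printed.  ``RECEPTOR_SCALED``
    (default): occupancy multiplied by the current surface receptor level, so
    that receptor downregulation has functional consequences.
    """

    LITERAL = "LITERAL"
    RECEPTOR_SCALED = "RECEPTOR_SCALED"


#: Variants whose printed equations carry only the CD70 (CD27) term.
CD70_ONLY_VARIANTS = frozenset(
    {
        ModelVariant.ALT1,
        ModelVariant.ALT2,
        ModelVariant.ALT3,
        ModelVariant.ALT4_LITERAL,
        ModelVariant.ALT4_ATTEN,
        ModelVariant.ALT5,
        ModelVariant.ALT6,
    }
)


@dataclass(frozen=True)
class VariantSpec:
    """A fully specified model variant.

    Parameters
    ----------
    variant :
        Integration point of co-stimulation.
    modulation_mode :
        Occupancy-only (``LITERAL``) or receptor-scaled modulation.
    erf_denom :
        ``"sqrt2"`` reads the switch argument as (C-mu)/(sqrt(2)*sigma), the
        normal-CDF convention; ``"two"`` keeps the literal (C-mu)/(2*sigma)
        typography.
    """

    variant: ModelVariant = ModelVariant.THRESHOLD_MOD
    modulation_mode: ModulationMode = ModulationMode.RECEPTOR_SCALED
    erf_denom: str = "sqrt2"

    def __post_init__(self) -> None:
        if self.erf_denom not in ("sqrt2", "two"):
            raise ValueError(f"erf_denom must be 'sqrt2' or 'two', got {self.erf_denom!r}")
        if not isinstance(self.variant, ModelVariant):
            object.__setattr__(self, "variant", ModelVariant(self.variant))
        if not isinstance(self.modulation_mode, ModulationMode):
            object.__setattr__(self, "modulation_mode", ModulationMode(self.modulation_mode))


_POSITIVE_FIELDS = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
    "mu", "sigma", "KA", "KD_CD27", "KD_41BB",
)


@dataclass
class ModelParameters:
    """Rate constants, thresholds and affinities of the ODE system.

    Attributes
    ----------
    k1 : TCR resynthesis rate (1/h).
    k2 : complex-driven TCR downregulation rate (1/h).
    k3 : Signal decay rate (1/h).
    k4 : cytokine production rate per unit Signal (concentration units/h).
    k5 : CD27 resynthesis rate (1/h).
    k6 : ligand-driven CD27 downregulation rate (1/h).
    k7 : Signal-driven 4-1BB synthesis rate (1/h).
    k8 : ligand-driven 4-1BB downregulation rate (1/h).
    k9 : constitutive 4-1BB decay rate (1/h).
    k10 : CD27 co-stimulation strength (dimensionless).
    k11 : 4-1BB co-stimulation strength (dimensionless).
    mu : mean activation threshold across the T-cell population (complex units).
    sigma : population SD of the activation threshold (complex units).
    KA : pMHC dose at half receptor occupancy (ng/well).
    n : Hill number of pMHC binding (dimensionless, >= 1).
    KD_CD27 : CD70 dose at half occupancy (ng/well).
    KD_41BB : 4-1BBL dose at half occupancy (ng/well).
    """

    k1: float = 0.05
    k2: float = 0.5
    k3: float = 0.5
    k4: float = 100.0
    k5: float = 0.05
    k6: float = 0.4
    k7: float = 0.3
    k8: float = 0.2
    k9: float = 0.05
    k10: float = 6.0
    k11: float = 3.0
    mu: float = 0.25
    sigma: float = 0.05
    KA: float = 50.0
    n: float = 1.0
    KD_CD27: float = 50.0
    KD_41BB: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.k10 < 0 or self.k11 < 0:
            raise ValueError("co-stimulation strengths k10, k11 must be >= 0")
        if self.n < 1:
            raise ValueError(f"Hill number n must be >= 1, got {self.n}")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


def gitr_like(params: ModelParameters) -> ModelParameters:
    """A GITR-like inducible receptor: the 4-1BB equations with slower, lower
    signal-induced synthesis (GITR is induced with slower kinetics and to a
    lesser extent than 4-1BB on CD8+ blasts)."""
    return params.replace(k7=0.3 * params.k7, k9=2.0 * params.k9)


# ---------------------------------------------------------------------------
# Config file round-trip: flat mapping of every parameter field plus
# variant/modulation_mode/erf_denom.  Unknown keys are rejected.
# ---------------------------------------------------------------------------

_SPEC_KEYS = ("variant", "modulation_mode", "erf_denom")


def save_config(path: str | Path, params: ModelParameters, spec: VariantSpec | None = None) -> None:
    """Write parameters (and optionally the variant spec) to YAML or JSON."""
    payload: dict[str, Any] = dict(params.to_dict())
    if spec is not None:
        payload["variant"] = spec.variant.value
        payload["modulation_mode"] = spec.modulation_mode.value
        payload["erf_denom"] = spec.erf_denom
    path = Path(path)
    text = (
        json.dumps(payload, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(payload, sort_keys=False)
    )
    path.write_text(text)


def load_config(path: str | Path) -> tuple[ModelParameters, VariantSpec]:
    """Read a config written by :func:`save_config`.

    Missing variant keys fall back to the defaults; unknown keys raise.
    """
    path = Path(path)
    raw = path.read_text()
    payload = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    spec_kwargs = {k: payload.pop(k) for k in _SPEC_KEYS if k in payload}
    params = ModelParameters.from_dict(payload)
    spec = VariantSpec(**spec_kwargs)
    return params, spec
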