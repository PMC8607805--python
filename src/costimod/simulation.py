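"""Numerical integration of the model over screens and plate-transfer protocols.

Single-phase simulations emulate the plate-bound ELISA screen (one well = one
constant-dose stimulation); two-phase simulations emulate the plate-transfer
design in which cells are moved to a second ligand composition after 16 h.
At transfer every cellular state (TCR, Signal, CD27, 4-1BB) carries over
continuously; only the secreted cytokine is removed with the supernatant, so
Cytokine is reset to 0 at the start of each new phase.

Integration uses :func:`scipy.integrate.solve_ivp` with a stiff-capable
method (LSODA by default): the switch makes the dynamics stiff near the
activation threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import STATE_NAMES, ModelState, StimulusPhase, resting_state, rhs
from .parameters import ModelParameters, ModelVariant, VariantSpec, gitr_like

__all__ = [
    "Protocol",
    "Trajectory",
    "LigandCondition",
    "ResponseSurface",
    "IntegrationError",
    "integrate",
    "simulate_screen",
    "simulate_two_phase",
    "default_pmhc_grid",
    "DEFAULT_TIMES",
]

DEFAULT_TIMES = (4.0, 8.0, 16.0, 24.0)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (t = {time:g} h)")
        self.time = time


@dataclass(frozen=True)
class Protocol:
    """An ordered list of one or two constant-dose stimulation phases."""

    phases: tuple[StimulusPhase, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.phases) <= 2:
            raise ValueError("protocol must have 1 or 2 phases")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @classmethod
    def single(cls, phase: StimulusPhase) -> "Protocol":
        return cls(phases=(phase,))


@dataclass
class Trajectory:
    """Time-resolved model states with provenance.

    ``times`` is strictly increasing and starts at 0; ``states`` has one row
    per time in the order ``(TCR, Signal, Cytokine, CD27, B41BB)``;
    ``phase_index`` maps each time to the phase it belongs to.  Cytokine is
    cumulative within a phase and reset to 0 at each transfer.
    """

    times: np.ndarray
    states: np.ndarray
    phase_index: np.ndarray
    protocol: Protocol
    params: ModelParameters
    spec: VariantSpec

    def state_at(self, t: float) -> ModelState:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise KeyError(f"time {t} not stored in trajectory")
        return ModelState.from_array(self.states[i])

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(STATE_NAMES):
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "phase": self.phase_index + 1,
                        "variable": name,
                        "value": self.states[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def default_pmhc_grid(top: float = 2000.0, n_doses: int = 12, dilution: float = 3.0) -> np.ndarray:
    """The screen's pMHC series: ``top`` with serial dilutions plus a 0 dose.

    Default: 2,000 ng/well with 11 three-fold dilutions plus 0 (12 doses),
    returned in ascending order.
    """
    doses = top / dilution ** np.arange(n_doses - 1)
    return np.concatenate([[0.0], doses[::-1]])


def integrate(
    params: ModelParameters,
    protocol: Protocol | StimulusPhase,
    spec: VariantSpec | ModelVariant = VariantSpec(),
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
    y0: ModelState | None = None,
    clamp_signal: bool = False,
) -> Trajectory:
    """Integrate the model over a protocol and return the trajectory.

    ``t_eval`` are absolute times (h) at which to store the state; phase
    boundaries and 0 are always included.  Cytokine is reset to 0 at the
    start of every phase after the first (supernatant washout).
    """
    if isinstance(protocol, StimulusPhase):
        protocol = Protocol.single(protocol)
    if isinstance(spec, ModelVariant):
        spec = VariantSpec(variant=spec)
    if not (rtol > 0 and atol > 0):
        raise ValueError("tolerances must be positive")

    boundaries = np.concatenate([[0.0], np.cumsum([p.duration for p in protocol.phases])])
    if t_eval is None:
        t_eval = np.unique(np.concatenate([
            np.linspace(boundaries[i], boundaries[i + 1], 97)
            for i in range(len(protocol.phases))
        ]))
    t_eval = np.unique(np.concatenate([np.asarray(t_eval, dtype=float), boundaries]))
    if t_eval[0] < 0 or t_eval[-1] > boundaries[-1] + 1e-9:
        raise ValueError("t_eval must lie within the protocol duration")

    y = (y0 or resting_state()).to_array().copy()
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    all_phase: list[np.ndarray] = []
    for i, phase in enumerate(protocol.phases):
        t0, t1 = float(boundaries[i]), float(boundaries[i + 1])
        if i > 0:
            y = y.copy()
            y[2] = 0.0  # washout: secreted cytokine removed at transfer
        mask = (t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-12)
        te = np.clip(t_eval[mask], t0, t1)
        sol = solve_ivp(
            lambda t, yy: rhs(yy, params, phase, spec, clamp_signal=clamp_signal),
            (t0, t1),
            y,
            method=method,
            t_eval=te,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}", float(sol.t[-1]) if len(sol.t) else t0)
        keep = slice(1, None) if i > 0 else slice(None)  # boundary time belongs to earlier phase
        all_t.append(sol.t[keep])
        all_y.append(sol.y.T[keep])
        all_phase.append(np.full(len(sol.t[keep]), i, dtype=int))
        y = sol.y[:, -1]

    states = np.vstack(all_y)
    # guard tiny negative excursions from solver tolerance
    states[states < 0] = np.where(states[states < 0] > -10 * atol, 0.0, states[states < 0])
    return Trajectory(
        times=np.concatenate(all_t),
        states=states,
        phase_index=np.concatenate(all_phase),
        protocol=protocol,
        params=params,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

_LIGANDS = ("none", "CD70", "4-1BBL", "GITRL")


@dataclass(frozen=True)
class LigandCondition:
    """One co-stimulatory arm of the screen.

    ``GITRL`` reuses the inducible-receptor (4-1BB) equations with the
    GITR-like parameter adjustment (slower/lower synthesis).
    """

    ligand: str = "none"
    dose: float = 0.0

    def __post_init__(self) -> None:
        if self.ligand not in _LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}; expected one of {_LIGANDS}")
        if self.dose < 0:
            raise ValueError("ligand dose must be >= 0")

    def phase(self, pmhc: float, duration: float) -> StimulusPhase:
        cd70 = self.dose if self.ligand == "CD70" else 0.0
        l41 = self.dose if self.ligand in ("4-1BBL", "GITRL") else 0.0
        return StimulusPhase(pMHC_dose=pmhc, CD70_dose=cd70, L41BB_dose=l41, duration=duration)

    def effective_params(self, params: ModelParameters) -> ModelParameters:
        return gitr_like(params) if self.ligand == "GITRL" else params


@dataclass
class ResponseSurface:
    """Simulated cytokine over a pMHC dose grid and time points for one arm."""

    condition: LigandCondition
    pmhc_doses: np.ndarray
    times: np.ndarray
    cytokine: np.ndarray  # shape (n_doses, n_times)
    trajectories: list[Trajectory] = field(default_factory=list)

    def emax(self) -> np.ndarray:
        """Max cytokine across the dose grid, per time point."""
        return self.cytokine.max(axis=0)

    def curve(self, time: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.times - time)))
        return self.cytokine[:, j]

    def to_tidy(self) -> pd.DataFrame:
        d, t = np.meshgrid(self.pmhc_doses, self.times, indexing="ij")
        return pd.DataFrame(
            {
                "time_h": t.ravel(),
                "pmhc_ng_well": d.ravel(),
                "ligand": self.condition.ligand,
                "ligand_ng_well": self.condition.dose,
                "variable": "Cytokine",
                "value": self.cytokine.ravel(),
            }
        )


def simulate_screen(
    params: ModelParameters,
    spec: VariantSpec | ModelVariant,
    pmhc_doses: Sequence[float],
    ligand_conditions: Iterable[LigandCondition],
    times: Sequence[float] = DEFAULT_TIMES,
    keep_trajectories: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> list[ResponseSurface]:
    """Simulate one plate screen: every (ligand condition x pMHC dose) well.

    Returns one :class:`ResponseSurface` per ligand condition; cytokine is
    cumulative, hence non-decreasing in time at every dose.
    """
    pmhc_doses = np.asarray(pmhc_doses, dtype=float)
    times = np.asarray(times, dtype=float)
    if pmhc_doses.size == 0 or times.size == 0:
        raise ValueError("dose and time grids must be non-empty")
    if np.any(pmhc_doses < 0):
        raise ValueError("pMHC doses must be >= 0")
    conditions = list(ligand_conditions)
    if not conditions:
        raise ValueError("at least one ligand condition required")

    duration = float(times.max())
    surfaces = []
    for cond in conditions:
        p_eff = cond.effective_params(params)
        cyt = np.empty((len(pmhc_doses), len(times)))
        trajs = []
        for i, dose in enumerate(pmhc_doses):
            traj = integrate(
                p_eff,
                cond.phase(float(dose), duration),
                spec,
                t_eval=times,
                rtol=rtol,
                atol=atol,
            )
            idx = [int(np.argmin(np.abs(traj.times - t))) for t in times]
            cyt[i] = traj.states[idx, 2]
            if keep_trajectories:
                trajs.append(traj)
        surfaces.append(
            ResponseSurface(condition=cond, pmhc_doses=pmhc_doses, times=times, cytokine=cyt, trajectories=trajs)
        )
    return surfaces


def simulate_two_phase(
    params: ModelParameters,
    spec: VariantSpec | ModelVariant,
    phase1: StimulusPhase,
    phase2: StimulusPhase,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> tuple[Trajectory, float]:
    """Plate-transfer protocol: integrate phase 1, carry every cellular state
    over, wash out the cytokine, integrate phase 2.

    Returns the full trajectory and the phase-2 cytokine output (cumulative
    cytokine at the end of phase 2).
    """
    traj = integrate(params, Protocol(phases=(phase1, phase2)), spec, rtol=rtol, atol=atol)
    return traj, float(traj.states[-1, 2])


def export_surfaces(
    surfaces: Iterable[ResponseSurface],
    out_csv: str | Path,
    params: ModelParameters,
    spec: VariantSpec,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> None:
    """Write surfaces as tidy CSV plus a JSON provenance sidecar."""
    surfaces = list(surfaces)
    out_csv = Path(out_csv)
    pd.concat([s.to_tidy() for s in surfaces], ignore_index=True).to_csv(out_csv, index=False)
    sidecar = {
        "params": params.to_dict(),
        "variant": spec.variant.value,
        "modulation_mode": spec.modulation_mode.value,
        "erf_denom": spec.erf_denom,
        "rtol": rtol,
        "atol": atol,
        "pmhc_doses": [float(x) for x in surfaces[0].pmhc_doses],
        "times_h": [float(x) for x in surfaces[0].times],
        "conditions": [
            {"ligand": s.condition.ligand, "dose_ng_well": s.condition.dose} for s in surfaces
        ],
    }
    out_csv.with_suffix(".provenance.json").write_text(json.dumps(sidecar, indent=2))
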