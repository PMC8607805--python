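"""Synthetic ELISA screen and plate-transfer datasets.

The study's readout is an ELISA screen: 12 pMHC doses x several trimeric
TNFSF-ligand doses x four time points (4, 8, 16, 24 h), in duplicate wells
across a few independent experiments (donors).  No such dataset is publicly
deposited, so this module generates one: ground truth comes from the ODE
model (:mod:`costimod.simulation`), measurement noise is layered on top.

Noise model (invented plumbing, configurable; the study reports no error
model):

* mean-one multiplicative lognormal noise per well (ELISA CV, default 0.15);
* a mean-one lognormal scale factor per experiment (donor/transduction
  variability, default SD 0.25) shared by all wells of that experiment;
* an additive lognormal detection background around the floor (default
  4 pg/ml), emulating the non-zero blank of the assay.

With all three sources at 0 the records equal the simulation exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import direct_response_metrics
from .model_core import StimulusPhase
from .parameters import ModelParameters, ModelVariant, VariantSpec
from .simulation import (
    DEFAULT_TIMES,
    LigandCondition,
    default_pmhc_grid,
    simulate_screen,
    simulate_two_phase,
)

__all__ = [
    "ScreenDesign",
    "NoiseModel",
    "generate_screen",
    "generate_transfer_dataset",
    "default_ligand_conditions",
]

RECORD_COLUMNS = (
    "experiment",
    "cytokine",
    "pmhc_ng_well",
    "ligand",
    "ligand_ng_well",
    "time_h",
    "replicate",
    "phase",
    "concentration_pg_ml",
)


def _titration(top: float, n: int, dilution: float = 2.0) -> list[float]:
    return [top / dilution**i for i in range(n)]


def default_ligand_conditions() -> list[LigandCondition]:
    """The screen's co-stimulation arms: no ligand plus 7-dose titrations of
    CD70 (top 200 ng/well), 4-1BBL (top 500) and GITRL (top 500) — 22
    conditions in total, matching the screen's 3-7 doses per trimeric ligand
    anchored at the doses used in the transfer experiments."""
    conditions = [LigandCondition("none", 0.0)]
    for ligand, top in (("CD70", 200.0), ("4-1BBL", 500.0), ("GITRL", 500.0)):
        conditions += [LigandCondition(ligand, d) for d in _titration(top, 7)]
    return conditions


@dataclass
class ScreenDesign:
    """Factorial layout of one screen."""

    pmhc_doses: np.ndarray = field(default_factory=default_pmhc_grid)
    ligand_conditions: list[LigandCondition] = field(default_factory=default_ligand_conditions)
    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 2
    n_experiments: int = 3
    cytokine: str = "IFNg"

    def __post_init__(self) -> None:
        self.pmhc_doses = np.asarray(self.pmhc_doses, dtype=float)
        if self.pmhc_doses.size == 0 or not self.ligand_conditions or not self.times:
            raise ValueError("all design grids must be non-empty")
        if self.replicates < 1 or self.n_experiments < 1:
            raise ValueError("replicates and n_experiments must be >= 1")

    @property
    def n_condition_rows(self) -> int:
        """Condition count before replication (doses x ligand arms x times)."""
        return len(self.pmhc_doses) * len(self.ligand_conditions) * len(self.times)


@dataclass
class NoiseModel:
    """ELISA-like measurement noise; all magnitudes configurable."""

    cv: float = 0.15
    scale_sd: float = 0.25
    floor_pg_ml: float = 4.0
    floor_sd_log: float = 0.3

    def __post_init__(self) -> None:
        if self.cv < 0 or self.scale_sd < 0 or self.floor_pg_ml < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def experiment_scales(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.scale_sd == 0:
            return np.ones(n)
        s = self.scale_sd
        return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)

    def corrupt(self, truth: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
        """Apply per-well noise to noiseless concentrations (mean-one
        multiplicative lognormal plus additive detection background)."""
        out = np.asarray(truth, dtype=float) * scale
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            out = out * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=out.shape)
        if self.floor_pg_ml > 0:
            out = out + self.floor_pg_ml * rng.lognormal(
                mean=-0.5 * self.floor_sd_log**2, sigma=self.floor_sd_log, size=out.shape
            )
        return out


def _records_from_truth(
    truth_rows: list[dict],
    design_replicates: int,
    n_experiments: int,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    scales = noise.experiment_scales(rng, n_experiments)
    records = []
    for e in range(n_experiments):
        for row in truth_rows:
            vals = noise.corrupt(
                np.full(design_replicates, row["truth"]), float(scales[e]), rng
            )
            for r, v in enumerate(vals):
                rec = {k: row[k] for k in row if k != "truth"}
                rec.update(experiment=f"exp{e + 1}", replicate=r + 1, concentration_pg_ml=float(v))
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    return df[list(RECORD_COLUMNS)]


def generate_screen(
    params: ModelParameters,
    variant: VariantSpec | ModelVariant,
    design: ScreenDesign | None = None,
    noise: NoiseModel | None = None,
    cytokine_scale: float = 1.0,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> tuple[pd.DataFrame, dict]:
    """Generate a tidy table of synthetic ELISA wells for one screen.

    Returns ``(records, truth)`` where ``truth`` is a sidecar carrying the
    generating parameters and the per-curve noiseless Emax (max cytokine over
    the dose grid, in pg/ml after ``cytokine_scale``).
    """
    design = design or ScreenDesign()
    noise = noise or NoiseModel()
    if not cytokine_scale > 0:
        raise ValueError("cytokine_scale must be > 0")
    rng = np.random.default_rng(seed)

    surfaces = simulate_screen(
        params, variant, design.pmhc_doses, design.ligand_conditions,
        times=design.times, rtol=rtol, atol=atol,
    )
    truth_rows = []
    true_emax = {}
    true_ec50 = {}
    for surf in surfaces:
        cyt_pg = surf.cytokine * cytokine_scale
        for j, t in enumerate(surf.times):
            key = f"{surf.condition.ligand}|{surf.condition.dose:g}|{t:g}"
            emax_t, ec50_t = direct_response_metrics(surf.pmhc_doses, cyt_pg[:, j])
            true_emax[key] = emax_t
            true_ec50[key] = ec50_t  # grid-resolution half-max crossing
            for i, dose in enumerate(surf.pmhc_doses):
                truth_rows.append(
                    dict(
                        cytokine=design.cytokine,
                        pmhc_ng_well=float(dose),
                        ligand=surf.condition.ligand,
                        ligand_ng_well=surf.condition.dose,
                        time_h=float(t),
                        phase=1,
                        truth=float(cyt_pg[i, j]),
                    )
                )
    records = _records_from_truth(truth_rows, design.replicates, design.n_experiments, noise, rng)
    truth = {
        "params": params.to_dict(),
        "variant": (variant.variant.value if isinstance(variant, VariantSpec) else ModelVariant(variant).value),
        "cytokine_scale": cytokine_scale,
        "seed": seed,
        "true_emax_pg_ml": true_emax,
        "true_ec50_ng_well": true_ec50,
    }
    return records, truth


def generate_transfer_dataset(
    params: ModelParameters,
    variant: VariantSpec | ModelVariant,
    pmhc_doses: Sequence[float] | None = None,
    phase1_conditions: Sequence[LigandCondition] = (
        LigandCondition("none", 0.0),
        LigandCondition("CD70", 200.0),
    ),
    phase2_conditions: Sequence[LigandCondition] = (
        LigandCondition("none", 0.0),
        LigandCondition("4-1BBL", 500.0),
    ),
    phase1_duration: float = 16.0,
    phase2_duration: float = 8.0,
    noise: NoiseModel | None = None,
    replicates: int = 2,
    n_experiments: int = 3,
    cytokine_scale: float = 1.0,
    seed: int = 0,
    cytokine: str = "IFNg",
) -> tuple[pd.DataFrame, dict]:
    """Two-phase plate-transfer dataset: phase-1 wells measured at transfer
    (16 h), phase-2 wells measured after a further 8 h at identical pMHC
    doses, for every phase-1 x phase-2 ligand arm combination.

    Phase-2 records carry ``phase=2`` and the *phase-2* ligand identity; the
    phase-1 arm is recorded in the ``pre_ligand``/``pre_ligand_ng_well``
    columns of the truth sidecar keys and in the ligand label of phase-1
    rows.  Secreted cytokine is washed out at transfer, so phase-2 readouts
    are de novo production of the carried-over cell states.
    """
    pmhc = np.asarray(pmhc_doses if pmhc_doses is not None else default_pmhc_grid(), dtype=float)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    truth_rows = []
    true_out = {}
    for c1 in phase1_conditions:
        for c2 in phase2_conditions:
            p_eff = c2.effective_params(c1.effective_params(params))
            for dose in pmhc:
                ph1 = c1.phase(float(dose), phase1_duration)
                ph2 = c2.phase(float(dose), phase2_duration)
                traj, cyt2 = simulate_two_phase(p_eff, variant, ph1, ph2)
                i16 = int(np.argmin(np.abs(traj.times - phase1_duration)))
                cyt1 = float(traj.states[i16, 2])
                key = f"{c1.ligand}{c1.dose:g}->{c2.ligand}{c2.dose:g}|{dose:g}"
                true_out[key] = {
                    "phase1_pg_ml": cyt1 * cytokine_scale,
                    "phase2_pg_ml": cyt2 * cytokine_scale,
                    "b41bb_at_transfer": float(traj.states[i16, 4]),
                }
                common = dict(cytokine=cytokine, pmhc_ng_well=float(dose))
                if c2 is phase2_conditions[0]:
                    # phase-1 wells are shared across phase-2 arms; emit once
                    truth_rows.append(
                        dict(
                            common,
                            ligand=f"{c1.ligand}->",
                            ligand_ng_well=c1.dose,
                            time_h=phase1_duration,
                            phase=1,
                            truth=cyt1 * cytokine_scale,
                        )
                    )
                truth_rows.append(
                    dict(
                        common,
                        ligand=f"{c1.ligand}->{c2.ligand}",
                        ligand_ng_well=c2.dose,
                        time_h=phase1_duration + phase2_duration,
                        phase=2,
                        truth=cyt2 * cytokine_scale,
                    )
                )
    records = _records_from_truth(truth_rows, replicates, n_experiments, noise, rng)
    truth = {
        "params": params.to_dict(),
        "variant": (variant.variant.value if isinstance(variant, VariantSpec) else ModelVariant(variant).value),
        "cytokine_scale": cytokine_scale,
        "seed": seed,
        "arms": true_out,
    }
    return records, truth


def save_dataset(records: pd.DataFrame, truth: dict, out_csv: str | Path) -> None:
    """Write the tidy records CSV and its truth sidecar JSON."""
    out_csv = Path(out_csv)
    records.to_csv(out_csv, index=False)
    out_csv.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))
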