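"""Model selection, synergy prediction and parameter calibration.

This module turns the qualitative observations of the cytokine screen and
the plate-transfer experiments into executable phenotype criteria, scores
every model variant against them, simulates the sequential CD27 -> 4-1BB
synergy prediction, and calibrates model parameters against (synthetic)
ELISA datasets.

Phenotype criteria
------------------
P1  adaptation: without co-stimulation cytokine output plateaus after ~8 h.
P2  CD27 front-loading: CD70 amplifies the early response but does not
    prolong it (amplification similar after 8 h, rate decreasing).
P3  4-1BB persistence: 4-1BBL amplification keeps growing beyond 8 h.
P4  rescue: CD70 added after 16 h of adaptation rescues cytokine output.
P5  pMHC dependence: without antigen there is no phase-2 response even with
    high 4-1BB expression and 4-1BBL present.
P6  CD70 pre-exposure penalty: CD70 during phase 1 downregulates CD27 and
    makes phase-2 CD70 co-stimulation less effective.
P7  TCR-surface direction: co-stimulation must not raise surface TCR above
    the no-co-stimulation trajectory (measurements show, if anything,
    enhanced TCR downregulation under ligand engagement).

Thresholds are configuration (:class:`PhenotypeConfig`) with documented
defaults; each criterion reports a numeric margin alongside its verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .dose_response import direct_response_metrics, extract_metrics, fit_bell
from .model_core import StimulusPhase
from .parameters import (
    CD70_ONLY_VARIANTS,
    ModelParameters,
    ModelVariant,
    VariantSpec,
    gitr_like,
)
from .simulation import (
    LigandCondition,
    default_pmhc_grid,
    simulate_screen,
    simulate_two_phase,
)

__all__ = [
    "PhenotypeConfig",
    "PhenotypeResult",
    "VariantScorecard",
    "evaluate_phenotypes",
    "rank_variants",
    "predict_synergy",
    "ModelCalibrator",
    "calibrate_parameters",
    "ALL_VARIANTS",
    "CRITERIA",
    "SCREEN_CRITERIA",
    "TRANSFER_CRITERIA",
]

ALL_VARIANTS: tuple[ModelVariant, ...] = tuple(ModelVariant)

CRITERIA = ("P1", "P2", "P3", "P4", "P5", "P6", "P7")
#: cytokine-screen criteria (used by the transfer-ablation analysis)
SCREEN_CRITERIA = ("P1", "P2", "P3")
#: plate-transfer criteria
TRANSFER_CRITERIA = ("P4", "P5", "P6")

_DESCRIPTIONS = {
    "P1": "adaptation: post-8 h production rate small without co-stimulation",
    "P2": "CD27 front-loading: early amplification, no prolongation",
    "P3": "4-1BB persistence: amplification continues beyond 8 h",
    "P4": "CD70 rescues adapted cells in a second stimulation phase",
    "P5": "no phase-2 response without pMHC despite 4-1BB + 4-1BBL",
    "P6": "phase-1 CD70 exposure blunts phase-2 CD70 co-stimulation",
    "P7": "co-stimulation does not raise surface TCR",
}


@dataclass(frozen=True)
class PhenotypeConfig:
    """Quantitative thresholds that operationalise the qualitative criteria.

    Defaults (chosen once, documented in the methods note):

    * ``p1_late_rate_ratio``: post-8 h rate must be < 10% of the 0-8 h mean
      rate (this is also the adaptation acceptance threshold).
    * ``p2_min_amplification``: CD70 must amplify 8 h output by >= 1.3x.
    * ``p2_max_late_gain``: CD70 amplification at 24 h must not exceed
      1.3x the amplification at 8 h (front-loaded, not prolonged).
    * ``p3_increment_ratio``: with 4-1BBL, (E24-E16) > 25% of (E8-E4).
    * ``p3_min_amplification``: 4-1BBL must amplify 24 h output by >= 1.5x.
    * ``p4_min_rescue``: phase-2 output with CD70 >= 2x without.
    * ``p5_max_no_antigen``: zero-pMHC phase-2 output <= 5% of the
      saturating-pMHC phase-2 output with 4-1BBL.
    * ``p6_max_penalised``: phase-2 CD70 output after phase-1 CD70 <= 80%
      of the same readout without phase-1 CD70.
    * ``p7_tcr_tolerance``: ligand arms may not exceed the no-costim TCR
      trajectory by more than 1% of the resting level.
    """

    p1_late_rate_ratio: float = 0.10
    p2_min_amplification: float = 1.3
    p2_max_late_gain: float = 1.3
    p3_increment_ratio: float = 0.25
    p3_min_amplification: float = 1.5
    p4_min_rescue: float = 2.0
    p5_max_no_antigen: float = 0.05
    p6_max_penalised: float = 0.80
    p7_tcr_tolerance: float = 0.01
    saturating_pmhc: float = 2000.0
    cd70_dose: float = 200.0
    l41bb_dose: float = 500.0
    times: tuple[float, ...] = (4.0, 8.0, 16.0, 24.0)


@dataclass
class PhenotypeResult:
    """Verdict and numeric margin for one criterion.

    ``margin`` is oriented so that larger is better and 0 is the pass/fail
    boundary.
    """

    id: str
    passed: bool
    margin: float
    description: str
    details: dict = field(default_factory=dict)


def _emax_series(
    params: ModelParameters,
    spec: VariantSpec,
    cond: LigandCondition,
    cfg: PhenotypeConfig,
    rtol: float,
    atol: float,
) -> np.ndarray:
    """Cytokine at the saturating pMHC dose for each time point (the
    phenotype criteria are statements about the top of the dose response)."""
    [surf] = simulate_screen(
        params, spec, [cfg.saturating_pmhc], [cond], times=cfg.times, rtol=rtol, atol=atol
    )
    return surf.cytokine[0]


def evaluate_phenotypes(
    params: ModelParameters,
    variant: VariantSpec | ModelVariant,
    config: PhenotypeConfig | None = None,
    criteria: Sequence[str] = CRITERIA,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> dict[str, PhenotypeResult]:
    """Evaluate the phenotype criteria for one variant/parameter set."""
    cfg = config or PhenotypeConfig()
    spec = variant if isinstance(variant, VariantSpec) else VariantSpec(variant=variant)
    t = np.asarray(cfg.times)
    results: dict[str, PhenotypeResult] = {}

    none_cond = LigandCondition("none", 0.0)
    cd70_cond = LigandCondition("CD70", cfg.cd70_dose)
    l41_cond = LigandCondition("4-1BBL", cfg.l41bb_dose)

    need_screen = bool(set(criteria) & {"P1", "P2", "P3", "P7"})
    if need_screen:
        e_none = _emax_series(params, spec, none_cond, cfg, rtol, atol)
        e_cd70 = _emax_series(params, spec, cd70_cond, cfg, rtol, atol)
        e_41bb = _emax_series(params, spec, l41_cond, cfg, rtol, atol)

    if "P1" in criteria:
        early_rate = e_none[1] / t[1]  # mean rate over 0-8 h (Emax(0)=0)
        late_rate = (e_none[3] - e_none[1]) / (t[3] - t[1])
        ratio = late_rate / early_rate if early_rate > 0 else np.inf
        results["P1"] = PhenotypeResult(
            "P1", ratio < cfg.p1_late_rate_ratio, cfg.p1_late_rate_ratio - ratio,
            _DESCRIPTIONS["P1"], {"late_over_early_rate": ratio},
        )

    if "P2" in criteria:
        amp8 = e_cd70[1] / e_none[1] if e_none[1] > 0 else np.inf
        amp24 = e_cd70[3] / e_none[3] if e_none[3] > 0 else np.inf
        late_gain = amp24 / amp8 if amp8 > 0 else np.inf
        rate_early = (e_cd70[1] - e_cd70[0]) / (t[1] - t[0])
        rate_late = (e_cd70[3] - e_cd70[2]) / (t[3] - t[2])
        ok = (
            amp8 >= cfg.p2_min_amplification
            and late_gain <= cfg.p2_max_late_gain
            and rate_late < rate_early
        )
        margin = min(
            amp8 - cfg.p2_min_amplification,
            cfg.p2_max_late_gain - late_gain,
            rate_early - rate_late,
        )
        results["P2"] = PhenotypeResult(
            "P2", bool(ok), float(margin), _DESCRIPTIONS["P2"],
            {"amplification_8h": amp8, "amplification_24h": amp24, "late_gain": late_gain},
        )

    if "P3" in criteria:
        increment_late = e_41bb[3] - e_41bb[2]
        increment_early = e_41bb[1] - e_41bb[0]
        inc_ok = increment_late > cfg.p3_increment_ratio * increment_early
        amp24 = e_41bb[3] / e_none[3] if e_none[3] > 0 else np.inf
        ok = inc_ok and amp24 >= cfg.p3_min_amplification
        margin = min(
            increment_late - cfg.p3_increment_ratio * increment_early,
            amp24 - cfg.p3_min_amplification,
        )
        results["P3"] = PhenotypeResult(
            "P3", bool(ok), float(margin), _DESCRIPTIONS["P3"],
            {"late_increment": increment_late, "early_increment": increment_early,
             "amplification_24h": amp24},
        )

    if "P4" in criteria:
        dose = cfg.saturating_pmhc
        ph1 = StimulusPhase(pMHC_dose=dose, duration=16.0)
        _, cyt_none = simulate_two_phase(
            params, spec, ph1, StimulusPhase(pMHC_dose=dose, duration=8.0), rtol=rtol, atol=atol
        )
        _, cyt_cd70 = simulate_two_phase(
            params, spec, ph1,
            StimulusPhase(pMHC_dose=dose, CD70_dose=cfg.cd70_dose, duration=8.0),
            rtol=rtol, atol=atol,
        )
        rescue = cyt_cd70 / cyt_none if cyt_none > 0 else np.inf
        results["P4"] = PhenotypeResult(
            "P4", rescue >= cfg.p4_min_rescue, float(rescue - cfg.p4_min_rescue),
            _DESCRIPTIONS["P4"], {"rescue_ratio": rescue},
        )

    if "P5" in criteria:
        # uniform phase-1 pMHC+CD70 induces 4-1BB; phase 2 probes antigen need
        ph1 = StimulusPhase(pMHC_dose=cfg.saturating_pmhc, CD70_dose=cfg.cd70_dose, duration=16.0)
        _, cyt_no_ag = simulate_two_phase(
            params, spec, ph1,
            StimulusPhase(pMHC_dose=0.0, L41BB_dose=cfg.l41bb_dose, duration=8.0),
            rtol=rtol, atol=atol,
        )
        _, cyt_sat = simulate_two_phase(
            params, spec, ph1,
            StimulusPhase(pMHC_dose=cfg.saturating_pmhc, L41BB_dose=cfg.l41bb_dose, duration=8.0),
            rtol=rtol, atol=atol,
        )
        frac = cyt_no_ag / cyt_sat if cyt_sat > 0 else (0.0 if cyt_no_ag == 0 else np.inf)
        results["P5"] = PhenotypeResult(
            "P5", frac <= cfg.p5_max_no_antigen, float(cfg.p5_max_no_antigen - frac),
            _DESCRIPTIONS["P5"], {"no_antigen_fraction": frac},
        )

    if "P6" in criteria:
        dose = cfg.saturating_pmhc
        ph2 = StimulusPhase(pMHC_dose=dose, CD70_dose=cfg.cd70_dose, duration=8.0)
        _, cyt_naive = simulate_two_phase(
            params, spec, StimulusPhase(pMHC_dose=dose, duration=16.0), ph2, rtol=rtol, atol=atol
        )
        _, cyt_pre = simulate_two_phase(
            params, spec,
            StimulusPhase(pMHC_dose=dose, CD70_dose=cfg.cd70_dose, duration=16.0), ph2,
            rtol=rtol, atol=atol,
        )
        ratio = cyt_pre / cyt_naive if cyt_naive > 0 else np.inf
        results["P6"] = PhenotypeResult(
            "P6", ratio <= cfg.p6_max_penalised, float(cfg.p6_max_penalised - ratio),
            _DESCRIPTIONS["P6"], {"penalised_ratio": ratio},
        )

    if "P7" in criteria:
        # surface TCR under ligand arms vs no-costim, saturating pMHC
        times = cfg.times
        excess = 0.0
        base_surf = simulate_screen(
            params, spec, [cfg.saturating_pmhc], [none_cond], times=times,
            keep_trajectories=True, rtol=rtol, atol=atol,
        )[0]
        tcr_none = base_surf.trajectories[0].component("TCR")
        tt = base_surf.trajectories[0].times
        for cond in (cd70_cond, l41_cond):
            surf = simulate_screen(
                params, spec, [cfg.saturating_pmhc], [cond], times=times,
                keep_trajectories=True, rtol=rtol, atol=atol,
            )[0]
            tcr = surf.trajectories[0].component("TCR")
            excess = max(excess, float(np.max(tcr - np.interp(surf.trajectories[0].times, tt, tcr_none))))
        results["P7"] = PhenotypeResult(
            "P7", excess <= cfg.p7_tcr_tolerance, float(cfg.p7_tcr_tolerance - excess),
            _DESCRIPTIONS["P7"], {"max_tcr_excess": excess},
        )

    return {k: results[k] for k in criteria if k in results}


# ---------------------------------------------------------------------------
# Variant ranking
# ---------------------------------------------------------------------------

#: best-effort co-stimulation strength grid for the per-variant refit
_K_GRID = (0.5, 1.0, 3.0, 8.0)


@dataclass
class VariantScorecard:
    """Boolean variant x criterion matrix with refit parameters and margins."""

    table: pd.DataFrame  # index: variant, columns: criteria, values: bool
    margins: pd.DataFrame
    refit_strengths: dict[str, tuple[float, float]]
    details: dict[str, dict[str, PhenotypeResult]]
    ec50_shift: dict[str, float] = field(default_factory=dict)

    @property
    def passing_variants(self) -> list[str]:
        return [v for v in self.table.index if bool(self.table.loc[v].all())]

    def to_markdown(self) -> str:
        lines = ["| variant | " + " | ".join(self.table.columns) + " | all |",
                 "|" + "---|" * (len(self.table.columns) + 2)]
        for v in self.table.index:
            row = self.table.loc[v]
            cells = " | ".join("pass" if bool(x) else "FAIL" for x in row)
            lines.append(f"| {v} | {cells} | {'PASS' if bool(row.all()) else '-'} |")
        return "\n".join(lines)


def _refit_strengths(
    params: ModelParameters,
    variant: ModelVariant,
    cfg: PhenotypeConfig,
    criteria: Sequence[str],
    rtol: float,
    atol: float,
) -> tuple[float, float]:
    """Best-effort per-variant calibration of the co-stimulation strengths:
    coarse grid search maximising criteria passed (margin sum as tie-break).

    The shared kinetic parameters stay fixed; only k10 (and k11 for variants
    with a 4-1BBL term) are refit, mirroring a per-variant best case.
    """
    if variant is ModelVariant.BASE:
        return params.k10, params.k11
    k11_grid: tuple[float, ...] = _K_GRID
    if variant in CD70_ONLY_VARIANTS:
        k11_grid = (params.k11,)  # unused by the equations; keep fixed
    best = None
    for k10 in _K_GRID:
        for k11 in k11_grid:
            p = params.replace(k10=k10, k11=k11)
            res = evaluate_phenotypes(p, variant, cfg, criteria, rtol=rtol, atol=atol)
            n_pass = sum(r.passed for r in res.values())
            margin_sum = float(np.sum([min(r.margin, 1.0) for r in res.values()]))
            key = (n_pass, margin_sum)
            if best is None or key > best[0]:
                best = (key, (k10, k11))
    return best[1]


def _ec50_from_surface(surf, time: float = 8.0) -> float | None:
    """EC50 of a simulated dose response via the bell-fit pipeline."""
    curve = surf.curve(time)
    try:
        fit = fit_bell(surf.pmhc_doses, curve)
    except ValueError:
        return None
    m = extract_metrics(fit, exclusion_threshold=0.0)
    return m.ec50


def rank_variants(
    params: ModelParameters,
    variants: Iterable[ModelVariant] = ALL_VARIANTS,
    config: PhenotypeConfig | None = None,
    criteria: Sequence[str] = CRITERIA,
    refit: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> VariantScorecard:
    """Score every variant against the phenotype criteria.

    Each variant gets a best-effort refit of its co-stimulation strengths
    (shared kinetics fixed) before scoring, so that a variant fails because
    of its structure, not because of an unflattering strength choice.  For
    the affinity-modulation variant (EXPLORE_KA) the scorecard additionally
    records the EC50 fold-shift its co-stimulation produces at 8 h, to
    document that it shifts sensitivity while failing the rate/duration
    criteria.
    """
    cfg = config or PhenotypeConfig()
    rows, margin_rows, details, strengths, ec50_shift = {}, {}, {}, {}, {}
    for variant in variants:
        name = variant.value
        k10, k11 = (
            _refit_strengths(params, variant, cfg, criteria, rtol, atol)
            if refit
            else (params.k10, params.k11)
        )
        p = params.replace(k10=k10, k11=k11)
        res = evaluate_phenotypes(p, variant, cfg, criteria, rtol=rtol, atol=atol)
        rows[name] = {c: res[c].passed for c in criteria}
        margin_rows[name] = {c: res[c].margin for c in criteria}
        details[name] = res
        strengths[name] = (k10, k11)
        if variant is ModelVariant.EXPLORE_KA:
            doses = default_pmhc_grid()
            none_s, cd70_s = simulate_screen(
                p, variant, doses,
                [LigandCondition("none", 0.0), LigandCondition("CD70", cfg.cd70_dose)],
                times=(8.0,), rtol=rtol, atol=atol,
            )
            e0, e1 = _ec50_from_surface(none_s, 8.0), _ec50_from_surface(cd70_s, 8.0)
            if e0 and e1:
                ec50_shift[name] = e1 / e0
    table = pd.DataFrame.from_dict(rows, orient="index")[list(criteria)]
    margins = pd.DataFrame.from_dict(margin_rows, orient="index")[list(criteria)]
    return VariantScorecard(
        table=table, margins=margins, refit_strengths=strengths,
        details=details, ec50_shift=ec50_shift,
    )


# ---------------------------------------------------------------------------
# Synergy prediction
# ---------------------------------------------------------------------------


def predict_synergy(
    params: ModelParameters,
    variant: VariantSpec | ModelVariant = ModelVariant.THRESHOLD_MOD,
    pmhc_doses: Sequence[float] | None = None,
    cd70_dose: float = 200.0,
    l41bb_dose: float = 500.0,
    inducible: str = "4-1BB",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Simulate the sequential CD27 -> 4-1BB two-phase synergy experiment.

    Phase 1 (16 h): pMHC dose range, with or without CD70.  Phase 2 (8 h):
    identical pMHC doses, with or without 4-1BBL.  Returns one row per pMHC
    dose with 4-1BB expression at transfer (with/without phase-1 CD70), the
    four phase-2 cytokine arms, and the synergy index

        [Cyt(CD70->4-1BBL) - Cyt(none->4-1BBL)]
          - [Cyt(CD70->none) - Cyt(none->none)]

    which is positive when early CD27 engagement improves later 4-1BB
    co-stimulation beyond its direct carry-over effect.  ``inducible="GITR"``
    runs the same protocol with the GITR-like receptor parameters.
    """
    doses = np.asarray(pmhc_doses if pmhc_doses is not None else default_pmhc_grid(), dtype=float)
    p = gitr_like(params) if inducible == "GITR" else params
    rows = []
    for dose in doses:
        row = {"pmhc_ng_well": float(dose)}
        cyt2 = {}
        for pre_cd70 in (0.0, cd70_dose):
            ph1 = StimulusPhase(pMHC_dose=float(dose), CD70_dose=pre_cd70, duration=16.0)
            for l41 in (0.0, l41bb_dose):
                ph2 = StimulusPhase(pMHC_dose=float(dose), L41BB_dose=l41, duration=8.0)
                traj, cyt = simulate_two_phase(p, variant, ph1, ph2, rtol=rtol, atol=atol)
                cyt2[(pre_cd70 > 0, l41 > 0)] = cyt
                if l41 == 0.0:
                    i16 = int(np.argmin(np.abs(traj.times - 16.0)))
                    key = "b41bb_16h_cd70" if pre_cd70 > 0 else "b41bb_16h_none"
                    row[key] = float(traj.states[i16, 4])
                    row["cyt_phase1_cd70" if pre_cd70 > 0 else "cyt_phase1_none"] = float(
                        traj.states[i16, 2]
                    )
        row.update(
            cyt2_none_none=cyt2[(False, False)],
            cyt2_none_41bbl=cyt2[(False, True)],
            cyt2_cd70_none=cyt2[(True, False)],
            cyt2_cd70_41bbl=cyt2[(True, True)],
        )
        row["synergy_index"] = (
            cyt2[(True, True)] - cyt2[(False, True)]
        ) - (cyt2[(True, False)] - cyt2[(False, False)])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    """Optimiser failed; carries the best parameters found so far."""

    def __init__(self, message: str, best_params: ModelParameters):
        super().__init__(message)
        self.best_params = best_params


class ModelCalibrator(BaseEstimator):
    """Least-squares calibration of model parameters to an ELISA dataset
    (scikit-learn estimator interface).

    The data are reduced once to per-(ligand arm, time) summary statistics —
    Emax and EC50 trajectories, the screen's own metrics — and the model is
    fit to those rather than to raw wells.  By default both sides use the
    same model-free extraction (:func:`direct_response_metrics`) on the
    replicate/experiment-averaged curves, so extraction bias cancels;
    ``use_bell_fit=True`` extracts the data-side Emax through the bell-fit
    pipeline instead.  Emax residuals are relative; EC50 residuals are
    log10 differences.  Free parameters are optimised in log space to
    enforce positivity.

    Parameters
    ----------
    free : names of the :class:`ModelParameters` fields to fit.
    variant : model variant used for the forward simulations.
    cytokine_scale : pg/ml per model cytokine unit.
    include_ec50 : add log-EC50 trajectories to the objective (EC50 carries
        the threshold/affinity information that Emax alone leaves flat).

    Attributes
    ----------
    params_ : fitted :class:`ModelParameters`.
    diagnostics_ : residuals, cost, convergence and identifiability warnings
        (flat objective directions from the Jacobian's singular spectrum).
    """

    def __init__(
        self,
        free: tuple[str, ...] = ("k1", "k2", "k3", "k4", "mu"),
        variant: ModelVariant = ModelVariant.THRESHOLD_MOD,
        cytokine_scale: float = 1.0,
        include_ec50: bool = True,
        use_bell_fit: bool = False,
        ec50_min_emax: float = 50.0,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        max_nfev: int = 200,
    ):
        self.free = free
        self.variant = variant
        self.cytokine_scale = cytokine_scale
        self.include_ec50 = include_ec50
        self.use_bell_fit = use_bell_fit
        self.ec50_min_emax = ec50_min_emax
        self.rtol = rtol
        self.atol = atol
        self.max_nfev = max_nfev

    # -- data reduction -------------------------------------------------
    def _reduce(self, records: pd.DataFrame) -> pd.DataFrame:
        """Per-(ligand, ligand dose, time) target Emax and log10-EC50,
        averaged across experiments (wells averaged per dose first)."""
        req = {
            "experiment", "pmhc_ng_well", "ligand", "ligand_ng_well",
            "time_h", "concentration_pg_ml",
        }
        missing = req - set(records.columns)
        if missing:
            raise ValueError(f"records table lacks columns: {sorted(missing)}")
        rows = []
        group_cols = ["experiment", "ligand", "ligand_ng_well", "time_h"]
        for (exp, ligand, ldose, t), sub in records.groupby(group_cols):
            curve = sub.groupby("pmhc_ng_well")["concentration_pg_ml"].mean()
            doses = curve.index.to_numpy(float)
            resp = curve.to_numpy(float)
            emax, ec50 = direct_response_metrics(doses, resp, self.ec50_min_emax)
            if self.use_bell_fit and np.count_nonzero(doses > 0) >= 5:
                try:
                    emax = extract_metrics(
                        fit_bell(doses, resp), exclusion_threshold=0.0
                    ).emax
                except ValueError:
                    pass
            rows.append(
                dict(
                    experiment=exp, ligand=ligand, ligand_ng_well=ldose, time_h=t,
                    emax=emax, log_ec50=(np.log10(ec50) if ec50 else np.nan),
                )
            )
        per_exp = pd.DataFrame(rows)
        return (
            per_exp.groupby(["ligand", "ligand_ng_well", "time_h"])[["emax", "log_ec50"]]
            .mean()
            .reset_index()
        )

    # -- forward model --------------------------------------------------
    def _predict(
        self, params: ModelParameters, targets: pd.DataFrame, pmhc_doses: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Model-side Emax and log10-EC50 per target row, extracted from the
        simulated curves with the same direct metric as the data side."""
        arms = targets[["ligand", "ligand_ng_well"]].drop_duplicates()
        times = np.sort(targets["time_h"].unique())
        conditions = [
            LigandCondition(str(r.ligand), float(r.ligand_ng_well)) for r in arms.itertuples()
        ]
        surfaces = simulate_screen(
            params, self.variant, pmhc_doses, conditions, times=times,
            rtol=self.rtol, atol=self.atol,
        )
        lookup = {}
        for surf in surfaces:
            for j, t in enumerate(surf.times):
                emax, ec50 = direct_response_metrics(
                    surf.pmhc_doses, surf.cytokine[:, j] * self.cytokine_scale,
                    self.ec50_min_emax,
                )
                lookup[(surf.condition.ligand, surf.condition.dose, float(t))] = (
                    emax, np.log10(ec50) if ec50 else np.nan
                )
        pred = [
            lookup[(r.ligand, float(r.ligand_ng_well), float(r.time_h))]
            for r in targets.itertuples()
        ]
        e = np.array([p[0] for p in pred])
        le = np.array([p[1] for p in pred])
        return e, le

    # -- sklearn API ----------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None, params0: ModelParameters | None = None):
        """Calibrate free parameters against a tidy MeasurementRecord table."""
        params0 = params0 or ModelParameters()
        targets = self._reduce(X)
        pmhc_doses = np.sort(X["pmhc_ng_well"].unique())
        obs_emax = targets["emax"].to_numpy(float)
        obs_lec50 = targets["log_ec50"].to_numpy(float)
        ec50_mask = self.include_ec50 & ~np.isnan(obs_lec50)
        w = 1.0 / np.maximum(obs_emax, 1.0)  # relative Emax weighting

        theta0 = np.log([getattr(params0, name) for name in self.free])

        def make_params(theta: np.ndarray) -> ModelParameters:
            return params0.replace(**{n: float(np.exp(v)) for n, v in zip(self.free, theta)})

        def residuals(theta: np.ndarray) -> np.ndarray:
            n_res = len(obs_emax) + int(np.sum(ec50_mask))
            try:
                pred_emax, pred_lec50 = self._predict(make_params(theta), targets, pmhc_doses)
            except Exception:
                return np.full(n_res, 1e3)
            res = (pred_emax - obs_emax) * w
            if np.any(ec50_mask):
                diff = pred_lec50[ec50_mask] - obs_lec50[ec50_mask]
                diff = np.where(np.isnan(diff), 3.0, diff)  # model lost its EC50: penalise
                res = np.concatenate([res, diff])
            return res

        sol = least_squares(
            residuals, theta0, method="trf",
            diff_step=1e-4, xtol=1e-12, ftol=1e-12, max_nfev=self.max_nfev,
        )
        fitted = make_params(sol.x)
        warnings_list = self._identifiability(sol)
        pred_emax, pred_lec50 = self._predict(fitted, targets, pmhc_doses)
        self.params_ = fitted
        self.diagnostics_ = {
            "cost": float(sol.cost),
            "residuals": sol.fun.tolist(),
            "nfev": int(sol.nfev),
            "success": bool(sol.success),
            "identifiability_warnings": warnings_list,
            "targets": targets.assign(predicted_emax=pred_emax, predicted_log_ec50=pred_lec50),
        }
        if not sol.success:
            raise CalibrationError(f"calibration did not converge: {sol.message}", fitted)
        return self

    def _identifiability(self, sol) -> list[str]:
        """Flag flat directions of the objective: singular values of the
        Jacobian (in log-parameter space) far below the largest indicate
        practically unidentifiable parameter combinations."""
        out = []
        J = np.atleast_2d(sol.jac)
        if J.shape[0] < len(self.free):
            out.append(
                f"fewer residuals ({J.shape[0]}) than free parameters ({len(self.free)})"
            )
        U, s, Vt = np.linalg.svd(J, full_matrices=False)
        if s[0] == 0:
            return out + ["degenerate Jacobian: all directions flat"]
        for i, sv in enumerate(s):
            if sv < 1e-3 * s[0]:
                weights = np.abs(Vt[i])
                dominant = [self.free[j] for j in np.argsort(weights)[::-1] if weights[j] > 0.4]
                if not dominant:
                    dominant = [self.free[int(np.argmax(weights))]]
                out.append(
                    f"flat objective direction (sv ratio {sv / s[0]:.1e}) dominated by {dominant}"
                )
        return out


def calibrate_parameters(
    records: pd.DataFrame,
    params0: ModelParameters | None = None,
    free: tuple[str, ...] = ("k1", "k2", "k3", "k4", "mu"),
    variant: ModelVariant = ModelVariant.THRESHOLD_MOD,
    cytokine_scale: float = 1.0,
    include_ec50: bool = True,
    use_bell_fit: bool = False,
    max_nfev: int = 200,
) -> tuple[ModelParameters, dict]:
    """Functional wrapper around :class:`ModelCalibrator`.

    Returns the fitted parameters and a diagnostics dict; on optimiser
    failure raises :class:`CalibrationError` carrying the best-so-far
    parameters.
    """
    cal = ModelCalibrator(
        free=free, variant=variant, cytokine_scale=cytokine_scale,
        include_ec50=include_ec50, use_bell_fit=use_bell_fit, max_nfev=max_nfev,
    )
    cal.fit(records, params0=params0)
    return cal.params_, cal.diagnostics_
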