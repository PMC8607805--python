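import numpy as np
import pytest

from costimod import (
    LigandCondition,
    ModelVariant,
    Protocol,
    StimulusPhase,
    VariantSpec,
    default_pmhc_grid,
    integrate,
    resting_state,
    simulate_screen,
    simulate_two_phase,
)
from costimod.model_core import rhs
from costimod.simulation import export_surfaces


def rk4_fixed_step(params, phase, spec, duration, dt=1e-3):
    """Independent brute-force integrator: classic fixed-step RK4."""
    y = resting_state().to_array()
    steps = int(round(duration / dt))
    for _ in range(steps):
        k1 = rhs(y, params, phase, spec)
        k2 = rhs(y + dt / 2 * k1, params, phase, spec)
        k3 = rhs(y + dt / 2 * k2, params, phase, spec)
        k4 = rhs(y + dt * k3, params, phase, spec)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


class TestIntegrate:
    def test_resting_cells_stay_resting(self, params, spec):
        traj = integrate(params, StimulusPhase(duration=24.0), spec)
        end = traj.states[-1]
        rest = resting_state().to_array()
        np.testing.assert_allclose(end[[0, 1, 3, 4]], rest[[0, 1, 3, 4]], atol=1e-5)
        # switch leak at C=0 is Phi(-mu/sigma) ~ 3e-7; the accumulated
        # cytokine over 24 h stays far below the ELISA detection floor
        assert end[2] < 0.01

    def test_agrees_with_fixed_step_oracle(self, params, spec):
        phase = StimulusPhase(pMHC_dose=2000.0, CD70_dose=200.0, L41BB_dose=500.0, duration=24.0)
        y_oracle = rk4_fixed_step(params, phase, spec, 24.0)
        traj = integrate(params, phase, spec, t_eval=[24.0])
        rel = np.abs(traj.states[-1] - y_oracle) / np.maximum(np.abs(y_oracle), 1e-8)
        assert rel.max() < 1e-4

    def test_self_convergence_under_tolerance_refinement(self, params, spec):
        phase = StimulusPhase(pMHC_dose=600.0, CD70_dose=200.0, duration=24.0)
        times = [4.0, 8.0, 16.0, 24.0]
        coarse = integrate(params, phase, spec, t_eval=times, rtol=1e-6, atol=1e-9)
        fine = integrate(params, phase, spec, t_eval=times, rtol=1e-7, atol=1e-10)
        rel = np.abs(coarse.states - fine.states) / np.maximum(np.abs(fine.states), 1e-6)
        assert rel.max() < 10 * 1e-6

    def test_time_grid_independence(self, params, spec):
        phase = StimulusPhase(pMHC_dose=2000.0, duration=24.0)
        sparse = integrate(params, phase, spec, t_eval=[4.0, 8.0, 16.0, 24.0])
        dense = integrate(params, phase, spec, t_eval=np.linspace(0, 24, 481))
        for t in (4.0, 8.0, 16.0, 24.0):
            a = sparse.state_at(t).to_array()
            b = dense.state_at(t).to_array()
            np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-7)

    def test_deterministic_bit_identical(self, params, spec):
        phase = StimulusPhase(pMHC_dose=100.0, CD70_dose=50.0, duration=24.0)
        t1 = integrate(params, phase, spec)
        t2 = integrate(params, phase, spec)
        assert np.array_equal(t1.states, t2.states) and np.array_equal(t1.times, t2.times)

    def test_state_invariants_along_trajectory(self, params, spec):
        phase = StimulusPhase(pMHC_dose=2000.0, CD70_dose=200.0, L41BB_dose=500.0, duration=24.0)
        traj = integrate(params, phase, spec)
        assert (traj.states >= -1e-9).all()
        assert traj.component("TCR").max() <= 1.0 + 1e-9
        # Signal bounded by production ceiling / decay rate
        assert traj.component("Signal").max() <= 1.0 / params.k3 + 1e-6
        # cumulative cytokine non-decreasing within the phase
        assert (np.diff(traj.component("Cytokine")) >= -1e-9).all()

    def test_invalid_tolerances_rejected(self, params, spec):
        with pytest.raises(ValueError):
            integrate(params, StimulusPhase(duration=1.0), spec, rtol=0.0)


class TestScreen:
    def test_zero_ligand_dose_matches_no_costim_arm(self, params, spec):
        doses = [0.0, 74.0, 667.0, 2000.0]
        surfs = simulate_screen(
            params, spec, doses,
            [LigandCondition("none", 0.0), LigandCondition("CD70", 0.0),
             LigandCondition("4-1BBL", 0.0)],
        )
        np.testing.assert_allclose(surfs[1].cytokine, surfs[0].cytokine, rtol=1e-9)
        np.testing.assert_allclose(surfs[2].cytokine, surfs[0].cytokine, rtol=1e-9)

    def test_cytokine_monotone_in_time_at_every_dose(self, params, spec):
        surfs = simulate_screen(
            params, spec, default_pmhc_grid(),
            [LigandCondition("none", 0.0), LigandCondition("4-1BBL", 500.0)],
        )
        for s in surfs:
            assert (np.diff(s.cytokine, axis=1) >= -1e-9).all()

    def test_cd70_amplifies_early_response_pointwise(self, params, spec):
        doses = default_pmhc_grid()
        none_s, cd70_s = simulate_screen(
            params, spec, doses,
            [LigandCondition("none", 0.0), LigandCondition("CD70", 200.0)],
            times=(4.0, 8.0),
        )
        # pointwise dominance up to integration-tolerance noise
        assert (cd70_s.cytokine >= none_s.cytokine * (1 - 1e-4) - 1e-6).all()

    def test_41bb_sustains_late_production_at_saturating_doses(self, params, spec):
        doses = [667.0, 2000.0]
        none_s, bb_s = simulate_screen(
            params, spec, doses,
            [LigandCondition("none", 0.0), LigandCondition("4-1BBL", 500.0)],
            times=(16.0, 24.0),
        )
        inc_none = none_s.cytokine[:, 1] - none_s.cytokine[:, 0]
        inc_bb = bb_s.cytokine[:, 1] - bb_s.cytokine[:, 0]
        assert (inc_bb > inc_none).all()

    def test_empty_grids_rejected(self, params, spec):
        with pytest.raises(ValueError):
            simulate_screen(params, spec, [], [LigandCondition("none", 0.0)])
        with pytest.raises(ValueError):
            simulate_screen(params, spec, [0.0, 10.0], [])

    def test_tidy_export_with_provenance(self, params, spec, tmp_path):
        surfs = simulate_screen(
            params, spec, [0.0, 100.0], [LigandCondition("CD70", 200.0)], times=(4.0, 8.0)
        )
        out = tmp_path / "screen.csv"
        export_surfaces(surfs, out, params, spec)
        import json

        import pandas as pd

        df = pd.read_csv(out)
        assert set(df.columns) == {
            "time_h", "pmhc_ng_well", "ligand", "ligand_ng_well", "variable", "value"
        }
        assert len(df) == 4
        sidecar = json.loads(out.with_suffix(".provenance.json").read_text())
        assert sidecar["params"]["KA"] == params.KA
        assert sidecar["variant"] == spec.variant.value


class TestTwoPhase:
    def test_cytokine_washed_out_other_states_continuous(self, params, spec):
        ph1 = StimulusPhase(pMHC_dose=2000.0, duration=16.0)
        ph2 = StimulusPhase(pMHC_dose=2000.0, CD70_dose=200.0, duration=8.0)
        eps = 1e-6
        traj = integrate(
            params, Protocol(phases=(ph1, ph2)), spec,
            t_eval=[16.0 - eps, 16.0 + eps],
        )
        before = traj.state_at(16.0 - eps).to_array()
        after = traj.state_at(16.0 + eps).to_array()
        # cytokine reset at transfer
        assert before[2] > 100.0
        assert after[2] < 1e-3
        # TCR, Signal, CD27, 4-1BB carried continuously
        for i in (0, 1, 3, 4):
            assert after[i] == pytest.approx(before[i], rel=1e-4, abs=1e-5)

    def test_adaptation_persists_through_transfer(self, params, spec):
        """Identical phases without ligands: the phase-2 response is a small
        fraction of the phase-1 response at the same dose."""
        ph = StimulusPhase(pMHC_dose=2000.0, duration=16.0)
        traj, cyt2 = simulate_two_phase(params, spec, ph, StimulusPhase(pMHC_dose=2000.0, duration=8.0))
        cyt1 = traj.state_at(16.0).Cytokine
        assert cyt2 < 0.05 * cyt1

    def test_no_antigen_no_phase2_response_despite_41bb(self, params, spec):
        ph1 = StimulusPhase(pMHC_dose=2000.0, CD70_dose=200.0, duration=16.0)
        traj, cyt2_no_ag = simulate_two_phase(
            params, spec, ph1, StimulusPhase(pMHC_dose=0.0, L41BB_dose=500.0, duration=8.0)
        )
        _, cyt2_sat = simulate_two_phase(
            params, spec, ph1,
            StimulusPhase(pMHC_dose=2000.0, L41BB_dose=500.0, duration=8.0),
        )
        assert traj.state_at(16.0).B41BB > 0.5  # 4-1BB was induced
        # without antigen the response collapses (residual carried-over
        # Signal decays away; no new production despite 4-1BB + 4-1BBL)
        assert cyt2_no_ag < 0.02 * cyt2_sat

    def test_phase1_cd70_raises_41bb_at_transfer(self, params, spec):
        for dose in (74.0, 667.0, 2000.0):
            t_no, _ = simulate_two_phase(
                params, spec,
                StimulusPhase(pMHC_dose=dose, duration=16.0),
                StimulusPhase(pMHC_dose=dose, duration=8.0),
            )
            t_cd, _ = simulate_two_phase(
                params, spec,
                StimulusPhase(pMHC_dose=dose, CD70_dose=200.0, duration=16.0),
                StimulusPhase(pMHC_dose=dose, duration=8.0),
            )
            assert t_cd.state_at(16.0).B41BB > t_no.state_at(16.0).B41BB

    def test_protocol_length_validated(self):
        with pytest.raises(ValueError):
            Protocol(phases=())
        with pytest.raises(ValueError):
            Protocol(phases=(StimulusPhase(duration=1.0),) * 3)
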