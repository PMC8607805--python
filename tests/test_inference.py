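import numpy as np
import pytest

from costimod import (
    LigandCondition,
    ModelParameters,
    ModelVariant,
    NoiseModel,
    ScreenDesign,
    generate_screen,
    predict_synergy,
)
from costimod.inference import (
    SCREEN_CRITERIA,
    CalibrationError,
    ModelCalibrator,
    calibrate_parameters,
    evaluate_phenotypes,
    rank_variants,
)

ACTIVATING_DOSES = [74.0, 667.0, 2000.0]


class TestPhenotypes:
    def test_base_model_adapts_but_shows_no_costim_phenotypes(self, params):
        res = evaluate_phenotypes(params, ModelVariant.BASE)
        assert res["P1"].passed  # adaptation is TCR-downregulation driven
        assert not res["P2"].passed  # no CD27 amplification arm exists
        assert not res["P3"].passed  # no 4-1BB persistence

    def test_alt4_literal_reading_abolishes_adaptation(self, params):
        """With decay gated on ligand (k3*S*k10*f), the control arm never
        stops producing cytokine, so adaptation fails structurally."""
        res = evaluate_phenotypes(params, ModelVariant.ALT4_LITERAL, criteria=("P1",))
        assert not res["P1"].passed

    def test_accepted_model_passes_every_criterion(self, params):
        res = evaluate_phenotypes(params, ModelVariant.THRESHOLD_MOD)
        failed = [k for k, r in res.items() if not r.passed]
        assert failed == []
        assert all(r.margin > 0 for r in res.values())

    def test_margins_reported_with_verdicts(self, params):
        res = evaluate_phenotypes(params, ModelVariant.BASE, criteria=("P1", "P2"))
        assert res["P1"].details["late_over_early_rate"] < 0.1
        assert np.isfinite(res["P2"].margin)


class TestScorecard:
    def test_scorecard_is_complete(self, scorecard):
        assert not scorecard.table.isna().any().any()
        assert len(scorecard.table) == len(ModelVariant)

    def test_threshold_mod_is_unique_passing_variant(self, scorecard):
        assert scorecard.passing_variants == ["THRESHOLD_MOD"]

    def test_affinity_modulation_shifts_ec50_but_fails_rate_criteria(self, scorecard):
        row = scorecard.table.loc["EXPLORE_KA"]
        assert not row["P2"] and not row["P3"]
        assert scorecard.ec50_shift["EXPLORE_KA"] < 0.8  # sensitivity does shift

    def test_tcr_modulation_fails_only_on_surface_tcr_direction(self, scorecard):
        row = scorecard.table.loc["EXPLORE_TCR"]
        assert row[["P1", "P2", "P3", "P4", "P5", "P6"]].all()
        assert not row["P7"]

    def test_screen_only_criteria_cannot_single_out_the_model(self, params):
        """Dropping the plate-transfer criteria leaves more than one variant
        standing: the transfer experiments carry the discriminative power."""
        card = rank_variants(params, criteria=SCREEN_CRITERIA)
        passing = card.passing_variants
        assert "THRESHOLD_MOD" in passing
        assert len(passing) >= 2

    def test_scorecard_reproducible(self, params, scorecard):
        again = rank_variants(
            params, variants=[ModelVariant.BASE, ModelVariant.THRESHOLD_MOD]
        )
        assert again.table.equals(scorecard.table.loc[["BASE", "THRESHOLD_MOD"]])


@pytest.fixture(scope="module")
def synergy(params):
    return predict_synergy(params, pmhc_doses=[0.0] + ACTIVATING_DOSES)


class TestSynergy:

    def test_phase1_cd70_raises_41bb_and_synergy_index(self, synergy):
        act = synergy[synergy.pmhc_ng_well > 0]
        assert (act.b41bb_16h_cd70 > act.b41bb_16h_none).all()
        assert (act.synergy_index > 0).all()

    def test_no_antigen_all_arms_collapse(self, synergy):
        row = synergy[synergy.pmhc_ng_well == 0].iloc[0]
        scale = synergy.cyt2_cd70_41bbl.max()
        arms = [row.cyt2_none_none, row.cyt2_none_41bbl, row.cyt2_cd70_none, row.cyt2_cd70_41bbl]
        assert max(arms) < 0.01 * scale
        assert abs(row.synergy_index) < 0.01 * scale

    def test_synergy_requires_cd27_signalling_not_just_expression(self, params):
        """With k10 = 0 the CD27->Signal->4-1BB feedback route is severed and
        the synergy index collapses, even though CD27 expression dynamics are
        untouched: the effect is signal-mediated."""
        on = predict_synergy(params, pmhc_doses=[667.0]).synergy_index.iloc[0]
        off = predict_synergy(params.replace(k10=0.0), pmhc_doses=[667.0]).synergy_index.iloc[0]
        assert off < 0.05 * on

    def test_gitr_like_receptor_preserves_synergy(self, params):
        table = predict_synergy(params, pmhc_doses=ACTIVATING_DOSES, inducible="GITR")
        assert (table.synergy_index > 0).all()

    def test_synergy_monotone_in_phase1_cd70_dose(self, params):
        """Non-decreasing in the CD70 dose; at saturating occupancy the
        switch ceiling makes it flat, so equality within solver noise is
        allowed."""
        indices = [
            predict_synergy(params, pmhc_doses=[667.0], cd70_dose=d).synergy_index.iloc[0]
            for d in (5.0, 50.0, 800.0)
        ]
        tol = 1e-3 * max(abs(i) for i in indices)
        assert indices[0] <= indices[1] + tol
        assert indices[1] <= indices[2] + tol

    def test_synergy_nonnegative_over_strength_grid(self, params):
        """Receptor-scaled threshold modulation gives non-negative synergy
        for any co-stimulation strengths >= 0 (up to solver noise when both
        arms saturate the switch ceiling)."""
        for k10 in (0.0, 2.0, 8.0):
            for k11 in (0.0, 2.0, 8.0):
                p = params.replace(k10=k10, k11=k11)
                table = predict_synergy(p, pmhc_doses=[24.7, 667.0])
                tol = 1e-6 * max(1.0, float(table.cyt2_cd70_41bbl.max()))
                assert (table.synergy_index > -tol).all()


class TestCalibration:
    DESIGN = ScreenDesign(
        ligand_conditions=[
            LigandCondition("none", 0.0),
            LigandCondition("CD70", 200.0),
            LigandCondition("4-1BBL", 500.0),
        ],
        replicates=2,
        n_experiments=2,
    )
    NOISELESS = NoiseModel(cv=0.0, scale_sd=0.0, floor_pg_ml=0.0)

    def test_noiseless_recovery_of_free_parameters(self, params):
        records, _ = generate_screen(
            params, ModelVariant.THRESHOLD_MOD, self.DESIGN, self.NOISELESS, seed=0
        )
        free = ("k2", "k4", "mu")
        p0 = params.replace(**{k: getattr(params, k) * 1.4 for k in free})
        fitted, diag = calibrate_parameters(records, params0=p0, free=free)
        for k in free:
            assert getattr(fitted, k) == pytest.approx(getattr(params, k), rel=0.01)
        assert diag["success"]

    def test_single_early_timepoint_flags_decay_as_unidentifiable(self, params):
        design = ScreenDesign(
            ligand_conditions=self.DESIGN.ligand_conditions,
            times=(4.0,),
            replicates=2,
            n_experiments=2,
        )
        records, _ = generate_screen(
            params, ModelVariant.THRESHOLD_MOD, design, self.NOISELESS, seed=0
        )
        cal = ModelCalibrator(free=("k1", "k2", "k3", "k4", "mu"))
        p0 = params.replace(k3=params.k3 * 1.2, k4=params.k4 * 1.2)
        try:
            cal.fit(records, params0=p0)
        except CalibrationError:
            pass  # crawling along the flat direction may exhaust the budget
        warnings = " ".join(cal.diagnostics_["identifiability_warnings"])
        assert "k3" in warnings

    def test_nonconvergence_raises_with_best_parameters(self, params):
        records, _ = generate_screen(
            params, ModelVariant.THRESHOLD_MOD, self.DESIGN, self.NOISELESS, seed=0
        )
        cal = ModelCalibrator(free=("k2", "k4", "mu"), max_nfev=2)
        p0 = params.replace(k2=params.k2 * 2.0)
        with pytest.raises(CalibrationError) as err:
            cal.fit(records, params0=p0)
        assert err.value.best_params.k2 > 0

    def test_estimator_exposes_sklearn_params(self):
        cal = ModelCalibrator()
        got = cal.get_params()
        assert got["free"] == ("k1", "k2", "k3", "k4", "mu")
        cal.set_params(max_nfev=50)
        assert cal.max_nfev == 50
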