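"""Covariate search and treatment-similarity machinery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecupop.covariates import (
    CovariateCandidate, eta_by_group, lrt, stepwise, treatment_effect_test,
)
from ecupop.dataset_io import StudyDataset
from ecupop.foce import EstimationOptions, FoceProblem
from ecupop.modelspec import pk_base_spec, pk_final_spec
from ecupop.simulate import (
    default_truth, inject_treatment_effect, phase1_design, simulate_pooled,
    simulate_study,
)


class TestLrt:
    @pytest.mark.parametrize("dofv,df,expected", [
        (3.841, 1, 0.05), (6.635, 1, 0.01), (0.0, 1, 1.0), (5.991, 2, 0.05),
    ])
    def test_chi_square_quantiles(self, dofv, df, expected):
        assert lrt(100.0 + dofv, 100.0, df) == pytest.approx(expected, abs=5e-4)

    def test_monotone_in_dofv(self):
        ps = [lrt(100.0 + d, 100.0, 1) for d in np.linspace(0, 20, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_within_slack_is_one(self):
        assert lrt(99.9, 100.0, 1) == 1.0

    def test_strongly_negative_raises(self):
        with pytest.raises(ValueError, match="higher OFV"):
            lrt(90.0, 100.0, 1)

    def test_df_below_one_raises(self):
        with pytest.raises(ValueError):
            lrt(105.0, 100.0, 0)


class TestStepwise:
    def test_empty_candidate_list_returns_base(self, truth, fast_options):
        ds = simulate_study(phase1_design(12), truth, seed=55)
        trace = stepwise(ds, pk_base_spec(), [], options=fast_options)
        assert len(trace.steps) == 0
        assert trace.final_spec.covariate_terms == pk_base_spec().covariate_terms

    def test_recovers_weight_effect_on_clearance(self, truth, fast_options):
        """Weight drives CL (exponent 1.14) in the generative truth; the
        pooled design (wide 43-111 kg weight range) identifies it, and the
        age decoy is rejected."""
        ds = simulate_pooled(truth, seed=56, n_phase1=36, n_phase3=12)
        cands = [CovariateCandidate("cl", "WT", "power", ref=80.9),
                 CovariateCandidate("cl", "AGE", "power")]
        trace = stepwise(ds, pk_base_spec(), cands, options=fast_options)
        kept = {t.name for t in trace.final_spec.covariate_terms}
        assert "cl:WT" in kept
        assert "cl:AGE" not in kept

    def test_null_truth_selects_nothing_beyond_nominal(self, truth, fast_options):
        flat = dataclasses.replace(
            truth, pk=dataclasses.replace(truth.pk, exp_cl_wt=0.0, exp_vc_wt=0.0))
        ds = simulate_pooled(flat, seed=57, n_phase1=36, n_phase3=12)
        cands = [CovariateCandidate("cl", "WT", "power", ref=80.9),
                 CovariateCandidate("cl", "AGE", "power")]
        trace = stepwise(ds, pk_base_spec(), cands, options=fast_options)
        extra = {t.name for t in trace.final_spec.covariate_terms} \
            - {t.name for t in pk_base_spec().covariate_terms}
        # backward elimination at p<0.01 should prune chance inclusions
        assert len(extra) <= 1

    def test_forward_steps_respect_alpha(self, truth, fast_options):
        ds = simulate_pooled(truth, seed=58, n_phase1=24, n_phase3=10)
        cands = [CovariateCandidate("cl", "WT", "power", ref=80.9)]
        trace = stepwise(ds, pk_base_spec(), cands, options=fast_options)
        included = trace.steps[trace.steps["decision"] == "included"]
        assert (included["p"] < 0.05).all()


class TestTreatmentEffectTest:
    def test_single_arm_errors(self, truth, fast_options):
        ds = simulate_study(phase1_design(9), truth, seed=60)
        one_arm = StudyDataset(
            ds.df[ds.df["TRT"] == "SB12"].reset_index(drop=True), ds.lloq_pk)
        with pytest.raises(ValueError, match="absent"):
            treatment_effect_test(one_arm, pk_final_spec(), "cl",
                                  options=fast_options)

    def test_unknown_grouping_errors(self, truth, fast_options):
        ds = simulate_study(phase1_design(9), truth, seed=60)
        with pytest.raises(ValueError, match="grouping"):
            treatment_effect_test(ds, pk_final_spec(), "cl", grouping="bogus")

    def test_null_data_not_significant(self, truth, fast_options):
        ds = simulate_study(phase1_design(36), truth, seed=61)
        res = treatment_effect_test(ds, pk_final_spec(), "cl",
                                    grouping="SB12-vs-ECU", options=fast_options)
        assert res.df == 1
        assert res.p >= 0.05
        assert res.decision == "no treatment effect"

    def test_injected_effect_detected(self, truth, fast_options):
        shifted = inject_treatment_effect(truth, "cl", 1.3)
        ds = simulate_study(phase1_design(36), shifted, seed=62)
        res = treatment_effect_test(ds, pk_final_spec(), "cl",
                                    grouping="SB12-vs-ECU", options=fast_options)
        assert res.p < 0.05
        assert res.decision == "treatment effect"
        # the recovered arm ratio should sit near the injected 1.3 fold
        ratio = res.extended_fit.theta["cl"] / res.extended_fit.theta["cl:TRTGROUP=ECU"]
        assert ratio == pytest.approx(1.3, rel=0.15)

    def test_three_level_grouping_has_two_df(self, truth, fast_options):
        ds = simulate_study(phase1_design(24), truth, seed=63)
        res = treatment_effect_test(ds, pk_final_spec(), "cl",
                                    grouping="3-level", options=fast_options)
        assert res.df == 2
        assert 0.0 <= res.p <= 1.0


class TestEtaByGroup:
    def _truth_fit(self, ds, truth):
        spec = pk_final_spec().with_inits(theta={
            "cl": truth.pk.cl, "vc": truth.pk.vc_healthy,
            "vc:POP=PNH": truth.pk.vc_patient, "vp": truth.pk.vp,
            "q": truth.pk.q, "cl:WT": truth.pk.exp_cl_wt,
            "vc:WT": truth.pk.exp_vc_wt})
        prob = FoceProblem(ds, spec, EstimationOptions(compute_se=False))
        return prob.evaluate(omega=truth.omega_pk, sigma=truth.sigma_pk)

    def test_null_medians_near_zero(self, truth):
        ds = simulate_study(phase1_design(120), truth, seed=64)
        fit = self._truth_fit(ds, truth)
        summ = eta_by_group(fit, ds, "TRT")
        med = summ[summ["eta"] == "eta_cl"]["median"]
        assert (med.abs() < 0.05).all()

    def test_single_subject_group_equals_its_eta(self, truth, phase1_small):
        fit = self._truth_fit(phase1_small, truth)
        df = phase1_small.df.copy()
        df["SOLO"] = np.where(df["ID"] == df["ID"].iloc[0], "one", "rest")
        ds = StudyDataset(df, phase1_small.lloq_pk)
        summ = eta_by_group(fit, ds, "SOLO")
        solo = summ[(summ["group"] == "one") & (summ["eta"] == "eta_cl")].iloc[0]
        eta_val = fit.ebes.set_index("ID").loc[df["ID"].iloc[0], "eta_cl"]
        assert solo["n"] == 1
        assert solo["median"] == pytest.approx(eta_val)
        assert solo["min"] == solo["max"] == pytest.approx(eta_val)

    def test_unknown_column_errors(self, truth, phase1_small):
        fit = self._truth_fit(phase1_small, truth)
        with pytest.raises(ValueError, match="grouping column"):
            eta_by_group(fit, phase1_small, "NOPE")
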