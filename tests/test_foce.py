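"""Estimation-engine tests: conditional likelihood against hand formulas,
the Laplace/FOCE objective against numerical quadrature, EBE behaviour,
CWRES calibration and parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from ecupop.dataset_io import DVID_PD, DVID_PK, StudyDataset
from ecupop.foce import (
    EstimationOptions, FoceProblem, conditional_neg2ll, ebe_estimate,
    foce_objective, ipp_link,
)
from ecupop.modelspec import ModelSpec, pk_final_spec
from ecupop.structural import OmegaBlock, SigmaModel
from ecupop.simulate import default_truth, phase1_design, simulate_study

LOG2PI = np.log(2 * np.pi)


def toy_pd_dataset(conc, tca, subject=1):
    """A PD-stage dataset: TCA observations with a fixed linked concentration."""
    n = len(conc)
    df = pd.DataFrame({
        "ID": [subject] * n, "TIME": np.arange(1.0, n + 1.0), "EVID": 0,
        "DV": tca, "DVID": DVID_PD, "WT": 80.9, "POP": "healthy",
        "CIPP": conc})
    return StudyDataset(df)


def toy_pd_spec(eta_names=("e0",), e0=85.9, ic50=36.6, hill=4.56, imax=0.93,
                omega_sd=0.15, sigma=0.186):
    return ModelSpec(
        stage="pd",
        theta_init={"e0": e0, "imax": imax, "ic50": ic50, "hill": hill},
        eta_names=tuple(eta_names),
        omega_sd_init={n: omega_sd for n in eta_names},
        sigma=SigmaModel("proportional", prop=sigma))


def tca_formula(c, e0, imax, ic50, hill):
    return e0 * (1 - imax * c ** hill / (ic50 ** hill + c ** hill))


class TestConditionalNeg2LL:
    def test_matches_hand_formula(self):
        """g(eta) for two TCA observations, written out longhand."""
        conc = np.array([10.0, 50.0])
        y = np.array([80.0, 20.0])
        spec = toy_pd_spec()
        ds = toy_pd_dataset(conc, y)
        eta = 0.12
        omega_sd, sig = 0.15, 0.186
        f = tca_formula(conc, 85.9 * np.exp(eta), 0.93, 36.6, 4.56)
        v = (sig * f) ** 2
        expected = (np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
                    + np.log(2 * np.pi * omega_sd ** 2)
                    + eta ** 2 / omega_sd ** 2)
        got = conditional_neg2ll(ds, spec, {1: [eta]})
        assert got.loc[1] == pytest.approx(expected, rel=1e-10)

    def test_zero_residual_leaves_log_variance_term(self):
        """y == prediction: the data term reduces to log(2 pi sigma^2 f^2)."""
        conc = np.array([30.0])
        spec = toy_pd_spec()
        f = tca_formula(conc, 85.9, 0.93, 36.6, 4.56)
        ds = toy_pd_dataset(conc, f)
        got = conditional_neg2ll(ds, spec, {1: [0.0]})
        expected = (np.log(2 * np.pi * (0.186 * f[0]) ** 2)
                    + np.log(2 * np.pi * 0.15 ** 2))
        assert got.loc[1] == pytest.approx(expected, rel=1e-10)

    def test_flat_prior_limit(self):
        """As omega -> inf, the prior contributes only its normalizing term."""
        conc = np.array([10.0, 50.0])
        y = np.array([80.0, 20.0])
        ds = toy_pd_dataset(conc, y)
        big = 1e4
        spec = toy_pd_spec(omega_sd=big)
        got = conditional_neg2ll(ds, spec, {1: [0.5]})
        f = tca_formula(conc, 85.9 * np.exp(0.5), 0.93, 36.6, 4.56)
        v = (0.186 * f) ** 2
        data = np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
        # quadratic prior contribution 0.5^2/omega^2 vanishes
        assert got.loc[1] - data - np.log(2 * np.pi * big ** 2) \
            == pytest.approx(0.0, abs=1e-6)

    def test_missing_observations_contribute_nothing(self):
        conc = np.array([10.0, 50.0])
        y = np.array([80.0, 20.0])
        ds = toy_pd_dataset(conc, y)
        df2 = ds.df.copy()
        extra = df2.iloc[[1]].copy()
        extra["TIME"] = 99.0
        extra["MDV"] = 1
        ds2 = StudyDataset(pd.concat([df2, extra], ignore_index=True))
        spec = toy_pd_spec()
        a = conditional_neg2ll(ds, spec, {1: [0.1]})
        b = conditional_neg2ll(ds2, spec, {1: [0.1]})
        assert a.loc[1] == pytest.approx(b.loc[1], rel=1e-12)

    def test_one_compartment_pk_special_case(self):
        """PK stage with Q ~ 0 against a hand-coded one-compartment solution."""
        cl, vc, dose, dur = 0.02, 4.0, 300.0, 0.583
        times = np.array([12.0, 96.0])
        ke = cl / vc
        r = dose / dur
        conc_hand = (r / (ke * vc) * (1 - np.exp(-ke * dur))
                     * np.exp(-ke * (times - dur)))
        y = np.array([70.0, 55.0])
        df = pd.DataFrame({
            "ID": 1, "TIME": np.concatenate([[0.0], times]),
            "EVID": [1, 0, 0], "AMT": [dose, 0, 0], "RATE": [dose / dur, 0, 0],
            "DV": [np.nan, *y], "DVID": [0, DVID_PK, DVID_PK],
            "WT": 80.9, "POP": "healthy"})
        ds = StudyDataset(df)
        spec = ModelSpec(
            stage="pk",
            theta_init={"cl": cl, "vc": vc, "vp": 1.0, "q": 1e-10},
            eta_names=("cl",), omega_sd_init={"cl": 0.2},
            sigma=SigmaModel("proportional", prop=0.1))
        got = conditional_neg2ll(ds, spec, {1: [0.0]})
        v = (0.1 * conc_hand) ** 2
        expected = (np.sum(np.log(2 * np.pi * v) + (y - conc_hand) ** 2 / v)
                    + np.log(2 * np.pi * 0.2 ** 2))
        assert got.loc[1] == pytest.approx(expected, rel=1e-5)


class TestFoceObjectiveOracle:
    def _quadrature_ofv(self, ds, spec, omega_sd):
        prob = FoceProblem(ds, spec)

        def integrand(eta):
            g = prob.conditional_neg2ll({1: [eta]}).loc[1]
            return np.exp(-0.5 * g)

        val, _ = integrate.quad(integrand, -10 * omega_sd, 10 * omega_sd,
                                limit=200, epsabs=1e-12, epsrel=1e-10)
        return -2.0 * np.log(val)

    @pytest.mark.parametrize("y", [
        [80.0, 45.0, 9.0],
        [95.0, 60.0, 12.0],
        [70.0, 30.0, 5.0],
    ])
    def test_single_eta_matches_quadrature(self, y):
        conc = np.array([5.0, 30.0, 80.0])
        ds = toy_pd_dataset(conc, np.array(y))
        spec = toy_pd_spec(omega_sd=0.2)
        exact = self._quadrature_ofv(ds, spec, 0.2)
        approx = foce_objective(ds, spec)
        assert abs(approx - exact) < 0.5

    def test_two_eta_matches_quadrature(self):
        conc = np.array([5.0, 20.0, 40.0, 80.0])
        y = np.array([88.0, 55.0, 22.0, 8.0])
        ds = toy_pd_dataset(conc, y)
        spec = toy_pd_spec(eta_names=("e0", "ic50"), omega_sd=0.2)
        prob = FoceProblem(ds, spec)

        def integrand(e1, e2):
            g = prob.conditional_neg2ll({1: [e1, e2]}).loc[1]
            return np.exp(-0.5 * g)

        val, _ = integrate.dblquad(integrand, -2.0, 2.0, -2.0, 2.0,
                                   epsabs=1e-10, epsrel=1e-8)
        exact = -2.0 * np.log(val)
        approx = foce_objective(ds, spec)
        assert abs(approx - exact) < 0.5

    def test_additivity_over_subjects(self):
        conc = np.array([5.0, 30.0, 80.0])
        y = np.array([80.0, 45.0, 9.0])
        ds1 = toy_pd_dataset(conc, y)
        df2 = ds1.df.copy()
        df2["ID"] = 2
        ds_both = StudyDataset(pd.concat([ds1.df, df2], ignore_index=True))
        spec = toy_pd_spec(omega_sd=0.2)
        assert foce_objective(ds_both, spec) \
            == pytest.approx(2 * foce_objective(ds1, spec), rel=1e-12)

    def test_omega_to_zero_limit_is_fixed_effects_neg2ll(self):
        conc = np.array([5.0, 30.0, 80.0])
        y = np.array([80.0, 45.0, 9.0])
        ds = toy_pd_dataset(conc, y)
        spec_small = toy_pd_spec(omega_sd=1e-7)
        f = tca_formula(conc, 85.9, 0.93, 36.6, 4.56)
        v = (0.186 * f) ** 2
        fixed = np.sum(np.log(2 * np.pi * v) + (y - f) ** 2 / v)
        assert foce_objective(ds, spec_small) == pytest.approx(fixed, abs=1e-4)


class TestEbeEstimate:
    def test_uninformative_subject_shrinks_to_zero(self):
        conc = np.array([10.0])
        ds = toy_pd_dataset(conc, np.array([80.0]))
        df = ds.df.copy()
        df.loc[:, "MDV"] = 1          # nothing informative left
        ds2 = StudyDataset(df)
        ebes = ebe_estimate(ds2, toy_pd_spec())
        assert ebes["eta_e0"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_eta_when_noise_vanishes(self, truth):
        tiny = dataclasses.replace(
            truth, sigma_pk=SigmaModel("proportional", prop=1e-6),
            sigma_pd=SigmaModel("proportional", prop=1e-6),
            sigma_ldh=SigmaModel("proportional", prop=1e-6))
        ds = simulate_study(phase1_design(6), tiny, seed=31)
        tp = ds.metadata["true_individual_parameters"]
        spec = pk_final_spec().with_inits(theta={
            "cl": truth.pk.cl, "vc": truth.pk.vc_healthy,
            "vc:POP=PNH": truth.pk.vc_patient, "vp": truth.pk.vp,
            "q": truth.pk.q, "cl:WT": truth.pk.exp_cl_wt,
            "vc:WT": truth.pk.exp_vc_wt})
        ebes = ebe_estimate(ds, spec, sigma=SigmaModel("proportional", prop=1e-6),
                            omega=truth.omega_pk).set_index("ID")
        typical_cl = truth.pk.cl * (tp["WT"] / 80.9) ** truth.pk.exp_cl_wt
        eta_true = np.log(tp["cl"].to_numpy() / typical_cl.to_numpy())
        eta_hat = ebes.loc[tp["ID"], "eta_cl"].to_numpy()
        assert np.max(np.abs(eta_hat - eta_true)) < 1e-3

    def test_duplicated_rows_same_mode_tighter_curvature(self):
        conc = np.array([5.0, 30.0, 80.0])
        y = np.array([80.0, 45.0, 9.0])
        ds1 = toy_pd_dataset(conc, y)
        dup = ds1.df.copy()
        dup["TIME"] = dup["TIME"] + 100.0
        ds2 = StudyDataset(pd.concat([ds1.df, dup], ignore_index=True))
        spec = toy_pd_spec(omega_sd=0.3)
        prob1, prob2 = FoceProblem(ds1, spec), FoceProblem(ds2, spec)
        r1 = prob1._solve_inner(*prob1._params(None, None, None))[0]
        r2 = prob2._solve_inner(*prob2._params(None, None, None))[0]
        _, eta1, _, J1, f1 = r1
        _, eta2, _, J2, f2 = r2
        assert eta2[0, 0] == pytest.approx(eta1[0, 0], abs=5e-3)
        # the Fisher data curvature sum(J^2/v) doubles with duplicated rows
        curv1 = float(np.sum(J1[0, :, 0] ** 2 / (0.186 * f1[0]) ** 2))
        curv2 = float(np.sum(J2[0, :, 0] ** 2 / (0.186 * f2[0]) ** 2))
        assert curv2 == pytest.approx(2 * curv1, rel=0.05)


class TestFitRecovery:
    def test_near_noise_free_theta_recovery(self, truth, fast_options):
        """With near-vanishing residual noise and IIV the fixed effects come
        back to a small fraction of a percent."""
        tiny = dataclasses.replace(
            truth,
            omega_pk=OmegaBlock.from_sd_corr(("cl", "vc", "vp"), [1e-3] * 3),
            sigma_pk=SigmaModel("proportional", prop=0.002))
        ds = simulate_study(phase1_design(12), tiny, seed=17)
        # variance initial values on the scale of the generative setting;
        # far-off variance inits leave the likelihood ridge-shaped
        spec = pk_final_spec().with_inits(
            omega_sd={"cl": 0.02, "vc": 0.02, "vp": 0.02},
            sigma=SigmaModel("proportional", prop=0.01))
        fit = FoceProblem(ds, spec, fast_options).fit()
        assert fit.theta["cl"] == pytest.approx(truth.pk.cl, rel=2e-3)
        assert fit.theta["vc"] == pytest.approx(truth.pk.vc_healthy, rel=2e-3)
        assert fit.theta["vp"] == pytest.approx(truth.pk.vp, rel=1e-2)
        assert fit.theta["q"] == pytest.approx(truth.pk.q, rel=1e-2)

    def test_refit_from_perturbed_inits_reaches_same_ofv(self, truth):
        # deep-convergence settings: the check is about the optimum being
        # re-found, so give the polish stage a generous budget
        opts = EstimationOptions(compute_se=False, outer_restarts=3,
                                 polish_maxfev=800)
        ds = simulate_study(phase1_design(16), truth, seed=23)
        spec = pk_final_spec()
        fit1 = FoceProblem(ds, spec, opts).fit()
        pert = {k: v * 1.2 for k, v in fit1.theta.items()}
        pert.update({k: v * 0.8 for k, v in list(pert.items())[::2]})
        spec2 = spec.with_inits(theta=pert)
        fit2 = FoceProblem(ds, spec2, opts).fit()
        assert fit2.ofv == pytest.approx(fit1.ofv, abs=0.1)


class TestCwres:
    def _evaluated_fit(self, truth, n=120, seed=77, sigma_scale=1.0,
                       omega=None):
        ds = simulate_study(phase1_design(n), truth, seed=seed)
        spec = pk_final_spec().with_inits(theta={
            "cl": truth.pk.cl, "vc": truth.pk.vc_healthy,
            "vc:POP=PNH": truth.pk.vc_patient, "vp": truth.pk.vp,
            "q": truth.pk.q, "cl:WT": truth.pk.exp_cl_wt,
            "vc:WT": truth.pk.exp_vc_wt})
        prob = FoceProblem(ds, spec, EstimationOptions(compute_se=False))
        return prob.evaluate(
            omega=omega if omega is not None else truth.omega_pk,
            sigma=SigmaModel("proportional",
                             prop=truth.sigma_pk.prop * sigma_scale))

    def test_mean_zero_variance_one_under_true_model(self, truth):
        fit = self._evaluated_fit(truth, n=240)
        cw = fit.obs_table["CWRES"].dropna().to_numpy()
        assert len(cw) > 2500
        assert abs(cw.mean()) < 0.05
        assert abs(cw.var() - 1.0) < 0.1

    def test_variance_scales_inversely_with_inflated_sigma(self, truth):
        small = OmegaBlock.from_sd_corr(("cl", "vc", "vp"), [1e-4] * 3)
        fit1 = self._evaluated_fit(truth, n=60, omega=small)
        fit2 = self._evaluated_fit(truth, n=60, omega=small, sigma_scale=2.0)
        v1 = fit1.obs_table["CWRES"].var()
        v2 = fit2.obs_table["CWRES"].var()
        assert v2 / v1 == pytest.approx(0.25, rel=0.05)

    def test_observation_at_linearized_mean_gives_zero(self):
        # with a vanishing eta prior the mode stays at zero, the linearized
        # mean equals the typical prediction, and an exact observation has
        # zero conditional weighted residual
        conc = np.array([30.0])
        spec = toy_pd_spec(omega_sd=1e-7)
        f = tca_formula(conc, 85.9, 0.93, 36.6, 4.56)
        ds = toy_pd_dataset(conc, f)
        prob = FoceProblem(ds, spec)
        fit = prob.evaluate()
        assert fit.obs_table["CWRES"].iloc[0] == pytest.approx(0.0, abs=1e-4)


class TestIppLink:
    def test_noise_free_link_equals_typical_prediction(self, truth):
        tiny_om = OmegaBlock.from_sd_corr(("cl", "vc", "vp"), [1e-6] * 3)
        tiny = dataclasses.replace(
            truth, omega_pk=tiny_om,
            sigma_pk=SigmaModel("proportional", prop=1e-6),
            sigma_pd=SigmaModel("proportional", prop=1e-6))
        ds = simulate_study(phase1_design(5), tiny, seed=41)
        spec = pk_final_spec().with_inits(theta={
            "cl": truth.pk.cl, "vc": truth.pk.vc_healthy,
            "vc:POP=PNH": truth.pk.vc_patient, "vp": truth.pk.vp,
            "q": truth.pk.q, "cl:WT": truth.pk.exp_cl_wt,
            "vc:WT": truth.pk.exp_vc_wt})
        prob = FoceProblem(ds, spec, EstimationOptions(compute_se=False))
        fit = prob.evaluate(omega=tiny_om,
                            sigma=SigmaModel("proportional", prop=1e-6))
        linked = ipp_link(fit, ds)
        pd_rows = linked.df[(linked.df["EVID"] == 0)
                            & (linked.df["DVID"] == DVID_PD)]
        from ecupop.structural import resolve_individual, two_compartment_conc
        for sid, sub in pd_rows.groupby("ID"):
            ind = resolve_individual(truth.pk, sub["WT"].iloc[0], "healthy")
            pred = two_compartment_conc(sub["TIME"].to_numpy(),
                                        [(0.0, 300.0, 0.583)],
                                        ind.cl, ind.vc, ind.vp, ind.q)
            np.testing.assert_allclose(sub["CIPP"].to_numpy(), pred, rtol=1e-4)

    def test_row_order_invariance(self, truth, phase1_small):
        spec = pk_final_spec()
        prob = FoceProblem(phase1_small, spec, EstimationOptions(compute_se=False))
        fit = prob.evaluate(omega=truth.omega_pk, sigma=truth.sigma_pk)
        linked1 = ipp_link(fit, phase1_small)
        shuffled = StudyDataset(
            phase1_small.df.sample(frac=1.0, random_state=5).reset_index(drop=True),
            phase1_small.lloq_pk)
        linked2 = ipp_link(fit, shuffled)
        key = ["ID", "TIME", "DVID"]
        a = linked1.df[linked1.df["EVID"] == 0].sort_values(key)["CIPP"].to_numpy()
        b = linked2.df[linked2.df["EVID"] == 0].sort_values(key)["CIPP"].to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_missing_upstream_ebe_raises(self, truth, phase1_small):
        subset = StudyDataset(
            phase1_small.df[phase1_small.df["ID"] <= 9].reset_index(drop=True),
            phase1_small.lloq_pk)
        prob = FoceProblem(subset, pk_final_spec(), EstimationOptions(compute_se=False))
        fit = prob.evaluate(omega=truth.omega_pk, sigma=truth.sigma_pk)
        with pytest.raises(ValueError, match="missing upstream"):
            ipp_link(fit, phase1_small)
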