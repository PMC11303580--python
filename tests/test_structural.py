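"""Structural-model tests: closed-form kinetics vs an ODE oracle, covariate
resolution, and the sigmoid Emax response functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from ecupop.structural import (
    EffThetas, IndividualParameters, OmegaBlock, PDThetas, PKThetas,
    SigmaModel, ldh_response, pk_concentration, residual_variance,
    resolve_individual, tca_response, two_compartment_conc,
)

PHASE1_TIMES = np.array([0.58, 4, 8, 12, 24, 48, 96, 168, 240, 336, 504,
                         672, 840, 1008, 1176, 1344, 1512], dtype=float)


class _OracleSolution:
    def __init__(self, y):
        self.y = y


def ode_oracle(times, doses, cl, vc, vp, q, rtol=1e-11):
    """Independent numerical solution of the two-compartment infusion model.

    Integrates piecewise over constant-infusion-rate segments.  State:
    (central amount, peripheral amount, cumulative eliminated).
    """
    k10, k12, k21 = cl / vc, q / vc, q / vp
    times = np.asarray(times, dtype=float)
    t_end = float(times.max())
    boundaries = sorted({0.0, t_end}
                        | {s for s, _, _ in doses if s <= t_end}
                        | {s + d for s, _, d in doses if s + d <= t_end})

    def rate_in(t):
        return sum(a / d for s, a, d in doses if s <= t < s + d)

    def rhs(t, y):
        a_c, a_p, _ = y
        return [rate_in(t) - (k10 + k12) * a_c + k21 * a_p,
                k12 * a_c - k21 * a_p,
                k10 * a_c]

    y0 = np.zeros(3)
    out = {}
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        inside = np.sort(times[(times > lo) & (times <= hi)])
        t_eval = np.unique(np.concatenate([inside, [hi]]))
        sol = solve_ivp(rhs, (lo, hi), y0, t_eval=t_eval, rtol=rtol,
                        atol=1e-12, method="LSODA")
        for t, col in zip(sol.t, sol.y.T):
            out[round(float(t), 9)] = col
        y0 = sol.y[:, -1]
    for t in times[times <= 0.0]:
        out[round(float(t), 9)] = np.zeros(3)
    y = np.column_stack([out[round(float(t), 9)] for t in times])
    conc = y[0] / vc
    return conc, _OracleSolution(y)


class TestResolveIndividual:
    def test_typical_values_at_reference_weight(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy",
                                 pd=truth.pd, eff=truth.eff)
        assert ind.cl == pytest.approx(0.0174)
        assert ind.vc == pytest.approx(3.47)
        assert ind.e0 == pytest.approx(85.9)
        assert ind.imax == pytest.approx(0.93)

    def test_patient_central_volume(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "PNH", pd=truth.pd)
        assert ind.vc == pytest.approx(5.68)
        assert ind.e0 == pytest.approx(101.0)
        assert ind.imax == pytest.approx(0.88)

    def test_weight_power_scaling(self, truth):
        ind = resolve_individual(truth.pk, 63.0, "healthy")
        assert ind.cl == pytest.approx(0.0174 * (63.0 / 80.9) ** 1.14)
        assert ind.vc == pytest.approx(3.47 * (63.0 / 80.9) ** 0.863)

    def test_eta_applied_exponentially(self, truth):
        eta = np.array([0.2, -0.1, 0.05])
        base = resolve_individual(truth.pk, 75.0, "healthy")
        ind = resolve_individual(truth.pk, 75.0, "healthy", eta)
        assert ind.cl == pytest.approx(base.cl * np.exp(0.2))
        assert ind.vc == pytest.approx(base.vc * np.exp(-0.1))
        assert ind.vp == pytest.approx(base.vp * np.exp(0.05))

    def test_invalid_inputs(self, truth):
        with pytest.raises(ValueError):
            resolve_individual(truth.pk, -1.0, "healthy")
        with pytest.raises(ValueError):
            resolve_individual(truth.pk, 70.0, "martian")
        with pytest.raises(ValueError):
            resolve_individual(truth.pk, 70.0, "healthy", np.zeros(2))


class TestTwoCompartmentKinetics:
    def test_zero_before_first_dose(self, typical_pk):
        doses = [(24.0, 300.0, 0.583)]
        conc = two_compartment_conc(np.array([0.0, 10.0, 23.9]), doses,
                                    **typical_pk)
        assert np.all(conc == 0.0)

    def test_matches_ode_oracle_single_infusion(self, typical_pk):
        doses = [(0.0, 300.0, 0.583)]
        closed = two_compartment_conc(PHASE1_TIMES, doses, **typical_pk)
        oracle, _ = ode_oracle(PHASE1_TIMES, doses, **typical_pk)
        assert np.max(np.abs(closed - oracle) / oracle) < 1e-6

    def test_matches_ode_oracle_multiple_dose(self, typical_pk):
        doses = [(w * 168.0, 600.0, 0.583) for w in range(4)]
        times = np.array([1.0, 24, 167.99, 200, 336, 500, 672.0])
        closed = two_compartment_conc(times, doses, **typical_pk)
        oracle, _ = ode_oracle(times, doses, **typical_pk)
        assert np.max(np.abs(closed - oracle) / oracle) < 1e-6

    def test_superposition_identity(self, typical_pk):
        t = np.linspace(0.1, 800, 57)
        both = two_compartment_conc(t, [(0.0, 300.0, 0.583),
                                        (168.0, 300.0, 0.583)], **typical_pk)
        first = two_compartment_conc(t, [(0.0, 300.0, 0.583)], **typical_pk)
        second = two_compartment_conc(t, [(168.0, 300.0, 0.583)], **typical_pk)
        np.testing.assert_allclose(both, first + second, rtol=1e-12)

    def test_mass_balance_in_ode_oracle(self, typical_pk):
        doses = [(0.0, 300.0, 0.583)]
        times = np.array([0.583, 24.0, 336.0, 1512.0])
        _, sol = ode_oracle(times, doses, **typical_pk)
        total = sol.y.sum(axis=0)
        np.testing.assert_allclose(total, 300.0, rtol=1e-8)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.005, 0.2), st.floats(1.0, 10.0), st.floats(0.3, 5.0),
           st.floats(0.005, 0.2))
    def test_closed_form_vs_ode_random_parameters(self, cl, vc, vp, q):
        doses = [(0.0, 300.0, 0.583)]
        closed = two_compartment_conc(PHASE1_TIMES, doses, cl, vc, vp, q)
        oracle, _ = ode_oracle(PHASE1_TIMES, doses, cl, vc, vp, q)
        # relative agreement down to the oracle's absolute accuracy floor
        assert np.all(np.abs(closed - oracle) <= 1e-6 * oracle + 1e-9)

    def test_rejects_invalid_inputs(self, typical_pk):
        with pytest.raises(ValueError):
            two_compartment_conc(np.array([-5.0]), [(0, 300, 0.583)], **typical_pk)
        with pytest.raises(ValueError):
            two_compartment_conc(np.array([1.0]), [(0, 300, 0.0)], **typical_pk)

    def test_individual_parameters_wrapper(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy")
        direct = two_compartment_conc(PHASE1_TIMES, [(0, 300, 0.583)],
                                      ind.cl, ind.vc, ind.vp, ind.q)
        wrapped = pk_concentration(PHASE1_TIMES, [(0, 300, 0.583)], ind)
        np.testing.assert_array_equal(direct, wrapped)


class TestResponseModels:
    def test_tca_null_drug_returns_baseline(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy", pd=truth.pd)
        assert tca_response(0.0, ind) == pytest.approx(85.9)

    def test_tca_at_ic50_is_half_maximal(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy", pd=truth.pd)
        assert tca_response(36.6, ind) == pytest.approx(85.9 * (1 - 0.93 / 2))

    def test_tca_saturates_at_full_inhibition(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy", pd=truth.pd)
        # E0*(1-Imax) = 85.9 * 0.07 = 6.013 at saturating concentration
        assert tca_response(1e9, ind) == pytest.approx(6.013, abs=1e-3)

    def test_tca_strictly_decreasing(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy", pd=truth.pd)
        conc = np.linspace(0.0, 400.0, 300)
        tca = tca_response(conc, ind)
        assert np.all(np.diff(tca) < 0)

    def test_ldh_floor_at_zero_activity(self, truth):
        ind = resolve_individual(truth.pk, 63.0, "PNH", pd=truth.pd, eff=truth.eff)
        assert ldh_response(0.0, ind) == pytest.approx(206.0)

    def test_ldh_half_maximal_at_lc50(self, truth):
        ind = resolve_individual(truth.pk, 63.0, "PNH", pd=truth.pd, eff=truth.eff)
        # LL0 + LMAX/2 = 206 + 840 = 1046
        assert ldh_response(39.0, ind) == pytest.approx(1046.0)

    def test_ldh_asymptote(self, truth):
        ind = resolve_individual(truth.pk, 63.0, "PNH", pd=truth.pd, eff=truth.eff)
        assert ldh_response(1e9, ind) == pytest.approx(206.0 + 1680.0, abs=1e-3)

    def test_ldh_strictly_increasing(self, truth):
        ind = resolve_individual(truth.pk, 63.0, "PNH", pd=truth.pd, eff=truth.eff)
        tca = np.linspace(0.0, 150.0, 200)
        ldh = ldh_response(tca, ind)
        assert np.all(np.diff(ldh) > 0)

    def test_negative_inputs_rejected(self, truth):
        ind = resolve_individual(truth.pk, 80.9, "healthy", pd=truth.pd,
                                 eff=truth.eff)
        with pytest.raises(ValueError):
            tca_response(-1.0, ind)
        with pytest.raises(ValueError):
            ldh_response(-1.0, ind)


class TestResidualVariance:
    @pytest.mark.parametrize("pred,sigma,expected", [
        (100.0, SigmaModel("proportional", prop=0.117), (0.117 * 100) ** 2),
        (0.0, SigmaModel("proportional", prop=0.117), 0.0),
        (57.0, SigmaModel("combined", prop=0.0, add=1.0), 1.0),
        (10.0, SigmaModel("combined", prop=0.1, add=2.0), 1.0 + 4.0),
    ])
    def test_variance_models(self, pred, sigma, expected):
        assert residual_variance(pred, sigma) == pytest.approx(expected)

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            residual_variance(-1.0, SigmaModel("proportional", prop=0.1))


class TestOmegaBlock:
    def test_iiv_percent_convention(self):
        om = OmegaBlock.from_sd_corr(("cl", "vc"), (0.1562, 0.1274),
                                     {("cl", "vc"): 0.54})
        np.testing.assert_allclose(om.iiv_percent, [15.62, 12.74])
        assert om.correlation("cl", "vc") == pytest.approx(0.54)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            OmegaBlock.from_sd_corr(("a", "b"), (0.1, 0.1), {("a", "b"): 1.5})
        with pytest.raises(ValueError):
            OmegaBlock(("a",), np.array([[-1.0]]))
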