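import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcekit as dk
from dcekit.exceptions import DomainError, FitError


def quadrature_oracle(ktrans, dv, cp, eval_times, dt=0.1):
    """Brute-force convolution on a fine grid, independent of the closed form."""
    kep = ktrans / (60.0 * dv)
    out = []
    for t in np.asarray(eval_times, dtype=float):
        if t <= 0:
            out.append(0.0)
            continue
        grid = np.append(np.arange(0.0, t, dt), t)
        cpg = np.interp(grid, cp.times, cp.values)
        out.append((ktrans / 6000.0) * np.trapezoid(cpg * np.exp(-kep * (t - grid)), grid))
    return np.array(out)


class TestToftsForward:
    def test_zero_influx(self, plasma_aif, schedule):
        ct = dk.tofts_forward(dk.KineticParams(0.0, 30.0), plasma_aif, schedule.frame_times)
        np.testing.assert_allclose(ct.values, 0.0)

    def test_equilibrium_with_constant_input(self):
        t = np.arange(0.0, 20000.0, 20.0)
        cp = dk.ConcentrationCurve("cp", t, np.full_like(t, 2.0), "arterial_plasma")
        ct = dk.tofts_forward(dk.KineticParams(10.0, 30.0), cp, t[-1:])
        assert ct.values[-1] == pytest.approx(0.3 * 2.0, rel=1e-6)

    def test_exponential_input_analytic_solution(self):
        t = np.arange(-30.0, 601.0, 0.5)
        cp_vals = np.where(t >= 0, np.exp(-0.01 * np.maximum(t, 0.0)), 0.0)
        cp = dk.ConcentrationCurve("cp", t, cp_vals, "arterial_plasma")
        eval_t = np.array([60.0, 300.0, 600.0])
        ct = dk.tofts_forward(dk.KineticParams(10.0, 30.0), cp, eval_t)
        kt_s, kep, a = 10 / 6000.0, 10 / (60 * 30.0), 0.01
        analytic = kt_s * (np.exp(-a * eval_t) - np.exp(-kep * eval_t)) / (kep - a)
        np.testing.assert_allclose(ct.values, analytic, rtol=1e-4)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(ktrans=st.floats(min_value=1.0, max_value=60.0),
           dv=st.floats(min_value=5.0, max_value=60.0))
    def test_matches_numerical_quadrature(self, plasma_aif, schedule, ktrans, dv):
        eval_t = schedule.frame_times[5::7]
        ct = dk.tofts_forward(dk.KineticParams(ktrans, dv), plasma_aif, eval_t)
        oracle = quadrature_oracle(ktrans, dv, plasma_aif, eval_t)
        assert np.max(np.abs(ct.values - oracle)) < 1e-4 * max(np.max(np.abs(oracle)), 1e-12)

    def test_monotone_in_ktrans_at_first_post_bolus_sample(self, plasma_aif, schedule):
        t_first = schedule.frame_times[5:6]  # first arterial-phase frame
        vals = [dk.tofts_forward(dk.KineticParams(k, 30.0), plasma_aif, t_first).values[0]
                for k in (1.0, 5.0, 20.0, 80.0)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            dk.KineticParams(-1.0, 30.0)
        with pytest.raises(DomainError):
            dk.KineticParams(10.0, 0.0)


class TestFitTofts:
    def test_noiseless_recovery(self, plasma_aif, schedule):
        truth = dk.KineticParams(10.0, 30.0)
        ct = dk.tofts_forward(truth, plasma_aif, schedule.frame_times)
        fit = dk.fit_tofts(ct, plasma_aif)
        assert fit.converged
        assert fit.params.ktrans == pytest.approx(10.0, rel=1e-2)
        assert fit.params.dv == pytest.approx(30.0, rel=1e-2)

    def test_zero_curve_gives_zero_ktrans(self, plasma_aif, schedule):
        ct = dk.ConcentrationCurve("t", schedule.frame_times,
                                   np.zeros(schedule.n_frames), "tissue")
        fit = dk.fit_tofts(ct, plasma_aif)
        assert fit.params.ktrans == 0.0 and fit.converged and fit.rss == 0.0

    def test_noisy_median_recovery(self, plasma_aif, schedule):
        rng = np.random.default_rng(42)
        truth = dk.KineticParams(20.0, 25.0)
        clean = dk.tofts_forward(truth, plasma_aif, schedule.frame_times)
        sd = clean.values.max() / 20.0
        est = []
        for _ in range(10):
            noisy = dk.ConcentrationCurve("t", clean.times,
                                          clean.values + rng.normal(0, sd, clean.values.shape),
                                          "tissue")
            fit = dk.fit_tofts(noisy, plasma_aif)
            est.append((fit.params.ktrans, fit.params.dv))
        med = np.median(est, axis=0)
        assert abs(med[0] / 20.0 - 1) < 0.10
        assert abs(med[1] / 25.0 - 1) < 0.10

    def test_too_few_post_injection_samples(self, plasma_aif):
        ct = dk.ConcentrationCurve("t", np.array([-5.0, 10.0, 20.0, 30.0]),
                                   np.array([0.0, 0.1, 0.2, 0.2]), "tissue")
        with pytest.raises(FitError):
            dk.fit_tofts(ct, plasma_aif)

    def test_fitted_curve_shares_times(self, plasma_aif, schedule):
        truth = dk.KineticParams(15.0, 40.0)
        ct = dk.tofts_forward(truth, plasma_aif, schedule.frame_times)
        fit = dk.fit_tofts(ct, plasma_aif)
        np.testing.assert_allclose(fit.fitted_curve.times, ct.times)
        assert fit.rss >= 0 and fit.n_points == len(ct)


@pytest.fixture(scope="module")
def dense_pair():
    t = np.arange(0.0, 300.0, 1.0)
    cp_v = np.where(t > 10, ((t - 10) / 8.0) ** 2 * np.exp(2 * (1 - (t - 10) / 8.0)), 0.0)
    pf_true = 50.0 / 6000.0  # 50 ml/100 ml/min as fraction/s
    ct_v = pf_true * np.convolve(cp_v, np.exp(-t / 40.0))[: len(t)]
    cp = dk.ConcentrationCurve("cp", t, cp_v, "arterial_plasma")
    ct = dk.ConcentrationCurve("ct", t, ct_v, "tissue")
    return ct, cp


class TestPlasmaFlowDeconvolution:
    def test_recovers_constructed_plasma_flow(self, dense_pair):
        ct, cp = dense_pair
        res = dk.plasma_flow_deconvolution(ct, cp, reg=0.01)
        assert res.pf == pytest.approx(50.0, rel=0.10)

    def test_zero_tissue_curve(self, dense_pair):
        _, cp = dense_pair
        ct0 = dk.ConcentrationCurve("ct", cp.times, np.zeros_like(cp.values), "tissue")
        assert dk.plasma_flow_deconvolution(ct0, cp, reg=0.01).pf == 0.0

    def test_scale_equivariance(self, dense_pair):
        ct, cp = dense_pair
        doubled = dk.ConcentrationCurve("ct", ct.times, 2 * ct.values, "tissue")
        a = dk.plasma_flow_deconvolution(ct, cp, reg=0.01).pf
        b = dk.plasma_flow_deconvolution(doubled, cp, reg=0.01).pf
        assert b == pytest.approx(2 * a, rel=1e-9)
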