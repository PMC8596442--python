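"""Transwell permeability estimators against hand computations and an
independent two-compartment ODE oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from glucassay.transport import (
    PappMethod,
    TransportError,
    TransportTimeCourse,
    compute_facum,
    cumulative_transported,
    estimate_papp_sink,
    fit_papp_nonsink,
    percent_of_control,
    select_papp,
    uptake_ratio,
)


def _course(times, cr, vs=0.0, vr=1.5, vd=0.5, c0=50.0, a=1.12, cd=None, cr0=0.0):
    return TransportTimeCourse(
        area_a=a, vol_donor_vd=vd, vol_receiver_vr=vr, vol_sample_vs=vs,
        conc_donor_c0=c0, conc_receiver_cr0=cr0, times=tuple(times),
        conc_receiver=tuple(cr), conc_donor_series=cd,
    )


def ode_receiver_conc(papp, a, vd, vr, c0, cr0, times):
    """Independent oracle: fine-tolerance integration of the two-compartment
    diffusion ODE (no closed-form exponential used)."""

    def rhs(_t, y):
        cd, cr = y
        flux = papp * a * (cd - cr)
        return [-flux / vd, flux / vr]

    sol = solve_ivp(rhs, (0.0, max(times)), [c0, cr0], t_eval=times,
                    rtol=1e-12, atol=1e-14, method="DOP853")
    return sol.y[1]


class TestCumulativeTransported:
    def test_zero_flux_gives_zero_mass(self):
        tc = _course([0, 300, 600], [0, 0, 0], vs=0.1)
        assert np.allclose(cumulative_transported(tc), 0.0)

    def test_no_sampling_reduces_to_cr_times_vr(self):
        tc = _course([0, 300, 600], [0, 1, 2], vs=0.0)
        assert np.allclose(cumulative_transported(tc), [0.0, 1.5, 3.0])

    def test_withdrawn_mass_added_back(self):
        # hand mass balance: Q(t2) = 2*1.5 + (0 + 1)*0.1 = 3.1
        tc = _course([0, 300, 600], [0, 1, 2], vs=0.1)
        assert np.allclose(cumulative_transported(tc), [0.0, 1.5, 3.1])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _course([0, 300, 300], [0, 1, 2])

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError, match="non-negative"):
            _course([0, 300, 600], [0, -1, 2])


class TestSinkEstimator:
    def test_linear_receiver_closed_form(self, linear_course):
        # C_R = k*t with V_S = 0  =>  Papp = k*V_R/(A*C0)
        tc, k = linear_course
        est = estimate_papp_sink(tc)
        expected = k * tc.vol_receiver_vr / (tc.area_a * tc.conc_donor_c0)
        assert est.papp == pytest.approx(expected, rel=1e-12)
        assert est.method is PappMethod.SINK_LINEAR
        assert est.r_squared == pytest.approx(1.0)

    def test_recovers_truth_against_ode_oracle(self):
        papp, a, vd, vr, c0 = 1e-5, 1.12, 0.5, 1.5, 50.0
        times = np.array([0.0, 150.0, 300.0, 450.0, 600.0])
        cr = ode_receiver_conc(papp, a, vd, vr, c0, 0.0, times)
        assert max(cr) < 0.02 * c0  # < 2% transported: genuinely sink regime
        est = estimate_papp_sink(_course(times, cr, a=a, vd=vd, vr=vr, c0=c0))
        assert est.papp == pytest.approx(papp, rel=0.02)
        assert not est.sink_violated

    def test_zero_receiver_gives_zero_papp(self):
        est = estimate_papp_sink(_course([0, 300, 600], [0, 0, 0]))
        assert est.papp == 0.0

    def test_requires_three_points(self):
        with pytest.raises(TransportError, match="3 time points"):
            estimate_papp_sink(_course([0, 300], [0, 1]))

    def test_requires_positive_c0(self):
        with pytest.raises(TransportError, match="C0"):
            estimate_papp_sink(_course([0, 300, 600], [0, 1, 2], c0=0.0))

    def test_flags_sink_violation(self):
        tc = _course([0, 300, 600], [0, 3, 6], c0=50.0)  # 6 > 0.1*50
        assert estimate_papp_sink(tc).sink_violated


class TestFacum:
    def test_zero_receiver_gives_zero_facum(self):
        tc = _course([0, 300, 600], [0, 0, 0])
        assert np.allclose(compute_facum(tc), 0.0)

    def test_constant_donor_telescopes_to_fraction_of_donor_mass(self):
        # V_S = 0 and constant C_D = C0: FAcum(t_i) = Q(t_i)/(C0*V_D)
        times, cr = [0, 300, 600, 900], [0.0, 0.5, 1.0, 1.5]
        tc = _course(times, cr, cd=(50.0,) * 4)
        q = cumulative_transported(tc)
        assert np.allclose(compute_facum(tc), q / (50.0 * 0.5))

    def test_slope_matches_papp_against_ode_oracle(self):
        papp, a, vd, vr, c0 = 1e-5, 1.12, 0.5, 1.5, 50.0
        times = np.array([0.0, 150.0, 300.0, 450.0, 600.0])
        cr = ode_receiver_conc(papp, a, vd, vr, c0, 0.0, times)
        fa = compute_facum(_course(times, cr, a=a, vd=vd, vr=vr, c0=c0))
        slope = np.polyfit(times, fa, 1)[0]
        assert slope * vd / a == pytest.approx(papp, rel=0.02)

    def test_rejects_nonpositive_donor_interval(self):
        tc = _course([0, 300, 600], [0, 1, 2], cd=(50.0, 0.0, 0.0))
        with pytest.raises(TransportError, match="donor concentration"):
            compute_facum(tc)


class TestNonsinkFit:
    def test_exact_recovery_from_closed_form(self, nonsink_sim):
        est = fit_papp_nonsink(nonsink_sim.timecourse)
        assert est.method is PappMethod.NONSINK_FIT
        assert abs(est.papp - nonsink_sim.papp_true) / nonsink_sim.papp_true < 1e-6
        assert est.r_squared == pytest.approx(1.0)
        assert est.mtot == pytest.approx(nonsink_sim.mtot)

    def test_agrees_with_sink_estimator_early_time(self, early_time_sim):
        tc = early_time_sim.timecourse
        sink = estimate_papp_sink(tc).papp
        nonsink = fit_papp_nonsink(tc).papp
        assert abs(nonsink - sink) / sink < 0.02

    def test_equilibrium_data_unidentifiable(self):
        # both chambers at the same concentration: any Papp fits
        tc = _course([0, 300, 600], [50.0] * 3, cr0=50.0, c0=50.0)
        with pytest.raises(TransportError, match="unidentifiable"):
            fit_papp_nonsink(tc)

    def test_requires_three_points(self):
        with pytest.raises(TransportError, match="3 time points"):
            fit_papp_nonsink(_course([0, 600], [0, 1]))


class TestSelectPapp:
    def test_below_threshold_uses_sink(self):
        tc = _course([0, 300, 600], [0.0, 1.25, 2.5], c0=50.0)  # max 5% of C0
        assert select_papp(tc).method is PappMethod.SINK_LINEAR

    def test_boundary_is_inclusive_for_sink(self):
        tc = _course([0, 300, 600], [0.0, 2.5, 5.0], c0=50.0)  # max exactly 10%
        assert select_papp(tc).method is PappMethod.SINK_LINEAR

    def test_above_threshold_uses_nonsink(self):
        from glucassay.synthetic import TransportSimConfig, simulate_transport

        cfg = TransportSimConfig(
            papp_true=3e-5, area_a=1.12, vol_sample_vs=0.0, noise_cv=0.0,
            sample_times=tuple(np.linspace(0.0, 7200.0, 8)),
        )
        tc = simulate_transport(cfg).timecourse
        assert max(tc.conc_receiver) > 0.10 * tc.conc_donor_c0
        est = select_papp(tc)
        assert est.method is PappMethod.NONSINK_FIT
        assert est.sink_violated


class TestDerivedColumns:
    @pytest.mark.parametrize(
        "ap, bl, expected",
        [(34.89e-6, 4.57e-6, 7.63), (17.21e-6, 6.54e-6, 2.63)],
    )
    def test_uptake_ratio_printed_rows(self, ap, bl, expected):
        assert round(uptake_ratio(ap, bl), 2) == expected

    def test_uptake_ratio_identity(self):
        assert uptake_ratio(5e-6, 5e-6) == pytest.approx(1.0)

    def test_uptake_ratio_rejects_zero_denominator(self):
        with pytest.raises(TransportError):
            uptake_ratio(1e-6, 0.0)

    @pytest.mark.parametrize(
        "sample, control, expected",
        [(12.79e-6, 34.56e-6, 37.01), (7.37e-6, 4.68e-6, 157.48)],
    )
    def test_percent_of_control_printed_rows(self, sample, control, expected):
        assert round(percent_of_control(sample, control), 2) == expected

    def test_percent_of_control_identity(self):
        assert percent_of_control(3e-6, 3e-6) == pytest.approx(100.0)

    def test_percent_of_control_rejects_zero_control(self):
        with pytest.raises(TransportError):
            percent_of_control(1e-6, 0.0)
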