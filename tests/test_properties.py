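"""Property-based invariants: scale/affine invariance, monotonicity,
mass conservation under randomized simulator configurations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucassay.composition import GCPeak, GCPeakTable, molar_ratios_from_gc
from glucassay.inhibition import Assay, InhibitionMeasurement, uptake_inhibition_rate
from glucassay.metabolic import pct_reduction_vs_reference
from glucassay.synthetic import TransportSimConfig, simulate_transport
from glucassay.transport import (
    TransportTimeCourse,
    compute_facum,
    cumulative_transported,
    estimate_papp_sink,
    percent_of_control,
    uptake_ratio,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")

finite_pos = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def _scaled_course(conc, scale, vs=0.1):
    return TransportTimeCourse(
        area_a=1.13, vol_donor_vd=0.5, vol_receiver_vr=1.5, vol_sample_vs=vs,
        conc_donor_c0=50.0 * scale, times=(0.0, 600.0, 1200.0, 1800.0),
        conc_receiver=tuple(c * scale for c in conc),
    )


class TestScaleEquivariance:
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           conc=st.tuples(*[st.floats(min_value=0, max_value=4)] * 4))
    def test_papp_and_facum_unchanged_by_concentration_rescaling(self, scale, conc):
        base = _scaled_course(conc, 1.0)
        scaled = _scaled_course(conc, scale)
        est_b, est_s = estimate_papp_sink(base), estimate_papp_sink(scaled)
        assert est_s.papp == pytest.approx(est_b.papp, rel=1e-9, abs=1e-18)
        assert np.allclose(compute_facum(scaled), compute_facum(base), rtol=1e-9, atol=1e-15)

    @given(ap=finite_pos, bl=finite_pos, c=st.floats(min_value=1e-2, max_value=1e2))
    def test_ur_and_pct_of_control_are_ratio_statistics(self, ap, bl, c):
        assert uptake_ratio(ap * c, bl * c) == pytest.approx(uptake_ratio(ap, bl))
        assert percent_of_control(ap * c, bl * c) == pytest.approx(percent_of_control(ap, bl))


class TestAffineInvariance:
    @given(
        as_=st.floats(min_value=0, max_value=3),
        ac=st.floats(min_value=0, max_value=3),
        ab=st.floats(min_value=0, max_value=3),
        shift=st.floats(min_value=0, max_value=5),
        scale=st.floats(min_value=1e-2, max_value=1e2),
    )
    def test_uptake_inhibition_invariant_to_common_shift_and_scale(
        self, as_, ac, ab, shift, scale
    ):
        if abs(ac - ab) < 1e-6:
            return
        def rate(a, c, b):
            return uptake_inhibition_rate(
                InhibitionMeasurement(assay=Assay.UPTAKE, abs_sample_as=a,
                                      abs_control_ac=c, abs_blank_ab=b)
            )
        base = rate(as_, ac, ab)
        assert rate(as_ + shift, ac + shift, ab + shift) == pytest.approx(base, abs=1e-6)
        assert rate(as_ * scale, ac * scale, ab * scale) == pytest.approx(base, abs=1e-6)


class TestMonotonicity:
    @given(increments=st.lists(st.floats(min_value=0, max_value=2), min_size=3, max_size=8),
           vs=st.floats(min_value=0, max_value=1.4))
    def test_q_and_facum_nondecreasing_for_nondecreasing_receiver(self, increments, vs):
        conc = tuple(np.cumsum(increments))
        times = tuple(600.0 * k for k in range(len(conc)))
        tc = TransportTimeCourse(
            area_a=1.13, vol_donor_vd=0.5, vol_receiver_vr=1.5, vol_sample_vs=vs,
            conc_donor_c0=1e4, times=times, conc_receiver=conc,
        )
        q = cumulative_transported(tc)
        assert np.all(np.diff(q) >= -1e-12)
        fa = compute_facum(tc)
        assert np.all(np.diff(fa) >= -1e-12)


class TestConservation:
    @given(
        papp=st.floats(min_value=0, max_value=1e-4),
        vs=st.floats(min_value=0, max_value=0.5),
        cr0=st.floats(min_value=0, max_value=20),
        c0=st.floats(min_value=1, max_value=100),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_sampling_ledger_is_conservative(self, papp, vs, cr0, c0, seed):
        cfg = TransportSimConfig(
            papp_true=papp, vol_sample_vs=vs, conc_receiver_cr0=cr0,
            conc_donor_c0=c0, noise_cv=0.0, seed=seed,
        )
        sim = simulate_transport(cfg)
        total = (np.asarray(sim.donor_mass) + np.asarray(sim.receiver_mass)
                 + np.asarray(sim.withdrawn_mass))
        assert np.allclose(total, sim.mtot, rtol=1e-12, atol=1e-12)


class TestRatioStatistics:
    @given(areas=st.lists(st.floats(min_value=1, max_value=1e4), min_size=2, max_size=6),
           scale=st.floats(min_value=1e-2, max_value=1e2))
    def test_gc_ratios_invariant_to_common_area_rescaling(self, areas, scale):
        names = [f"S{i}" for i in range(len(areas))]
        def table(mult):
            peaks = tuple(
                GCPeak(name=n, retention_time=10.0 + i, area=a * mult)
                for i, (n, a) in enumerate(zip(names, areas))
            )
            return molar_ratios_from_gc(GCPeakTable(peaks=peaks, reference_sugar="S0"))
        base, scaled = table(1.0), table(scale)
        for name in names:
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)

    @given(v=st.floats(min_value=0, max_value=100), r=st.floats(min_value=1e-3, max_value=100))
    def test_pct_reduction_antisymmetry(self, v, r):
        assert pct_reduction_vs_reference(v, r) == pytest.approx(-100.0 * (v - r) / r, abs=1e-9)
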