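import numpy as np
import pytest

from sprscreen import (ArtifactModel, ReportPoint, ReportPointKind, Sensorgram,
                       apply_solvent_correction, double_reference,
                       fit_solvent_calibration, measure_ref_bulk, report_point,
                       select_calibration, simulate_cycle)
from sprscreen.processing import SolventCalibration
from sprscreen.simulate import BLANK_PROFILE


def flat(value: float, t_start=10.0, t_stop=40.0, t_end=70.0, hz=5.0):
    times = np.arange(int(t_end * hz) + 1) / hz
    return Sensorgram(times=times, response=np.full(times.size, value),
                      t_start=t_start, t_stop=t_stop)


class TestSensorgram:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Sensorgram(times=[0, 1, 1], response=[0, 0, 0], t_start=0, t_stop=1)

    def test_markers_must_lie_inside(self):
        with pytest.raises(ValueError, match="markers"):
            Sensorgram(times=[0, 1, 2], response=[0, 0, 0], t_start=0, t_stop=5)


class TestDoubleReference:
    def test_active_equals_reference_gives_zero(self):
        out = double_reference(flat(3.0), flat(3.0))
        assert np.allclose(out.response, 0.0)

    def test_common_mode_offset_rejected(self):
        a, r = flat(7.0), flat(4.0)
        base = double_reference(flat(4.0), flat(1.0))
        shifted = double_reference(a, r)
        assert np.allclose(base.response, shifted.response)

    def test_blank_pair_subtraction(self):
        out = double_reference(flat(5.0), flat(1.0), blank=(flat(3.0), flat(1.0)))
        assert np.allclose(out.response, 2.0)

    def test_grid_mismatch_errors_unless_interpolated(self):
        a = flat(1.0, hz=5.0)
        r = flat(1.0, hz=4.0)
        with pytest.raises(ValueError, match="interpolate"):
            double_reference(a, r)
        out = double_reference(a, r, interpolate=True)
        assert np.allclose(out.response, 0.0)

    def test_blank_removes_systematic_artifact(self, clean_binder, c1r_surface,
                                               schedule):
        """Blank subtraction cancels a drift artifact exactly, recovering the
        pure binding trace (noise-free simulator check)."""
        drifty = ArtifactModel(noise_sd=0.0, drift=0.05,
                               excl_coeffs=(0.0, 0.0, 0.0))
        ideal = ArtifactModel(noise_sd=0.0, excl_coeffs=(0.0, 0.0, 0.0))
        a, r = simulate_cycle(clean_binder, 2e-4, c1r_surface, schedule, drifty)
        # the blank cycle carries the same drift but no analyte
        ba, br = simulate_cycle(BLANK_PROFILE, 0.0, c1r_surface, schedule, drifty)
        corrected = double_reference(a, r, blank=(ba, br))
        a0, r0 = simulate_cycle(clean_binder, 2e-4, c1r_surface, schedule, ideal)
        pure = double_reference(a0, r0)
        assert np.allclose(corrected.response, pure.response, atol=1e-10)

    def test_pipeline_is_linear(self, rng):
        """Correcting the sum of two cycles equals the sum of corrections."""
        mk = lambda: flat(0.0).response + rng.normal(size=flat(0.0).times.size)
        t = flat(0.0)
        s1a, s1r = mk(), mk()
        s2a, s2r = mk(), mk()
        build = lambda resp: Sensorgram(times=t.times, response=resp,
                                        t_start=t.t_start, t_stop=t.t_stop)
        joint = double_reference(build(s1a + s2a), build(s1r + s2r))
        sep = (double_reference(build(s1a), build(s1r)).response
               + double_reference(build(s2a), build(s2r)).response)
        assert np.allclose(joint.response, sep)


def calibration_cycles(artifacts: ArtifactModel, dmso_levels, surface, schedule):
    return [simulate_cycle(BLANK_PROFILE, 0.0, surface, schedule, artifacts,
                           dmso_actual=d)
            for d in dmso_levels]


class TestSolventCalibration:
    def test_zero_offsets_give_identity_correction(self, c1r_surface, schedule):
        art = ArtifactModel(noise_sd=0.0, excl_coeffs=(0.0, 0.0, 0.0))
        cycles = calibration_cycles(art, np.linspace(4.0, 5.5, 6),
                                    c1r_surface, schedule)
        cal = fit_solvent_calibration(cycles)
        assert cal.offset(10.0) == pytest.approx(0.0, abs=1e-9)
        value, ok = apply_solvent_correction(5.0, 10.0, cal)
        assert value == pytest.approx(5.0, abs=1e-9) and ok

    def test_recovers_generating_polynomial(self, c1r_surface, schedule):
        """The fitted curve matches the simulator's excluded-volume
        polynomial to better than 1% over the calibrated range."""
        art = ArtifactModel(noise_sd=0.0, excl_coeffs=(0.0, 0.012, 2e-4))
        cycles = calibration_cycles(art, np.linspace(4.0, 5.5, 8),
                                    c1r_surface, schedule)
        cal = fit_solvent_calibration(cycles)
        for bulk in np.linspace(*cal.validity, 11):
            assert cal.offset(bulk) == pytest.approx(art.excl_offset(bulk),
                                                     rel=0.01, abs=1e-6)

    def test_needs_three_spanning_points(self, c1r_surface, schedule):
        art = ArtifactModel(noise_sd=0.0)
        with pytest.raises(ValueError, match="at least 3"):
            fit_solvent_calibration(
                calibration_cycles(art, [4.0, 5.0], c1r_surface, schedule))
        with pytest.raises(ValueError, match="degenerate"):
            fit_solvent_calibration(
                calibration_cycles(art, [5.0, 5.0, 5.0], c1r_surface, schedule))

    def test_out_of_range_flagged_not_extrapolated(self):
        cal = SolventCalibration(points=[(0, 0), (1, 0), (2, 0)],
                                 coeffs=np.array([0.0]), validity=(-10.0, 10.0))
        _, ok = apply_solvent_correction(1.0, 50.0, cal)
        assert not ok
        _, ok = apply_solvent_correction(1.0, 0.0, cal)
        assert ok

    def test_piecewise_selection_by_cycle_span(self):
        mk = lambda span: SolventCalibration(points=[(0, 0)] * 3,
                                             coeffs=np.array([0.0]),
                                             validity=(0, 1), cycle_span=span)
        cals = [mk((1, 50)), mk((51, 100))]
        assert select_calibration(cals, 10) is cals[0]
        assert select_calibration(cals, 80) is cals[1]
        assert select_calibration(cals, 200) is cals[1]


class TestReportPoint:
    def test_constant_trace_returns_value(self):
        s = flat(4.2)
        for kind in ReportPointKind:
            assert report_point(s, kind).value == pytest.approx(4.2)

    def test_binding_point_equals_plateau(self, clean_binder, c1r_surface,
                                          schedule, quiet):
        a, r = simulate_cycle(clean_binder, 480e-6, c1r_surface, schedule, quiet)
        corrected = double_reference(a, r)
        km = clean_binder.kinetics
        req = 480e-6 * 27.6 / (480e-6 + km.kd_eq)
        rp = report_point(corrected, ReportPointKind.BINDING)
        assert rp.value == pytest.approx(req, rel=1e-3)

    def test_residual_of_fast_dissociating_binder_is_negligible(
            self, clean_binder, c1r_surface, schedule, quiet):
        """kd = 1/s means the signal has decayed by e^-10 at the 10 s
        residual point."""
        a, r = simulate_cycle(clean_binder, 480e-6, c1r_surface, schedule, quiet)
        corrected = double_reference(a, r)
        residual = report_point(corrected, ReportPointKind.RESIDUAL)
        r_stop = corrected.response[np.searchsorted(corrected.times,
                                                    schedule.t_stop)]
        assert residual.value < r_stop * np.exp(-9)
        assert residual.value == pytest.approx(0.0, abs=1e-3)

    def test_window_outside_trace_errors(self):
        s = flat(1.0, t_end=45.0)
        with pytest.raises(ValueError, match="window"):
            report_point(s, ReportPointKind.RESIDUAL)  # needs t_stop + 10 s

    def test_extraction_commutes_with_double_referencing(self, clean_binder,
                                                         c1r_surface, schedule):
        art = ArtifactModel(noise_sd=0.3, seed=9)
        a, r = simulate_cycle(clean_binder, 2e-4, c1r_surface, schedule, art)
        corrected = double_reference(a, r)
        direct = report_point(corrected, ReportPointKind.BINDING).value
        separate = (report_point(a, ReportPointKind.BINDING).value
                    - report_point(r, ReportPointKind.BINDING).value)
        assert direct == pytest.approx(separate, abs=1e-12)

    def test_measure_ref_bulk(self, c1r_surface, schedule):
        art = ArtifactModel(noise_sd=0.0, dmso_actual=5.3)
        _, r = simulate_cycle(BLANK_PROFILE, 0.0, c1r_surface, schedule, art)
        assert measure_ref_bulk(r) == pytest.approx(art.bulk_ru(), rel=1e-9)

    def test_width_must_be_positive(self):
        with pytest.raises(ValueError):
            ReportPoint(value=0.0, center=1.0, width=0.0,
                        kind=ReportPointKind.BINDING)
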