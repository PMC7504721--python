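import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sprscreen import (ArtifactModel, BinderClass, CompoundProfile,
                       InjectionSchedule, KineticModel, ReportPointKind,
                       default_concentration_series, double_reference,
                       report_point, simulate_campaign, simulate_cycle,
                       simulate_dose_series, simulate_elisa_plate,
                       synthetic_library, theoretical_rmax_ru)
from sprscreen.simulate import inhibition_fraction


class TestKineticModel:
    def test_equilibrium_consistency(self):
        km = KineticModel(ka=2083.0, kd_rate=1.0)
        assert km.kd_eq * km.ka == pytest.approx(km.kd_rate)
        km2 = KineticModel.from_equilibrium(480e-6, kd_rate=1.5)
        assert km2.kd_eq == pytest.approx(480e-6)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            KineticModel(ka=-1, kd_rate=1)


class TestSimulateCycle:
    def test_no_analyte_means_no_signal(self, clean_binder, c1r_surface,
                                        schedule, quiet):
        a, r = simulate_cycle(clean_binder, 0.0, c1r_surface, schedule, quiet)
        corrected = double_reference(a, r)
        assert np.allclose(corrected.response, 0.0)

    def test_half_saturation_plateau(self, c1r_surface, schedule, quiet):
        """At C = KD the noise-free plateau equals Rmax·n/2 to 1e-9 relative."""
        km = KineticModel.from_equilibrium(480e-6, kd_rate=5.0)
        profile = CompoundProfile("X", mw=276.0, kinetics=km)
        long = InjectionSchedule(t_start=10, t_stop=200, t_dissoc_end=230, hz=5)
        a, r = simulate_cycle(profile, 480e-6, c1r_surface, long, quiet)
        corrected = double_reference(a, r)
        plateau = corrected.response[np.searchsorted(corrected.times, 200.0)]
        rmax = theoretical_rmax_ru(c1r_surface, 276.0)
        assert plateau == pytest.approx(rmax / 2, rel=1e-9)

    def test_association_matches_ode_oracle(self, quiet):
        """Closed-form kinetics agree with numerical integration of
        dR/dt = ka·C·(Rmax − R) − kd·R; at t_start + 1 s, R ≈ 8.65 RU."""
        ka, kd, conc, rmax = 1e3, 1.0, 1e-3, 20.0
        surface_immob = rmax / (276.0 / 92000.0)
        from sprscreen import SurfaceDef
        surf = SurfaceDef("L", 92000.0, surface_immob)
        profile = CompoundProfile("X", mw=276.0,
                                  kinetics=KineticModel(ka=ka, kd_rate=kd))
        sch = InjectionSchedule(hz=50)
        a, r = simulate_cycle(profile, conc, surf, sch, quiet)
        corrected = double_reference(a, r)

        sol = solve_ivp(lambda t, y: ka * conc * (rmax - y[0]) - kd * y[0],
                        (0.0, 30.0), [0.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        t_assoc = corrected.times[(corrected.times >= sch.t_start)
                                  & (corrected.times <= sch.t_stop)]
        expected = sol.sol(t_assoc - sch.t_start)[0]
        got = corrected.response[(corrected.times >= sch.t_start)
                                 & (corrected.times <= sch.t_stop)]
        assert np.allclose(got, expected, atol=1e-6)
        at_1s = np.interp(sch.t_start + 1.0, corrected.times, corrected.response)
        assert at_1s == pytest.approx(8.6466, abs=1e-3)

    def test_dissociation_is_log_linear(self, clean_binder, c1r_surface,
                                        schedule, quiet):
        a, r = simulate_cycle(clean_binder, 500e-6, c1r_surface, schedule, quiet)
        corrected = double_reference(a, r)
        mask = (corrected.times > schedule.t_stop + 0.5) & \
               (corrected.times < schedule.t_stop + 8)
        slope = np.polyfit(corrected.times[mask],
                           np.log(corrected.response[mask]), 1)[0]
        assert slope == pytest.approx(-clean_binder.kinetics.kd_rate, rel=1e-6)

    def test_negative_concentration_rejected(self, clean_binder, c1r_surface,
                                             schedule, quiet):
        with pytest.raises(ValueError):
            simulate_cycle(clean_binder, -1e-6, c1r_surface, schedule, quiet)

    def test_seeded_reproducibility(self, clean_binder, c1r_surface, schedule):
        noisy = ArtifactModel(noise_sd=0.5, seed=42)
        a1, r1 = simulate_cycle(clean_binder, 1e-4, c1r_surface, schedule, noisy)
        a2, r2 = simulate_cycle(clean_binder, 1e-4, c1r_surface, schedule, noisy)
        assert np.array_equal(a1.response, a2.response)
        assert np.array_equal(r1.response, r2.response)
        other = ArtifactModel(noise_sd=0.5, seed=43)
        a3, _ = simulate_cycle(clean_binder, 1e-4, c1r_surface, schedule, other)
        assert not np.array_equal(a1.response, a3.response)


class TestDoseSeries:
    def test_default_series_is_seven_point_twofold(self):
        concs = default_concentration_series()
        assert len(concs) == 7
        assert concs[-1] == pytest.approx(500e-6)
        assert concs[0] == pytest.approx(500e-6 / 2 ** 6)  # 7.8125 µM
        assert np.allclose(concs[1:] / concs[:-1], 2.0)

    def test_noise_free_replicates_identical(self, clean_binder, c1r_surface,
                                             schedule, quiet):
        reps = simulate_dose_series(clean_binder, None, c1r_surface, schedule,
                                    quiet, replicates=2)
        for (a1, _), (a2, _) in zip(*reps):
            assert np.array_equal(a1.response, a2.response)

    def test_plateaus_increase_with_concentration(self, clean_binder,
                                                  c1r_surface, schedule, quiet):
        (rep,) = simulate_dose_series(clean_binder, None, c1r_surface,
                                      schedule, quiet, replicates=1)
        plateaus = [report_point(double_reference(a, r),
                                 ReportPointKind.BINDING).value
                    for a, r in rep]
        assert np.all(np.diff(plateaus) > 0)

    def test_replicates_must_be_positive(self, clean_binder, c1r_surface,
                                         schedule, quiet):
        with pytest.raises(ValueError):
            simulate_dose_series(clean_binder, None, c1r_surface, schedule,
                                 quiet, replicates=0)


class TestCampaign:
    def test_empty_library_rejected(self, c1r_surface, quiet):
        with pytest.raises(ValueError):
            simulate_campaign([], c1r_surface, quiet)

    def test_fractions_must_sum_to_one(self, c1r_surface, quiet):
        lib = synthetic_library(10, seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_campaign(lib, c1r_surface, quiet,
                              class_fractions={"clean_binder": 0.5})

    def test_planted_sticky_set_exceeds_clean_threshold(self, c1r_surface,
                                                        quiet):
        """Noise-free: exactly the planted sticky compounds show > 5 RU
        residual 10 s post injection on the bare surface."""
        from sprscreen.pipeline import process_campaign
        lib = synthetic_library(100, seed=7)
        camp = simulate_campaign(
            lib, c1r_surface, quiet, seed=7,
            class_fractions={"clean_binder": 0.0, "non_binder": 0.9,
                             "sticky": 0.1, "superstoichiometric": 0.0})
        processed = process_campaign(camp, solvent_correct=False)
        clean = processed[processed["stage"] == "clean"]
        flagged = set(clean.loc[clean["residual_ru"] > 5.0, "compound_id"])
        planted = set(camp.truth.loc[
            camp.truth["binder_class"] == BinderClass.STICKY.value,
            "compound_id"])
        assert flagged == planted and len(planted) == 10

    def test_campaign_determinism(self, c1r_surface):
        lib = synthetic_library(20, seed=3)
        art = ArtifactModel(noise_sd=0.4, seed=3)
        c1 = simulate_campaign(lib, c1r_surface, art, seed=3)
        c2 = simulate_campaign(lib, c1r_surface, art, seed=3)
        assert c1.truth.equals(c2.truth)
        for r1, r2 in zip(c1.cycles, c2.cycles):
            assert np.array_equal(r1.active.response, r2.active.response)


class TestElisaPlate:
    def test_half_maximal_at_ic50(self):
        plate = simulate_elisa_plate(520e-6, concentrations=[520e-6],
                                     noise_cv=0.0)
        from sprscreen import percent_activity
        norm = percent_activity(plate)
        sample = norm[norm["role"] == "sample"]
        assert sample["pct_activity"].iloc[0] == pytest.approx(50.0)

    def test_zero_concentration_is_full_activity(self):
        assert inhibition_fraction(0.0, 520e-6) == 0.0

    def test_saturating_concentration_approaches_zero_activity(self):
        assert inhibition_fraction(1.0, 520e-6) == pytest.approx(1.0, abs=1e-3)

    def test_controls_present_per_column(self):
        plate = simulate_elisa_plate(520e-6, noise_cv=0.0)
        for _, col in plate.groupby("col"):
            roles = set(col["role"])
            assert {"positive_control", "negative_control"} <= roles

    def test_invalid_ic50(self):
        with pytest.raises(ValueError):
            simulate_elisa_plate(0.0)
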