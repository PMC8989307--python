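"""Full-pipeline runs: decoupling, controls, monotonicity, onset lag."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cachexim import (
    AGED_HOST,
    ChemoEffect,
    HostTrajectory,
    Scenario,
    healthy_equilibrium,
    make_cycle,
    make_daily,
    run,
    run_control,
)
from cachexim.tissue import aged_params, proliferation_rate, renewal_probability


class TestControls:
    def test_untreated_young_host_grows_to_equilibrium_lean_mass(self, mp):
        """The young host grows toward 11.217 g: monotone through the growth
        phase, with a modest (< 1%) overshoot around day ~55 before settling
        — the starting stem ratio exceeds the homeostatic one."""
        traj = run(Scenario(schedule=make_daily(24).empty(), t_end=400.0))
        growth = traj.times <= 40.0
        assert np.all(np.diff(traj.lean[growth]) > -1e-9)
        assert traj.lean.max() < 11.2166 * 1.01
        assert traj.lean[-1] == pytest.approx(11.2166, abs=1e-3)

    def test_control_equals_run_on_zero_dose_scenario(self):
        sc = Scenario(schedule=make_daily(24).empty())
        a, b = run(sc), run_control(sc)
        assert np.array_equal(a.S, b.S) and np.array_equal(a.M, b.M)

    def test_young_stem_ratio_declines_to_equilibrium_ratio(self, mp):
        traj = run(Scenario(schedule=make_daily(24).empty(), t_end=300.0))
        ratio = traj.stem_ratio
        assert np.all(np.diff(ratio) < 1e-12)
        eq = healthy_equilibrium(mp)
        assert ratio[-1] == pytest.approx(eq.S / eq.M, abs=1e-5)
        assert eq.S / eq.M == pytest.approx(0.05156, abs=1e-5)

    def test_aged_control_declines_toward_reduced_equilibrium(self, mp):
        traj = run_control(Scenario(schedule=make_daily(24), aged=True, t_end=400.0))
        assert traj.lean[0] == pytest.approx(0.002 * (275 + 5333), rel=1e-12)
        aged_eq = healthy_equilibrium(aged_params(mp))
        target = mp.density * (aged_eq.S + aged_eq.M)
        assert target == pytest.approx(10.94, abs=0.005)
        assert traj.lean[-1] == pytest.approx(target, abs=1e-3)
        assert traj.lean[-1] < traj.lean[0]


class TestDecoupling:
    def test_pk_series_identical_to_standalone_run(self, pk, five_two_run):
        from cachexim.pharmacokinetics import average_exposure, simulate_pk

        pkt = simulate_pk(pk, make_cycle(5, 2, 35), t_end=56.0)
        assert np.array_equal(pkt.C1, five_two_run.C1)
        assert np.array_equal(pkt.C2, five_two_run.C2)
        assert np.array_equal(average_exposure(pkt, 8.0).y, five_two_run.y)

    def test_zero_dose_run_matches_healthy_integration(self, mp):
        """Coupled run with an empty schedule equals the plain healthy ODE."""
        sc = Scenario(schedule=make_daily(24).empty())
        traj = run(sc)

        def rhs(t, x):
            S, M = x
            p = renewal_probability(M, mp)
            nu = proliferation_rate(M, mp)
            return [(2 * p - 1) * nu * S, 2 * (1 - p) * nu * S - mp.d0 * M]

        res = solve_ivp(
            rhs, (0, 56.0), [267.5, 4732.5], method="LSODA",
            t_eval=traj.times, rtol=1e-8, atol=1e-10, max_step=1.0,
        )
        assert np.max(np.abs(res.y[0] - traj.S) / traj.S) < 1e-9
        assert np.max(np.abs(res.y[1] - traj.M) / traj.M) < 1e-9


class TestTumourCoupling:
    def test_five_two_controls_tumour_but_daily_does_not(
        self, standard_daily_run, five_two_run
    ):
        """35 mg/kg 5-on/2-off pushes the tumour below 1 mm^3; 24 daily does not."""
        assert five_two_run.T.min() < 1.0
        assert standard_daily_run.T.min() >= 1.0

    def test_tumour_absent_without_tumour_params(self):
        traj = run(Scenario(schedule=make_daily(24)))
        assert traj.T is None


class TestTreatmentShape:
    def test_transient_stem_ratio_disruption(self):
        """The treatment-induced stem-ratio disruption dies away: below 0.2%
        of control 150 days after the last dose and below 0.1% by 180 days
        (the recovery is rate-limited by the ~0.03/day slow mode)."""
        sc = Scenario(schedule=make_daily(35), t_end=210.0)
        tr, ct = run(sc), run_control(sc)
        rel = np.abs(tr.stem_ratio - ct.stem_ratio) / ct.stem_ratio
        assert rel[np.searchsorted(tr.times, 177.0)] < 2e-3
        assert rel[-1] < 1e-3
        assert rel.max() > 0.05  # the disruption itself is substantial

    def test_lean_nadir_non_increasing_in_dose_five_two(self):
        """Across the experimental 14-60 mg/kg span (5-on/2-off family)."""
        nadirs = [
            run(Scenario(schedule=make_cycle(5, 2, d))).lean.min()
            for d in range(14, 61, 4)
        ]
        assert np.all(np.diff(nadirs) <= 1e-9)

    def test_lean_nadir_non_increasing_in_dose_daily(self):
        """Daily family over its experimental 14-35 mg/kg span."""
        nadirs = [
            run(Scenario(schedule=make_daily(d))).lean.min()
            for d in range(14, 36, 3)
        ]
        assert np.all(np.diff(nadirs) <= 1e-9)

    def test_averaging_window_delays_onset(self):
        """Under 35 mg/kg daily, lean mass crosses 2% below control later with
        tau = 11 than with tau = 1."""

        def onset_day(tau):
            sc = Scenario(schedule=make_daily(35), ce=ChemoEffect(Rd=6.8, tau=tau))
            tr, ct = run(sc), run_control(sc)
            below = np.nonzero(tr.lean / ct.lean < 0.98)[0]
            return tr.times[below[0]]

        assert onset_day(11.0) > onset_day(1.0)

    def test_weekend_holiday_oscillations(self):
        """5-on/2-off dosing leaves weekly wiggles in the lean-mass curve."""
        tr = run(Scenario(schedule=make_cycle(5, 2, 50)))
        phase = (tr.times > 7) & (tr.times < 28)
        slope_sign = np.sign(np.diff(tr.lean[phase]))
        changes = np.sum(np.diff(slope_sign) != 0)
        assert changes >= 2


class TestScenario:
    def test_schedule_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            Scenario(schedule=make_daily(24), t_end=20.0)

    def test_aged_flag_defaults(self, mp):
        sc = Scenario(schedule=make_daily(24), aged=True)
        assert sc.initial_host == AGED_HOST
        assert sc.effective_mp.p1 == pytest.approx(0.98 * mp.p1)

    def test_morphine_flag_scales_rates(self, pk):
        sc = Scenario(schedule=make_daily(24), morphine=True)
        assert sc.effective_pk.k10 == pytest.approx(0.65 * pk.k10)

    def test_output_grid_density_does_not_change_dynamics(self):
        """Halving the output resolution leaves day-28 lean mass unchanged
        (< 1e-4 g): the grid only samples the solution."""
        lean = {}
        for res in (0.005, 0.0025):
            sc = Scenario(schedule=make_daily(35), resolution=res)
            tr = run(sc)
            lean[res] = tr.at_day(28.0)["lean"]
        assert abs(lean[0.005] - lean[0.0025]) < 1e-4

    def test_trajectory_csv_round_trip(self, tmp_path, standard_daily_run):
        path = tmp_path / "traj.csv"
        standard_daily_run.to_csv(path)
        back = HostTrajectory.from_csv(path)
        assert np.allclose(back.lean, standard_daily_run.lean)
        assert np.allclose(back.T, standard_daily_run.T)

    def test_lean_mass_and_ratio_identities(self, standard_daily_run, mp):
        tr = standard_daily_run
        assert np.allclose(tr.lean, mp.density * (tr.S + tr.M), rtol=1e-12)
        assert np.allclose(tr.stem_ratio, tr.S / tr.M, rtol=1e-12)
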