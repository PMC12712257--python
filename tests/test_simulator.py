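"""Single-compartment ventilation simulation: step physics, modes, analysis."""

import numpy as np
import pandas as pd
import pytest

from bronchosim import (
    RespiratorySystem,
    RohrerModel,
    SimulationConfig,
    VentilationModel,
    VentilatorSettings,
    analyze_breaths,
    rohrer_dp,
    run_atc,
    run_pc,
    run_vc,
    step,
)
from conftest import tube_at


class TestStep:
    def test_equilibrium_is_stationary(self, bench_system, reference_tube):
        flow, paw, ptrach, palv = step(
            0.0, bench_system, reference_tube, p_aw_applied=0.0
        )
        assert flow == 0.0 and paw == ptrach == palv == 0.0

    def test_pressure_driven_flow_solves_quadratic(self, bench_system, reference_tube):
        """p_aw = 10 mbar on an empty compartment: k2 f^2 + (k1 + R_aw) f = 10,
        i.e. 2.88 f^2 + 2.72 f = 10, whose positive root is 1.45007225..."""
        flow, paw, _, _ = step(0.0, bench_system, reference_tube, p_aw_applied=10.0)
        assert flow == pytest.approx(1.4500722529773284, abs=1e-12)
        assert paw == 10.0

    def test_flow_driven_back_computes_pressure(self, bench_system, reference_tube):
        flow, paw, ptrach, palv = step(
            100.0, bench_system, reference_tube, flow_applied=0.5
        )
        assert palv == pytest.approx(2.0)  # 100 ml / 50 ml/mbar
        assert ptrach == pytest.approx(palv + 2.0 * 0.5)
        assert paw == pytest.approx(ptrach + rohrer_dp(reference_tube, 0.5))

    def test_pressure_balance_residual(self, bench_system, reference_tube):
        """The implicit solve satisfies the pressure balance to < 1e-9 mbar."""
        for p_applied in (-20.0, -3.0, 0.5, 10.0, 60.0):
            for v in (0.0, 250.0, 600.0):
                f, paw, _, palv = step(
                    v, bench_system, reference_tube, p_aw_applied=p_applied
                )
                resid = paw - rohrer_dp(reference_tube, f) - bench_system.r_aw * f - palv
                assert abs(resid) < 1e-9

    def test_requires_exactly_one_boundary_condition(self, bench_system, reference_tube):
        with pytest.raises(ValueError):
            step(0.0, bench_system, reference_tube)
        with pytest.raises(ValueError):
            step(0.0, bench_system, reference_tube, p_aw_applied=1.0, flow_applied=1.0)


class TestVolumeControlled:
    def test_unobstructed_tube_full_exhalation(self, vc_settings, bench_system):
        res = run_vc(vc_settings, bench_system, tube_at(20.0, has_scope=False))
        assert res.steady.converged
        assert res.steady.ipeep < 0.2

    def test_delivered_volume_matches_setting_for_any_tube(
        self, vc_settings, bench_system
    ):
        for d_eff in (3.8, 6.0, 20.0):
            res = run_vc(vc_settings, bench_system, tube_at(d_eff))
            assert res.steady.v_insp == pytest.approx(500.0, abs=1.0)

    def test_narrow_lumen_builds_intrinsic_peep(self, vc_settings, bench_system):
        res = run_vc(vc_settings, bench_system, tube_at(3.8))
        assert res.steady.converged
        assert res.steady.ipeep > 5.0
        # iPEEP approach from zero initial volume is monotone non-decreasing
        ipeeps = [b.ipeep for b in res.breaths]
        assert all(b >= a - 1e-9 for a, b in zip(ipeeps, ipeeps[1:]))

    def test_airway_pressure_ceiling_is_flagged_not_enforced(
        self, vc_settings, bench_system
    ):
        """VC is a flow source: the back-computed airway pressure may exceed
        the ventilator ceiling and the samples are counted."""
        res = run_vc(vc_settings, bench_system, tube_at(3.8))
        assert res.steady.p_aw_peak > 80.0
        assert res.steady.n_over_pmax > 0

    def test_volume_continuity_and_steady_balance(self, vc_settings, bench_system):
        res = run_vc(vc_settings, bench_system, tube_at(5.0))
        w = res.waveforms
        flow = w["flow_Lps"].to_numpy()
        vol = w["vol_ml"].to_numpy()
        dt = w["t_s"].iloc[1] - w["t_s"].iloc[0]
        trap = 0.5 * (flow[:-1] + flow[1:]) * dt * 1000.0
        assert np.max(np.abs(np.diff(vol) - trap)) < 1e-9
        s = res.steady
        assert abs(s.v_insp - s.v_exp) < 0.01 * s.v_insp

    def test_dt_convergence_worst_case(self, vc_settings, bench_system):
        """Halving the step from 4 ms changes steady iPEEP and V_T by < 1%
        even for the narrowest lumen."""
        tube = tube_at(3.8)
        r1 = run_vc(vc_settings, bench_system, tube, SimulationConfig(dt=0.004))
        r2 = run_vc(vc_settings, bench_system, tube, SimulationConfig(dt=0.002))
        assert r1.steady.ipeep == pytest.approx(r2.steady.ipeep, rel=0.01)
        assert r1.steady.v_insp == pytest.approx(r2.steady.v_insp, rel=0.01)

    def test_mode_mismatch_rejected(self, pc_settings, bench_system, reference_tube):
        with pytest.raises(ValueError):
            run_vc(pc_settings, bench_system, reference_tube)


class TestPressureControlled:
    def test_wide_lumen_delivers_full_support_volume(self, pc_settings, bench_system):
        """Above ~7 mm effective diameter the tidal volume equilibrates to
        PS * C = 500 ml with no noticeable intrinsic PEEP."""
        res = run_pc(pc_settings, bench_system, tube_at(7.5))
        assert res.steady.converged
        assert res.steady.v_insp == pytest.approx(500.0, rel=0.02)
        assert res.steady.ipeep < 0.5

    def test_tidal_volume_bounded_by_ps_times_c(self, pc_settings, bench_system):
        for d_eff in (3.8, 5.0, 7.5, 30.0):
            res = run_pc(pc_settings, bench_system, tube_at(d_eff))
            assert res.steady.v_insp <= pc_settings.ps * bench_system.compliance + 0.5

    def test_very_wide_tube_reaches_full_equilibration(self, pc_settings, bench_system):
        res = run_pc(pc_settings, bench_system, tube_at(40.0))
        assert res.steady.v_insp == pytest.approx(
            pc_settings.ps * bench_system.compliance, abs=0.5
        )

    def test_ipeep_below_applied_pressure(self, pc_settings, bench_system):
        res = run_pc(pc_settings, bench_system, tube_at(4.0))
        assert res.steady.ipeep < pc_settings.ps + pc_settings.peep


class TestAutomaticTubeCompensation:
    def test_waveforms_independent_of_tube(self, atc_settings, bench_system):
        """With an unbounded pressure source the tracheal-pressure and flow
        waveforms do not depend on the tube at all."""
        st = VentilatorSettings(mode="atc", p_max=1e9)
        ra = run_atc(st, bench_system, tube_at(3.8))
        rb = run_atc(st, bench_system, tube_at(8.0))
        for col in ("ptrach_mbar", "flow_Lps"):
            a = ra.waveforms[col].to_numpy()
            b = rb.waveforms[col].to_numpy()
            assert np.max(np.abs(a - b)) < 1e-6

    def test_no_intrinsic_peep(self, atc_settings, bench_system):
        res = run_atc(atc_settings, bench_system, tube_at(3.8))
        assert res.steady.ipeep <= 0.1

    def test_subatmospheric_expiratory_airway_pressure(
        self, atc_settings, bench_system
    ):
        """Compensating a narrow lumen during expiration drives the airway
        pressure below atmospheric while the tracheal pressure stays at or
        above PEEP."""
        res = run_atc(atc_settings, bench_system, tube_at(3.8))
        w = res.waveforms
        exp_mask = w["phase"].to_numpy() == 0
        assert w["paw_mbar"].to_numpy()[exp_mask].min() < 0.0
        assert w["ptrach_mbar"].to_numpy().min() >= atc_settings.peep - 0.01

    def test_pressure_cap_limits_tidal_volume(self, bench_system):
        """When the ceiling binds, inspiratory airway pressure saturates there
        and the delivered volume falls below the uncapped value."""
        uncapped = run_atc(
            VentilatorSettings(mode="atc", p_max=1e9), bench_system, tube_at(3.8)
        )
        capped = run_atc(
            VentilatorSettings(mode="atc", p_max=40.0), bench_system, tube_at(3.8)
        )
        assert capped.steady.p_aw_peak == pytest.approx(40.0, abs=1e-9)
        assert capped.steady.v_insp < uncapped.steady.v_insp - 10.0

    def test_zero_airway_resistance_rejected(self, atc_settings, reference_tube):
        with pytest.raises(ValueError):
            run_atc(atc_settings, RespiratorySystem(r_aw=0.0), reference_tube)


class TestAnalyzeBreaths:
    def test_square_flow_rectangle_volume(self):
        """A 0.5 L/s square inspiratory flow for 1 s integrates to 500 ml."""
        settings = VentilatorSettings(mode="vc", vt_set=500, t_in=1.0, t_ex=1.0)
        dt = 0.004
        n_in = n_ex = 250
        n_cycle = n_in + n_ex
        n = 2 * n_cycle + 1
        flow = np.zeros(n)
        phase = np.zeros(n, dtype=int)
        for b in range(2):
            s = b * n_cycle
            flow[s : s + n_in + 1] = 0.5
            phase[s : s + n_in] = 1
        t = np.arange(n) * dt
        w = pd.DataFrame(
            {
                "t_s": t, "flow_Lps": flow, "vol_ml": np.zeros(n),
                "paw_mbar": np.zeros(n), "ptrach_mbar": np.zeros(n),
                "palv_mbar": np.zeros(n), "phase": phase,
            }
        )
        breaths, steady = analyze_breaths(w, settings)
        assert breaths[0].v_insp == pytest.approx(500.0, abs=1.0)

    def test_tracheal_pressure_close_to_alveolar_at_end_expiration(
        self, pc_settings, bench_system
    ):
        """With a wide-open tube the end-expiratory flow is tiny, so the
        tracheal iPEEP proxy sits within 0.1 mbar of the alveolar value."""
        res = run_pc(pc_settings, bench_system, tube_at(20.0, has_scope=False))
        assert abs(res.steady.ipeep - res.steady.ipeep_alv) < 0.1

    def test_truncated_waveform_rejected(self, vc_settings, bench_system):
        res = run_vc(vc_settings, bench_system, tube_at(8.0))
        short = res.waveforms.iloc[:300]
        with pytest.raises(ValueError):
            analyze_breaths(short, vc_settings)


class TestValidation:
    def test_settings_invariants(self):
        with pytest.raises(ValueError):
            VentilatorSettings(mode="vc", t_in=0.0)
        with pytest.raises(ValueError):
            VentilatorSettings(mode="vc", vt_set=-1.0)
        with pytest.raises(ValueError):
            VentilatorSettings(mode="pc", ps=0.0)
        with pytest.raises(ValueError):
            VentilatorSettings(mode="vc", peep=10.0, p_max=5.0)

    def test_subatmospheric_default_follows_mode(self):
        assert not VentilatorSettings(mode="vc").allow_subatmospheric
        assert not VentilatorSettings(mode="pc").allow_subatmospheric
        assert VentilatorSettings(mode="atc").allow_subatmospheric

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(max_breaths=1)

    def test_too_coarse_dt_rejected(self, vc_settings, bench_system, reference_tube):
        with pytest.raises(ValueError):
            run_vc(vc_settings, bench_system, reference_tube, SimulationConfig(dt=0.1))
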