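"""Single-compartment simulation of mechanical ventilation through a tube.

The respiratory system is modelled as one elastic compartment (compliance
``C``, ml/mbar) behind a linear airway resistance (``R_aw``, mbar·s/L), fed
through the nonlinear endotracheal tube (Rohrer model).  At every instant the
pressure balance (equation of motion, passive patient)

    p_aw - dp_tube(V') - R_aw * V' - p_alv = 0,    p_alv = V / C - p_mus

determines the flow algebraically; the only dynamic state is the compartment
volume, advanced by trapezoidal integration at a fixed time step (default
0.004 s, i.e. 250 Hz).  Three ventilation modes are provided:

* **VC** (volume-controlled): constant square inspiratory flow delivering the
  set tidal volume over ``t_in``; passive exhalation against PEEP.
* **PC** (pressure-controlled): constant inspiratory airway pressure
  ``PEEP + PS`` (optionally ramped); passive exhalation against PEEP.
* **ATC** (automatic tube compensation): the ventilator servo-controls the
  airway pressure so that the *tracheal* pressure follows a triangular target
  ramp, cancelling the tube's resistive pressure drop in both directions; the
  applied pressure may go sub-atmospheric and is clamped at ``p_max``.

Breaths repeat until the end-expiratory tracheal pressure (intrinsic PEEP)
changes by less than a tolerance between consecutive breaths, or a breath cap
is reached.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .resistance import RohrerModel, rohrer_dp, flow_from_driving_pressure

PHASE_INSP = 1
PHASE_EXP = 0

_ML_PER_L = 1000.0


class Mode(str, Enum):
    VC = "vc"
    PC = "pc"
    ATC = "atc"


@dataclass(frozen=True)
class RespiratorySystem:
    """Passive single-compartment respiratory mechanics.

    compliance : ml/mbar, r_aw : mbar·s/L, p_mus : mbar (respiratory-muscle
    pressure, 0 for a passive patient), v_rest : ml (volume offset at zero
    elastic recoil).
    """

    compliance: float = 50.0
    r_aw: float = 2.0
    p_mus: float = 0.0
    v_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ValueError("compliance must be positive")
        if self.r_aw < 0:
            raise ValueError("airway resistance must be non-negative")

    def p_alv(self, volume_ml: float) -> float:
        return (volume_ml - self.v_rest) / self.compliance - self.p_mus


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator configuration for one run.

    ``vt_set`` (ml) applies in VC; ``ps`` (mbar above PEEP) in PC;
    ``atc_target_peak`` (mbar above PEEP) in ATC.  ``r_valve`` is a linear
    expiratory valve/circuit resistance in series with the tube during
    passive exhalation.  ``allow_subatmospheric`` defaults to True only in
    ATC mode (commercial ventilators cannot deliver negative pressure).
    """

    mode: Mode = Mode.VC
    vt_set: float = 500.0
    peep: float = 0.0
    ps: float = 10.0
    t_in: float = 1.8
    t_ex: float = 2.2
    ramp_time: float = 0.0
    atc_target_peak: float = 10.0
    p_max: float = 80.0
    allow_subatmospheric: bool | None = None
    r_valve: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if self.t_in <= 0 or self.t_ex <= 0:
            raise ValueError("inspiratory and expiratory times must be positive")
        if self.mode is Mode.VC and self.vt_set <= 0:
            raise ValueError("VC mode requires a positive set tidal volume")
        if self.mode is Mode.PC and self.ps <= 0:
            raise ValueError("PC mode requires a positive pressure support")
        if self.p_max <= self.peep:
            raise ValueError("pressure ceiling must exceed PEEP")
        if self.r_valve < 0 or self.ramp_time < 0:
            raise ValueError("r_valve and ramp_time must be non-negative")
        if self.allow_subatmospheric is None:
            object.__setattr__(
                self, "allow_subatmospheric", self.mode is Mode.ATC
            )

    @property
    def respiratory_rate(self) -> float:
        """Breaths per minute implied by the cycle timing."""
        return 60.0 / (self.t_in + self.t_ex)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings: fixed step ``dt`` (s), breath cap, steady-state
    tolerance on breath-to-breath intrinsic-PEEP change (mbar)."""

    dt: float = 0.004
    max_breaths: int = 100
    steady_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_breaths < 2:
            raise ValueError("max_breaths must be at least 2")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be positive")


@dataclass(frozen=True)
class BreathResult:
    """Per-breath summary metrics."""

    index: int
    v_insp: float  # ml, inspired volume (integral of positive flow, insp phase)
    v_exp: float  # ml, expired volume (integral of -flow, exp phase)
    ipeep: float  # mbar, end-expiratory tracheal pressure (measured proxy)
    ipeep_alv: float  # mbar, end-expiratory alveolar pressure
    p_aw_peak: float  # mbar
    p_aw_min: float  # mbar
    p_alv_peak: float  # mbar


@dataclass(frozen=True)
class SteadySummary:
    """Summary of the final (steady-state) breath."""

    converged: bool
    n_breaths: int
    v_insp: float
    v_exp: float
    ipeep: float
    ipeep_alv: float
    p_aw_peak: float
    p_aw_min: float
    p_alv_peak: float
    n_over_pmax: int  # samples whose airway pressure exceeded p_max


@dataclass
class SimulationResult:
    """Waveforms plus per-breath and steady-state summaries.

    ``waveforms`` is a DataFrame with columns
    ``t_s, flow_Lps, vol_ml, paw_mbar, ptrach_mbar, palv_mbar, phase``.
    """

    waveforms: pd.DataFrame
    breaths: list[BreathResult]
    steady: SteadySummary
    settings: VentilatorSettings
    system: RespiratorySystem
    tube: RohrerModel
    config: SimulationConfig

    def summary(self) -> str:
        s = self.steady
        buf = io.StringIO()
        buf.write(f"Mode {self.settings.mode.value.upper()}: ")
        buf.write(f"{'converged' if s.converged else 'NOT converged'} "
                  f"after {s.n_breaths} breaths\n")
        buf.write(f"  steady tidal volume   {s.v_insp:8.1f} ml\n")
        buf.write(f"  intrinsic PEEP        {s.ipeep:8.2f} mbar (tracheal)"
                  f"  [{s.ipeep_alv:.2f} alveolar]\n")
        buf.write(f"  peak airway pressure  {s.p_aw_peak:8.1f} mbar\n")
        buf.write(f"  min airway pressure   {s.p_aw_min:8.1f} mbar\n")
        buf.write(f"  peak alveolar pressure{s.p_alv_peak:8.1f} mbar\n")
        if s.n_over_pmax:
            buf.write(f"  WARNING: airway pressure exceeded the "
                      f"{self.settings.p_max:.0f} mbar ceiling on "
                      f"{s.n_over_pmax} samples\n")
        return buf.getvalue()


def _steps_per_phase(settings: VentilatorSettings, dt: float) -> tuple[int, int]:
    n_in = int(round(settings.t_in / dt))
    n_ex = int(round(settings.t_ex / dt))
    if n_in < 50 or n_ex < 50:
        raise ValueError(
            f"dt={dt} too coarse for t_in={settings.t_in}, t_ex={settings.t_ex}: "
            "need at least 50 steps per phase"
        )
    return n_in, n_ex


def _solve_volume_step(v_i, f_i, flow_of_volume, dt):
    """Advance volume by an implicit trapezoid step.

    Solves v = v_i + 0.5*(f_i + g(v))*dt*1000 by fixed-point iteration; the
    map is strongly contractive because dt << C * (R_aw + k1).
    """
    half = 0.5 * dt * _ML_PER_L
    v = v_i + f_i * dt * _ML_PER_L  # explicit Euler predictor
    for _ in range(100):
        f_new = flow_of_volume(v)
        v_next = v_i + half * (f_i + f_new)
        if abs(v_next - v) < 1e-12 * max(1.0, abs(v_next)):
            v = v_next
            break
        v = v_next
    return v, flow_of_volume(v)


class VentilationModel:
    """Mechanical-ventilation simulation through a nonlinear tube.

    Parameters
    ----------
    settings : VentilatorSettings
        Mode and ventilator configuration.
    system : RespiratorySystem
        Patient respiratory mechanics.
    tube : RohrerModel
        Pressure–flow model of the tube(–scope) combination.
    config : SimulationConfig, optional
        Numerical settings.

    Examples
    --------
    >>> from bronchosim import *
    >>> tube = scaling_law_model(TubeScopeGeometry.from_effective_diameter(7.5))
    >>> res = VentilationModel(VentilatorSettings(mode="pc"), RespiratorySystem(),
    ...                        tube).simulate()
    >>> round(res.steady.v_insp / 10) * 10
    500
    """

    def __init__(
        self,
        settings: VentilatorSettings,
        system: RespiratorySystem,
        tube: RohrerModel,
        config: SimulationConfig | None = None,
    ) -> None:
        self.settings = settings
        self.system = system
        self.tube = tube
        self.config = config or SimulationConfig()
        if settings.mode is Mode.ATC and system.r_aw == 0:
            raise ValueError(
                "ATC requires a positive airway resistance: the ideal "
                "controller computes flow as (target - p_alv) / R_aw"
            )

    # -- boundary conditions ------------------------------------------------

    def _insp_flow_vc(self) -> float:
        return self.settings.vt_set / (_ML_PER_L * self.settings.t_in)

    def _pc_source_pressure(self, t_in_phase: float) -> float:
        st = self.settings
        if st.ramp_time > 0 and t_in_phase < st.ramp_time:
            return st.peep + st.ps * t_in_phase / st.ramp_time
        return st.peep + st.ps

    def _atc_target(self, t_in_breath: float) -> float:
        st = self.settings
        if t_in_breath <= st.t_in:
            frac = t_in_breath / st.t_in
            return st.peep + st.atc_target_peak * frac
        frac = (t_in_breath - st.t_in) / st.t_ex
        return st.peep + st.atc_target_peak * (1.0 - frac)

    def _atc_step_quantities(self, v: float, target: float):
        """Ideal-controller flow and airway pressure for one ATC sample,
        with the pressure clamped into the deliverable range."""
        st, sys_, tube = self.settings, self.system, self.tube
        p_alv = sys_.p_alv(v)
        flow = (target - p_alv) / sys_.r_aw
        p_aw = target + rohrer_dp(tube, flow)
        p_floor = -np.inf if st.allow_subatmospheric else 0.0
        if p_aw > st.p_max:
            p_aw = st.p_max
            flow = flow_from_driving_pressure(tube, sys_.r_aw, p_aw - p_alv)
        elif p_aw < p_floor:
            p_aw = p_floor
            flow = flow_from_driving_pressure(tube, sys_.r_aw, p_aw - p_alv)
        return flow, p_aw

    # -- main loop ----------------------------------------------------------

    def simulate(self) -> SimulationResult:
        st, sys_, tube, cfg = self.settings, self.system, self.tube, self.config
        dt = cfg.dt
        n_in, n_ex = _steps_per_phase(st, dt)
        n_cycle = n_in + n_ex

        # state arrays, one breath appended at a time
        t_list: list[np.ndarray] = []
        f_list: list[np.ndarray] = []
        v_list: list[np.ndarray] = []
        paw_list: list[np.ndarray] = []
        phase_list: list[np.ndarray] = []

        v = sys_.v_rest + sys_.compliance * st.peep  # elastic equilibrium at PEEP
        f = 0.0
        breaths: list[BreathResult] = []
        converged = False
        t0 = 0.0
        prev_ipeep = None

        # sample 0
        first = True

        for b in range(cfg.max_breaths):
            tt = np.empty(n_cycle + (1 if first else 0))
            ff = np.empty_like(tt)
            vv = np.empty_like(tt)
            pw = np.empty_like(tt)
            ph = np.empty(tt.shape, dtype=int)
            k = 0
            if first:
                tt[0], ff[0], vv[0] = t0, f, v
                pw[0] = self._paw_sample(f, v, 0.0, PHASE_INSP)
                ph[0] = PHASE_INSP
                k = 1
                first = False

            for j in range(n_cycle):
                phase = PHASE_INSP if j < n_in else PHASE_EXP
                t_breath = (j + 1) * dt  # time within breath at the new sample
                v, f = self._advance(v, f, t_breath, phase, dt)
                tt[k] = t0 + t_breath
                ff[k] = f
                vv[k] = v
                pw[k] = self._paw_sample(f, v, t_breath, phase)
                ph[k] = phase
                k += 1

            t0 += n_cycle * dt
            t_list.append(tt)
            f_list.append(ff)
            v_list.append(vv)
            paw_list.append(pw)
            phase_list.append(ph)

            ipeep = sys_.p_alv(v) + sys_.r_aw * f  # end-expiratory tracheal p.
            if prev_ipeep is not None and abs(ipeep - prev_ipeep) < cfg.steady_tol:
                converged = True
            prev_ipeep = ipeep
            if converged:
                break

        t = np.concatenate(t_list)
        flow = np.concatenate(f_list)
        vol = np.concatenate(v_list)
        paw = np.concatenate(paw_list)
        phase = np.concatenate(phase_list)
        palv = (vol - sys_.v_rest) / sys_.compliance - sys_.p_mus
        ptrach = palv + sys_.r_aw * flow

        waveforms = pd.DataFrame(
            {
                "t_s": t,
                "flow_Lps": flow,
                "vol_ml": vol,
                "paw_mbar": paw,
                "ptrach_mbar": ptrach,
                "palv_mbar": palv,
                "phase": phase,
            }
        )
        breaths, steady = analyze_breaths(
            waveforms, st, steady_tol=cfg.steady_tol, converged=converged
        )
        return SimulationResult(
            waveforms=waveforms,
            breaths=breaths,
            steady=steady,
            settings=st,
            system=sys_,
            tube=tube,
            config=cfg,
        )

    def _advance(self, v, f, t_breath, phase, dt):
        st, sys_, tube = self.settings, self.system, self.tube
        mode = st.mode
        if mode is Mode.VC and phase == PHASE_INSP:
            f_new = self._insp_flow_vc()
            v_new = v + 0.5 * (f + f_new) * dt * _ML_PER_L
            return v_new, f_new
        if mode is Mode.ATC:
            target = self._atc_target(t_breath)

            def g(vol):
                return self._atc_step_quantities(vol, target)[0]

            return _solve_volume_step(v, f, g, dt)
        # passive pressure boundary (PC inspiration, VC/PC expiration)
        if phase == PHASE_INSP:  # PC only
            p_src = self._pc_source_pressure(t_breath)
            r_series = sys_.r_aw
        else:
            p_src = st.peep
            r_series = sys_.r_aw + st.r_valve

        def g(vol):
            return flow_from_driving_pressure(
                tube, r_series, p_src - sys_.p_alv(vol)
            )

        return _solve_volume_step(v, f, g, dt)

    def _paw_sample(self, f, v, t_breath, phase) -> float:
        """Airway pressure (at the tube inlet) for a stored sample."""
        st, sys_, tube = self.settings, self.system, self.tube
        p_alv = sys_.p_alv(v)
        if st.mode is Mode.ATC:
            target = self._atc_target(t_breath)
            return self._atc_step_quantities(v, target)[1]
        if st.mode is Mode.VC and phase == PHASE_INSP:
            return p_alv + sys_.r_aw * f + rohrer_dp(tube, f)
        if phase == PHASE_INSP:  # PC
            return self._pc_source_pressure(t_breath)
        return st.peep - st.r_valve * f  # passive exhalation via the valve


def analyze_breaths(
    waveforms: pd.DataFrame,
    settings: VentilatorSettings,
    steady_tol: float = 0.01,
    converged: bool | None = None,
) -> tuple[list[BreathResult], SteadySummary]:
    """Segment a waveform table into breaths and summarise each.

    Inspired volume is the trapezoidal integral of positive flow over the
    inspiration phase; expired volume the integral of negative flow over
    expiration.  Intrinsic PEEP is the tracheal pressure at the last
    expiratory sample of each breath (the measured proxy for alveolar
    pressure); the alveolar value is reported alongside.

    If ``converged`` is None it is inferred from the last breath-to-breath
    iPEEP change vs ``steady_tol``.
    """
    t = waveforms["t_s"].to_numpy()
    if len(t) < 3:
        raise ValueError("waveform too short to contain a breath")
    dt = t[1] - t[0]
    n_in = int(round(settings.t_in / dt))
    n_cycle = n_in + int(round(settings.t_ex / dt))
    n_breaths = (len(t) - 1) // n_cycle
    if n_breaths < 2:
        raise ValueError("waveforms must cover at least two full breaths")

    flow = waveforms["flow_Lps"].to_numpy()
    paw = waveforms["paw_mbar"].to_numpy()
    ptrach = waveforms["ptrach_mbar"].to_numpy()
    palv = waveforms["palv_mbar"].to_numpy()

    breaths: list[BreathResult] = []
    for b in range(n_breaths):
        s = b * n_cycle
        m = s + n_in  # last inspiration sample / first expiration sample
        e = s + n_cycle
        f_in = np.maximum(flow[s : m + 1], 0.0)
        f_ex = np.minimum(flow[m : e + 1], 0.0)
        v_insp = np.trapezoid(f_in, dx=dt) * _ML_PER_L
        v_exp = -np.trapezoid(f_ex, dx=dt) * _ML_PER_L
        breaths.append(
            BreathResult(
                index=b,
                v_insp=float(v_insp),
                v_exp=float(v_exp),
                ipeep=float(ptrach[e]),
                ipeep_alv=float(palv[e]),
                p_aw_peak=float(paw[s : e + 1].max()),
                p_aw_min=float(paw[s : e + 1].min()),
                p_alv_peak=float(palv[s : e + 1].max()),
            )
        )

    if converged is None:
        converged = (
            len(breaths) >= 2
            and abs(breaths[-1].ipeep - breaths[-2].ipeep) < steady_tol
        )
    last = breaths[-1]
    steady = SteadySummary(
        converged=bool(converged),
        n_breaths=len(breaths),
        v_insp=last.v_insp,
        v_exp=last.v_exp,
        ipeep=last.ipeep,
        ipeep_alv=last.ipeep_alv,
        p_aw_peak=last.p_aw_peak,
        p_aw_min=last.p_aw_min,
        p_alv_peak=last.p_alv_peak,
        n_over_pmax=int((paw > settings.p_max).sum()),
    )
    return breaths, steady


def step(
    volume_ml: float,
    system: RespiratorySystem,
    tube: RohrerModel,
    *,
    p_aw_applied: float | None = None,
    flow_applied: float | None = None,
    r_extra: float = 0.0,
) -> tuple[float, float, float, float]:
    """One algebraic evaluation of the instantaneous pressure balance.

    Exactly one boundary condition must be given.  With an applied airway
    pressure the flow is solved (closed form) from

        p_aw - dp_tube(V') - (R_aw + r_extra) * V' - p_alv = 0 ;

    with an applied flow (VC inspiration) the airway pressure is
    back-computed.  Returns ``(flow, p_aw, p_trach, p_alv)``.
    """
    if (p_aw_applied is None) == (flow_applied is None):
        raise ValueError("supply exactly one of p_aw_applied or flow_applied")
    p_alv = system.p_alv(volume_ml)
    if p_aw_applied is not None:
        flow = flow_from_driving_pressure(
            tube, system.r_aw + r_extra, p_aw_applied - p_alv
        )
        p_aw = p_aw_applied
    else:
        flow = flow_applied
        p_aw = p_alv + (system.r_aw + r_extra) * flow + rohrer_dp(tube, flow)
    p_trach = p_alv + system.r_aw * flow
    return flow, p_aw, p_trach, p_alv


# -- thin mode-checked wrappers --------------------------------------------


def _run_mode(mode, settings, system, tube, config):
    if settings.mode is not mode:
        raise ValueError(f"settings.mode is {settings.mode.value!r}, expected {mode.value!r}")
    return VentilationModel(settings, system, tube, config).simulate()


def run_vc(settings, system, tube, config=None) -> SimulationResult:
    """Run a volume-controlled simulation (square inspiratory flow)."""
    return _run_mode(Mode.VC, settings, system, tube, config)


def run_pc(settings, system, tube, config=None) -> SimulationResult:
    """Run a pressure-controlled simulation (constant inspiratory pressure)."""
    return _run_mode(Mode.PC, settings, system, tube, config)


def run_atc(settings, system, tube, config=None) -> SimulationResult:
    """Run an automatic-tube-compensation simulation (tracheal-pressure ramp)."""
    return _run_mode(Mode.ATC, settings, system, tube, config)
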