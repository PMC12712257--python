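"""Parameter sweeps: ventilation outcomes vs effective diameter and settings.

These reproduce the package's headline outputs: intrinsic PEEP and tidal
volume as functions of the effective tube diameter for a given mode, and
sensitivity scans over compliance, respiratory rate, and I:E ratio.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import TubeScopeGeometry
from .resistance import ScalingLaw, scaling_law_model, secant_resistance
from .simulator import (
    RespiratorySystem,
    SimulationConfig,
    VentilationModel,
    VentilatorSettings,
)

SCENARIO_AXES = ("compliance", "rate", "ie_ratio")


def _run_point(settings, system, tube, config):
    res = VentilationModel(settings, system, tube, config).simulate()
    s = res.steady
    return s


def sweep_deff(
    settings: VentilatorSettings,
    system: RespiratorySystem,
    law: ScalingLaw | None = None,
    d_eff_grid: Sequence[float] = (),
    config: SimulationConfig | None = None,
    has_scope: bool = True,
) -> pd.DataFrame:
    """Steady-state outcomes over a grid of effective diameters.

    Each grid point builds the tube's Rohrer model from the scaling law
    (scope regime, beta = -5, by default) and runs the configured mode to
    steady state.  Returns a tidy table with one row per diameter:
    ``d_eff_mm, r_1Lps, ipeep_mbar, vt_ml, paw_peak_mbar, paw_min_mbar,
    converged``.
    """
    grid = np.asarray(list(d_eff_grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("d_eff grid must be non-empty and positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("d_eff grid must be strictly ascending")
    law = law or ScalingLaw()
    rows = []
    for d in grid:
        tube = scaling_law_model(
            TubeScopeGeometry.from_effective_diameter(d, has_scope=has_scope), law
        )
        s = _run_point(settings, system, tube, config)
        rows.append(
            {
                "d_eff_mm": d,
                "r_1Lps": secant_resistance(tube),
                "ipeep_mbar": s.ipeep,
                "vt_ml": s.v_insp,
                "paw_peak_mbar": s.p_aw_peak,
                "paw_min_mbar": s.p_aw_min,
                "converged": s.converged,
            }
        )
    return pd.DataFrame(rows)


def _settings_for_axis(
    base: VentilatorSettings, axis: str, value: float, system: RespiratorySystem,
    vt_target: float,
) -> tuple[VentilatorSettings, RespiratorySystem]:
    if axis == "compliance":
        system = replace(system, compliance=float(value))
        if base.mode.value == "pc":
            # keep the tidal-volume target fixed: PS = V_T,target / C
            base = replace(base, ps=vt_target / float(value))
        return base, system
    if axis == "rate":
        # rescale the whole cycle at fixed I:E; value in breaths/min
        t_tot = 60.0 / float(value)
        frac_in = base.t_in / (base.t_in + base.t_ex)
        return (
            replace(base, t_in=t_tot * frac_in, t_ex=t_tot * (1.0 - frac_in)),
            system,
        )
    if axis == "ie_ratio":
        # value = T_ex / T_in (an I:E of 1:3 -> value 3) at fixed rate
        t_tot = base.t_in + base.t_ex
        t_in = t_tot / (1.0 + float(value))
        return replace(base, t_in=t_in, t_ex=t_tot - t_in), system
    raise ValueError(f"unknown scenario axis {axis!r}; choose from {SCENARIO_AXES}")


def sweep_scenarios(
    base_settings: VentilatorSettings,
    system: RespiratorySystem,
    law: ScalingLaw | None = None,
    axis: str = "compliance",
    grid: Sequence[float] = (),
    d_eff: float | Iterable[float] = 5.0,
    config: SimulationConfig | None = None,
    vt_target: float = 500.0,
    has_scope: bool = True,
) -> pd.DataFrame:
    """Sensitivity scan along one scenario axis, per effective diameter.

    Axes: ``compliance`` (ml/mbar; in PC mode the pressure support is
    re-targeted as PS = V_T,target / C), ``rate`` (breaths/min, cycle rescaled
    at fixed I:E), ``ie_ratio`` (T_ex/T_in at fixed rate).  Returns rows of
    ``(axis, value, d_eff_mm, ipeep_mbar, vt_ml, converged)``.
    """
    values = np.asarray(list(grid), dtype=float)
    if values.size == 0:
        raise ValueError("scenario grid must be non-empty")
    d_list = [d_eff] if np.isscalar(d_eff) else list(d_eff)
    law = law or ScalingLaw()
    rows = []
    for value in values:
        settings, sys_v = _settings_for_axis(
            base_settings, axis, value, system, vt_target
        )
        for d in d_list:
            tube = scaling_law_model(
                TubeScopeGeometry.from_effective_diameter(d, has_scope=has_scope),
                law,
            )
            s = _run_point(settings, sys_v, tube, config)
            rows.append(
                {
                    "axis": axis,
                    "value": float(value),
                    "d_eff_mm": float(d),
                    "ipeep_mbar": s.ipeep,
                    "vt_ml": s.v_insp,
                    "converged": s.converged,
                }
            )
    return pd.DataFrame(rows)
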