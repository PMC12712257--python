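"""Synthetic bench data emulating the tube-resistance measurements.

The physical measurement drives a slow blower pressure ramp (about ±80 mbar
at zero flow) through the tube and records flow and the pressure drop across
the tube.  :func:`generate_sweep` reproduces that protocol numerically: the
driving pressure follows a triangular up/down ramp, the true flow comes from
inverting the Rohrer relation, and zero-mean Gaussian noise is added to both
channels.  :func:`generate_resistance_table` produces (effective diameter,
secant resistance at 1 L/s) tables from the scaling law with multiplicative
log-normal scatter, for exercising the power-law fitter end-to-end.

All generators are pure functions of their spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import PressureFlowSweep
from .geometry import TubeScopeGeometry
from .resistance import (
    RohrerModel,
    ScalingLaw,
    flow_from_driving_pressure,
    scaling_law_model,
    secant_resistance,
)


@dataclass(frozen=True)
class SweepSpec:
    """Specification of one synthetic pressure–flow sweep.

    ``max_dp`` is the peak driving pressure of the blower ramp (mbar, default
    80); noise standard deviations apply to the pressure (mbar) and flow
    (L/s) channels.
    """

    truth: RohrerModel
    max_dp: float = 80.0
    n_samples: int = 400
    noise_sd_p: float = 0.0
    noise_sd_f: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_dp <= 0:
            raise ValueError("max_dp must be positive")
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")
        if self.noise_sd_p < 0 or self.noise_sd_f < 0:
            raise ValueError("noise standard deviations must be non-negative")


def generate_sweep(spec: SweepSpec, label: str = "synthetic") -> PressureFlowSweep:
    """Synthesize one blower up/down ramp through the tube.

    The driving pressure traverses 0 -> +max_dp -> 0 -> -max_dp -> 0 with
    uniform spacing in pressure; the noise-free samples satisfy the Rohrer
    relation exactly.
    """
    phase = np.linspace(0.0, 4.0, spec.n_samples)
    knots_x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    knots_y = np.array([0.0, spec.max_dp, 0.0, -spec.max_dp, 0.0])
    dp_true = np.interp(phase, knots_x, knots_y)
    flow_true = np.array(
        [flow_from_driving_pressure(spec.truth, 0.0, dp) for dp in dp_true]
    )
    rng = np.random.default_rng(spec.seed)
    dp = dp_true + rng.normal(0.0, spec.noise_sd_p, dp_true.shape) if spec.noise_sd_p else dp_true
    flow = (
        flow_true + rng.normal(0.0, spec.noise_sd_f, flow_true.shape)
        if spec.noise_sd_f
        else flow_true
    )
    return PressureFlowSweep(flow=flow, dp=dp, label=label)


def sweep_to_frame(sweep: PressureFlowSweep) -> pd.DataFrame:
    """Reduced CSV dialect of a sweep (columns flow_Lps, dp_mbar)."""
    return pd.DataFrame({"flow_Lps": sweep.flow, "dp_mbar": sweep.dp})


def generate_resistance_table(
    law: ScalingLaw | None,
    geometries: Sequence[TubeScopeGeometry],
    rel_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Secant resistances at 1 L/s for a set of geometries, with scatter.

    The noise is multiplicative log-normal: R_obs = R_true * exp(eps),
    eps ~ N(0, rel_noise), matching the straight-line-plus-scatter appearance
    of measured resistances in double-logarithmic coordinates.  Columns:
    ``d_tube_mm, d_scope_mm, d_eff_mm, has_scope, r_1Lps``.
    """
    if len(geometries) == 0:
        raise ValueError("geometry list must be non-empty")
    if rel_noise < 0:
        raise ValueError("rel_noise must be non-negative")
    law = law or ScalingLaw()
    rng = np.random.default_rng(seed)
    rows = []
    for g in geometries:
        r = secant_resistance(scaling_law_model(g, law))
        if rel_noise:
            r *= float(np.exp(rng.normal(0.0, rel_noise)))
        rows.append(
            {
                "d_tube_mm": g.d_tube,
                "d_scope_mm": g.d_scope if g.d_scope is not None else np.nan,
                "d_eff_mm": g.d_eff,
                "has_scope": g.has_scope,
                "r_1Lps": r,
            }
        )
    return pd.DataFrame(rows)


# The tube/scope grid of the bench study: inner tube diameters 6-9 mm,
# bronchoscope shaft diameters 3.8 / 5.0 / 5.9 mm where they fit.
STANDARD_TUBES = (6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0)
STANDARD_SCOPES = (3.8, 5.0, 5.9)


def standard_geometries(with_scope: bool = True) -> list[TubeScopeGeometry]:
    """All feasible tube(-scope) combinations of the standard bench grid.

    A scope is considered to fit only when its shaft is more than 1 mm
    narrower than the tube lumen (a 6.0 mm tube only admits the small scope,
    a 6.5 mm tube the small and medium), giving 18 scoped combinations.
    """
    if not with_scope:
        return [TubeScopeGeometry(d) for d in STANDARD_TUBES]
    return [
        TubeScopeGeometry(d_tube, d_scope)
        for d_tube in STANDARD_TUBES
        for d_scope in STANDARD_SCOPES
        if d_scope < d_tube - 1.0
    ]
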