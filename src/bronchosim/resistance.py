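"""Nonlinear pressure–flow model of the endotracheal tube.

The pressure drop across an endotracheal tube (with or without an inserted
bronchoscope) is well described by the Rohrer equation,

    dp(V') = k1 * V' + sign(V') * k2 * (V' / V'0)**2 ,

with a linear (laminar-like) coefficient ``k1`` [mbar·s/L], a quadratic
(turbulent-like) coefficient ``k2`` [mbar], and a reference flow ``V'0``
(1 L/s throughout this package).  ``k1`` is shared between inspiration and
expiration; ``k2`` may differ between the two flow directions because of the
compression–expansion asymmetry at the tube tip.

Across tube–bronchoscope combinations both coefficients collapse onto a
single-parameter scaling law in the effective diameter ``D_eff``:

    dp = k1ref * (D_eff / D0)**beta * (V' + sign(V') * 4 * (V'/V'0)**2)

with ``k1ref = 0.72`` mbar, ``D0 = 10`` mm, and exponent ``beta = -3.6`` for
an unobstructed tube or ``-5`` with an inserted bronchoscope.  At the
reference diameter the secant resistance at 1 L/s is k1 + k2 = 5*k1 = 3.6
mbar·s/L.

Sign convention: positive flow is inspiratory (toward the lung), and an
inspiratory pressure drop is positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import TubeScopeGeometry

BETA_UNOBSTRUCTED = -3.6
BETA_WITH_SCOPE = -5.0


@dataclass(frozen=True)
class RohrerModel:
    """Rohrer coefficients of one tube(–scope) configuration.

    Attributes
    ----------
    k1 : float
        Linear coefficient, mbar·s/L; shared between flow directions.
    k2_insp, k2_exp : float
        Quadratic coefficients, mbar, for inspiratory (flow >= 0) and
        expiratory (flow < 0) flow.
    v_ref : float
        Reference flow V'0, L/s (default 1, so k1 + k2 is the pressure drop
        at 1 L/s).
    """

    k1: float
    k2_insp: float
    k2_exp: float
    v_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2_insp < 0 or self.k2_exp < 0:
            raise ValueError("Rohrer coefficients must be non-negative")
        if self.v_ref <= 0:
            raise ValueError("reference flow must be positive")

    @classmethod
    def symmetric(cls, k1: float, k2: float, v_ref: float = 1.0) -> "RohrerModel":
        return cls(k1=k1, k2_insp=k2, k2_exp=k2, v_ref=v_ref)

    def pressure_drop(self, flow):
        """Alias for :func:`rohrer_dp` as a method (array-aware)."""
        return rohrer_dp(self, flow)


@dataclass(frozen=True)
class ScalingLaw:
    """Power-law scaling of tube resistance with effective diameter.

    ``k1(D_eff) = k1_ref * (D_eff / d_ref)**beta`` and ``k2 = k2_over_k1 * k1``.
    ``beta`` defaults per regime: -3.6 for an unobstructed tube, -5 with a
    bronchoscope; set ``beta`` explicitly to force one exponent.
    """

    k1_ref: float = 0.72
    k2_over_k1: float = 4.0
    beta: float | None = None
    d_ref: float = 10.0

    def __post_init__(self) -> None:
        if self.k1_ref <= 0 or self.k2_over_k1 <= 0 or self.d_ref <= 0:
            raise ValueError("scaling-law amplitude, ratio and d_ref must be positive")
        if self.beta is not None and self.beta >= 0:
            raise ValueError("scaling exponent must be negative")

    def exponent_for(self, has_scope: bool) -> float:
        if self.beta is not None:
            return self.beta
        return BETA_WITH_SCOPE if has_scope else BETA_UNOBSTRUCTED


def rohrer_dp(model: RohrerModel, flow):
    """Pressure drop (mbar) across the tube at the given flow (L/s).

    Uses ``k2_insp`` for non-negative flow and ``k2_exp`` for negative flow;
    odd-symmetric when the two coincide.  Accepts scalars or arrays.
    """
    f = np.asarray(flow, dtype=float)
    k2 = np.where(f >= 0.0, model.k2_insp, model.k2_exp)
    dp = model.k1 * f + np.sign(f) * k2 * (f / model.v_ref) ** 2
    if np.isscalar(flow) or f.ndim == 0:
        return float(dp)
    return dp


def secant_resistance(model: RohrerModel, flow: float = 1.0) -> float:
    """Secant resistance dp(flow)/flow in mbar·s/L (default at 1 L/s).

    Positive for either flow direction; equals k1 + k2 at the reference flow
    with symmetric k2.
    """
    if flow == 0:
        raise ValueError("secant resistance is undefined at zero flow")
    return rohrer_dp(model, flow) / flow


def scaling_law_model(
    geom: TubeScopeGeometry, law: ScalingLaw | None = None
) -> RohrerModel:
    """Rohrer model predicted by the scaling law for a given geometry.

    The exponent follows the geometry's scope flag (-3.6 without, -5 with a
    bronchoscope) unless the law fixes ``beta``.  The law emits a symmetric
    quadratic coefficient k2 = k2_over_k1 * k1 (= 4 k1 by default).
    """
    law = law or ScalingLaw()
    beta = law.exponent_for(geom.has_scope)
    k1 = law.k1_ref * (geom.d_eff / law.d_ref) ** beta
    k2 = law.k2_over_k1 * k1
    return RohrerModel(k1=k1, k2_insp=k2, k2_exp=k2)


def flow_from_driving_pressure(
    model: RohrerModel, r_linear_extra: float, dp: float
) -> float:
    """Flow (L/s) through the tube in series with a linear resistance.

    Solves the sign-consistent quadratic

        sign(V') * k2 * (V'/v_ref)**2 + (k1 + r) * V' = dp

    in closed form; ``k2_insp`` applies for dp >= 0 and ``k2_exp`` for
    dp < 0 (flow and driving pressure always share a sign because the forward
    map is strictly increasing through zero).
    """
    if r_linear_extra < 0:
        raise ValueError("series linear resistance must be non-negative")
    if dp == 0.0:
        return 0.0
    sign = 1.0 if dp > 0 else -1.0
    k2 = model.k2_insp if dp > 0 else model.k2_exp
    a = k2 / (model.v_ref * model.v_ref)
    b = model.k1 + r_linear_extra
    mag = abs(dp)
    if a == 0.0:
        if b == 0.0:
            raise ValueError("zero total resistance: flow undefined for dp != 0")
        return sign * mag / b
    # positive root of a*f^2 + b*f - |dp| = 0, written to avoid cancellation
    disc = math.sqrt(b * b + 4.0 * a * mag)
    return sign * (2.0 * mag / (disc + b))
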