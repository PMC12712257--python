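"""Tube–bronchoscope geometry and the effective diameter.

When a bronchoscope is inserted into an endotracheal tube (ETT), gas flows
through the annular gap between the scope shaft and the tube wall.  For the
purpose of flow resistance, that annulus behaves like a circular tube with the
same open cross-sectional area, whose diameter is

    D_eff = sqrt(D_tube**2 - D_scope**2)

with ``D_tube`` the *inner* diameter of the ETT and ``D_scope`` the *outer*
shaft diameter of the bronchoscope (both in mm).  Without a scope,
``D_eff = D_tube``.  The effective diameter is the single geometric parameter
that determines the tube's pressure–flow behaviour: two different tube–scope
combinations with equal effective diameter produce identical flow and
pressure profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class GeometryError(ValueError):
    """Raised for impossible tube–scope geometries (zero or negative lumen)."""


def effective_diameter(d_tube: float, d_scope: float | None = None) -> float:
    """Effective inner diameter (mm) of a tube with an optional bronchoscope.

    Parameters
    ----------
    d_tube : float
        Inner diameter of the endotracheal tube, mm.  Must be positive.
    d_scope : float, optional
        Outer shaft diameter of the inserted bronchoscope, mm.  If omitted or
        None, the tube is unobstructed and ``d_tube`` is returned.

    Returns
    -------
    float
        Diameter (mm) of the circular tube with the same open cross section.

    Raises
    ------
    GeometryError
        If ``d_scope >= d_tube`` (no open lumen remains).
    ValueError
        If either diameter is not positive.
    """
    if not math.isfinite(d_tube) or d_tube <= 0:
        raise ValueError(f"tube diameter must be positive, got {d_tube!r}")
    if d_scope is None:
        return float(d_tube)
    if not math.isfinite(d_scope) or d_scope <= 0:
        raise ValueError(f"scope diameter must be positive, got {d_scope!r}")
    if d_scope >= d_tube:
        raise GeometryError(
            f"scope diameter {d_scope} mm >= tube diameter {d_tube} mm: "
            "no open lumen remains"
        )
    return math.sqrt(d_tube * d_tube - d_scope * d_scope)


@dataclass(frozen=True)
class TubeScopeGeometry:
    """An endotracheal tube with an optional inserted bronchoscope.

    Attributes
    ----------
    d_tube : float
        Inner tube diameter, mm.
    d_scope : float or None
        Bronchoscope outer shaft diameter, mm, or None if unobstructed.
    has_scope : bool
        Whether a scope is (treated as) inserted; controls which power-law
        regime applies.  Defaults to ``d_scope is not None`` but can be forced
        when the geometry is built from a bare effective diameter.
    d_eff : float
        Derived effective diameter, mm (computed, not settable).
    """

    d_tube: float
    d_scope: float | None = None
    has_scope: bool | None = None
    d_eff: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "d_eff", effective_diameter(self.d_tube, self.d_scope)
        )
        if self.has_scope is None:
            object.__setattr__(self, "has_scope", self.d_scope is not None)

    @classmethod
    def from_effective_diameter(
        cls, d_eff: float, has_scope: bool = True
    ) -> "TubeScopeGeometry":
        """Build a geometry directly from a known effective diameter.

        Used when only ``d_eff`` matters (e.g. a sweep grid).  ``has_scope``
        selects the power-law regime downstream; no scope diameter is
        fabricated.
        """
        return cls(d_tube=float(d_eff), d_scope=None, has_scope=has_scope)
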