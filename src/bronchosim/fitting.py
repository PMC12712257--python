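"""Estimation of Rohrer coefficients and the resistance–diameter power law.

Two small regression models in the statsmodels spirit: a model object is
constructed from data and ``fit()`` returns a results object carrying the
point estimates, their standard errors, residual diagnostics and a
``summary()`` table.

* :class:`RohrerRegression` — least squares of measured tube pressure drop on
  the Rohrer basis (linear + sign-consistent quadratic flow terms); the
  linear coefficient k1 is shared between inspiration and expiration while
  the quadratic coefficient k2 may be estimated per flow direction.
* :class:`PowerLawRegression` — ordinary least squares of log resistance on
  log diameter, estimating the amplitude (resistance at the reference
  diameter) and the scaling exponent.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .resistance import RohrerModel


class FitError(RuntimeError):
    """Raised when a regression design is degenerate (rank-deficient)."""


@dataclass(frozen=True)
class PressureFlowSweep:
    """A bench pressure–flow recording reduced to (flow, tube pressure drop).

    ``dp`` is the pressure difference across the tube, p_aw - p_trach, in
    mbar; ``flow`` in L/s, positive toward the lung.
    """

    flow: np.ndarray
    dp: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        flow = np.asarray(self.flow, dtype=float)
        dp = np.asarray(self.dp, dtype=float)
        if flow.shape != dp.shape or flow.ndim != 1:
            raise ValueError("flow and dp must be 1-D arrays of equal length")
        if flow.size < 10:
            raise ValueError("a sweep needs at least 10 samples")
        if not (np.all(np.isfinite(flow)) and np.all(np.isfinite(dp))):
            raise ValueError("sweep contains non-finite values")
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "dp", dp)

    @property
    def both_signs(self) -> bool:
        return bool(np.any(self.flow > 0) and np.any(self.flow < 0))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "PressureFlowSweep":
        """Build a sweep from a raw recording or a pre-reduced table.

        Accepts either columns ``flow_Lps, dp_mbar`` or the raw dialect
        ``time_s, flow_Lps, paw_mbar, ptrach_mbar`` (dp = paw - ptrach).
        """
        cols = set(df.columns)
        if {"flow_Lps", "dp_mbar"} <= cols:
            return cls(df["flow_Lps"].to_numpy(), df["dp_mbar"].to_numpy(), label)
        if {"flow_Lps", "paw_mbar", "ptrach_mbar"} <= cols:
            dp = df["paw_mbar"].to_numpy() - df["ptrach_mbar"].to_numpy()
            return cls(df["flow_Lps"].to_numpy(), dp, label)
        raise ValueError(
            "expected columns (flow_Lps, dp_mbar) or "
            "(time_s, flow_Lps, paw_mbar, ptrach_mbar); got "
            + ", ".join(map(str, df.columns))
        )


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    """Plain OLS with covariance; raises FitError on rank deficiency."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError(
            f"rank-deficient design (rank {rank} < {p}) for parameters {names}"
        )
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, resid, np.sqrt(np.diag(cov))


@dataclass
class RohrerFitResults:
    """Results of a Rohrer-equation fit."""

    params: dict[str, float]
    bse: dict[str, float]
    resid: np.ndarray
    nobs: int
    shared_k2: bool
    label: str = ""
    clipped: list[str] = field(default_factory=list)

    @property
    def resid_norm(self) -> float:
        return float(np.linalg.norm(self.resid))

    @property
    def rohrer_model(self) -> RohrerModel:
        p = self.params
        return RohrerModel(k1=p["k1"], k2_insp=p["k2_insp"], k2_exp=p["k2_exp"])

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Rohrer equation fit")
        if self.label:
            buf.write(f" [{self.label}]")
        buf.write(f"  (n = {self.nobs}, shared k2: {self.shared_k2})\n")
        for name in ("k1", "k2_insp", "k2_exp"):
            unit = "mbar·s/L" if name == "k1" else "mbar"
            buf.write(
                f"  {name:8s} {self.params[name]:10.4f} ± "
                f"{self.bse[name]:.4f}  {unit}\n"
            )
        buf.write(f"  residual norm {self.resid_norm:.4g} mbar\n")
        if self.clipped:
            buf.write(f"  note: clipped to zero: {', '.join(self.clipped)}\n")
        return buf.getvalue()


class RohrerRegression:
    """Least-squares fit of the Rohrer pressure–flow relation to a sweep.

    The design is linear in the coefficients: with s = sign(flow),

        dp = k1 * flow + k2_insp * [flow >= 0] * flow**2
                       - k2_exp  * [flow < 0]  * flow**2 .

    Parameters
    ----------
    sweep : PressureFlowSweep or pandas.DataFrame
        The measured pressure–flow samples.
    v_ref : float
        Reference flow of the Rohrer model, L/s.
    """

    def __init__(self, sweep, v_ref: float = 1.0) -> None:
        if isinstance(sweep, pd.DataFrame):
            sweep = PressureFlowSweep.from_dataframe(sweep)
        self.sweep = sweep
        self.v_ref = float(v_ref)

    def fit(self, shared_k2: bool = False) -> RohrerFitResults:
        """Estimate (k1, k2_insp, k2_exp); with ``shared_k2`` a single k2.

        Negative estimates are clipped to zero with a warning (the physical
        coefficients are non-negative).
        """
        f = self.sweep.flow
        dp = self.sweep.dp
        q = (f / self.v_ref) ** 2
        if shared_k2:
            X = np.column_stack([f, np.sign(f) * q])
            names = ["k1", "k2"]
        else:
            if not self.sweep.both_signs:
                raise FitError(
                    "separate inspiratory/expiratory k2 requires flow samples "
                    "of both signs; pass shared_k2=True for one-sided sweeps"
                )
            X = np.column_stack([f, np.where(f >= 0, q, 0.0), np.where(f < 0, -q, 0.0)])
            names = ["k1", "k2_insp", "k2_exp"]
        beta, resid, bse = _ols(X, dp, names)

        clipped = [n for n, b in zip(names, beta) if b < 0]
        if clipped:
            warnings.warn(
                f"negative Rohrer coefficient(s) clipped to zero: {clipped}",
                stacklevel=2,
            )
            beta = np.maximum(beta, 0.0)
        est = dict(zip(names, map(float, beta)))
        err = dict(zip(names, map(float, bse)))
        if shared_k2:
            est = {"k1": est["k1"], "k2_insp": est["k2"], "k2_exp": est["k2"]}
            err = {"k1": err["k1"], "k2_insp": err["k2"], "k2_exp": err["k2"]}
        return RohrerFitResults(
            params=est,
            bse=err,
            resid=resid,
            nobs=f.size,
            shared_k2=shared_k2,
            label=self.sweep.label,
            clipped=clipped,
        )


@dataclass
class PowerLawFitResults:
    """Results of the log–log resistance–diameter regression."""

    amplitude: float  # mbar·s/L at the reference diameter
    exponent: float
    bse: dict[str, float]
    resid_log: np.ndarray
    nobs: int
    d_ref: float

    def predict(self, d_eff) -> np.ndarray:
        return self.amplitude * (np.asarray(d_eff, dtype=float) / self.d_ref) ** self.exponent

    def summary(self) -> str:
        return (
            "Power-law fit R = A (D_eff/D0)^beta\n"
            f"  A    {self.amplitude:8.3f} ± {self.bse['amplitude']:.3f} mbar·s/L "
            f"(at D0 = {self.d_ref:g} mm)\n"
            f"  beta {self.exponent:8.3f} ± {self.bse['exponent']:.3f}\n"
            f"  log-residual RMS {np.sqrt(np.mean(self.resid_log**2)):.4g} "
            f"(n = {self.nobs})\n"
        )


class PowerLawRegression:
    """OLS of log resistance on log(effective diameter / reference diameter).

    The straight line in double-logarithmic coordinates corresponds to
    R = amplitude * (d_eff / d_ref)**exponent.
    """

    def __init__(self, d_eff, resistance, d_ref: float = 10.0) -> None:
        d = np.asarray(d_eff, dtype=float)
        r = np.asarray(resistance, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("d_eff and resistance must be 1-D of equal length")
        if d.size < 3:
            raise ValueError("need at least 3 points for a power-law fit")
        if np.any(d <= 0) or np.any(r <= 0):
            raise ValueError("diameters and resistances must be positive")
        self.d = d
        self.r = r
        self.d_ref = float(d_ref)

    def fit(self) -> PowerLawFitResults:
        x = np.log(self.d / self.d_ref)
        y = np.log(self.r)
        X = np.column_stack([np.ones_like(x), x])
        beta, resid, bse = _ols(X, y, ["log_amplitude", "exponent"])
        amplitude = float(np.exp(beta[0]))
        return PowerLawFitResults(
            amplitude=amplitude,
            exponent=float(beta[1]),
            # delta method for the amplitude standard error
            bse={"amplitude": amplitude * float(bse[0]), "exponent": float(bse[1])},
            resid_log=resid,
            nobs=x.size,
            d_ref=self.d_ref,
        )


def fit_rohrer(sweep, shared_k2: bool = False, v_ref: float = 1.0) -> RohrerFitResults:
    """Fit the Rohrer equation to a pressure–flow sweep (convenience wrapper)."""
    return RohrerRegression(sweep, v_ref=v_ref).fit(shared_k2=shared_k2)


def fit_power_law(points, d_ref: float = 10.0) -> PowerLawFitResults:
    """Fit R = A (d/d_ref)^beta to (d_eff, resistance-at-1-L/s) pairs.

    ``points`` may be a sequence of pairs, a 2-column array, or a DataFrame
    with columns ``d_eff_mm`` and ``r_1Lps``.
    """
    if isinstance(points, pd.DataFrame):
        d, r = points["d_eff_mm"].to_numpy(), points["r_1Lps"].to_numpy()
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (d_eff, resistance) pairs")
        d, r = arr[:, 0], arr[:, 1]
    return PowerLawRegression(d, r, d_ref=d_ref).fit()


def mape(measured, predicted) -> float:
    """Mean absolute percentage error, in percent.

    100/n * sum |measured_i - predicted_i| / |measured_i|.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.size == 0:
        raise ValueError("mape of an empty sequence is undefined")
    if m.shape != p.shape:
        raise ValueError("measured and predicted must have equal length")
    if np.any(m == 0):
        raise ValueError("mape undefined when a measured value is zero")
    return float(100.0 * np.mean(np.abs(m - p) / np.abs(m)))
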