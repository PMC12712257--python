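"""CSV readers/writers and run manifests.

Units are fixed package-wide (pressures in mbar, flow in L/s, volume in ml,
time in s, diameters in mm); file columns carry the unit in their name.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .fitting import PressureFlowSweep

WAVEFORM_COLUMNS = [
    "t_s", "flow_Lps", "vol_ml", "paw_mbar", "ptrach_mbar", "palv_mbar", "phase",
]


def read_sweep_csv(path) -> PressureFlowSweep:
    """Read a pressure–flow sweep CSV in either supported dialect.

    Raw recordings (``time_s, flow_Lps, paw_mbar, ptrach_mbar``) are reduced
    by dp = paw - ptrach; pre-reduced files need ``flow_Lps, dp_mbar``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or malformed CSV") from exc
    try:
        return PressureFlowSweep.from_dataframe(df, label=path.stem)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_sweep_csv(sweep: PressureFlowSweep, path) -> None:
    pd.DataFrame({"flow_Lps": sweep.flow, "dp_mbar": sweep.dp}).to_csv(
        path, index=False
    )


def write_waveforms_csv(result, path) -> None:
    """Write simulation waveforms (SimulationResult or DataFrame)."""
    df = result.waveforms if hasattr(result, "waveforms") else result
    df.to_csv(path, index=False, columns=WAVEFORM_COLUMNS)


def coefficients_frame(entries) -> pd.DataFrame:
    """Tabulate fitted Rohrer coefficients.

    ``entries`` is a sequence of (label_tube, label_scope, RohrerFitResults
    or RohrerModel)-like triples; mirrors the layout tube, scope, k1,
    k2_insp, k2_exp.
    """
    rows = []
    for tube_label, scope_label, fit in entries:
        model = fit.rohrer_model if hasattr(fit, "rohrer_model") else fit
        rows.append(
            {
                "tube": tube_label,
                "scope": scope_label,
                "k1_mbar_s_L": model.k1,
                "k2_insp_mbar": model.k2_insp,
                "k2_exp_mbar": model.k2_exp,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    """Record of one CLI run: command, resolved parameters, files touched.

    Serialized next to every output so any result can be regenerated by
    re-running the recorded command with the recorded configuration.
    """

    command: str
    config: dict
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
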