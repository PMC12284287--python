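"""Current-clamp sweep container and the sweep-table file dialect.

A sweep is one membrane-potential time series together with the injected
current waveform.  On disk a sweep is a CSV table with columns
``time_ms, voltage_mV, current_pA`` plus a JSON sidecar carrying
``sampling_rate_hz, protocol, holding_mV, cell_id, group``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: digitization range of the recordings the analyses expect (Hz)
SAMPLING_RANGE = (10_000.0, 20_000.0)

#: nominal holding potential (mV); larger deviations trigger a warning
HOLDING_MV = -70.0


@dataclass
class Sweep:
    time: np.ndarray  # ms
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA
    sampling_rate: float  # Hz
    holding_mV: float = HOLDING_MV
    protocol_id: str = "unknown"
    cell_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (self.time.size == self.voltage.size == self.current.size):
            raise ValueError("time, voltage and current must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not SAMPLING_RANGE[0] <= self.sampling_rate <= SAMPLING_RANGE[1]:
            warnings.warn(
                f"sampling rate {self.sampling_rate:g} Hz outside the expected "
                f"{SAMPLING_RANGE[0]:g}-{SAMPLING_RANGE[1]:g} Hz digitization range",
                stacklevel=2,
            )
        if abs(self.holding_mV - HOLDING_MV) > 5.0:
            warnings.warn(
                f"holding potential {self.holding_mV:g} mV deviates >5 mV from "
                f"the nominal {HOLDING_MV:g} mV",
                stacklevel=2,
            )

    @property
    def dt(self) -> float:
        """Sample period in ms."""
        return 1000.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return float(self.time[-1] - self.time[0]) + self.dt

    def __len__(self) -> int:
        return self.time.size


def write_sweep(sweep: Sweep, csv_path) -> Path:
    """Write a sweep table plus its JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "time_ms": sweep.time,
            "voltage_mV": sweep.voltage,
            "current_pA": sweep.current,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.6g")
    sidecar = {
        "sampling_rate_hz": sweep.sampling_rate,
        "protocol": sweep.protocol_id,
        "holding_mV": sweep.holding_mV,
        "cell_id": sweep.cell_id,
        "group": sweep.group,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path


def read_sweep(csv_path) -> Sweep:
    """Read a sweep table written by :func:`write_sweep`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return Sweep(
        time=df["time_ms"].to_numpy(),
        voltage=df["voltage_mV"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        sampling_rate=float(meta.get("sampling_rate_hz", 1000.0 / np.median(np.diff(df["time_ms"])))),
        holding_mV=float(meta.get("holding_mV", HOLDING_MV)),
        protocol_id=str(meta.get("protocol", "unknown")),
        cell_id=str(meta.get("cell_id", "")),
        group=str(meta.get("group", "")),
    )
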