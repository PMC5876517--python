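"""CSV/JSON readers and writers for traces, link logs and metrics.

Signal CSVs carry the header ``time_s,amplitude_mV``; link logs carry
``t_s,tx_dbm,rssi_dbm,received``.  All numeric output uses '.' decimals
regardless of locale (pandas defaults).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import BiquadCoefficients, SignalTrace
from .linksim import LinkRecord

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_annotations_json",
    "read_annotations_json",
    "write_coefficients_json",
    "read_coefficients_json",
    "write_link_csv",
    "read_link_csv",
]


def read_trace_csv(path: str | Path) -> SignalTrace:
    """Read a ``time_s,amplitude_mV`` CSV; fs is inferred from the time grid."""
    df = pd.read_csv(path)
    expected = ["time_s", "amplitude_mV"]
    if list(df.columns) != expected:
        raise ValueError(
            f"expected columns {expected}, got {list(df.columns)} in {path}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"need >= 2 samples to infer sampling rate in {path}")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"non-uniform time grid in {path}")
    fs = 1.0 / float(np.mean(dt))
    return SignalTrace(
        samples=df["amplitude_mV"].to_numpy(dtype=float), fs=fs, t0=float(t[0])
    )


def write_trace_csv(trace: SignalTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times(), "amplitude_mV": trace.samples}
    ).to_csv(path, index=False)


def write_annotations_json(r_peaks: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"r_peaks": [int(i) for i in np.asarray(r_peaks)]}, indent=2)
    )


def read_annotations_json(path: str | Path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    return np.asarray(data["r_peaks"], dtype=np.int64)


def write_coefficients_json(
    coeffs: BiquadCoefficients | Sequence[BiquadCoefficients], path: str | Path
) -> None:
    if isinstance(coeffs, BiquadCoefficients):
        payload: object = coeffs.to_dict()
    else:
        payload = [c.to_dict() for c in coeffs]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_coefficients_json(
    path: str | Path,
) -> BiquadCoefficients | list[BiquadCoefficients]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        return [BiquadCoefficients.from_dict(d) for d in data]
    return BiquadCoefficients.from_dict(data)


def write_link_csv(records: Sequence[LinkRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": [r.t for r in records],
            "tx_dbm": [r.tx_power for r in records],
            "rssi_dbm": [r.rssi for r in records],
            "received": [int(r.received) for r in records],
        }
    ).to_csv(path, index=False)


def read_link_csv(path: str | Path) -> list[LinkRecord]:
    df = pd.read_csv(path)
    return [
        LinkRecord(
            t=float(r.t_s),
            tx_power=float(r.tx_dbm),
            rssi=float(r.rssi_dbm),
            received=bool(r.received),
        )
        for r in df.itertuples()
    ]
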