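"""R-peak detection and heart-rate (BPM) estimation.

The detector is a minimal slope-energy scheme suited to template-like
ECG: the squared first difference of the signal is smoothed with a short
moving average, candidate beats are local maxima of that energy envelope
that exceed a fraction of its trailing running maximum and are separated
by a refractory interval, and each candidate is then refined to the
local amplitude maximum of the input trace.  Slope energy separates the
steep, narrow QRS complex from the taller-but-slow T wave by more than
an order of magnitude, and the relative threshold makes the detector
invariant to global amplitude scaling.

Heart rate is the median R-R interval converted to beats per minute:
``BPM = 60 * fs / median(diff(peaks))``.  At 250 samples/s a 60 BPM
rhythm has R peaks exactly 250 samples apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .filters import SignalTrace

__all__ = [
    "PeakParams",
    "QrsError",
    "TraceTooShortError",
    "InsufficientPeaksError",
    "detect_r_peaks",
    "estimate_bpm",
]


class QrsError(ValueError):
    """Detector/estimator input error."""


class TraceTooShortError(QrsError):
    """Trace shorter than the 1 s minimum the detector needs."""


class InsufficientPeaksError(QrsError):
    """Fewer than two peaks — no R-R interval to estimate BPM from."""


@dataclass(frozen=True)
class PeakParams:
    """Detector tuning.

    smoothing_window : s
        Moving-average length applied to the slope energy; also the
        half-width of the final amplitude-refinement search.
    threshold_fraction : of running max
        A candidate must reach this fraction of the trailing running
        maximum of the energy envelope.
    refractory : s
        Minimum separation between detected beats.
    running_max_window : s
        Centered window over which the running maximum adapts; centering
        (rather than a trailing window) keeps the threshold meaningful
        before the first beat, where a trailing window has seen nothing
        taller than the P wave yet.
    """

    smoothing_window: float = 0.10
    threshold_fraction: float = 0.5
    refractory: float = 0.20
    running_max_window: float = 2.0

    def validate(self) -> None:
        for name in (
            "smoothing_window",
            "threshold_fraction",
            "refractory",
            "running_max_window",
        ):
            if getattr(self, name) <= 0:
                raise QrsError(f"{name} must be positive, got {getattr(self, name)}")


def detect_r_peaks(
    trace: SignalTrace, params: PeakParams = PeakParams()
) -> np.ndarray:
    """Detect R-peak sample indices (0-based, strictly increasing).

    Raises :class:`TraceTooShortError` for traces under 1 s.  A flat
    (constant) trace yields an empty array, not an error.
    """
    params.validate()
    fs = trace.fs
    x = trace.samples
    if x.size < fs:
        raise TraceTooShortError(
            f"need >= 1 s of signal ({int(fs)} samples), got {x.size}"
        )

    # slope energy: squared first difference, then short moving average
    energy = np.zeros_like(x)
    energy[1:] = np.diff(x) ** 2
    w = max(1, int(round(params.smoothing_window * fs)))
    envelope = np.convolve(energy, np.ones(w) / w, mode="same")

    run_max = (
        pd.Series(envelope)
        .rolling(
            max(1, int(round(params.running_max_window * fs))),
            min_periods=1,
            center=True,
        )
        .max()
        .to_numpy()
    )

    dist = max(1, int(round(params.refractory * fs)))
    candidates, _ = find_peaks(envelope, distance=dist)
    candidates = candidates[
        (run_max[candidates] > 0)
        & (envelope[candidates] >= params.threshold_fraction * run_max[candidates])
    ]

    # refine each candidate to the amplitude maximum of the input trace
    refined: list[int] = []
    for c in candidates:
        lo = max(0, c - w)
        hi = min(x.size, c + w + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        if not refined or p - refined[-1] >= dist:
            refined.append(p)
    return np.asarray(refined, dtype=np.int64)


def estimate_bpm(peaks: np.ndarray, fs: float) -> float:
    """Median R-R interval converted to beats per minute.

    The median is robust to a single missed or spurious beat; on a
    constant rhythm it coincides with the mean.
    """
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise InsufficientPeaksError(
            f"need >= 2 peaks to estimate BPM, got {peaks.size}"
        )
    rr = np.diff(peaks)
    return 60.0 * fs / float(np.median(rr))
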