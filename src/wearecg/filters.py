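"""Second-order (biquad) IIR filters for ECG denoising.

Design is by the bilinear transform with frequency prewarping
``K = tan(pi * f0 / fs)``, which maps the analog prototype cutoff exactly
onto the requested digital frequency.  Three kinds are supported:

* ``notch``    — unit-circle zeros at +-f0 (power-line rejection, 50/60 Hz),
* ``lowpass``  — 2nd-order Butterworth-style low pass,
* ``highpass`` — 2nd-order Butterworth-style high pass,

all sharing the quality factor ``Q`` (default 1/sqrt(2), the Butterworth
value, at which the low/high-pass -3 dB point lands exactly at f0).

Filtering is streamed through the Transposed Direct-Form II (TDF-II)
realization with two internal state variables ``w1, w2``:

    y[n]  = b0*x[n] + w1[n-1]
    w1[n] = b1*x[n] - a1*y[n] + w2[n-1]
    w2[n] = b2*x[n] - a2*y[n]

Coefficients are stored normalized with a0 = 1; all arithmetic is double
precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "FilterKind",
    "BiquadCoefficients",
    "FilterState",
    "SignalTrace",
    "FilterDesignError",
    "CutoffAliasError",
    "NonPositiveParameterError",
    "NonFiniteSampleError",
    "FrequencyRangeError",
    "CutoffSearchError",
    "design_biquad",
    "design_cascade",
    "step",
    "filter_signal",
    "frequency_response",
    "find_cutoff",
]

FilterKind = Literal["notch", "lowpass", "highpass"]

#: Butterworth quality factor, 1/sqrt(2); the -3 dB point of a 2nd-order
#: low/high-pass designed at this Q falls exactly on f0.
BUTTERWORTH_Q = 1.0 / math.sqrt(2.0)


class FilterDesignError(ValueError):
    """A biquad design request that cannot be satisfied."""


class CutoffAliasError(FilterDesignError):
    """Requested center/cutoff frequency at or above the Nyquist rate."""


class NonPositiveParameterError(FilterDesignError):
    """A design parameter (f0, Q, fs) that must be strictly positive is not."""


class NonFiniteSampleError(ValueError):
    """A NaN/inf sample reached the streaming filter."""


class FrequencyRangeError(ValueError):
    """Frequency outside [0, fs/2] passed to the response evaluator."""


class CutoffSearchError(ValueError):
    """find_cutoff could not bracket exactly one magnitude crossing."""


@dataclass(frozen=True)
class BiquadCoefficients:
    """Normalized biquad coefficients (a0 = 1) plus design metadata.

    ``b0, b1, b2`` are feedforward, ``a1, a2`` feedback.  ``f0`` is the
    notch center or -3 dB cutoff in Hz, ``q`` the quality factor, ``fs``
    the sampling rate the design targets.
    """

    b0: float
    b1: float
    b2: float
    a1: float
    a2: float
    kind: str
    f0: float
    q: float
    fs: float

    def is_stable(self) -> bool:
        """Stability triangle: both poles strictly inside the unit circle."""
        return abs(self.a2) < 1.0 and abs(self.a1) < 1.0 + self.a2

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "f0": self.f0,
            "q": self.q,
            "fs": self.fs,
            "b0": self.b0,
            "b1": self.b1,
            "b2": self.b2,
            "a1": self.a1,
            "a2": self.a2,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BiquadCoefficients":
        return cls(
            b0=float(d["b0"]),
            b1=float(d["b1"]),
            b2=float(d["b2"]),
            a1=float(d["a1"]),
            a2=float(d["a2"]),
            kind=str(d["kind"]),
            f0=float(d["f0"]),
            q=float(d["q"]),
            fs=float(d["fs"]),
        )


@dataclass(frozen=True)
class FilterState:
    """TDF-II internal delay variables; a fresh state is exactly (0, 0)."""

    w1: float = 0.0
    w2: float = 0.0


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled amplitude series (mV) with sampling rate fs (Hz)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64)
        )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


def design_biquad(
    kind: FilterKind, f0: float, q: float = BUTTERWORTH_Q, fs: float = 250.0
) -> BiquadCoefficients:
    """Design a notch / lowpass / highpass biquad by bilinear transform.

    Parameters
    ----------
    kind : {"notch", "lowpass", "highpass"}
    f0 : float
        Notch center or -3 dB cutoff frequency, Hz; must satisfy
        0 < f0 < fs/2.
    q : float
        Quality factor; 1/sqrt(2) gives the Butterworth response for
        lowpass/highpass.
    fs : float
        Sampling rate, Hz.

    Returns
    -------
    BiquadCoefficients
        Stable, a0-normalized coefficients.  A notch has exact zeros on
        the unit circle at +-f0 (|H(f0)| = 0) and unity DC gain.

    Raises
    ------
    CutoffAliasError
        If f0 >= fs/2 (the design would alias).
    NonPositiveParameterError
        If f0, q or fs is not strictly positive.
    """
    if fs <= 0:
        raise NonPositiveParameterError(f"fs must be > 0, got {fs}")
    if f0 <= 0:
        raise NonPositiveParameterError(f"f0 must be > 0, got {f0}")
    if q <= 0:
        raise NonPositiveParameterError(f"Q must be > 0, got {q}")
    if f0 >= fs / 2:
        raise CutoffAliasError(
            f"f0={f0} Hz is at/above Nyquist ({fs / 2} Hz) for fs={fs} Hz"
        )

    # prewarped analog frequency; w = f0/fs is the normalized cutoff
    k = math.tan(math.pi * f0 / fs)
    k2 = k * k
    norm = 1.0 / (1.0 + k / q + k2)
    a1 = 2.0 * (k2 - 1.0) * norm
    a2 = (1.0 - k / q + k2) * norm

    if kind == "notch":
        b0 = (1.0 + k2) * norm
        b1 = a1
        b2 = b0
    elif kind == "lowpass":
        b0 = k2 * norm
        b1 = 2.0 * b0
        b2 = b0
    elif kind == "highpass":
        b0 = norm
        b1 = -2.0 * norm
        b2 = norm
    else:
        raise FilterDesignError(
            f"unknown filter kind {kind!r}; expected notch|lowpass|highpass"
        )

    return BiquadCoefficients(
        b0=b0, b1=b1, b2=b2, a1=a1, a2=a2, kind=kind, f0=f0, q=q, fs=fs
    )


def design_cascade(
    fs: float = 250.0,
    notch_f0: float = 60.0,
    highpass_f0: float = 0.67,
    lowpass_f0: float = 100.0,
    q: float = BUTTERWORTH_Q,
) -> list[BiquadCoefficients]:
    """The full denoising chain: notch -> highpass -> lowpass.

    Defaults are the wearable-ECG chain: 60 Hz power-line notch, 0.67 Hz
    baseline-wander highpass, 100 Hz anti-noise lowpass at 250 SPS.
    """
    return [
        design_biquad("notch", notch_f0, q, fs),
        design_biquad("highpass", highpass_f0, q, fs),
        design_biquad("lowpass", lowpass_f0, q, fs),
    ]


def step(
    state: FilterState, coeffs: BiquadCoefficients, x: float
) -> tuple[float, FilterState]:
    """Advance the TDF-II recursion by one sample.

    Pure function of (state, coeffs, x); returns the output sample and
    the successor state.  Rejects non-finite input (propagating NaN
    through a downstream controller is unsafe).
    """
    if not math.isfinite(x):
        raise NonFiniteSampleError(f"non-finite input sample: {x!r}")
    y = coeffs.b0 * x + state.w1
    w1 = coeffs.b1 * x - coeffs.a1 * y + state.w2
    w2 = coeffs.b2 * x - coeffs.a2 * y
    return y, FilterState(w1=w1, w2=w2)


def filter_signal(
    trace: SignalTrace,
    coeffs: BiquadCoefficients | Iterable[BiquadCoefficients],
    initial_state: FilterState | None = None,
) -> SignalTrace:
    """Filter a whole trace by folding :func:`step` left to right.

    ``coeffs`` may be a single biquad or a cascade (applied in order,
    each stage starting from a fresh zero state; ``initial_state`` seeds
    the first stage only).  An empty trace passes through unchanged.
    Output length and sampling rate equal the input's.
    """
    if isinstance(coeffs, BiquadCoefficients):
        stages = [coeffs]
    else:
        stages = list(coeffs)

    x = trace.samples
    if x.size == 0:
        return SignalTrace(samples=x.copy(), fs=trace.fs, t0=trace.t0)
    if not np.all(np.isfinite(x)):
        raise NonFiniteSampleError("trace contains non-finite samples")

    for i, c in enumerate(stages):
        st = initial_state if (i == 0 and initial_state is not None) else FilterState()
        y = np.empty_like(x)
        b0, b1, b2, a1, a2 = c.b0, c.b1, c.b2, c.a1, c.a2
        w1, w2 = st.w1, st.w2
        for n in range(x.size):
            xn = x[n]
            yn = b0 * xn + w1
            w1 = b1 * xn - a1 * yn + w2
            w2 = b2 * xn - a2 * yn
            y[n] = yn
        x = y
    return SignalTrace(samples=x, fs=trace.fs, t0=trace.t0)


def frequency_response(
    coeffs: BiquadCoefficients, f: float | np.ndarray
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Evaluate H(z) on the unit circle at z = exp(i*2*pi*f/fs).

    Returns (magnitude, phase in radians); accepts a scalar frequency or
    an array.  Frequencies must lie in [0, fs/2].
    """
    f_arr = np.asarray(f, dtype=np.float64)
    if np.any(f_arr < 0) or np.any(f_arr > coeffs.fs / 2):
        raise FrequencyRangeError(
            f"frequency outside [0, {coeffs.fs / 2}] Hz: {f!r}"
        )
    z = np.exp(1j * 2.0 * np.pi * f_arr / coeffs.fs)
    zi = 1.0 / z
    num = coeffs.b0 + coeffs.b1 * zi + coeffs.b2 * zi * zi
    den = 1.0 + coeffs.a1 * zi + coeffs.a2 * zi * zi
    h = num / den
    mag = np.abs(h)
    phase = np.angle(h)
    if np.isscalar(f) or f_arr.ndim == 0:
        return float(mag), float(phase)
    return mag, phase


def find_cutoff(
    coeffs: BiquadCoefficients,
    level: float = BUTTERWORTH_Q,
    band: tuple[float, float] = (0.01, 124.0),
    *,
    f_tol: float = 1e-6,
    n_scan: int = 512,
) -> float:
    """Locate the frequency where |H(f)| crosses ``level`` within ``band``.

    A coarse scan brackets the crossing (erroring if none or more than
    one sign change is found), then bisection refines it to ``f_tol`` Hz.
    """
    lo, hi = band
    if not (0 <= lo < hi <= coeffs.fs / 2):
        raise FrequencyRangeError(f"band {band} not inside [0, {coeffs.fs / 2}]")

    grid = np.linspace(lo, hi, n_scan)
    mags, _ = frequency_response(coeffs, grid)
    g = np.asarray(mags) - level
    signs = np.sign(g)
    # a zero on the grid counts as a crossing at that point
    crossings = np.nonzero(np.diff(signs < 0))[0]
    if crossings.size == 0:
        raise CutoffSearchError(
            f"|H| never crosses {level} within band {band}"
        )
    if crossings.size > 1:
        raise CutoffSearchError(
            f"|H| crosses {level} more than once within band {band}"
        )

    a, b = grid[crossings[0]], grid[crossings[0] + 1]
    ga = float(frequency_response(coeffs, a)[0]) - level
    while b - a > f_tol:
        m = 0.5 * (a + b)
        gm = float(frequency_response(coeffs, m)[0]) - level
        if (ga < 0) == (gm < 0):
            a, ga = m, gm
        else:
            b = m
    return 0.5 * (a + b)
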