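"""Filter design and streaming-engine tests.

The independent design oracle is scipy's bilinear transform applied to
the analog prototypes (notch (s^2+K^2)/(s^2+sK/Q+K^2), and the
Butterworth low/high-pass), plus scipy.signal.butter and lfilter as
cross-checks of the designed response and of the streaming engine.
"""

import math

import numpy as np
import pytest
import scipy.signal as sig
from hypothesis import given, settings, strategies as st

from wearecg.filters import (
    BUTTERWORTH_Q,
    BiquadCoefficients,
    CutoffAliasError,
    CutoffSearchError,
    FilterState,
    FrequencyRangeError,
    NonFiniteSampleError,
    NonPositiveParameterError,
    SignalTrace,
    design_biquad,
    filter_signal,
    find_cutoff,
    frequency_response,
    step,
)

FS = 250.0


def reference_design(kind: str, f0: float, q: float, fs: float):
    """Independent oracle: scipy bilinear transform of the analog prototype
    prewarped at K = tan(pi*f0/fs) (the substitution s -> (1-z^-1)/(1+z^-1)
    corresponds to fs=1/2 in scipy's convention)."""
    k = math.tan(math.pi * f0 / fs)
    protos = {
        "notch": ([1.0, 0.0, k * k], [1.0, k / q, k * k]),
        "lowpass": ([k * k], [1.0, k / q, k * k]),
        "highpass": ([1.0, 0.0, 0.0], [1.0, k / q, k * k]),
    }
    b, a = sig.bilinear(*protos[kind], fs=0.5)
    return b, a


def direct_difference_equation(coeffs, x):
    """Brute-force y[n] = b0 x[n] + b1 x[n-1] + b2 x[n-2] - a1 y[n-1] - a2 y[n-2]."""
    y = np.zeros(len(x))
    for n in range(len(x)):
        acc = coeffs.b0 * x[n]
        if n >= 1:
            acc += coeffs.b1 * x[n - 1] - coeffs.a1 * y[n - 1]
        if n >= 2:
            acc += coeffs.b2 * x[n - 2] - coeffs.a2 * y[n - 2]
        y[n] = acc
    return y


class TestDesign:
    @pytest.mark.parametrize(
        "kind,f0",
        [("notch", 60.0), ("notch", 50.0), ("lowpass", 100.0), ("highpass", 0.67)],
    )
    def test_matches_reference_bilinear_design(self, kind, f0):
        c = design_biquad(kind, f0, BUTTERWORTH_Q, FS)
        b, a = reference_design(kind, f0, BUTTERWORTH_Q, FS)
        np.testing.assert_allclose([c.b0, c.b1, c.b2], b, atol=1e-9)
        np.testing.assert_allclose([1.0, c.a1, c.a2], a, atol=1e-9)

    @pytest.mark.parametrize("kind,btype", [("lowpass", "low"), ("highpass", "high")])
    def test_matches_scipy_butterworth(self, kind, btype):
        f0 = 100.0 if kind == "lowpass" else 0.67
        c = design_biquad(kind, f0, BUTTERWORTH_Q, FS)
        b, a = sig.butter(2, f0, btype, fs=FS)
        np.testing.assert_allclose([c.b0, c.b1, c.b2], b, atol=1e-9)
        np.testing.assert_allclose([1.0, c.a1, c.a2], a, atol=1e-9)

    def test_powerline_notch_worked_values(self, notch60):
        # frozen from the analog-prototype oracle at f0=60, Q=0.707, fs=250
        k = math.tan(math.pi * 60.0 / 250.0)
        assert k == pytest.approx(0.93906, abs=1e-5)
        norm = 1.0 / (1.0 + k / 0.707 + k * k)
        assert norm == pytest.approx(0.31152, abs=1e-5)
        c = design_biquad("notch", 60.0, 0.707, 250.0)
        assert c.b0 == pytest.approx(0.5862290, abs=1e-6)
        assert c.b2 == c.b0
        assert c.b1 == pytest.approx(-0.0736192, abs=1e-6)
        assert c.a1 == c.b1
        assert c.a2 == pytest.approx(0.1724580, abs=1e-6)

    def test_notch_unity_dc_gain(self, notch60):
        c = notch60
        dc = (c.b0 + c.b1 + c.b2) / (1.0 + c.a1 + c.a2)
        assert dc == pytest.approx(1.0, abs=1e-12)

    def test_rejects_aliasing_cutoff(self):
        with pytest.raises(CutoffAliasError):
            design_biquad("notch", 125.0, 0.707, 250.0)

    @pytest.mark.parametrize(
        "kwargs", [{"f0": -1.0}, {"q": 0.0}, {"fs": -250.0}]
    )
    def test_rejects_nonpositive_parameters(self, kwargs):
        args = {"f0": 60.0, "q": 0.707, "fs": 250.0, **kwargs}
        with pytest.raises(NonPositiveParameterError):
            design_biquad("notch", args["f0"], args["q"], args["fs"])

    @given(
        kind=st.sampled_from(["notch", "lowpass", "highpass"]),
        f0=st.floats(0.1, 124.0),
        q=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_designed_filters_are_stable(self, kind, f0, q):
        c = design_biquad(kind, f0, q, FS)
        assert abs(c.a2) < 1.0
        assert abs(c.a1) < 1.0 + c.a2


class TestStep:
    def test_first_impulse_sample_is_b0(self, notch60):
        y, _ = step(FilterState(), notch60, 1.0)
        assert y == notch60.b0

    def test_zero_in_zero_out(self, notch60):
        y, state = step(FilterState(), notch60, 0.0)
        assert y == 0.0
        assert state == FilterState(0.0, 0.0)

    def test_impulse_response_matches_difference_equation(self, notch60):
        x = np.zeros(3)
        x[0] = 1.0
        expected = direct_difference_equation(notch60, x)
        state = FilterState()
        got = []
        for xn in x:
            y, state = step(state, notch60, xn)
            got.append(y)
        np.testing.assert_allclose(got, expected, atol=1e-15)

    def test_rejects_nonfinite_sample(self, notch60):
        with pytest.raises(NonFiniteSampleError):
            step(FilterState(), notch60, float("nan"))


class TestFilterSignal:
    def test_equals_repeated_step(self, notch60, rng):
        x = rng.normal(size=500)
        trace = SignalTrace(x, FS)
        batch = filter_signal(trace, notch60).samples
        state = FilterState()
        streamed = []
        for xn in x:
            y, state = step(state, notch60, xn)
            streamed.append(y)
        np.testing.assert_array_equal(batch, np.array(streamed))

    def test_tdf2_equals_difference_equation_10k(self, notch60, rng):
        x = rng.normal(size=10_000)
        y = filter_signal(SignalTrace(x, FS), notch60).samples
        y_ref = direct_difference_equation(notch60, x)
        assert np.max(np.abs(y - y_ref)) < 1e-9

    def test_matches_scipy_lfilter(self, highpass067, rng):
        x = rng.normal(size=5_000)
        y = filter_signal(SignalTrace(x, FS), highpass067).samples
        c = highpass067
        y_ref = sig.lfilter([c.b0, c.b1, c.b2], [1.0, c.a1, c.a2], x)
        assert np.max(np.abs(y - y_ref)) < 1e-9

    def test_linearity(self, notch60, rng):
        x = rng.normal(size=1_000)
        y1 = filter_signal(SignalTrace(3.7 * x, FS), notch60).samples
        y2 = 3.7 * filter_signal(SignalTrace(x, FS), notch60).samples
        np.testing.assert_allclose(y1, y2, rtol=1e-12, atol=1e-12)

    def test_fresh_states_give_bit_identical_output(self, notch60, rng):
        x = rng.normal(size=1_000)
        a = filter_signal(SignalTrace(x, FS), notch60).samples
        b = filter_signal(SignalTrace(x, FS), notch60).samples
        np.testing.assert_array_equal(a, b)

    def test_empty_trace_passes_through(self, notch60):
        out = filter_signal(SignalTrace(np.array([]), FS), notch60)
        assert len(out) == 0 and out.fs == FS

    def test_length_and_fs_preserved(self, lowpass100, rng):
        x = rng.normal(size=777)
        out = filter_signal(SignalTrace(x, FS), lowpass100)
        assert len(out) == 777 and out.fs == FS

    @pytest.mark.parametrize("kind,f0", [("notch", 60.0), ("highpass", 0.67), ("lowpass", 100.0)])
    def test_impulse_response_decays(self, kind, f0):
        c = design_biquad(kind, f0, BUTTERWORTH_Q, FS)
        x = np.zeros(10_051)
        x[0] = 1.0
        h = filter_signal(SignalTrace(x, FS), c).samples
        assert np.max(np.abs(h[10_001:])) < 1e-12

    def test_notch_passes_constant_input(self, notch60):
        x = np.full(5_000, 0.7)
        y = filter_signal(SignalTrace(x, FS), notch60).samples
        assert abs(y[-1] - 0.7) < 1e-6


class TestFrequencyResponse:
    def test_notch_null_at_center(self, notch60):
        mag, _ = frequency_response(notch60, 60.0)
        assert mag < 1e-12

    def test_notch_unity_at_dc_and_nyquist(self, notch60):
        assert frequency_response(notch60, 0.0)[0] == pytest.approx(1.0, abs=1e-12)
        assert frequency_response(notch60, FS / 2)[0] == pytest.approx(1.0, abs=1e-12)

    def test_butterworth_passband_edges(self, lowpass100, highpass067):
        assert frequency_response(lowpass100, 0.0)[0] == pytest.approx(1.0, abs=1e-12)
        assert frequency_response(highpass067, FS / 2)[0] == pytest.approx(1.0, abs=1e-12)

    def test_minus_3db_at_cutoff(self, lowpass100, highpass067):
        for c in (lowpass100, highpass067):
            mag, _ = frequency_response(c, c.f0)
            assert mag == pytest.approx(1.0 / math.sqrt(2.0), abs=1e-9)

    def test_rejects_out_of_range_frequency(self, notch60):
        with pytest.raises(FrequencyRangeError):
            frequency_response(notch60, 130.0)
        with pytest.raises(FrequencyRangeError):
            frequency_response(notch60, -1.0)


class TestFindCutoff:
    def test_highpass_cutoff_at_067_hz(self, highpass067):
        f = find_cutoff(highpass067, band=(0.01, 10.0))
        assert f == pytest.approx(0.67, rel=0.01)

    def test_lowpass_cutoff_at_100_hz(self, lowpass100):
        f = find_cutoff(lowpass100, band=(10.0, 124.0))
        assert f == pytest.approx(100.0, rel=0.01)

    def test_recovers_closed_form_crossing(self):
        # Butterworth lowpass: |H|^2 = 1/(1+(tan(pi f/fs)/K)^4); crossing of
        # level L at f = (fs/pi) * atan(K * ((1-L^2)/L^2)^(1/4))
        c = design_biquad("lowpass", 20.0, BUTTERWORTH_Q, FS)
        level = 0.3
        k = math.tan(math.pi * 20.0 / FS)
        f_true = (FS / math.pi) * math.atan(
            k * ((1 - level**2) / level**2) ** 0.25
        )
        f = find_cutoff(c, level=level, band=(1.0, 124.0))
        assert f == pytest.approx(f_true, abs=1e-5)

    @given(f0=st.floats(1.0, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_prewarped_cutoff_within_0p1_pct(self, f0):
        for kind in ("lowpass", "highpass"):
            c = design_biquad(kind, f0, BUTTERWORTH_Q, FS)
            f = find_cutoff(c, band=(f0 / 10, min(FS / 2 - 1e-6, f0 * 10)))
            assert f == pytest.approx(f0, rel=1e-3)

    def test_no_crossing_raises(self, notch60):
        # far below the notch the magnitude stays near 1, above 1/sqrt(2)
        with pytest.raises(CutoffSearchError):
            find_cutoff(notch60, band=(0.1, 10.0))

    def test_multiple_crossings_raise(self, notch60):
        with pytest.raises(CutoffSearchError):
            find_cutoff(notch60, level=0.5, band=(40.0, 80.0))


def test_coefficients_json_round_trip(notch60):
    d = notch60.to_dict()
    again = BiquadCoefficients.from_dict(d)
    assert again == notch60
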