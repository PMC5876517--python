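# Methods

This note documents the models implemented in `wearecg`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical and design decisions a maintainer would want recorded.

## Biquad filter chain

The denoising chain is three second-order IIR sections at 250 samples/s:
a power-line notch (50 or 60 Hz), a 0.67 Hz high-pass for baseline
wander, and a 100 Hz low-pass for wideband noise. Each section is
designed by the bilinear transform of its analog prototype with the
prewarped frequency

    K = tan(pi * f0 / fs),    norm = 1 / (1 + K/Q + K^2),

which maps the analog cutoff exactly onto the requested digital
frequency. With the shared quality factor Q = 1/sqrt(2) the low/high-pass
sections are 2nd-order Butterworth and their −3 dB points land exactly at
f0; the notch places its zeros on the unit circle at ±f0, so the null is
exact and DC gain is exactly 1. Coefficients are stored normalized
(a0 = 1) in double precision; every design is checked against the
stability triangle |a2| < 1, |a1| < 1 + a2.

Streaming uses the Transposed Direct-Form II recursion

    y[n]  = b0 x[n] + w1[n−1]
    w1[n] = b1 x[n] − a1 y[n] + w2[n−1]
    w2[n] = b2 x[n] − a2 y[n]

with a fresh state of exactly (0, 0). Batch filtering is defined as the
left fold of this one-sample step, so streamed and batch output are
bit-identical; the test suite cross-checks both against a brute-force
direct difference equation and `scipy.signal.lfilter` at 1e−9, and the
designs against an independent route (scipy's `bilinear` applied to the
analog prototypes, plus `butter` for the Butterworth sections). There is
no zero-phase (forward–backward) mode: the intended deployment is a
real-time stream. Consequence worth knowing: the 100 Hz low-pass changes
a clean ECG by ~3% in L2 — almost entirely sub-sample phase lag, not
amplitude (a zero-phase application of the same coefficients changes it
by far less than 1%).

`find_cutoff` brackets a single crossing of |H(f)| = level on a coarse
grid (512 points) and bisects to 1e−6 Hz; it refuses bands with zero or
multiple crossings rather than guessing.

## Synthetic ECG

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with defaults

| wave | amplitude (mV) | width σ (s) | offset from R (s) |
|------|---------------:|------------:|------------------:|
| P    | 0.12  | 0.05  | −0.20 |
| Q    | −0.12 | 0.015 | −0.03 |
| R    | 1.0   | 0.02  | 0.00  |
| S    | −0.20 | 0.015 | +0.03 |
| T    | 0.30  | 0.08  | +0.25 |

The per-beat template is evaluated on the sample grid and rescaled so its
maximum equals the configured R amplitude exactly (the overlapping Q/S
tails would otherwise shave ~4% off the nominal 1 mV peak); the template
argmax is the ground-truth R index. Beats repeat at the exact period
`round(60·fs/bpm)` samples — 250 samples at 60 BPM and 250 SPS — with
constant rate (no heart-rate variability; the use case is fixed-rate
bench validation at 60–180 BPM). Contamination layers: a line-frequency
sinusoid (default amplitude 0.2 mV — visible against the 1 mV R wave
without burying it), a baseline-wander sinusoid (default 0.15 Hz,
below the 0.67 Hz high-pass cutoff so the filter demonstrably removes
it), and seeded white Gaussian noise. Identical (config, seed) gives
bit-identical output.

What this generator does *not* emulate: arrhythmia and morphology
variation, electrode motion artifacts, muscle noise, respiration
modulation, heart-rate variability, or amplitude drift. Detector results
on it therefore demonstrate correctness of the pipeline plumbing and of
the noise-removal chain at the modelled noise types — not clinical-grade
QRS detection performance on real recordings.

## R-peak detection and heart rate

The detector computes a slope-energy envelope — the squared first
difference smoothed by a 0.10 s moving average — and takes local maxima
that exceed 0.5× the envelope's running maximum (2 s centered window)
and are at least 0.20 s apart; each candidate is then refined to the
amplitude maximum of the input trace within ±0.10 s. Slope energy is the
discriminating statistic because the narrow, steep QRS complex carries
~40× more of it than the taller-but-slow T wave, whereas a plain
amplitude envelope at these defaults leaves the smoothed T wave above
half the smoothed R peak and double-fires. The running-max window is
centered rather than trailing so the threshold is already meaningful at
the first beat (a trailing window that has seen only a P wave would pass
it). The relative threshold makes detection invariant to global
amplitude scaling. Degenerate inputs: a constant (flat) trace yields no
peaks; traces under 1 s are rejected.

Heart rate is `60·fs / median(RR)` with RR the successive peak spacings
in samples; the median tolerates a single missed or spurious beat and
equals the mean on a constant rhythm. Note the generator quantizes the
beat period to whole samples, so e.g. "80 BPM" is truly 60·250/188 =
79.79 BPM; estimates are asserted to ±1 BPM.

## Transmission power control

The ETPC controller adapts the radio's discrete TX power from periodic
RSSI feedback (windows of 10 packets by default). Parameters, all
configurable: RSSI target −85 dBm; constant lower threshold TRL −88 dBm;
adaptive upper threshold TRH_var = TRL + σ with σ the population SD of
the window's received RSSI; EWMA weights α1 = 0.9 (good channel) and
α2 = 0.6 (bad); power table (−23, −20, −16, −12, −8, −4, 0, 4) dBm
(CC2540-class radio registers); steps +2 table indices up, −1 down,
clamped.

Per feedback window: R_lowest is the minimum received RSSI (anchoring
the average to the worst sample protects reliability); the channel is
*good* only if every packet arrived and the mean RSSI reaches the
target — any loss classifies it bad, because received-only statistics
are survivor-biased upward exactly when the link degrades; the running
average updates as R̄ ← α·R_lowest + (1−α)·R̄; then ΔP = +2 if R̄ < TRL,
−1 if R̄ > TRH_var, 0 inside the closed band (boundary ties hold). A
window that lost *every* packet carries no measurable RSSI: R̄ and
TRH_var are held and the controller takes the step-up branch outright.
This outage-recovery rule is deliberate: freezing power on silence would
make deep fades an absorbing state (in closed loop the controller then
rides to minimum power and stays there with a dead link). The asymmetric
+2/−1 step climbs fast out of fades and backs off gently.

Dead-band geometry worth knowing: on a noiseless channel the window SD
is 0, TRH_var collapses onto TRL, and no discrete 4 dB level can place
R̄ *inside* a zero-width band — the steady state is then a tight
three-level limit cycle around the level whose RSSI equals TRL (or a pin
at a table boundary when the link is uniformly too good or too bad).
With any real shadowing the band has positive width and the controller
dwells inside it.

The constant-TPC baseline transmits at a fixed level, by default the
table maximum — the "direct high power" strategy ETPC is measured
against.

## Link simulator and calibration

The on-body channel (chest-to-hip analogue, 2.4 GHz) is a fixed mean
path loss plus stationary AR(1) log-normal shadowing: marginal SD
`sigma_shadow` = 6 dB, per-packet autocorrelation ρ = 0.95 at
25 packets/s (fading correlation time ≈ 0.8 s, posture/motion scale),
RSSI = TX − path_loss + s[t]. Reception is Bernoulli with probability
sigmoid((RSSI − s50)/k), s50 = −88 dBm, k = 1.5 dB; k → 0 degenerates to
a hard sensitivity threshold. Shadowing and reception consume
independent substreams of the run seed, so two policies simulated with
the same seed face the identical shadowing path and reception variates —
comparisons are paired.

The mean path loss default, 88 dB, is the calibrated operating point:
it puts the table-maximum transmitter's mean RSSI at −84 dBm, a few dB
above the controller's dead band, so full constant power is adequate
but not wasteful headroom. At that point the paired comparison over
60 s runs reproduces the qualitative economy of adaptive control: ETPC
median energy savings ≈ 30–35% versus constant-at-maximum (strictly
positive on every seed tested), a modestly higher packet-loss ratio
(ETPC deliberately rides near the sensitivity point — s50 coincides
with TRL, so simulated PLR levels are high in absolute terms), and a
lower RSSI standard deviation (the controller cancels the slow fades
the constant baseline passes through). With a much smaller path loss
the baseline is grossly overpowered and "savings" become arbitrarily
large while ETPC's PLR advantage disappears — informative about the
baseline, not about the controller.

Energy is accounted as radiated power, 10^(P_dBm/10) mW per packet at
fixed airtime; per-level current-draw tables of a specific radio are
out of scope, as are retransmissions, interference, and mid-run posture
transitions (one posture = one channel config). Problem sizes used
throughout evaluation: 60 s × 25 packets/s = 1500 packets per run,
20 paired seeds per comparison.

## Numerical conventions

Sample indices are 0-based; times in seconds; powers in dBm (mW only in
metrics); all arithmetic double precision. Validation failures raise
distinct error classes naming the offending quantity. Every stochastic
path (ECG noise, shadowing, reception) flows from an explicit integer
seed through `numpy.random.default_rng`; nothing reads global RNG state.
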