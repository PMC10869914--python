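# Methods

## Signal model and pipeline

A PPG waveform is treated as a quasi-periodic pulse train carrying
three respiratory modulations: pulse amplitude (RIAV), additive
baseline (RIIV), and instantaneous beat frequency (RIFV). A fourth
beat-domain feature, the successive systolic difference (RISSDV), is
the first difference of the peak-amplitude series; because a first
difference is a high-pass operation on the beat series, it suppresses
the very slow, non-respiratory amplitude drift that contaminates RIIV
while keeping the respiratory band, and — unlike the interval series —
it is only locally perturbed when a beat is missing.

Processing order matters: channels are band-pass filtered over the
whole record (PPG 0.05–10 Hz, respiration 0.05–1 Hz), and only then
cut into 60-s windows. Filtering each window separately leaves the
0.05 Hz high-pass edge transient — whose natural timescale is tens of
seconds — ringing across a large part of the window whenever the cut
lands mid-pulse, which buries the baseline feature RIIV under an
artificial very-low-frequency bow. Record-level filtering confines the
transient to the first and last few seconds of the record; those
seconds are flagged (`FilterDesign.edge_guard_s`, default 2 s) and can
be excluded from fiducial scoring with `trim_fiducials`, but are kept
in the default pipeline.

Filters are 4th-order Butterworth run forward–backward
(`sosfiltfilt`). Zero phase is the one non-negotiable choice: group
delay would shift fiducial times and corrupt the interval feature.
Family and order are configurable.

## Peak–trough detection

The detector is causal and counter-based: consecutive rising samples
increment a counter (equal samples neither increment nor reset); a
falling sample terminating an upslope of at least `count_threshold`
samples makes the preceding local maximum a pulse candidate, with the
upslope's start as its trough. Defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `count_threshold` | `round(0.04·fs)` (5 @ 125 Hz) | minimum upslope length; clean systolic upslopes last ~0.1–0.2 s, so 40 ms of monotone rise is always cleared while short noise wiggles are not |
| `refractory_init_s` | 0.33 s | initial refractory period (≈180 beats/min ceiling) |
| `refractory_update` | 0.25 | smoothing weight `w`; refractory ← (1−w)·refractory + w·(0.6·IPI) after each accepted pulse |
| `refractory_fraction` | 0.6 | the refractory period tracks 60% of the running interpulse interval (IPI) |
| `restart_factor` | 1.75 | watchdog: elapsed time since the last accepted peak > 1.75× the smoothed expected IPI clears the adaptive state, so the next pulse is treated as the first |
| `min_prominence` | 0.3 | a candidate's rise must reach 30% of the running rise of accepted pulses |

The restart rule is read as a time-based watchdog on the expected
interpulse interval; a literal reading in which the upslope *counter*
exceeding 1.75× `count_threshold` triggers the restart is available as
`restart_mode="counter"` but would fire within a single normal beat at
typical sampling rates.

The prominence guard exists because a zero-phase band-pass leaves a
small rebound ripple after each pulse; without the guard, those
ripples alternate with real beats and halve the apparent interpulse
interval. It is relative (a fraction of a running rise estimate), so
fiducial *times* are exactly invariant to rescaling the input. Two
refinements fell out of testing on simulated data: the rise estimate
survives watchdog restarts, so the first candidate after a pulse gap
cannot be a small ripple; and because the online estimate has no scale
until the first acceptance, a final offline pass prunes pulses whose
rise is below `min_prominence`× the median rise — this removes noise
wiggles accepted before the first real beat. A consequence worth
knowing: beats whose true amplitude falls below ~30% of the running
median are rejected as artifacts.

## RIV series and spectral RR

Per accepted pulse `i` (times uneven, at beat instants):
RIAV[i] = peak − trough, RIIV[i] = peak amplitude, both at the peak
time; RIFV[i] = t[i+1] − t[i] and RISSDV[i] = a[i+1] − a[i], stamped
at the *later* peak's time (a difference exists only once its second
member is observed; a midpoint convention is available).

RR is the argmax frequency of the classical Lomb–Scargle periodogram
of the mean-subtracted series, evaluated on 0.067–0.5 Hz (4–30
breaths/min) at 0.001 Hz spacing — 0.06 breaths/min granularity,
negligible against the error scales of interest. Ties break toward the
lower frequency (deterministic, conservative toward slow breathing).
The periodogram is a per-frequency least-squares sinusoid fit, valid
for uneven sampling, so the beat series is never interpolated; the
band restriction itself acts as the respiratory band-pass. An explicit
FIR 0.05–0.6 Hz band-limiting stage for the beat series
(`band_limit_riv`: interpolate to a 4 Hz grid, zero-phase FIR, read
back at the beat times) is provided but off by default; its grid
interpolation is cubic because linear interpolation at ~1–2 Hz beat
rates distorts respiratory-band content by 10–20%. Peak *location* is
invariant to the periodogram normalization, to amplitude scaling and
to constant offsets; estimates are marked invalid (never clamped or
imputed) when a series has fewer than 4 points or zero variance.

Fused estimates are unweighted means of three single-feature
estimates (AIF, SIF, ASF, AIS), valid only when all three constituents
are. A fused estimate inherits 1/3 of any constituent's deviation —
the price of averaging is sensitivity to a single outlier feature.

## Synthetic records

The generator is the test bed's ground truth. Instantaneous beat
frequency is `f_h(t) = (hr/60)·(1 + m_rifv·sin(2π f_r t + φ_f))`; its
phase integral is closed-form and beat times are its integer crossings
(bracketed root-finding, exact spacing when `m_rifv = 0`). Each beat
renders an asymmetric raised-cosine pulse (0.12 s rise, 0.23 s decay,
one systolic maximum — injectable for stress tests), scaled by
`1 + m_riav·sin(2π f_r t_beat + φ_a)`; a baseline
`m_riiv·sin(2π f_r t + φ_b)` and white noise are added; beats drop
independently with probability `p_missing`, or deterministically every
k-th beat in irregular-rhythm mode (doubling that interval). The
reference respiration channel is `sin(2π f_r t)`.

Defaults: 480 s at 125 Hz, 80 beats/min, 15 breaths/min, modulation
depths 0.1/0.1/0.05 (amplitude/baseline/interval), noise SD 0.01 of
unit pulse height, no drops. These are plausible resting adult values;
the three modulations are independently switchable and their relative
phases configurable, since phase alignment is physiologically
unspecified and must not affect a peak-frequency estimate.

What the simulator does *not* model: dicrotic notches, pulse-shape
changes with vascular tone, motion artifacts, amplitude-dependent or
colored noise, and non-stationary respiratory rates. Passing tests on
it therefore demonstrate correctness of the pipeline's mechanics and
the *relative* robustness properties (e.g. RISSDV vs RIFV under
missing pulses), not clinical-grade accuracy on hospital recordings.

## Statistics

RMSE and MAE are computed per record over its segments (est − ref, in
breaths/min). Method comparisons use Kruskal–Wallis followed by all
pairwise two-sided Mann–Whitney tests, Bonferroni-multiplied by the
number of pairs and capped at 1. The unit of observation is the
per-record error: segments within a record share physiology and are
not independent, which Kruskal–Wallis assumes (a per-segment mode
exists for exploration). Bland–Altman reports bias = mean(est − ref),
limits of agreement bias ± 1.96·SD (n−1 denominator), and a t-based
95% CI of the bias (normal-approximation variant available); the
"line of equality" check asks whether 0 lies in that CI. Invalid
segment estimates are excluded from their method's pairs and tallied,
never imputed.

## Numerical and degenerate-input choices

- Segment windows are half-open `[kW, (k+1)W)`; sample `i` sits at
  `t0 + i/fs`; a trailing partial window is discarded.
- Records shorter than one window, constant signals, single-pulse
  segments and all-dropped simulations degrade to empty results with
  warnings rather than errors.
- CSV round-trips are exact: values are written at 17 significant
  digits and re-read with round-trip float parsing.
- The acceptance script sizes its simulations (60-s single-segment
  runs for the sweeps; ten 8-min records for the dataset evaluation)
  to keep a full from-scratch reproduction under a minute on one core.

## Known limitations

- The detector's prominence pruning assumes a roughly stationary pulse
  amplitude scale within a record; a genuine 3× amplitude collapse
  would be scored as artifact.
- `band_limit_riv` needs ≥ 4 points spanning two periods of the low
  band edge and returns its input unchanged (with a warning) below
  that.
- The WFDB reading path requires the optional `wfdb` package; CSV is
  the reference format.
- Fusion is a plain mean; no outlier rejection or quality weighting is
  attempted.
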