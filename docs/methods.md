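# Methods

This note documents the models, parameter choices and numerical decisions
behind `runzc`: what the detector assumes, what the simulator does and does
not emulate, and where genuinely open design choices were resolved.

## Signal model and conventions

A recording is a 6-channel time series at `fs = 60 Hz`: vertical,
anterior–posterior and medio-lateral acceleration in g (range ±16 g) and
roll/pitch/yaw angular velocity in deg/s (range ±2000 dps). The anatomical
frame is fixed by convention — `acc_vert` is aligned with gravity during
quiet standing (≈ +1 g), `gyr_roll` is frontal-plane rotation with positive
= pronating (inward) roll, `gyr_pitch` is sagittal-plane rotation — and raw
device axes are mapped into it through an explicit `AxisMap`, because which
physical gyroscope axis corresponds to which anatomical plane depends
entirely on how the sensor is strapped to the foot. Time is seconds from
recording start.

During running, each step stamps the vertical channel with a sharp positive
impact transient at initial contact (IC), a burst of damped post-impact
oscillation, a negative unloading trough at final contact (FC) and a shallow
sub-1 g dip during flight. Ground contact time (GCT) is the elapsed time
between IC and FC, reported in integer milliseconds
(`round(n_samples / fs * 1000)`, half away from zero) so that values from
devices with different sampling rates — 200 Hz optical capture, 60 Hz IMU —
live on a common scale (38 samples at 200 Hz → 190 ms; 11 samples at 60 Hz
→ 183 ms).

## Preprocessing

**Static calibration.** Runners stand still before a bout; per-channel means
over a stance window (≥ 1 s) estimate offsets from local inclination and
fitting misalignment. The vertical offset is taken relative to +1 g so
calibrated standing acceleration stays ≈ 1 g. A window whose gyroscope
standard deviation exceeds 20 dps is rejected as non-static, as is any
profile with a gyroscope offset ≥ 10 dps. Calibration is guarded against
double application through a metadata flag.

**Band-pass conditioning.** The detection channels (`acc_vert`, `gyr_roll`,
`gyr_pitch`) are filtered with a Butterworth band-pass, default 4th order,
0.5–5 Hz, applied forward–backward (zero phase) so event latencies are not
shifted; edges are reflect-padded with `3 × order` samples. The 0.5 Hz
high-pass removes drift without touching the step-frequency band (~2.5–3 Hz);
the 5 Hz low-pass suppresses post-impact ringing and wide-band noise. The
exact corner frequencies of the original treadmill-validated pipeline are
not recoverable, so every filter parameter is configurable
(`filter.order`, `filter.low_cut_hz`, `filter.high_cut_hz`,
`filter.zero_phase`).

## Event detection

**ZC gradient-maxima scan.** Candidates are samples where the first
difference of the signal crosses from positive to negative (for plateaus of
equal samples, the first index is taken) and whose value strictly exceeds a
dynamic threshold

    θ[i] = maxima_fraction × max |x| over a centered window,

with defaults `maxima_fraction = 0.4` and `maxima_window_s = 2.5` (about
six to seven strides — long enough to be stable, short enough to track
amplitude drift within a bout). The window maximum is clipped at the bout
edges. A refractory pass then removes ringing-induced false positives: a
first threshold-only pass estimates the median inter-peak interval (a
parameter-free cadence estimate), and a second greedy left-to-right pass
enforces a minimum gap of `refractory_fraction × median` (default 0.5),
keeping the larger peak when two candidates conflict. Detection is fully
deterministic and scale-invariant (the threshold is a fraction of the local
maximum).

**Coarse-to-fine timing.** A 5 Hz zero-phase low-pass at 60 Hz unavoidably
blurs a ~25 ms impact transient by several samples, so detection is split in
two stages: candidates are found on the band-passed signal (robust to
noise), then each event is snapped to the local extremum of the calibrated,
unfiltered signal within a small radius (`detect.ic_refine_samples = 2`,
`detect.fc_refine_samples = 6`). On noise-free synthetic bouts this recovers
IC and FC within ±1 sample at every speed; without refinement the filtered
signal alone is systematically late/early by up to 5 samples at 8 km/h,
where the flight phase lasts only ~30 ms.

**Final contact.** The same ZC scan runs on the negated vertical
acceleration inside a region of interest after each IC. Three refinements
proved necessary at slow speeds and are configurable:

1. the ROI starts at `IC + min_gct_ms` (default 120 ms, a physiological
   floor — running contact times are ≥ ~200 ms), because the decaying
   impact otherwise dominates the segment and masks the trough;
2. the threshold is referenced to the maximum of the negated segment (the
   inverse-peak amplitude scale) rather than the absolute maximum, for the
   same masking reason;
3. candidate search may look 3 samples past the next IC (the filtered
   trough lobe leans early), but the accepted FC is always strictly before
   the next IC and within the 500 ms ROI, which also prevents cross-step
   pairing.

When several inverse peaks pass the threshold, each is refined on the
calibrated signal and the deepest refined trough wins; the raw unloading
trough is unambiguous even when the filtered lobes are not. ICs without an
accepted FC yield a step with absent FC/GCT rather than an error.

## Features and classification

Rotational velocity is observed in a `window_ms = 167` ms window centered on
each IC — the same window used for the noise analysis below; no separate
feature window is defined anywhere, so one length serves both. Over the
centered window the roll and pitch means are computed; the pronation angle
is the trapezoidal integral of roll velocity from the IC over the trailing
half-window, converted to degrees. Integrating makes the classic angle rule
directly applicable: |angle| ≥ 5° ⇒ *pronated* (inclusive bound), ≥ 2° ⇒
*slight*, else *neutral*. The 5° bound is the published rule; the 2°
neutral/slight bound and the ±50 dps heel/fore pitch-velocity bounds are
package defaults (`features.*`) — sensible but not canonical, and flagged as
such. Features are extracted from the **calibrated, unfiltered** gyroscope
channels: the 5 Hz low-pass attenuates the brief (~83 ms) roll pulse and
would shrink the integral, breaking the degree scale of the rule.

Bout summaries are majority votes over steps with ties resolved toward the
more severe class (pronated > slight > neutral; heel > mid > fore, ordered
by injury relevance), plus means of GCT and |pronation|.

## Agreement statistics

ICC(2,1) — two-way random effects, absolute agreement, single measures — is
computed from the two-way ANOVA mean squares
(`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, k = 2 raters) and
banded as poor (< 0.500), moderate (0.500–0.750), good (0.750–0.900),
excellent (> 0.900); boundary values go to the higher band except 0.900,
which stays good (the excellent band is strictly above). Degenerate input
with zero total variance is defined as ICC 1.0 with a warning. Bland–Altman
bias and limits use the sample SD (n−1). `mean_error_pct` is
`100 |mean(a) − mean(b)| / mean(b)`. Agreement is intended for bout-level
aggregates (mean GCT per pace); a constant-pace bout has almost no
between-step GCT variance and its step-level ICC is uninformative by
construction. For categorical outcomes the report gives plain accuracy and
the mean absolute difference of ordinal codes (neutral/slight/pronated and
heel/mid/fore coded 0/1/2) — an interpretation, since no canonical numeric
scale exists for these labels, and flagged as such in the output.

The noise-to-signal ratio splits each gyroscope channel into a smooth
component (zero-phase 2nd-order low-pass at 5 Hz, computed over the whole
channel so short windows carry no filter transients) and a residual, and
reports `100 × RMS(residual)/RMS(segment)` averaged over the 167 ms IC
windows. With a 5-sample half-window at 60 Hz the genuine roll pulse itself
has spectral content above 5 Hz, so part of the signal lands in the
residual; the ratio is therefore most meaningful as a *comparison* (roll vs
pitch, low vs high noise), not as an absolute noise estimate.

## Simulator

The simulator emulates the morphology of foot-mounted vertical acceleration
during treadmill running, not its biomechanics. Per-step templates on a 1 g
baseline: impact Gaussian (σ = 11 ms, half-width ≈ 25 ms), one-sided damped
12 Hz ringing (decay 50 ms) scaled by `ringing_gain`, unloading trough
(Gaussian, σ = 14 ms, depth 0.35 × impact amplitude) at FC, and a −0.10 g
flight dip. The roll channel carries a squared-raised-cosine pulse on the
sample grid over the trailing feature half-window whose trapezoidal time
integral equals the requested pronation angle exactly (the flat onset makes
the integral insensitive to one-sample event-timing error); the pitch
channel carries a ±250 dps raised-cosine pulse (140 ms) centered on the IC,
signed by strike type (heel negative, fore positive, mid zero).

Speed maps, fixed once from the trends such protocols report and applied
between 8 and 18 km/h:

| quantity | map | at 8 / 16 km/h |
|---|---|---|
| cadence (steps/min, one foot ×2) | 160 + 2.5 (v − 8) | 160 / 180 |
| ground contact time (ms) | 345 − 12 (v − 8) | 345 / 249 |
| impact amplitude (g) | 3 + 0.5 (v − 8) | 3 / 7 |
| ringing gain (–) | 0.1 + 0.05 (v − 8) | 0.1 / 0.5 |
| accelerometer noise SD (g) | 0.02 + 0.01 (v − 8) | 0.02 / 0.10 |

Gyroscope noise is tied to accelerometer noise with the roll (horizontal)
plane three times noisier than pitch (150 vs 50 dps per g of accelerometer
noise), encoding the empirical observation that the horizontal rotation
plane is the one that degrades at speed while the vertical plane stays
clean — which is why pronation accuracy degrades under noise while
foot-strike accuracy barely moves. Per-step jitter (cadence ±2%, impact
amplitude ±5%, uniform) is on by default; a single seeded generator makes
output bit-identical for a fixed seed. Infeasible specifications
(GCT ≥ step period) are rejected.

**What passing tests do and do not show.** The simulator provides exact
ground truth, so tests demonstrate that the implementation recovers what the
templates encode — timing to ±1 sample, angles to ~0.05°, classes at 100% in
the noise-free limit, and graceful degradation with noise and ringing. Real
recordings contain inter-subject template variation, drift, soft-tissue
artifacts and asymmetries the templates do not model; performance numbers on
simulated bouts therefore bound implementation correctness, not field
accuracy.

## Numerical choices and degenerate inputs

- Rolling maximum via a centered max filter with edge replication, exactly
  equal to the clipped-window maximum; thresholds compare strictly (`>`).
- Plateau maxima take the first index; refractory conflicts keep the larger
  peak, replacing the previously accepted one.
- GCT rounds half away from zero to integer ms.
- All-constant series yield no events (not an error); recordings shorter
  than 1.5 s are rejected for detection; series shorter than `3 × order`
  samples are rejected for filtering with a message stating the minimum.
- Events that refine onto the same sample are merged (first kept).
- Empty step lists summarize to an empty bout (n = 0, absent aggregates),
  not an error.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use 20–30 steps per simulated
bout (a ~1 min bout at one-foot cadence contains ~57), 45 noise-free
condition cells (5 speeds × 3 pronation levels × 3 strike types), a
5 × 3 × 20-seed noise/ringing grid for the degradation properties, and
15 bouts across speeds for bout-level agreement. These sizes give stable
medians and exact recovery checks while keeping a full run in the order of
seconds.

## Known limitations

- The detector assumes a quasi-periodic gait; starts, stops and shuffles
  within a bout will produce spurious or missing events.
- No orientation estimation or drift correction is performed; the static
  calibration removes constant offsets only.
- The 5°/2°/±50 dps class boundaries are configurable defaults, not
  clinically validated cut-offs.
- Left and right feet are independent recordings; no bilateral pairing.
- The simulator's parameter-speed maps are stylized trends; they are not a
  substitute for validation against instrumented-treadmill data.
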