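# runzc

Running-gait assessment from a single foot-mounted IMU (±16 g accelerometer,
±2000 dps gyroscope, 60 Hz), for sports scientists and wearable-algorithm
engineers who need per-step gait events and foot-mechanics labels without a
motion-capture lab.

The core algorithm is **zero-crossing (ZC) gradient-maxima** peak detection:

- **Initial contact (IC).** A sample *i* of the vertical acceleration
  *a(t)* is an event candidate when the first difference changes sign
  (Δa[i−1] > 0, Δa[i] < 0 — a gradient zero-crossing at a local maximum) and
  *a[i]* exceeds a dynamic threshold
  *θ[i] = f · max |a|* over a 2.5 s centered window (*f* = 0.4 by default).
  A refractory pass derived from the median inter-peak interval removes
  false positives caused by post-impact ringing.
- **Final contact (FC).** The same scan on the negated signal inside a
  500 ms region of interest after each IC; ground contact time is
  GCT = round((i_FC − i_IC) / f_s · 1000) ms.
- **Foot mechanics.** Around each IC, frontal-plane roll velocity is
  integrated to a pronation angle (≥ 5° ⇒ *pronated*) and the mean
  sagittal-plane pitch velocity classifies the strike location
  (*heel* / *mid* / *fore*).
- **Agreement statistics.** ICC(2,1) (two-way random effects, absolute
  agreement, single measures) with the conventional poor/moderate/good/
  excellent banding, Bland–Altman bias and 95% limits of agreement, and mean
  errors — the toolkit used to validate such algorithms against 3D motion
  capture.

Because no public recordings exist for this sensor placement, the package
includes a simulator that generates stylized running bouts (8–18 km/h) with
exact ground-truth event times, pronation angles and strike classes, so the
whole pipeline is testable end to end.

## Worked example

```sh
runzc simulate --speed 12 --steps 25 --pronation 8 --footstrike heel \
    --noise 0 --seed 42 -o bout.csv --truth truth.csv
runzc analyze bout.csv -o out/
cat out/bout_bout.json
```

```json
{
  "bout_footstrike_class": "heel",
  "bout_pronation_class": "pronated",
  "config_hash": "83d47c4c934b",
  "mean_gct_ms": 294.56,
  "mean_pronation_deg": 7.959256958799989,
  "n_steps": 25,
  "source": "bout.csv"
}
```

All 25 simulated steps were found; the mean ground contact time of
294.6 ms sits within one sample period (16.7 ms at 60 Hz) of the simulated
297 ms, the recovered roll angle of 7.96° matches the requested 8° (hence
*pronated*, ≥ 5°), and every step is classified as a heel strike.
Comparing the per-step output against the exported ground truth:

```sh
runzc validate --algorithm out/bout_steps.csv --labels truth.csv
```

reports Bland–Altman bias/limits and mean errors for contact time (here:
bias −2.4 ms, mean absolute error 6.5 ms) and classification accuracy for
the categorical outcomes (here: 100% for both). It also reports ICC(2,1)
with its agreement band — note that within a single constant-pace bout the
true contact time barely varies between steps, so the step-level ICC is
uninformative by construction; agreement is normally assessed on bout-level
means across paces, which is what `scripts/acceptance.py` does.

The same API is available from Python:

```python
from runzc import SimulationSpec, simulate_bout, run_gait_analysis

recording, truth = simulate_bout(SimulationSpec(speed_kmh=12, pronation_deg=8.0))
analysis = run_gait_analysis(recording)
print(analysis.bout.mean_gct_ms, analysis.bout.bout_pronation_class)
```

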