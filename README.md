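# fuzzrula

Offline biomechanical risk assessment for seated work, from body-worn
inertial sensors.

Long periods of seated computer work drive musculoskeletal disorders, and
the standard ergonomic screen — the Rapid Upper Limb Assessment (RULA)
worksheet — is observational: an expert watches a worker and assigns
ordinal posture categories by eye. `fuzzrula` replaces the observational
step with measurement. Six inertial measurement units (IMUs) worn on the
left/right arms (LA, RA), left/right shoulders (LS, RS), cervical spine
(C) and sacrum (S) stream orientation at 50 Hz; the package decodes the
raw sensor frames, derives the relative joint angles RULA cares about, and
scores injury risk continuously in time with a three-stage Mamdani fuzzy
inference system.

## What it computes

**Joint angles.** Each sensor reports absolute Euler angles. An arm sensor
alone cannot distinguish arm flexion from trunk lean, so relative angles
are formed against the proximal reference sensor, on the shortest signed
arc:

- arm flexion/extension = arm pitch − shoulder pitch (per side)
- arm abduction = arm roll − shoulder roll (sign set so "away from trunk"
  is positive on both sides)
- trunk flexion = cervical pitch − sacrum pitch; trunk twist = cervical
  yaw − sacrum yaw

**Risk scores.** Three Mamdani fuzzy models (min AND, clipped consequents,
max aggregation, centroid defuzzification) adapt the RULA worksheet:

1. *Group A* — arm flexion/extension and abduction → score A ∈ [3, 7]
2. *Group B* — trunk flexion and twist (±5° centred tolerance) → score
   B ∈ [1, 6]
3. both scores get the worksheet's +1 *static-posture* adjustment (posture
   held > 1 min), giving A′ ∈ [4, 8], B′ ∈ [2, 7]
4. *Final* — (A′, B′) → Total C ∈ [3, 7], a monotone surface following the
   worksheet's grand-score matrix

Membership breakpoints encode the published RULA angle categories
(trapezoids with ±5° crossovers); rule consequents are generated from the
crisp worksheet tables, and the evaluator's per-trial categories (forearm,
wrist, neck, legs) select the rule base. Total C maps to risk bands
Medium (< 4.5), High (< 6.5), Severe (≥ 6.5), and per-band cumulative
exposure seconds are tabulated per body side.

The package also covers the acquisition bookkeeping around the models:
20-byte frame encode/decode with stream resynchronisation, text-log I/O,
series alignment to the nominal 15,000 samples per 5-minute block,
loss/efficiency percentages and trial statistics, theoretical link
throughput, and Fleiss' kappa for expert-vs-system agreement on risk
labels. A synthetic posture/packet generator (upright / slouched /
reclined presets with Gaussian noise, slow drift, count jitter and packet
drops) stands in for the hardware.

## Worked example

Simulate a 5-minute slouched-sitting block and run the whole chain:

```sh
fuzzrula pipeline --scenario slouched --seed 42 --duration 300 --out demo
```

which prints the per-side exposure table:

```
                 Medium Injury Risk [s]  High Injury Risk [s]  Severe Injury Risk [s]
Upper Limb Side
Left                                0.0                298.42                    1.58
Right                               0.0                298.44                    1.56
```

The slouched preset holds ~55° arm flexion and ~30° trunk flexion, which
the crisp worksheet grades as High risk; the fuzzy pipeline agrees for
298.4 of the 300 s on each side. The remaining ~1.6 s are brief Severe
excursions where sensor noise pushes the trunk twist past the ±5°
tolerance band — exactly the kind of transient the continuous score
surfaces and an observational assessment misses. The run also writes the
per-sensor logs, the derived posture angles, and a `ground_truth.json`
sidecar with the noise-free angles and intended category.

The same stages are available individually (`fuzzrula decode | simulate |
metrics | assess | profile | agreement`) and as library functions; see the
module docstrings and `docs/methods.md`.

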