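# Methods

This note records the models and procedures implemented by `fuzzrula`, the
assumptions behind them, and the design choices made where the design was
genuinely open.

## Sensor frames and units

Each IMU reading is a 20-byte frame: a header octet (0x55), a frame-type
octet (0x61 for the measurement block), then nine little-endian signed
16-bit words — acceleration, angular velocity and orientation, three axes
each. Raw words map to physical units by the device's full-scale ranges:

    acc   = raw / 32768 × 16  g
    gyro  = raw / 32768 × 2000  °/s
    angle = raw / 32768 × 180  °

The ranges are the manufacturer's documented defaults and are configurable
(`CodecSettings`) for other variants. Encoding rounds to the nearest raw
word, so an encode/decode round trip is exact to one quantisation step
(LSB) per channel. Stream decoding resynchronises on the header pattern:
unrecognised bytes are skipped singly and counted; frames with a known
header but a different type octet (e.g. quaternion register blocks) are
skipped whole and counted separately. A lone frame carries no clock, so
stream timestamps are assigned as `index / nominal_rate`; text logs carry
an explicit time column. Logs are tab-separated with a header row by
default (CSV by flag) and floats are written at 17 significant digits so a
write/parse round trip is bit-exact.

## Alignment and acquisition metrics

A nominal acquisition block is 5 min at 50 Hz = 15,000 samples; real BLE
streams under-run (packet loss) or over-run (delayed manual stop). Series
are brought to the nominal length before kinematics: shorter series are
linearly interpolated on a uniform index map [0, n−1] → [0, target−1]
(endpoints preserved, no overshoot, idempotent), longer series keep their
first `target` samples because the excess accrues at the end of a run.
Linear interpolation is the minimal-assumption choice for a dense,
slowly-varying 50 Hz orientation signal; a spline would add nothing at
this oversampling factor and could overshoot.

Quality metrics are defined as
loss % = (expected − received)/expected × 100 (negative = excess data) and
efficiency % = received/expected × 100, so loss + efficiency ≡ 100.
Trial statistics use the sample (n−1) denominator — the convention for a
handful of repeated trials — with CV = SD/mean × 100, bias = mean −
expected and MPE = bias/expected × 100. Theoretical link throughput is
rate × packet size per sensor (50 × 20 = 1000 bytes/s) and ×8 bits × n
sensors aggregate (48 kbps for six).

## Joint-angle derivation

Relative angles remove the trunk's orientation from the limb reading:
subtracting the proximal sensor (shoulder for arms, sacrum for the trunk)
makes the result invariant to tilting the whole body, which is the point
of pairing each distal sensor with a reference. All differences are taken
on the shortest signed arc and wrapped to [−180, 180), so circular yaw
behaves correctly across the ±180° seam.

The Euler-axis mapping is a convention, not a measurement: with sensors
mounted flat on the segments, pitch (`angle_y`) carries
flexion/extension, roll (`angle_x`) abduction/lateral tilt, and yaw
(`angle_z`) twist. Signs are set so flexion forward, twist to the right
and abduction away from the trunk are positive; the right-side roll sign
is flipped accordingly. Both the mapping and the signs live in `AxisMap`
and can be reconfigured per mounting. Full 3-D joint coordinate systems
(ISB-style) and quaternion kinematics are out of scope: the risk models
consume single-plane angles, and the per-axis subtraction is exact for
the near-sagittal seated postures being assessed, degrading gracefully as
postures leave that plane.

## The Mamdani engine

The inference engine implements the classical Mamdani pipeline:
piecewise-linear trapezoidal/triangular membership functions (a triangle
is the degenerate trapezoid b = c; coincident breakpoints make vertical
shoulders with membership 1 at the edge), minimum t-norm for AND,
implication by clipping each consequent at its rule's firing strength,
pointwise-maximum aggregation, and centroid defuzzification.

Numerical choices:

- The centroid is computed by trapezoidal integration of the aggregated
  shape on a uniform grid of 1,001 points (configurable). Because the
  aggregated shape is piecewise linear, trapezoidal integration is exact
  between grid points and the only error comes from kinks falling off the
  grid; against an independent 10⁵-point brute-force centroid the engine
  agrees to better than 10⁻³ across random models (see the test suite).
- The grid spans the full *support* of the output terms, not just the
  declared universe. Truncating an edge term at the universe boundary
  would silently skew its centroid; with the full support included, a
  symmetric edge term centred on the boundary defuzzifies to the boundary
  value exactly.
- Crisp inputs outside an input universe are clipped to its edge rather
  than rejected — measured angles can exceed nominal worksheet ranges.
- If no rule fires with positive strength the engine raises by default
  (`fallback="error"`); a midpoint fallback is available. The shipped
  models shoulder every variable's edge terms, so in-range inputs always
  fire at least one rule and the fallback is unreachable in the pipeline.

Sugeno/TSK inference, rule learning and type-2 sets are non-goals. Models
serialise to a declarative dict/YAML form (variables, breakpoint lists,
rules as term-name tuples), so the shipped models are data, editable
without code changes.

## The three RULA models

RULA splits the body into Group A (upper arm, forearm, wrist) and Group B
(neck, trunk, legs) and combines the two group scores through a grand
table. `fuzzrula` keeps the sensor-derived quantities fuzzy and the
rater-supplied quantities crisp:

- **Fuzzy inputs**: arm flexion/extension and abduction (Group A), trunk
  flexion and twist (Group B). Membership breakpoints follow the
  published worksheet angle categories — arm ±20°/45°/90°, trunk
  20°/60° — as trapezoids with plateaus on each category and ±5°-wide
  linear crossovers. The figures defining these shapes in the source
  material print no numbers, so the shipped breakpoints are documented
  reconstructions (`configs/rula_default.yaml`).
- **Crisp evaluator inputs**: forearm, wrist, wrist-twist, neck and legs
  categories plus a shoulder-raised flag, entered once per trial. They
  select the rule base: for every combination of fuzzy input terms, the
  consequent is the crisp worksheet-table score for the implied posture
  categories under those evaluator settings, clamped to the model's
  output universe. This keeps the fuzzy models provably consistent with
  the worksheet they adapt, and editing the evaluator settings re-derives
  the rules. Defaults describe seated desk work: forearm 2, wrist 2,
  wrist-twist 1, neck 1, legs 1 (supported).
- **Outputs**: score A on [3, 7] and score B on [1, 6], with narrow
  symmetric triangles (half-width 0.5) at each integer score. Symmetry
  matters: the centroid of a clipped symmetric shape does not move, so a
  single dominating rule defuzzifies to its integer score exactly.

Trunk twist gets a dedicated "centred" term with a ±5° plateau — sitting
straight within that tolerance is acceptable; beyond it the trunk counts
as twisted (left or right), which adds one worksheet point. The trunk
variable also includes a deep-extension band (score 3 beyond ~20° of
backward lean): the plain worksheet grades any extension as 2, but a
pronounced recline loads the lumbar and cervical spine and the
reclined-sitting experiment is expected to grade as high risk; this
adaptation is a deliberate extension, isolated in the config.

**Static adjustment.** A posture held for more than one minute adds one
point to each group score, so adjusted ranges become [4, 8] and [2, 7].
The 5-minute seated blocks assessed here are static by construction, so
the flag defaults to true.

**Final model.** Inputs are the adjusted scores; rule consequents follow
the worksheet grand table, mapping scores 3–4 to a Medium term, 5–6 to
High and 7 to Severe. Two shape decisions keep the defuzzified surface
monotone nondecreasing in both inputs, as the worksheet's logic demands:

1. *Symmetric output terms* — medium trapezoid (2.5, 3, 4, 4.5), high
   trapezoid (4, 5, 6, 7), severe triangle (6, 7, 8). Supports extend
   half a point past the [3, 7] universe so each term is symmetric about
   its band centre; clipping then never moves a term's centroid, so
   within a single-category region the surface is flat instead of
   rippled. The surface consequently spans [3.5, 7.0] ⊂ [3, 7].
2. *Staggered trapezoidal input terms* — each integer score owns a
   plateau [i − 0.5, i + 0.5]; the next term rises to 1 over
   [i + 0.3, i + 0.5], before the current one falls over
   [i + 0.5, i + 0.7]. Under minimum-AND with maximum aggregation, a
   conventional simultaneous crossfade lets a lower consequent's strength
   dip and recover while a higher one stays capped, producing local
   non-monotone ripples; staggering removes the adverse region entirely.
   The suite verifies monotonicity on dense grids.

Crisp Total C maps to categories with cuts at 4.5 and 6.5 — the midpoints
between the integer bands (3–4 medium, 5–6 high, 7 severe) — the
minimal-assumption extension of integer bands to a continuous score.
Exposure per category is count × sample period, so exposures sum to the
block duration exactly.

## Rater agreement

Expert-vs-system comparisons use Fleiss' kappa over subjects × raters
tables of categorical risk labels (the computation delegates to
statsmodels' inter-rater routines; an independent hand-formula oracle
cross-checks it in the tests). A table whose every rating is one single
category makes expected agreement 1 and the statistic 0/0; the package
returns 1.0 by convention with a warning. Interpretation bands follow the
usual convention with 0.75 itself graded moderate-to-good: poor < 0.4 ≤
moderate-to-good ≤ 0.75 < excellent.

## Synthetic data: what it emulates, and what it does not

The generator replaces the BLE hardware: for each of the six placements
it draws angle channels as mean + Gaussian noise (default SD 2°) + slow
linear drift (default 0.5°/min), at 50 Hz for 5-minute blocks, with
optional signed sample-count jitter (percent of the expected 15,000),
per-frame packet drops, and accelerometer/gyroscope channels filled with
a plausible gravity-plus-noise signal. One global seed fans out to
per-placement substreams (`SeedSequence` spawn keys), so adding a sensor
never perturbs the noise of the others, and every run is reproducible.

The three presets encode the study postures qualitatively, since no
numeric posture angles are published: *upright* (≈10° arm flexion,
near-neutral trunk → Medium), *slouched* (≈55° arm flexion, ≈30° trunk
flexion → High) and *reclined* (≈35° backward lean, splayed raised arms →
High). Preset means sit ≥10° inside one worksheet angle band wherever the
band is wide enough, so at the default 2° noise the pipeline recovers the
intended category on ≥95% of samples — a property the suite checks
end-to-end. Each generated recording carries its noise-free relative
angles and the category they imply through the *crisp* worksheet chain,
giving the fuzzy pipeline an independent label to hit.

What the generator does not emulate: BLE radio timing, RSSI and range
effects, asynchronous inter-sensor clock skew, posture transitions within
a block, soft-tissue artefact, or orientation-filter error in the sensors
themselves. Passing tests therefore demonstrate the correctness of the
decoding, kinematics, inference and accounting chain under controlled
noise — not the field accuracy of any particular sensor.

## Problem sizes

The test suite runs the fuzzy chain on blocks of 500–15,000 samples and
checks the engine against a 10⁵-point brute-force centroid on 200 random
models; the acceptance script aligns a 12,000-sample series and scans the
final surface on a 51×51 grid. These sizes exercise every code path at
full numerical fidelity; the per-sample models are stateless, so longer
recordings change runtime only, not behaviour.

## Known limitations

- Single-plane angle subtraction approximates true 3-D joint angles; far
  from the sagittal plane the arm flexion/abduction decomposition blurs.
- The appendix rule lists of the source material were not machine-readable,
  so rule bases are generated from the published crisp worksheet tables
  rather than transcribed; any hand-tuning the original authors applied
  to individual rules is not reproduced.
- Evaluator inputs are constant per trial; dynamic muscle-use scoring
  beyond the +1 static rule, force/load scoring, and other worksheets
  (REBA etc.) are out of scope.
- Fleiss' kappa assumes independent raters and a fixed rater count per
  subject; weighted variants for the ordinal Medium<High<Severe scale are
  not implemented.
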