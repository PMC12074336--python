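# Methods

This note records the models, conventions and design choices behind
`plmdkit`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Sensing model and units

Six ultrasonic rangers hang above the bed in three rows (upper 2.2 m, middle
2.1 m, lower 1.9 m sensor-to-mattress; canonical channel order `UBL, UBR,
MBL, MBR, LLL, LLR`). Each reports, at 4 Hz, the distance to the nearest
surface below it within the sensor's 2 cm – 4 m range.

Distances are stored as whole **tenths of a millimetre** (200–40 000),
which fits the capture datapath's fixed 20-bit word while keeping sub-mm
resolution. The word width is a hardware-style commitment: the capture FIFO
rejects any value outside 20 bits before insertion.

The beam-coverage calculator is a plain tangent projection,
`coverage = tan(angle) × height`, reported in whole centimetres **truncated
toward zero**. Truncation (not rounding) is the declared convention because
it reproduces all three of the rig's printed coverages (88 / 84 / 76 cm at
2.2 / 2.1 / 1.9 m, 22°); `tan(22°) × 2.2 m = 88.886 cm` would round to 89.
Whether 22° is a half-angle or a full beam width is physically ambiguous;
the calculator implements the one-sided formula as printed and makes no
beam-diameter claim. Bed length/width default to 2.0 m × 0.9 m (a typical
single bed); they enter no computed quantity.

The latency calculator models an `S`-stage pipeline at clock period
`T_clk` processing `N` iterations: `per-iteration = S·T_clk`,
`total = (N + S − 1)·T_clk`. These are pure calculators of the datapath
model, not measurements.

## Synthetic sessions: what is emulated and what is not

A session is baseline + oscillation + limb dips + drift + noise, quantized
and clamped:

* **Posture baselines.** Each of six poses (supine, prone, fetal-left/right,
  log-left/right — names follow common posture taxonomies; tests rely on
  label identity only) has a per-channel body-thickness offset table in mm.
  Occupied channels read `mount height − offset`; an offset ≥ 100 mm marks
  the channel occupied. The table is constructed so that (a) every pose has
  a distinct six-bit occupancy pattern at the default 100 mm margin and
  (b) every channel's baseline separates every pair of poses. (b) makes the
  12 posture classes separable from almost any feature subset, which is what
  lets a small forest reach zero held-out error on noise-free data.
* **Static vs time-variant variants.** Each pose exists in a `static` and a
  `time_variant` variant (12 classes). The time-variant variant adds a
  20 mm, 0.5 Hz sinusoidal body oscillation on occupied channels — enough to
  give windows nonzero variance and shifted means, small enough that
  consecutive one-second window means never differ by more than ~24 mm,
  far below the 100 mm limb-motion threshold.
* **Limb-movement episodes.** An episode is `movement_count` movements of
  `movement_duration_s` seconds, `inter_movement_interval_s` apart, on the
  left, right or both lower-limb channels, with a dip of `magnitude_mm`.
  During each in-motion second the limb **toggles** between its resting
  level and the dipped level. This waveform is chosen deliberately: the
  detector's motion statistic is the difference of consecutive one-second
  window means, so a held constant dip would make seconds 2…d of a d-second
  movement invisible, while the toggle makes every scheduled movement second
  — and no other second — produce a super-threshold difference on a
  noise-free stream. That is what makes "detected events equal injected
  ground truth exactly" a well-posed property.
  Episode timing is validated to whole seconds, onset ≥ 1 s, and runs on the
  same limb separated by ≥ 1 static second (so ground-truth events are
  maximal runs).
* **Ground truth.** Per-frame posture labels, per-second limb flags (from
  the episode table, plus a transition flag on a limb when a posture change
  moves that limb channel's baseline by more than `flag_threshold`,
  default equal to the detector's threshold), and the episode table itself.
* **Noise and drift.** Additive Gaussian noise per channel per frame
  (default sd 3 mm — the documented default study condition; the
  window-mean difference then has sd ≈ 2.1 mm, a ~47 σ margin below the
  movement threshold) and a linear whole-session drift (default 0).

Not emulated: acoustic multipath and inter-transducer crosstalk, PWM echo
timing, bedding/mattress compliance, multi-subject beds, and real
inter-subject variability of body geometry. Passing tests therefore show
the *pipeline logic* is exact under its stated model, not that the default
thresholds are clinically calibrated for real patients.

## Capture and normalization

* **Capture FIFO**: 6 channels × 40 frames × 20-bit words; strictly
  oldest-first eviction. The depth of 40 frames is taken as the binding
  buffer dimension; one buffered "block" is one frame.
* **Early normalization**: per-channel mean of an empty-bed stream.
  **Encoded normalization**: per-posture, per-channel mean of a labelled
  subject session (the per-posture-mean reading of "encoded" is the
  implemented interpretation; nothing richer is assumed). The mean-distance
  finder exposes a stable/changed feedback flag at a 5 mm drift tolerance.
* **Binary pattern**: bit = 1 iff the channel reads ≥ `occupancy_margin`
  (default 100 mm) nearer than its early baseline. The margin must exceed
  sensor noise and undershoot body-thickness dips; 100 mm does both by a
  wide margin under the defaults.
* **Feature vector** (M = 24): per channel — normalized mean (early −
  window mean), raw window mean, *population* variance (divide by n; the
  windows have fixed width, and the convention is declared rather than
  argued), occupancy bit. The composition is this package's concrete
  choice; forest defaults (`m = ⌈√M⌉`) adapt automatically if it changes.

## Random forest

Authored from scratch (scikit-learn appears only in tests, as an independent
cross-check on accuracy):

* **Split criterion**: Gini impurity, candidate thresholds at midpoints
  between consecutive distinct sorted values.
* **Growth rule**: a node is split while it is impure and any assigned
  feature still varies within it; the best-gain split is taken *even when
  the gain is zero*. Requiring strictly positive gain would stop an
  XOR-labelled node at the root (every single split has zero gain) and
  break the fully-grown guarantee; under the implemented rule every leaf is
  pure or holds only conflicting duplicates, so training error is minimal —
  a property the tests verify against an exhaustive search over all
  binary-feature trees on small datasets.
* **Determinism**: one seeded generator; per tree, bootstrap indices are
  drawn first, then the feature subset. Ties break toward the lowest
  feature index, then the lowest threshold; vote ties toward the lowest
  class in the fixed 12-label order. Equal inputs give bit-identical
  forests, predictions and JSON documents.
* **Defaults**: T = 10 trees, m = ⌈√24⌉ = 5. Both are configuration keys;
  no claim is made that these match any particular deployment.
* The tree-count loop is over T only; T is independent of the feature
  count M.

The BST fast path keys each one-second window by
`(occupancy pattern value << 1) | motion bit`, the motion bit set when any
channel's window variance exceeds `motion_var_threshold` (default 4000
tenths² — above the noise-only variance at sd 3 mm, below the oscillation
variance of a time-variant window). Exact key hits return the stored label;
misses fall back to the forest vote.

## Detector conventions

* One **unit** of limb movement = one one-second analysis window (4
  frames). This matches the per-second left/right comparison and makes TLM
  a seconds quantity.
* **Flags**: second t is flagged for a limb iff
  `|mean(w_t) − mean(w_{t−1})| > movement_threshold` (default 100 mm),
  strictly. Second 0 has no prior window and is never flagged. Sub-threshold
  movement onsets are simply not flagged; no onset interpolation is
  attempted.
* **Events**: per second the limb state is none/left/right/both; maximal
  constant-state runs are events, so partially overlapping left and right
  runs split deterministically into both + residual single-limb events.
  TLM counts each flagged second once.
* **Exclusions**: a single one-unit both-limb event coinciding with a
  posture-label change is a pose change, not PLMD; any run longer than
  `max_event_units` (default 40 s) is constant movement, not PLMD.
* **Series confirmation**: ≥ `min_series` (default 4) surviving events with
  inter-event gaps ≤ `max_interval_s` (default 90 s) and durations within
  [1, 40] units — defaults follow standard clinical periodic-limb-movement
  scoring conventions, and all are configuration keys.
* **Stage**: events/hour < 25 → early, 25–50 → middle, ≥ 50 → high
  (package defaults for an otherwise unquantified early/middle/high
  vocabulary). Confirmed durations feed a capacity-8 circular FIFO.
* The three comparison intervals of the measurement chain are read as three
  consecutive one-second windows.

**Exact-recovery precondition.** On a noise-free stream, detected events
equal the injected episode table exactly provided the effective per-second
fusion magnitude clears the threshold: `10·magnitude_mm >
movement_threshold + 2·((1+√2)/4)·10·osc_amp_mm` — with the defaults,
magnitude_mm > 124.2 (the second term is the worst-case window-mean swing
of the time-variant oscillation, ≈ 241 tenths). The randomized-scenario
tests draw magnitudes from [130, 300) mm accordingly. With transitions
between time-variant poses the transition-second flag can additionally be
perturbed by the oscillation phase; the randomized exactness scenarios use
single-posture schedules, and posture transitions are exercised by the
presets with static poses.

## Pipeline and problem sizes

A full run calibrates on a 60 s empty-bed stream, trains on a 12 × 20 s
labelled session (240 windows × 24 features), and analyses a 600 s scenario
— sizes chosen so a complete run takes on the order of a second while every
class and rule path is exercised; all are configuration keys. All
randomness derives from one run seed via fixed per-stage offsets, and every
output file is byte-reproducible from (config, seed).

## Known limitations

* The simulator's movement waveform is a two-level toggle; real limb
  movements have velocity profiles and partial-second alignment that would
  blur flag edges (this is the honest counterpart of unclear static-to-
  movement offsets in real recordings).
* Posture classification of noisy static windows occasionally carries a
  spurious motion bit (~0.4 % of windows at default noise), relabelling a
  window as its time-variant twin; this perturbs only the posture-change
  count in the report, never the limb flags.
* Stage bounds and series-confirmation defaults are software defaults, not
  clinically validated cut-offs; the detector is not a diagnostic device.
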