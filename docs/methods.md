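# Methods

This note documents the models, parameters and design choices behind
`tgamopt`, and what the synthetic-data experiments do and do not show.

## Protocol model

Both TGAM record types share the frame `AA AA <len> <payload…> <chk>` with
`chk = low8(~Σ payload)`. The big-packet payload layout is the de-facto
ThinkGear dialect (`02 ps 83 18 <24 band bytes> 04 att 05 med`, 32 payload
bytes); the codec is the single source of truth for that layout, so the
simulator and the parser cannot disagree. Two documented quirks of the
protocol's published description are resolved as follows:

* **Signed splicing.** The raw-sample rule is `v = 256·hi + lo`, then
  `v − 65536` iff `v > 32768`. This is the only rule consistent with the
  device's stated output range `[−32767, 32768]`, which an exhaustive test
  over all 65536 byte pairs confirms.
* **Timing.** Timestamps are derived (sample index × 2 ms; one big packet
  per 512 small packets ≈ 1.024 s). Wall-clock jitter and inter-byte read
  pauses are acquisition concerns outside the library's scope.

The parser is tolerant by design: a frame whose checksum fails is still
emitted, flagged, because rejection policy belongs to the pipeline. A failed
checksum may also mean a *misaligned* frame (e.g. a corrupted length byte
producing a fake 36-byte frame spanning several real packets), so the parser
consumes a full frame only when its checksum verifies and otherwise resyncs
one byte at a time. This bounds the damage of k corrupted bytes to roughly k
lost packets and keeps clean streams byte-exact.

## Regularization and anomaly bounds

The eight band powers are firmware-defined integers with no unit, so each is
divided by a per-band calibration scale (the per-band maximum of the
calibration window). Within-packet vector normalization was rejected: three
components simultaneously above ~0.6 is impossible under an L2 constraint,
and simultaneous exceedance is exactly the corruption signal the rule needs
(a packet is rejected when **≥ 3** regularized bands strictly exceed their
thresholds; a value exactly at the bound is not an exceedance).

Thresholds are derived from calibration data with an Isolation Forest
(scikit-learn backend): per band, the threshold is the largest regularized
value among points the forest keeps as inliers. Defaults: 100 trees,
subsample 256, contamination 0.05, fixed seed 20200618 — all configurable.
Per-band fitting is the default; a joint 8-D fit is available via
`joint=True`. Degenerate bands (all values identical) get threshold 1.0 with
a warning. The shipped threshold table (Delta 0.635 … MidGamma 0.630) is
authoritative regardless of refitting; the shipped *scales* are the bundled
simulator's generating scales, because the true divisors are
device-and-session specific — real deployments should refit via
`fit_band_thresholds`.

The attention→meditation admissible band is fitted the same way on 2-D
pairs: per integer attention bucket, the admissible interval is the min/max
meditation among inliers; buckets inside the covered span with no inliers
inherit the nearest covered bucket (ties toward the lower attention). The
shipped default is the classification table's meditation columns verbatim,
with permissive [0, 100] buckets on the abandoned intervals 0–4 and 98–100
(the firmware does emit those values; rejecting them is the classifier's
job, with its own rejection reason, not the boundary's).

### Recovery-experiment design

Two properties of the max-inlier extraction shape how recovery experiments
must be run:

* The contamination setting must **upper-bound** the true outlier fraction:
  with the cutoff exactly at the true rate, score-ranking noise lets single
  outliers leak into the inlier set, and one leaked point controls the max
  statistic. Band-threshold recovery tests therefore fit at contamination
  0.07 against a generated 5% outlier rate (4000 rows).
* Edge estimation from extremes needs finer isolation granularity than the
  default screening configuration. The boundary-recovery experiment uses
  8000 pairs, 200 trees and subsample 2048, and evaluates recovered bounds
  against the generating rectangle edges at rectangle resolution (each
  rectangle, spanning two attention columns, is the generating unit).
  Recovered edges land within ±6 meditation units; sub-rectangle bucket
  extremes are noisier because a rectangle's corners are individually rare.

## Blink model

Detection: a blink fires where the consecutive-sample difference is ≥ 1000
ADC units (inclusive at the bound). One physical blink is a multi-sample
excursion, so crossings within a 0.4 s refractory window collapse into one
event; 0.4 s covers a full excursion at 2 ms sampling without merging
blinks ≥ 1 s apart. A windowed mode (max−min of a short rolling window) is
available for slow-ramp artifacts. Checksum-failed samples advance time but
break the difference chain.

The inter-blink interval uses the last two blinks only (no running average)
and is read in seconds-per-blink, feeding the region table: < 2 s invalid,
[2, 4.81) normal (+10), [4.81, 6.51) focus (+10 + 0.8·f), [6.51, 8.33]
highly-focus (+10 + 1.5·f), > 8.33 s invalid. Boundary values are
left-closed except 8.33, which closes the highly-focus row so its printed
range is honored.

Correction is deferred to the next big packet and has two additive terms:
*dip stabilization* (if the drop from the previous output lies in the
expected 8–20 band, add the base 10 — drops outside the band are left
alone, since a larger drop is evidence of something other than a blink) and
the *frequency bonus* (the region compensation, which already includes the
base, when the interval fell in a valid region). The result is clamped to
[0, 97] so compensation can never push output into the abandoned top band.
The pending compensation expires with the first big packet after the blink,
accepted or not — the deferred-correction window closes with it.

## Pipeline semantics

Validation reasons are mutually exclusive and ordered (checksum,
cross_check, poor_signal, wave_bounds, am_boundary, null_region); the first
failure wins. The poor-signal gate rejects any value above 0 by default
(strictest reading; configurable), since nonzero contact-quality complaints
co-occur with unreliable data. Rejected packets emit an output row carrying
the reason and the held smoothed value, so consumers see an unbroken series
with provenance.

Smoothing is a two-value mean (the first value seeds the series); an
exponential mode is available by configuration. Level classification keeps
strict firmware-integer semantics at the API: null singletons and boundary
bands "never appear" in clean data, so their appearance is a data error, and
0–4 / 98–100 are abandoned outright (their occurrences are rare, erratic and
discontinuous with their neighbors). Inside the pipeline, the *reported*
level comes from the smoothed output snapped to the nearest retained
attention value: corrected and smoothed values are algorithm-generated
reals, not firmware integers, and snapping is what makes the ≤ 1-level
stability guarantee hold through stabilized dips.

## Synthetic streams

The simulator emulates the statistical structure the pipeline depends on —
not physiological EEG spectra:

* raw baseline: Gaussian noise, sd 170 (≈ 96% of samples within ±350),
  clipped to the observed extremes [−427, 528];
* blinks: ~0.2 s biphasic pulses whose onset step equals the drawn
  amplitude (uniform 1200–1800), guaranteeing a first-difference at or above
  the detection threshold;
* attention: a bounded integer random walk over the retained values (at most
  one step in the flattened range list per big packet, hence at most one
  level), the minimal process consistent with the observed ≤ 1-level
  dynamics; meditation uniform within the current attention's admissible
  interval; consecutive pairs never repeat;
* post-blink dips: the first big packet after a blink emits attention
  lowered by 8–20 points, snapped back onto a retained value;
* band powers: per-band lognormal fractions (median 0.15, σ 0.6) capped at
  0.58 of scale, so clean packets stay below every shipped threshold;
  anomaly injection pushes ≥ 3 bands to 0.70–0.95 of scale;
* corruption: per packet, one payload byte XOR-flipped after checksum
  computation, so corruption is always detectable.

The calibration emitter (`emit_calibration_set`) deliberately differs from
the session process: it sweeps attention uniformly over the retained values
(a state-space sweep is the right calibration design; a session walk
concentrates mid-scale and starves edge buckets).

Because the generator never emits null-region pairs, never repeats pairs and
keeps clean bands below threshold, passing tests show the pipeline's rules
are implemented exactly — they do not show how often real hardware violates
each rule, nor that real blink artifacts always exceed the 1000-unit
difference.

## Problem sizes

Default test and script sizes: session-scale checksum integrity uses 9698
big packets generated and serialized directly (the equivalent interleaved
stream would carry ~5 million small packets and adds nothing to a checksum
property); full interleaved sessions in tests run 4–30 s; the blink-recovery
trace is 4143 samples (~8.3 s) with seven excursions at 1.1 s spacing;
recovery experiments use 4000 (bands) and 8000 (pairs) calibration rows.

## Known limitations

* The shipped band scales are the simulator's; real devices need refitting.
* The attention–meditation boundary is bucketed per integer attention value;
  no smoothing across buckets beyond nearest-neighbor gap filling.
* Meditation is validated but never optimized.
* Live serial/Bluetooth acquisition is out of scope; input is an offline
  byte stream or packet JSONL.
* `check_am` cannot reject every forest-flagged calibration point: gap
  buckets inherit neighbor bounds, so flagged points there may fall inside
  the inherited interval.
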