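# tgamopt

Attention optimization for single-node TGAM EEG headsets.

The TGAM (ThinkGear Asic Module) is the single-electrode prefrontal EEG
module inside most consumer "mind reader" headsets. Its firmware streams two
kinds of binary records over a serial link: 8-byte **small packets** (one raw
ADC sample every 2 ms) and 36-byte **big packets** (one per 512 small
packets) carrying a contact-quality indicator (*poor signal*, 0–200), eight
spectral band powers (Delta … MidGamma, 3-byte little-endian integers), and
the firmware's *attention* and *meditation* scores (0–100 integers). The raw
attention output is noisy: blinks and facial micro-movements punch 8–20
point dips into the series, corrupted packets pass through unfiltered, and
the 0–100 scale is artificially sliced — many attention–meditation
combinations never occur in clean data.

`tgamopt` re-implements, in library form, a post-hoc optimization pipeline
for that stream:

1. **Codec** — bit-exact parsing/serialization of both packet types.
   Checksum: `chk = low8(~Σ payload)`. Raw samples splice as
   `v = 256·hi + lo`, with `v − 65536` when `v > 32768`, giving exactly
   `[−32767, 32768]`.
2. **Validation chain** (first failure wins): checksum → cross-check (a
   repeated attention+meditation pair means a collection fault) →
   poor-signal gate → band bounds → attention–meditation boundary. Band
   powers are *regularized* (divided by per-band calibration scales, so
   calibration data lies in [0, 1]); a packet with **≥ 3** bands above their
   fitted upper thresholds (Delta 0.635, Theta 0.610, LowAlpha 0.640,
   HighAlpha 0.600, LowBeta 0.615, HighBeta 0.605, LowGamma 0.620, MidGamma
   0.630) is judged corrupted. Thresholds and the admissible meditation band
   per attention value are fitted with Isolation Forests (largest regularized
   value among inliers).
3. **Blink feedback** — a blink is a consecutive-sample raw difference
   ≥ 1000. The inter-blink interval `f` (seconds per blink) maps to:
   invalid (< 2 s), normal (+10), focus (+10 + 0.8·f), highly-focus
   (+10 + 1.5·f), invalid (> 8.33 s). Corrections are deferred to the next
   big packet: an 8–20 point post-blink dip is pulled back by the base
   compensation, the frequency bonus is added on top, everything clamped to
   [0, 97].
4. **Smoothing and levels** — two-value mean smoothing, then classification
   into seven ordinal levels after removing null singletons, boundary bands
   and the abandoned intervals 0–4 / 98–100.

A deterministic stream **simulator** generates byte-exact synthetic sessions
(baseline raw noise ≥ 95% within ±350, biphasic blink excursions, bounded
attention walks inside the retained rectangles, configurable corruption)
with ground-truth logs, so the whole pipeline is testable without hardware.

## Worked example

`python examples/02_blink_feedback.py` synthesizes an ~8.3 s raw trace
(4143 samples) with seven blink excursions and runs the detector:

```
trace: 4143 samples, 7 blink events detected
  blink at  0.90s  peak diff  1284  interval    -    region none          pending compensation +0.0
  blink at  2.00s  peak diff  1643  interval  1.10s  region invalid_low   pending compensation +0.0
  ...
```

All seven injected excursions are recovered; their 1.1 s rhythm falls below
the 2 s floor of the segmentation table, so the region is invalid — only dip
stabilization, not a frequency bonus, would apply at the next big packet. A
3 s rhythm classifies as the normal region and earns the base +10.

`python examples/04_optimize_session.py` runs the full pipeline over a
simulated 25 s session with three blinks and 2% packet corruption:

```
 packet_index  raw_attention  corrected  smoothed  level   reason
            0             44       44.0 44.000000    3.0       ok
            ...
            4             26       36.0 39.937500    3.0       ok
            ...
            8             40        NaN 38.492188    NaN checksum
```

At packet 4 the post-blink dip (raw 26, a 17.9-point drop from the running
output) is stabilized back to 36 before smoothing; the corrupted packet 8 is
rejected with its reason while the smoothed series holds. Defined levels
never jump by more than one step.

The other examples cover the codec (`01_parse_packets.py`) and boundary
refitting (`03_fit_boundaries.py`). The same operations are scriptable via
the thin CLI: `tgamopt simulate|parse|fit|optimize`.

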