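# Methods

This note documents the models, conventions and design choices behind the
package, and what the emulator-driven tests do and do not demonstrate
about real hardware.

## Frame layout and CRC conventions

A frame is a MSB-first bit string serialised big-endian:

```
[zero pad to byte boundary] [AI samples, 12 b each, AI1 first]
[AX samples, 24 b each, AX1 first] [I1 I2 O1 O2] [seq, 12 b] [CRC, 4 b]
```

The padding sits at the front so the sequence number and CRC are at fixed
offsets from the *end* of every frame, which is what makes tail-anchored
resynchronisation possible after corruption. This layout reproduces every
published frame length — the full 20-row configuration→bytes table and the
prose-quoted 18/4/6/9/10/12-byte cases — but the bit-level field order is
this package's own canonical choice; it is not claimed wire-compatible
with any shipped firmware, whose exact layout is not recoverable from
documentation.

CRC parameters: polynomial x⁴+x+1 (the standard telecom CRC-4
convention), initial value 0, no reflection, no final XOR, computed over
the whole frame with the CRC nibble zeroed. Because the generator has
more than one term, every single-bit error is detected; the test suite
verifies this exhaustively (every bit position, one frame per
configuration) rather than taking it on faith. The independent oracle is
a textbook long-division over the frame's bit string, implemented
separately from the codec.

The command table (one tag byte, 0–2 payload bytes, digital-out trigger
packed into a single byte) is likewise self-consistent between client and
emulator rather than firmware-compatible. Multibyte integers are
little-endian. The battery-threshold command takes a unitless level 0–63;
its hardware meaning is deliberately unspecified.

## Sequence accounting

Sequence numbers start at 0 at acquisition start and wrap modulo 4096.
The client counts losses as `(curr − prev − 1) mod 4096` between
CRC-valid frames, seeding `prev` with a virtual 4095 so losses at the very
start of a stream are counted. The interpretation is exact while loss
bursts stay below 4095 consecutive frames; a longer burst aliases, which
is a property of the 12-bit field, not of the implementation. A frame
dropped for CRC failure is counted once in `crc_failures`, and gap
accounting is skipped across the failure so the same tick is never also
counted as lost; the cost is that a genuine loss adjacent to a corruption
is hidden inside that skip — a deliberate trade against double counting.

Resynchronisation slides one byte at a time and accepts a candidate frame
only when its CRC validates *and* its sequence number is within a
plausibility window (default 16) of the last accepted frame. The window
exists because a 4-bit CRC validates 1/16 of random byte windows; the
joint condition makes a false acceptance after an anchor require both a
CRC collision and a small sequence jump (probability ≈ 16/4096 per
collision).

## Emulator timing model

The sample timer counts an integer number of ticks of an 80 MHz base
clock, so the effective period is `round(80e6/SR)/80e6` (round to
nearest, half away from zero — rounding minimises |ε| and yields drift of
either sign depending on SR). The emulator spaces frame timestamps by
this period plus an optional constant ε override; the structural
quantization error is always present. Waveforms are evaluated at the
*true* emitted timestamps and quantized to the channel depth, so a
recording whose timestamps are reconstructed as n/SR exhibits exactly the
drift the timer model predicts: slope `−(SR·round(80e6/SR)/80e6 − 1)` per
second, zero iff SR divides 80 MHz. The square waveform spends the first
half of each cycle low, so a duration of N cycles contains exactly N
rising edges.

Cadence is logical: timestamps are computed, never slept on, so a 240 s
characterisation runs in well under a second. The TCP server streams as
fast as the client consumes; the in-memory transport pumps the sans-IO
emulator core one tick at a time, which makes the emulator's generated
tick count an exact conservation reference (`frames_ok + frames_lost =
ticks generated`) in tests.

## Battery model

Piecewise linear: 4.2 V (full) falling to the 3.3 V regulator dropout
over the first 95% of the nominal runtime `capacity/draw` (defaults
900 mAh, 46 mA ≈ 19.6 h), then to the 3.0 V shutdown voltage at exactly
the nominal runtime, continuing to fall beyond it. Readings are
unaffected above dropout (the regulators hold the rail), scale by
`v/3.3` between dropout and shutdown — the sharp sensor-reading collapse
seen at end of discharge — and the device stops emitting below shutdown.
Published autonomy figures are a consequence of the configured effective
draw, not a constant of the model: a 6.5 h runtime corresponds to
`draw = capacity/6.5 h`. The real discharge curve of a Li-ion cell is
convex, not linear; the model reproduces the three regimes and their
order, not the curve's shape.

## Timing validation

Edge detection thresholds at 50% of the observed amplitude range with a
10% hysteresis band (re-arming requires the signal to fall below
threshold − 0.1·range), and refines each crossing by linear interpolation
between the bracketing samples. An oscilloscope needs no such choices;
these are stated so measurements are reproducible.

Period statistics are mean, median, standard deviation (population
convention, ddof = 0) and the signed max/min deviations from the nominal
period, over successive edge differences; `n_cycles` counts detected
rising edges, one per waveform cycle. Drift is the per-edge difference
device − reference (negative when the device falls behind), paired by
index from the first edge; no outlier removal is applied.

Two drift fits are provided. The default follows the compensation rule
as stated: slope = (most negative drift)/duration, so the model's value
at the horizon equals the worst observed drift. A least-squares
alternative exists because the min-based fit inherits up to one
sampling period of edge-quantization bias (≈ 11% at SR = 3000 over
240 s), while the regression averages the reconstruction sawtooth away;
the slope-recovery check in the acceptance suite uses the regression, the
compensation checks use the min-based rule. Compensation adds |f(t)| to
each timestamp — correct for the lagging-device case the rule was written
for; a device running *fast* would need the sign flipped, which the
model's signed slope makes visible.

Throughput feasibility is a pure budget: a configuration at rate SR fits
a link iff `SR × frame_size ≤ capacity` (bytes/s), with the maximum rate
optionally restricted to divisors of 80 MHz (the drift-free rates). Link
capacity is a model parameter; published maximum-rate ceilings are
hardware observations involving radio and external-ADC limits that a
byte-budget cannot reproduce, and are not targets here.

## Storage

The CSV dialect (comma, LF, UTF-8, `#`-prefixed `key=value` metadata,
`NSeq,I1,I2,O1,O2,<CH>_raw...[,<CH>_mv...]`) is fixed so golden-file
comparisons are bit-exact; millivolts are written with 6 significant
digits, so round trips are exact for integers and within 1e-6 relative
for mV. Lost frames are absent rows, never interpolated. The SD binary
layout (16-byte header: magic `SCIS`, version, channel mask, u16-LE rate,
u16-LE vref, 6 reserved; then canonical frames) is artifact-canonical.
The writer enforces the two on-device modes (all-internal @ 2000 Hz;
all-internal + 1–2 external @ 100 Hz); the reader accepts any valid
header. Converted output is raw-only: the card format does not record an
attenuation factor, so millivolt conversion is left to the reader.

## Conversion and references

Internal channels convert with the 1100 mV reference the device reports;
external 24-bit channels use a separate configurable full scale (default
3300 mV) because no external-ADC transfer function is documented. The
attenuation mode is modelled as a pure multiplicative factor (default 1)
reported in device status.

## Problem sizes and determinism

Characterisation runs in the tests and examples use 240 s at rates up to
3000 Hz (720k samples, vectorized) and frame-level sessions of a few
thousand frames — large enough to cross the 4096 sequence wrap and to
average the reconstruction sawtooth, small enough to keep the whole suite
in seconds. All randomness (frame contents, loss patterns, corruption
bit positions, noise) is seeded; identical configuration yields
byte-identical streams and CSV files.

## Known limitations

The wire layouts (frame bit order, command bytes, SD header) are
self-consistent, tested definitions, not reverse-engineered firmware
formats. Radio transports, their pairing and retransmission behaviour
are out of scope (TCP and in-memory byte streams stand in). The emulator
has no jitter model beyond the constant-ε and quantization terms — real
inter-sample spacing also varies with processing load — and passing the
drift tests shows the *methodology* recovers a known model, not that any
particular board meets a number. Measured hardware values (period
deviations, maximum achieved rates, battery autonomy) are
hardware-specific observations the software stack deliberately does not
claim to reproduce.
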