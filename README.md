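# corestream

An all-software biosignal-acquisition stack for a low-cost ESP32-class
acquisition board: the bit-exact data-frame codec and command protocol, a
device emulator reproducing the firmware's operating modes and timing
non-idealities, an acquisition client with integrity checking and
millivolt conversion, the timing-validation methodology (period
statistics, clock-drift fitting and compensation, throughput budgeting),
and CSV / SD-binary persistence. It is aimed at people who build, teach,
or validate streaming physiological-signal pipelines (ECG, EMG, EDA, PPG,
PCG) and want the full data path — framing, corruption, loss, clock drift,
battery effects — exercisable on a laptop with no hardware attached.

## The data path in brief

One sampling tick of up to six 12-bit internal channels (AI1–AI6, 0–1.1 V
full scale) and two 24-bit external channels (AX1, AX2) is packed into a
variable-length frame of

```
L = ceil((20 + 12·n_AI + 24·n_AX) / 8)   bytes
```

where the 20 overhead bits are a 12-bit sequence number *S*, a 4-bit CRC
(polynomial x⁴+x+1) and four digital bits — 4 bytes for one internal
channel, 18 bytes for all eight. Loss is detected from sequence gaps
`(S_curr − S_prev − 1) mod 4096`; corruption is detected by the CRC, which
flags every single-bit error; recovery is by byte-wise resynchronisation.

The device times its ADC with an integer number of ticks of an 80 MHz base
clock, so the effective sampling period is `round(80 MHz / SR) / 80 MHz`.
When SR divides 80 MHz the period is exactly 1/SR; otherwise recordings
drift behind true time linearly, and the drift is modelled and corrected
with

```
f(x) = (Min / duration) · x ,      t' = t + |f(t)|
```

where *Min* is the most negative drift observed over the acquisition.
Raw levels convert to millivolts as `raw / (2^bits − 1) × Vref × att`.

## A worked example

`examples/03_timing_drift.py` emulates 240 s of a 10 Hz square wave at
SR = 3000 Hz — a rate that does **not** divide 80 MHz — then measures and
corrects the resulting drift:

```
2400 cycles; measured period mean 99.9989 ms, std 0.0192 ms
terminal drift -2.833 ms after 240 s (closed form predicts -3.000 ms)
compensation per second: 0.01181 ms
residual terminal drift after compensation: -0.0006 ms (< one sampling period, 0.333 ms)
```

240 s of a 10 Hz wave is 2400 cycles; the mean period is on the nominal
100 ms, but because the quantized timer runs 12.5 ppm slow the recording
ends 2.8 ms behind true time. Fitting the linear model and adding the
compensation back shrinks the terminal error three orders of magnitude,
to well under one sampling period. The other examples cover the frame
codec and CRC (`01`), a full emulated acquisition with injected packet
loss (`02`), and SD-binary logging with a corrupted frame (`04`).

A thin CLI wraps the same library: `corestream emulate` (serve a software
device over TCP), `corestream acquire` (connect, stream, record CSV),
`corestream validate` (period/drift statistics from recordings) and
`corestream convert` (SD binary log to CSV).

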