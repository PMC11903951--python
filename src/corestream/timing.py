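"""Timing characterization: period statistics, clock drift, throughput.

The device times its ADC with an integer number of ticks of an 80 MHz base
clock, so the achievable sampling period is quantized
(:func:`~corestream.emulator.effective_sampling_period`).  When the chosen
rate does not divide the base clock the real inter-sample spacing is
``1/SR + ε`` while recorded timestamps assume exactly ``1/SR``; the
recording therefore drifts behind a true-time reference linearly, with
closed-form slope ``-(SR * round(base/SR)/base - 1)`` seconds of drift per
second of acquisition.

This module implements the validation recipe for that behaviour:

1. acquire a known square wave and detect its rising edges
   (:func:`detect_rising_edges`);
2. summarise the measured periods — mean, median, standard deviation and
   the signed max/min deviations from nominal (:func:`period_stats`);
3. difference device edges against reference edges (:func:`drift_series`),
   fit the linear drift model ``f(x) = (Min / duration) * x``
   (:func:`fit_drift`; a least-squares alternative is provided), and
   correct timestamps with ``t' = t + |f(t)|``
   (:func:`compensate_timestamps`);
4. check a (rate, channel set) point against a link-throughput budget
   (:func:`throughput_feasible`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .emulator import BASE_CLOCK_HZ
from .errors import AlignmentError, InsufficientDataError
from .frames import ChannelConfig, frame_size

__all__ = [
    "PeriodStats",
    "DriftModel",
    "detect_rising_edges",
    "period_stats",
    "drift_series",
    "fit_drift",
    "fit_drift_least_squares",
    "compensate_timestamps",
    "quantization_drift_slope",
    "ThroughputResult",
    "throughput_feasible",
]


class PeriodStats(NamedTuple):
    """Measured-period summary for a periodic waveform, all in ms.

    ``n_cycles`` counts detected rising edges (one per waveform cycle); the
    statistics are over the ``n_cycles - 1`` successive edge differences.
    Deviations are signed differences from the nominal period, so
    ``min_deviation_ms <= 0 <= max_deviation_ms`` for any well-centred
    measurement.
    """

    mean_ms: float
    median_ms: float
    std_ms: float
    max_deviation_ms: float
    min_deviation_ms: float
    n_cycles: int


@dataclass(frozen=True)
class DriftModel:
    """Linear drift model ``f(x) = slope * x`` (x in s, f in ms).

    Fitted per the published convention: the slope is the most negative
    drift value observed over the acquisition divided by its duration, so
    ``|f(duration)| = |min_drift_ms|`` and ``f(0) = 0``.  The magnitude of
    the slope is the "compensation per second" — the drift to add back per
    second of recording.
    """

    min_drift_ms: float
    duration_s: float

    @property
    def slope_ms_per_s(self) -> float:
        return self.min_drift_ms / self.duration_s

    @property
    def compensation_per_second_ms(self) -> float:
        return abs(self.slope_ms_per_s)

    def f(self, x):
        """Modelled drift (ms) at time(s) *x* seconds."""
        return self.slope_ms_per_s * np.asarray(x, dtype=float)


def detect_rising_edges(
    samples, fs_hz: float, threshold: float = 0.5, hysteresis: float = 0.1
):
    """Times (s) of low-to-high threshold crossings, with hysteresis.

    The threshold sits at *threshold* of the observed amplitude range; a
    new edge is armed only after the signal falls below the threshold minus
    *hysteresis* of the range, which rejects chatter near the level.  Edge
    times are refined by linear interpolation between the bracketing
    samples.  A flat signal yields an empty result (not an error).
    """
    s = np.asarray(samples, dtype=float)
    if s.size < 2:
        raise InsufficientDataError("need at least two samples")
    lo, hi = float(s.min()), float(s.max())
    amplitude = hi - lo
    if amplitude <= 0:
        return np.empty(0)
    th = lo + threshold * amplitude
    th_low = th - hysteresis * amplitude
    below = s < th_low
    crossings = np.flatnonzero((s[:-1] < th) & (s[1:] >= th)) + 1
    if crossings.size == 0:
        return np.empty(0)
    # prefix[i] = number of below-threshold samples in s[:i+1]
    prefix = np.cumsum(below)
    edges = []
    last_accept = -1  # sample index of the last accepted edge
    for i in crossings:
        armed = prefix[i - 1] > (prefix[last_accept] if last_accept >= 0 else 0) or (
            last_accept < 0 and below[: i].any()
        )
        if not armed:
            continue
        frac = (th - s[i - 1]) / (s[i] - s[i - 1])
        edges.append((i - 1 + frac) / fs_hz)
        last_accept = i - 1
    return np.asarray(edges)


def period_stats(edge_times, nominal_period_ms: float) -> PeriodStats:
    """Five-number period summary from rising-edge times (s)."""
    edges = np.asarray(edge_times, dtype=float)
    if edges.size < 2:
        raise InsufficientDataError("need at least two edges to measure a period")
    periods_ms = np.diff(edges) * 1000.0
    deviations = periods_ms - nominal_period_ms
    return PeriodStats(
        mean_ms=float(np.mean(periods_ms)),
        median_ms=float(np.median(periods_ms)),
        std_ms=float(np.std(periods_ms)),
        max_deviation_ms=float(np.max(deviations)),
        min_deviation_ms=float(np.min(deviations)),
        n_cycles=int(edges.size),
    )


def drift_series(device_edges, reference_edges):
    """Per-edge drift (ms): device edge time minus reference edge time.

    Pairing is by index from the first common edge; trailing unmatched
    edges on the longer sequence are dropped.  Sign convention: a device
    that falls behind the reference produces increasingly negative values.
    """
    dev = np.asarray(device_edges, dtype=float)
    ref = np.asarray(reference_edges, dtype=float)
    if dev.size == 0 or ref.size == 0:
        raise AlignmentError("cannot pair empty edge sequences")
    n = min(dev.size, ref.size)
    if n == 0 or abs(int(dev.size) - int(ref.size)) > max(1, n // 2):
        raise AlignmentError(
            f"edge counts too different to pair: {dev.size} vs {ref.size}"
        )
    return (dev[:n] - ref[:n]) * 1000.0


def fit_drift(drift_ms, duration_s: float) -> DriftModel:
    """Fit ``f(x) = (Min / duration) * x`` from a drift series.

    Uses the minimum (most negative) drift value over the horizon, exactly
    as the compensation rule is stated; see
    :func:`fit_drift_least_squares` for a regression alternative.
    """
    drift = np.asarray(drift_ms, dtype=float)
    if drift.size == 0:
        raise InsufficientDataError("empty drift series")
    return DriftModel(min_drift_ms=float(np.min(drift)), duration_s=float(duration_s))


def fit_drift_least_squares(drift_ms, times_s, duration_s: float = None) -> DriftModel:
    """Least-squares linear fit of the drift series (zero intercept not forced).

    Returns a :class:`DriftModel` whose ``min_drift_ms`` is the fitted
    slope times the duration, so the two fitting routes are interchangeable
    downstream.
    """
    drift = np.asarray(drift_ms, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if drift.size < 2:
        raise InsufficientDataError("need at least two drift samples")
    if duration_s is None:
        duration_s = float(t[-1] - t[0]) or 1.0
    slope, _intercept = np.polyfit(t, drift, 1)
    return DriftModel(min_drift_ms=float(slope * duration_s), duration_s=float(duration_s))


def compensate_timestamps(timestamps_s, model: DriftModel):
    """Drift-corrected timestamps: ``t' = t + |f(t)|`` (|f| in ms, t in s).

    The absolute value of the modelled drift is added back, pushing the
    lagging reconstructed timeline forward onto the reference; with a zero
    slope this is the identity.
    """
    t = np.asarray(timestamps_s, dtype=float)
    return t + np.abs(model.f(t)) * 1e-3


def quantization_drift_slope(sr_hz: int, base_clock_hz: int = BASE_CLOCK_HZ) -> float:
    """Closed-form drift slope (ms of drift per second) from timer quantization.

    ``-(SR * round(base/SR) / base - 1) * 1000`` — zero exactly when SR
    divides the base clock; negative (device falls behind) when the
    quantized period exceeds 1/SR.
    """
    q, r = divmod(int(base_clock_hz), int(sr_hz))
    ticks = q + (1 if 2 * r >= sr_hz else 0)
    return -(sr_hz * ticks / base_clock_hz - 1.0) * 1000.0


class ThroughputResult(NamedTuple):
    feasible: bool
    max_sr_hz: int


def _largest_divisor_at_most(n: int, cap: int) -> int:
    best = 0
    d = 1
    while d * d <= n:
        if n % d == 0:
            for candidate in (d, n // d):
                if candidate <= cap:
                    best = max(best, candidate)
        d += 1
    return best


def throughput_feasible(
    config: ChannelConfig,
    sr_hz: int,
    link_capacity_bytes_per_s: float,
    divisor_friendly: bool = False,
    base_clock_hz: int = BASE_CLOCK_HZ,
) -> ThroughputResult:
    """Can *config* stream at *sr_hz* within a link budget?

    Feasible iff ``SR * frame_size <= capacity``; the reported maximum rate
    is ``floor(capacity / frame_size)``, optionally restricted to rates
    that divide the base clock (the drift-free rates).  Link capacity is a
    model parameter here, not a measured radio property.
    """
    if link_capacity_bytes_per_s <= 0:
        raise ValueError("link capacity must be positive")
    size = frame_size(config)
    feasible = sr_hz * size <= link_capacity_bytes_per_s
    max_sr = int(link_capacity_bytes_per_s // size)
    if divisor_friendly:
        max_sr = _largest_divisor_at_most(int(base_clock_hz), max_sr)
    return ThroughputResult(feasible, max_sr)
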