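"""Rotary-encoder speed and behavioral-state segmentation.

The treadmill cylinder (146 mm diameter) drives a quadrature encoder with
2000 edges per revolution.  Speed is computed at 10 ms intervals as the
distance travelled since the last interval; the acquisition system's
movement flag is reproduced digitally: raised when the counter increased by
at least 2 vs. 10 ms earlier, dropped when it increased by fewer than 11 vs.
50 ms earlier.

Four mutually exclusive behavioral states tile the session:

- ``LM`` locomotion: sustained movement-flag periods longer than
  ``lm_min_duration`` with mean speed above ``lm_speed_threshold``,
- ``SM`` small movements: any other movement-flag period,
- ``WS`` whisking/sniffing: whisk channel active without movement,
- ``IM`` immobility: everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .data_model import EpochSet

__all__ = ["SpeedSeries", "encoder_to_speed", "voltage_to_speed", "segment_states"]


@dataclass
class SpeedSeries:
    """Speed (m/s) and movement flag sampled on the 10 ms behavioral grid."""

    times: np.ndarray      # s, spaced by speed_interval
    speed: np.ndarray      # m/s, magnitude
    moving: np.ndarray     # bool movement flag
    direction: np.ndarray | None = None   # +1 forward / -1 backward / 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.moving = np.asarray(self.moving, dtype=bool)
        if not (self.times.size == self.speed.size == self.moving.size):
            raise ValueError("times, speed and moving must be the same length")
        if np.any(self.speed < -1e-12):
            raise ValueError("speed magnitude must be >= 0")


def voltage_to_speed(volts, config: Optional[AnalysisConfig] = None) -> np.ndarray:
    """Convert the calibrated analog speed signal to m/s (1 V = 0.6912 m/s)."""
    config = config or AnalysisConfig()
    return np.asarray(volts, dtype=float) * config.speed_calibration


def encoder_to_speed(counter: np.ndarray, sample_rate: float,
                     config: Optional[AnalysisConfig] = None,
                     t0: float = 0.0) -> SpeedSeries:
    """Convert the encoder counter to a speed series on the 10 ms grid.

    ``counter`` is the integer tick count sampled at ``sample_rate`` (>= the
    1/``speed_interval`` output resolution).  Each tick is 1/2000th of a
    wheel revolution; backward motion decrements the counter and is reported
    as speed magnitude with direction -1.
    """
    config = config or AnalysisConfig()
    counter = np.asarray(counter)
    if not np.issubdtype(counter.dtype, np.integer):
        if not np.allclose(counter, np.round(counter)):
            raise ValueError("encoder counter must be integer-valued")
        counter = np.round(counter).astype(np.int64)
    dt = config.speed_interval
    step = sample_rate * dt
    if step < 1 - 1e-9:
        raise ValueError("counter must be sampled at least every speed_interval")
    n_out = int(math.floor((counter.size - 1) / step)) + 1
    idx = np.round(np.arange(n_out) * step).astype(int)
    c = counter[idx].astype(float)
    times = t0 + idx / sample_rate

    circumference = math.pi * config.wheel_diameter
    dist_per_tick = circumference / config.encoder_edges_per_rev
    delta = np.diff(c, prepend=c[0])
    speed = np.abs(delta) * dist_per_tick / dt
    direction = np.sign(delta).astype(int)

    # movement flag latch: raise on >= +2 ticks per 10 ms,
    # drop on < +11 ticks per 50 ms
    lag10 = 1
    lag50 = max(1, int(round(0.05 / dt)))
    moving = np.zeros(n_out, dtype=bool)
    state = False
    for i in range(n_out):
        d10 = c[i] - c[max(0, i - lag10)]
        d50 = c[i] - c[max(0, i - lag50)]
        if d10 >= 2:
            state = True
        elif d50 < 11:
            state = False
        moving[i] = state
    return SpeedSeries(times, speed, moving, direction)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs; stop is exclusive."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def segment_states(speed: SpeedSeries,
                   whisk: Optional[np.ndarray] = None,
                   config: Optional[AnalysisConfig] = None) -> EpochSet:
    """Label the session exhaustively with the four behavioral states."""
    config = config or AnalysisConfig()
    n = speed.times.size
    if n < 2:
        raise ValueError("speed series too short to segment")
    dt = float(np.median(np.diff(speed.times)))
    labels = np.full(n, "IM", dtype=object)

    if whisk is not None:
        whisk = np.asarray(whisk, dtype=bool)
        if whisk.size != n:
            raise ValueError("whisk channel must match the speed series")
        labels[whisk & ~speed.moving] = "WS"

    for s, e in _runs(speed.moving):
        duration = (e - s) * dt
        sustained = (duration > config.lm_min_duration
                     and speed.speed[s:e].mean() >= config.lm_speed_threshold)
        labels[s:e] = "LM" if sustained else "SM"

    intervals = []
    start = 0
    t_edge = np.append(speed.times, speed.times[-1] + dt)
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            intervals.append((t_edge[start], t_edge[i], labels[start]))
            start = i
    return EpochSet(intervals)
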