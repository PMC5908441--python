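"""LFP event and epoch detectors.

All filtering is zero-phase (forward-backward Butterworth, ``sosfiltfilt``),
so detected trough times on noiseless test signals sit within one sample of
the analytic trough.  Detectors are invariant to adding a constant offset to
the trace and equivariant to time shifts.

Detectors
---------
- theta / non-theta epochs from a sliding theta(5-12 Hz)/delta(2-4 Hz)
  power ratio,
- theta phase by linear interpolation between filtered-trace troughs
  (0° and 360° at the troughs),
- mid-gamma (55-80 Hz) troughs of cycles whose amplitude exceeds the mean
  cycle amplitude by 1 s.d.,
- sharp-wave ripples from smoothed 130-230 Hz envelope power crossing
  mean + 4 s.d., windows extended back to the mean,
- large-amplitude-irregular-activity (LIA) falling zero-crossings after
  0.08 s smoothing and 0.2 s DC removal, thinned to >= 0.2 s spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .data_model import EpochSet, EventSet, Lfp

__all__ = [
    "bandpass",
    "PhaseSeries",
    "detect_theta_epochs",
    "theta_phase",
    "detect_gamma_troughs",
    "gamma_cycles",
    "detect_swr",
    "detect_lia_cycles",
    "event_correlation",
]


def bandpass(lfp: Lfp, band: Tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the trace.

    Generous reflective padding (three periods of the band's low edge)
    suppresses the filter's edge transients.
    """
    nyq = lfp.rate / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist ({nyq} Hz)")
    sos = signal.butter(order, band, btype="bandpass", fs=lfp.rate, output="sos")
    padlen = min(lfp.samples.size - 1, int(3 * lfp.rate / band[0]))
    return signal.sosfiltfilt(sos, lfp.samples - lfp.samples.mean(),
                              padlen=padlen)


def _refine_extremum(x: np.ndarray, i: int) -> Tuple[float, float]:
    """Parabolic sub-sample refinement of a local extremum at index i.

    Returns (offset in samples within [-0.5, 0.5], refined value).
    """
    if i <= 0 or i >= x.size - 1:
        return 0.0, float(x[i])
    a, b, c = x[i - 1], x[i], x[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0, float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, float(b - 0.25 * (a - c) * d)


def _troughs(filtered: np.ndarray, rate: float, min_freq_sep: float
             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local minima with sub-sample refinement.

    Returns ``(indices, refined_times_in_samples, refined_values)``;
    minima are separated by at least half the band's shortest period.
    """
    distance = max(1, int(round(rate / min_freq_sep / 2.0)))
    idx, _ = signal.find_peaks(-filtered, distance=distance)
    offs = np.empty(idx.size)
    vals = np.empty(idx.size)
    for k, i in enumerate(idx):
        offs[k], vals[k] = _refine_extremum(filtered, i)
    return idx, idx + offs, vals


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    return signal.convolve(x, kernel, mode="same")


# ---------------------------------------------------------------------------
# theta
# ---------------------------------------------------------------------------

def detect_theta_epochs(lfp: Lfp, config: Optional[AnalysisConfig] = None) -> EpochSet:
    """Partition the trace into ``theta`` and ``non_theta`` epochs.

    The theta/delta power ratio is computed per sample over a sliding
    ``theta_ratio_window`` (power = moving average of the squared band-passed
    trace); samples with ratio >= ``theta_delta_ratio_threshold`` are theta.
    Epochs are closed morphologically: gaps shorter than ``theta_merge_gap``
    within a state are absorbed.
    """
    config = config or AnalysisConfig()
    if lfp.rate < 250:
        raise ValueError("theta epoch detection requires rate >= 250 Hz")
    win = int(round(config.theta_ratio_window * lfp.rate))
    if lfp.samples.size < win:
        raise ValueError("trace shorter than one analysis window")
    theta = bandpass(lfp, config.theta_band, config.theta_filter_order)
    delta = bandpass(lfp, config.delta_band, config.theta_filter_order)
    p_theta = _moving_average(theta ** 2, win)
    p_delta = _moving_average(delta ** 2, win)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_theta / p_delta
    mask = np.where(np.isfinite(ratio),
                    ratio >= config.theta_delta_ratio_threshold,
                    p_theta > 0)
    mask = _close_gaps(mask, int(round(config.theta_merge_gap * lfp.rate)))
    mask = ~_close_gaps(~mask, int(round(config.theta_merge_gap * lfp.rate)))
    return _mask_to_epochs(mask, lfp, "theta", "non_theta")


def _close_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False runs shorter than max_gap that sit between True runs."""
    out = mask.copy()
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = edges[mask[edges]] + 1          # True -> False transitions
    for s in starts:
        e = s
        while e < mask.size and not mask[e]:
            e += 1
        if e < mask.size and (e - s) < max_gap:
            out[s:e] = True
    return out


def _mask_to_epochs(mask: np.ndarray, lfp: Lfp, on: str, off: str) -> EpochSet:
    intervals = []
    boundaries = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    idx = np.concatenate([[0], boundaries, [mask.size]])
    for s, e in zip(idx[:-1], idx[1:]):
        label = on if mask[s] else off
        intervals.append((lfp.t0 + s / lfp.rate, lfp.t0 + e / lfp.rate, label))
    return EpochSet(intervals)


@dataclass
class PhaseSeries:
    """Trough-interpolated phase clock.

    Phase is 0° at each trough, increasing linearly to 360° at the next
    trough; times before the first or after the last trough have no phase
    (NaN).
    """

    troughs: np.ndarray

    def __post_init__(self) -> None:
        self.troughs = np.asarray(self.troughs, dtype=float)
        if self.troughs.size < 2:
            raise ValueError("a phase series needs at least two troughs")

    def at(self, t) -> np.ndarray:
        """Phase (degrees, [0, 360)) at the given times; NaN when uncovered."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.troughs, t, side="right") - 1
        out = np.full(t.shape, np.nan)
        ok = (idx >= 0) & (idx < self.troughs.size - 1)
        i = idx[ok]
        frac = (t[ok] - self.troughs[i]) / (self.troughs[i + 1] - self.troughs[i])
        out[ok] = (frac * 360.0) % 360.0
        return out

    def unwrapped(self, t) -> np.ndarray:
        """Cumulative phase (degrees, cycle index * 360 + phase)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.troughs, t, side="right") - 1
        out = np.full(t.shape, np.nan)
        ok = (idx >= 0) & (idx < self.troughs.size - 1)
        i = idx[ok]
        frac = (t[ok] - self.troughs[i]) / (self.troughs[i + 1] - self.troughs[i])
        out[ok] = (i + frac) * 360.0
        return out


def theta_phase(lfp: Lfp, config: Optional[AnalysisConfig] = None
                ) -> Tuple[PhaseSeries, EventSet]:
    """Theta phase clock and trough events of the band-passed trace."""
    config = config or AnalysisConfig()
    filtered = bandpass(lfp, config.theta_band, config.theta_filter_order)
    _, pos, _ = _troughs(filtered, lfp.rate, config.theta_band[1])
    if pos.size < 2:
        raise ValueError("fewer than two detectable theta troughs")
    times = lfp.t0 + pos / lfp.rate
    return PhaseSeries(times), EventSet(times, "theta_trough")


# ---------------------------------------------------------------------------
# mid-gamma
# ---------------------------------------------------------------------------

def gamma_cycles(lfp: Lfp, config: Optional[AnalysisConfig] = None
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """All gamma-trough times and a supra-threshold mask per cycle.

    Cycle i spans trough i to trough i+1; its amplitude is the peak-to-trough
    difference of the band-passed trace within that span (sub-sample refined
    extremum values).  A cycle is supra-threshold when its amplitude strictly
    exceeds the mean cycle amplitude + ``gamma_amp_sd_threshold`` s.d.; an
    essentially constant amplitude distribution (coefficient of variation
    below 1%, the s.d. = 0 degenerate case up to numerical residue) yields no
    events at all.  The mask for the final trough, which starts no full
    cycle, is False.
    """
    config = config or AnalysisConfig()
    if lfp.rate < 400:
        raise ValueError("gamma trough detection requires rate >= 400 Hz")
    filtered = bandpass(lfp, config.mid_gamma_band, config.gamma_filter_order)
    idx, pos, tvals = _troughs(filtered, lfp.rate, config.mid_gamma_band[1])
    times = lfp.t0 + pos / lfp.rate
    supra = np.zeros(times.size, dtype=bool)
    if times.size < 2:
        return times, supra
    amps = np.empty(idx.size - 1)
    for i in range(idx.size - 1):
        j = idx[i] + int(np.argmax(filtered[idx[i]:idx[i + 1] + 1]))
        _, peak = _refine_extremum(filtered, j)
        amps[i] = peak - tvals[i]
    # exclude cycles inside the filter settle margin at the trace edges
    # (edge transients inflate amplitudes there)
    margin = 5.0 * lfp.rate / config.mid_gamma_band[0]
    interior = (idx[:-1] > margin) & (idx[1:] < filtered.size - margin)
    if not interior.any():
        interior = np.ones(amps.size, dtype=bool)
    mean, sd = amps[interior].mean(), amps[interior].std()
    if sd < 0.01 * abs(mean):
        return times, supra
    supra[:-1] = interior & (amps > mean + config.gamma_amp_sd_threshold * sd)
    return times, supra


def detect_gamma_troughs(lfp: Lfp, config: Optional[AnalysisConfig] = None) -> EventSet:
    """Troughs of supra-threshold mid-gamma cycles."""
    times, supra = gamma_cycles(lfp, config)
    return EventSet(times[supra], "gamma_trough")


# ---------------------------------------------------------------------------
# sharp-wave ripples
# ---------------------------------------------------------------------------

def detect_swr(lfp: Lfp, config: Optional[AnalysisConfig] = None) -> EventSet:
    """Sharp-wave ripple windows from ripple-band envelope power.

    Power is the squared magnitude of the analytic (Hilbert) envelope of the
    130-230 Hz band-passed trace, smoothed over ``ripple_power_smooth``.
    Supra-threshold segments (mean + 4 s.d.) are extended outward to where
    the power falls back to the mean; overlapping windows merge.  The event
    time is the power maximum inside each window.
    """
    config = config or AnalysisConfig()
    if lfp.rate < 500:
        raise ValueError("SWR detection requires rate >= 500 Hz")
    filtered = bandpass(lfp, config.ripple_band, config.ripple_filter_order)
    power = np.abs(signal.hilbert(filtered)) ** 2
    power = _moving_average(power, int(round(config.ripple_power_smooth * lfp.rate)))
    mean, sd = power.mean(), power.std()
    if sd == 0:
        return EventSet(np.empty(0), "swr", windows=np.empty((0, 2)))
    thresh = mean + config.ripple_power_sd_threshold * sd
    above = power > thresh
    if not above.any():
        return EventSet(np.empty(0), "swr", windows=np.empty((0, 2)))
    # supra-threshold runs
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    below_mean = power <= mean
    windows, peaks = [], []
    for s, e in zip(starts, ends):
        # extend to where power falls back to the mean
        ws = s
        while ws > 0 and not below_mean[ws - 1]:
            ws -= 1
        we = e
        while we < power.size and not below_mean[we]:
            we += 1
        if windows and ws <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], we))
        else:
            windows.append((ws, we))
    for ws, we in windows:
        peaks.append(ws + int(np.argmax(power[ws:we])))
    t = lfp.t0 + np.asarray(peaks, dtype=float) / lfp.rate
    w = lfp.t0 + np.asarray(windows, dtype=float) / lfp.rate
    # invariant start < time <= end
    w[:, 1] = np.maximum(w[:, 1], t + 0.5 / lfp.rate)
    return EventSet(t, "swr", windows=w)


# ---------------------------------------------------------------------------
# LIA
# ---------------------------------------------------------------------------

def detect_lia_cycles(lfp: Lfp, config: Optional[AnalysisConfig] = None) -> EventSet:
    """Falling zero-crossings of the smoothed, DC-removed trace.

    Smoothing is a 0.08 s moving average; DC removal subtracts a 0.2 s moving
    average.  Successive crossings closer than ``lia_min_interval`` are
    thinned, keeping the earlier one.
    """
    config = config or AnalysisConfig()
    if lfp.rate < 100:
        raise ValueError("LIA detection requires rate >= 100 Hz")
    x = _moving_average(lfp.samples, int(round(config.lia_smooth_window * lfp.rate)))
    x = x - _moving_average(x, int(round(config.lia_dc_window * lfp.rate)))
    falling = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
    times = lfp.t0 + falling / lfp.rate
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= config.lia_min_interval:
            kept.append(t)
    return EventSet(np.asarray(kept), "lia_falling")


# ---------------------------------------------------------------------------
# event correlation
# ---------------------------------------------------------------------------

def event_correlation(events_a: EventSet | np.ndarray,
                      events_b: EventSet | np.ndarray,
                      window: float = 0.25,
                      binwidth: float = 0.01) -> Tuple[np.ndarray, np.ndarray]:
    """Counts of a-events in time bins relative to each b-event.

    Returns ``(lags, counts)`` with lag bin centers spanning the symmetric
    ``[-window, window]`` interval.
    """
    a = events_a.times if isinstance(events_a, EventSet) else np.asarray(events_a)
    b = events_b.times if isinstance(events_b, EventSet) else np.asarray(events_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("event_correlation requires non-empty event sets")
    nbins = int(round(2 * window / binwidth))
    edges = -window + binwidth * np.arange(nbins + 1)
    counts = np.zeros(nbins, dtype=int)
    for t in b:
        lo = np.searchsorted(a, t - window)
        hi = np.searchsorted(a, t + window)
        d = a[lo:hi] - t
        counts += np.histogram(d, bins=edges)[0]
    lags = (edges[:-1] + edges[1:]) / 2.0
    return lags, counts
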