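"""Burst detection and per-cell rate/burst statistics.

A burst is a maximal run of at least ``min_burst_spikes`` (default 4, the
literal reading of "a train of >3 spikes") consecutive spikes whose
interspike intervals are all below ``isi_max`` (40 ms).  Rates and burst
incidence are means over non-overlapping 1 s windows anchored at each epoch
start (trailing partial windows dropped); burst duration and interburst
interval are medians with hinge-style IQRs (see :func:`hinge_quartiles`);
intraburst frequency per burst is ``(n_spikes - 1) / duration``.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .data_model import (BEHAVIOR_STATES, Burst, CellMetrics, EpochSet,
                         EventSet, SpikeTrain, STATE_METRICS)

__all__ = [
    "detect_bursts",
    "hinge_quartiles",
    "burst_statistics",
    "firing_rates",
    "burst_incidence",
    "lm_im_index",
    "autocorrelogram",
    "spikes_per_cycle",
    "cell_metrics",
]


def detect_bursts(train: SpikeTrain,
                  config: Optional[AnalysisConfig] = None) -> List[Burst]:
    """Maximal runs of consecutive sub-``isi_max`` ISIs with enough spikes."""
    config = config or AnalysisConfig()
    t = train.times
    if t.size < config.min_burst_spikes:
        return []
    short = np.diff(t) < config.isi_max
    bursts: List[Burst] = []
    i = 0
    while i < short.size:
        if short[i]:
            j = i
            while j < short.size and short[j]:
                j += 1
            if (j - i) + 1 >= config.min_burst_spikes:
                bursts.append(Burst(t[i:j + 1]))
            i = j
        i += 1
    return bursts


def hinge_quartiles(values: Sequence[float]) -> Tuple[float, float, float]:
    """(Q1, median, Q3) with quartiles at position h = n*p + 1/2.

    Linear interpolation between order statistics; identical to Tukey hinges
    for even n.  This is the convention the package uses for every reported
    IQR.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")

    def q(p: float) -> float:
        h = n * p + 0.5
        lo = int(math.floor(h)) - 1
        frac = h - math.floor(h)
        lo = min(max(lo, 0), n - 1)
        hi = min(lo + 1, n - 1)
        return float(x[lo] + frac * (x[hi] - x[lo]))

    return q(0.25), q(0.5), q(0.75)


def _epoch_windows(epochs: EpochSet, label: str, width: float) -> List[Tuple[float, float]]:
    """Non-overlapping windows anchored at each epoch start, partials dropped."""
    wins = []
    for s, e in epochs.select(label):
        k = int(math.floor((e - s) / width + 1e-9))
        wins.extend((s + i * width, s + (i + 1) * width) for i in range(k))
    return wins


def _window_counts(times: np.ndarray, windows: List[Tuple[float, float]]) -> np.ndarray:
    return np.array([np.searchsorted(times, e) - np.searchsorted(times, s)
                     for s, e in windows], dtype=float)


def firing_rates(train: SpikeTrain, epochs: EpochSet,
                 config: Optional[AnalysisConfig] = None,
                 states: Sequence[str] = BEHAVIOR_STATES) -> Dict[str, Tuple[float, float]]:
    """Per-state mean ± s.d. firing rate from 1 s window counts.

    States whose total usable time is below one window are unavailable
    (NaN, NaN).
    """
    config = config or AnalysisConfig()
    out: Dict[str, Tuple[float, float]] = {}
    for st in states:
        wins = _epoch_windows(epochs, st, config.rate_window)
        if not wins:
            out[st] = (math.nan, math.nan)
            continue
        counts = _window_counts(train.times, wins) / config.rate_window
        sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
        out[st] = (float(counts.mean()), sd)
    return out


def burst_incidence(bursts: Sequence[Burst], epochs: EpochSet,
                    config: Optional[AnalysisConfig] = None,
                    states: Sequence[str] = BEHAVIOR_STATES) -> Dict[str, Tuple[float, float]]:
    """Bursts per 1 s window (mean ± s.d.), bursts assigned by first spike."""
    config = config or AnalysisConfig()
    starts = np.array(sorted(b.start for b in bursts))
    out: Dict[str, Tuple[float, float]] = {}
    for st in states:
        wins = _epoch_windows(epochs, st, config.rate_window)
        if not wins:
            out[st] = (math.nan, math.nan)
            continue
        counts = _window_counts(starts, wins) / config.rate_window
        sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
        out[st] = (float(counts.mean()), sd)
    return out


def burst_statistics(bursts: Sequence[Burst], epochs: EpochSet,
                     states: Sequence[str] = BEHAVIOR_STATES
                     ) -> Dict[str, Dict[str, float]]:
    """Per-state burst duration, interburst interval and intraburst frequency.

    Bursts belong to the state of their first spike.  Interburst intervals
    (first spike to first spike) are measured only between consecutive bursts
    within the same state epoch.  States with no bursts yield NaN.
    """
    out: Dict[str, Dict[str, float]] = {}
    for st in states:
        sel = [b for b in bursts if epochs.contains(np.array([b.start]), st)[0]]
        stats = {
            "burst_duration_median": math.nan, "burst_duration_iqr": math.nan,
            "interburst_median": math.nan, "interburst_iqr": math.nan,
            "intraburst_mean": math.nan, "intraburst_sd": math.nan,
        }
        if sel:
            durs = [b.duration_ms for b in sel]
            q1, med, q3 = hinge_quartiles(durs)
            stats["burst_duration_median"] = med
            stats["burst_duration_iqr"] = q3 - q1
            freqs = np.array([b.intraburst_freq for b in sel])
            stats["intraburst_mean"] = float(freqs.mean())
            stats["intraburst_sd"] = (float(freqs.std(ddof=1))
                                      if freqs.size > 1 else 0.0)
            ibis = []
            for s, e in epochs.select(st):
                inside = sorted(b.start for b in sel if s <= b.start < e)
                ibis.extend(1e3 * (b2 - b1) for b1, b2 in zip(inside, inside[1:]))
            if ibis:
                q1, med, q3 = hinge_quartiles(ibis)
                stats["interburst_median"] = med
                stats["interburst_iqr"] = q3 - q1
        out[st] = stats
    return out


def lm_im_index(rate_lm: float, rate_im: float) -> float:
    """Normalized locomotion-immobility rate index (LM - IM)/(LM + IM)."""
    if math.isnan(rate_lm) or math.isnan(rate_im):
        raise ValueError("both rates must be available")
    if rate_lm == rate_im == 0:
        return math.nan
    return (rate_lm - rate_im) / (rate_lm + rate_im)


def autocorrelogram(train: SpikeTrain, binwidth: float = 0.005,
                    max_lag: float = 0.5, epochs: Optional[EpochSet] = None,
                    label: Optional[str] = None,
                    peak_range: Tuple[float, float] = (0.080, 0.250),
                    smooth_bins: int = 3
                    ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Spike autocorrelogram and its first rhythmic peak lag.

    Returns ``(lags, counts, peak_lag)``.  Counts are symmetric and exclude
    the zero-lag self-pairs; the peak is the maximum of the boxcar-smoothed
    counts within ``peak_range`` (NaN when the histogram is empty there).
    If ``epochs``/``label`` are given, only reference spikes inside those
    epochs contribute.
    """
    t = train.times
    if t.size < 2:
        raise ValueError("autocorrelogram requires at least two spikes")
    ref = t if label is None else t[epochs.contains(t, label)]
    nbins = int(round(2 * max_lag / binwidth))
    edges = -max_lag + binwidth * np.arange(nbins + 1)
    counts = np.zeros(nbins, dtype=float)
    for x in ref:
        lo = np.searchsorted(t, x - max_lag)
        hi = np.searchsorted(t, x + max_lag)
        d = t[lo:hi] - x
        d = d[d != 0.0]
        counts += np.histogram(d, bins=edges)[0]
    lags = (edges[:-1] + edges[1:]) / 2.0
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(counts, kernel, mode="same")
    in_range = (lags >= peak_range[0]) & (lags <= peak_range[1])
    if not in_range.any() or smoothed[in_range].max() == 0:
        peak = math.nan
    else:
        peak = float(lags[in_range][np.argmax(smoothed[in_range])])
    return lags, counts, peak


def spikes_per_cycle(train: SpikeTrain,
                     theta_troughs: EventSet | np.ndarray) -> Tuple[float, float]:
    """Mean ± s.d. spike count per trough-to-trough theta cycle.

    Cycles with zero spikes are included.
    """
    troughs = (theta_troughs.times if isinstance(theta_troughs, EventSet)
               else np.asarray(theta_troughs, dtype=float))
    if troughs.size < 2:
        raise ValueError("need at least two theta troughs")
    counts = np.diff(np.searchsorted(train.times, troughs)).astype(float)
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return float(counts.mean()), sd


def cell_metrics(train: SpikeTrain, epochs: EpochSet,
                 config: Optional[AnalysisConfig] = None,
                 cell: Optional[str] = None) -> CellMetrics:
    """Assemble the per-state rate/burst portion of a CellMetrics row."""
    config = config or AnalysisConfig()
    bursts = detect_bursts(train, config)
    rates = firing_rates(train, epochs, config)
    incidence = burst_incidence(bursts, epochs, config)
    bstats = burst_statistics(bursts, epochs)
    per_state: Dict[str, Dict[str, float]] = {}
    for st in BEHAVIOR_STATES:
        d = {m: math.nan for m in STATE_METRICS}
        d["rate_mean"], d["rate_sd"] = rates[st]
        d["burst_incidence_mean"], d["burst_incidence_sd"] = incidence[st]
        d.update(bstats[st])
        per_state[st] = d
    return CellMetrics(cell=cell or train.unit_id, per_state=per_state)
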