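"""Firing-rate modulation during sharp-wave ripples.

Compares a unit's rate inside SWR windows against its baseline rate outside
SWRs, with theta periods excluded from the baseline.  Two tests are
available: the closed-form two-sided Poisson tail on the inside spike count
given the outside rate, and an empirical control that re-draws the SWR
windows (same durations) 1000 times from the eligible baseline time.  Units
with fewer than ``min_swr_count`` detected SWRs are refused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .data_model import EpochSet, EventSet, SpikeTrain

__all__ = ["SwrTestResult", "swr_rate_test", "peri_swr_histogram"]


@dataclass
class SwrTestResult:
    status: str                # "ok" | "too_few_swrs"
    n_swr: int
    rate_inside: float = math.nan      # Hz
    lambda_outside: float = math.nan   # Hz
    p_poisson: float = math.nan
    p_shuffle: float = math.nan
    direction: str = ""                # "increase" | "decrease" | "none"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _count_in_windows(times: np.ndarray, windows: np.ndarray) -> int:
    lo = np.searchsorted(times, windows[:, 0])
    hi = np.searchsorted(times, windows[:, 1], side="right")
    return int((hi - lo).sum())


def _eligible_intervals(span: Tuple[float, float], swr: EventSet,
                        theta_epochs: Optional[EpochSet]) -> List[Tuple[float, float]]:
    """Session time outside SWR windows and outside theta epochs."""
    blockers = [tuple(w) for w in swr.windows]
    if theta_epochs is not None:
        blockers += theta_epochs.select("theta")
    blockers.sort()
    out, cursor = [], span[0]
    for s, e in blockers:
        if s > cursor:
            out.append((cursor, min(s, span[1])))
        cursor = max(cursor, e)
        if cursor >= span[1]:
            break
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return [(s, e) for s, e in out if e - s > 1e-9]


def swr_rate_test(train: SpikeTrain, swr: EventSet,
                  theta_epochs: Optional[EpochSet] = None,
                  span: Optional[Tuple[float, float]] = None,
                  config: Optional[AnalysisConfig] = None,
                  rng: Optional[np.random.Generator] = None) -> SwrTestResult:
    """Poisson and shuffle tests of SWR firing modulation.

    ``span`` is the analyzed session interval (defaults to the extent of the
    data).  The Poisson p is two-sided (doubled smaller tail, capped at 1);
    the shuffle p is the add-one-corrected fraction of ``n_shuffles``
    re-drawn same-duration window sets whose rate deviates from the outside
    rate at least as much as the observed inside rate.
    """
    config = config or AnalysisConfig()
    if swr.kind != "swr":
        raise ValueError("expected an EventSet of kind 'swr'")
    if len(swr) < config.min_swr_count:
        return SwrTestResult("too_few_swrs", n_swr=len(swr))
    if span is None:
        lo = min(train.times[0] if len(train) else np.inf, swr.windows[:, 0].min())
        hi = max(train.times[-1] if len(train) else -np.inf, swr.windows[:, 1].max())
        span = (float(lo), float(hi))

    durations = swr.durations
    total_dur = float(durations.sum())
    if total_dur <= 0:
        raise ValueError("SWR windows have zero total duration")
    inside_count = _count_in_windows(train.times, swr.windows)
    rate_inside = inside_count / total_dur

    eligible = _eligible_intervals(span, swr, theta_epochs)
    out_dur = sum(e - s for s, e in eligible)
    if out_dur <= 0:
        raise ValueError("no eligible time outside SWRs and theta")
    out_count = sum(
        int(np.searchsorted(train.times, e, side="right")
            - np.searchsorted(train.times, s))
        for s, e in eligible)
    lam = out_count / out_dur

    mu = lam * total_dur
    lower = sps.poisson.cdf(inside_count, mu)
    upper = sps.poisson.sf(inside_count - 1, mu)   # P(X >= k)
    p_poisson = min(1.0, 2.0 * min(lower, upper))
    direction = ("increase" if rate_inside > lam
                 else "decrease" if rate_inside < lam else "none")

    # shuffle control: same-duration windows re-drawn from eligible time
    # (n_shuffles = 0 skips it, e.g. for Poisson-only calibration runs)
    p_shuffle = math.nan
    if config.n_shuffles > 0:
        rng = rng or np.random.default_rng(config.rng_seed)
        lengths = np.array([e - s for s, e in eligible])
        starts = np.array([s for s, _ in eligible])
        counts = np.zeros(config.n_shuffles)
        for d in durations:          # batched over shuffles per window
            fit = lengths - d
            w = np.clip(fit, 0.0, None)
            if w.sum() <= 0:
                continue
            i = rng.choice(lengths.size, size=config.n_shuffles, p=w / w.sum())
            s0 = starts[i] + rng.uniform(size=config.n_shuffles) * fit[i]
            counts += (np.searchsorted(train.times, s0 + d, side="right")
                       - np.searchsorted(train.times, s0))
        shuffled = counts / total_dur
        observed_dev = abs(rate_inside - lam)
        extreme = int(np.sum(np.abs(shuffled - lam) >= observed_dev - 1e-12))
        p_shuffle = (extreme + 1) / (config.n_shuffles + 1)

    return SwrTestResult("ok", n_swr=len(swr), rate_inside=rate_inside,
                         lambda_outside=lam, p_poisson=p_poisson,
                         p_shuffle=p_shuffle, direction=direction)


def peri_swr_histogram(train: SpikeTrain, swr: EventSet,
                       window: float = 0.5, binwidth: float = 0.02
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Peri-SWR time histogram of firing rate (Hz) around SWR event times."""
    if len(swr) == 0:
        raise ValueError("no SWR events")
    nbins = int(round(2 * window / binwidth))
    edges = -window + binwidth * np.arange(nbins + 1)
    counts = np.zeros(nbins)
    for t in swr.times:
        d = train.times[(train.times >= t - window) & (train.times < t + window)] - t
        counts += np.histogram(d, bins=edges)[0]
    rate = counts / (len(swr) * binwidth)
    return (edges[:-1] + edges[1:]) / 2.0, rate
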