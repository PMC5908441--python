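"""Circular statistics of spikes and LFP events against oscillation phase.

Phase convention, fixed package-wide: degrees, with 0° (= 360°) at the
oscillation trough and 180° at the peak.  Internally angles are converted to
radians only inside the resultant-vector arithmetic.

The Rayleigh test for circular uniformity uses the classical approximation
``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with resultant length
``R = n * r``, accurate to a few units in the third decimal for n >= 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .data_model import EventSet, Lfp, PhaseStats, SpikeTrain
from . import oscillations

__all__ = [
    "rayleigh_p",
    "circular_stats",
    "circular_mean_deg",
    "circular_distance_deg",
    "assign_phase",
    "gamma_coupling",
    "GammaCouplingResult",
    "lfp_trough_coupling",
    "phase_histogram",
]


def rayleigh_p(n: float, r: float) -> float:
    """Rayleigh uniformity test p-value from sample size and vector length."""
    if n <= 0:
        raise ValueError("n must be positive")
    big_r2 = (n * r) ** 2
    p = math.exp(min(0.0, math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r2))
                     - (1.0 + 2.0 * n)))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def _resultant(phases_deg: np.ndarray,
               weights: Optional[np.ndarray]) -> Tuple[float, float, float]:
    rad = np.deg2rad(np.asarray(phases_deg, dtype=float))
    if weights is None:
        w = np.ones_like(rad)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != rad.shape:
            raise ValueError("weights must match phases")
    n = w.sum()
    c = float(np.sum(w * np.cos(rad)))
    s = float(np.sum(w * np.sin(rad)))
    return c, s, float(n)


def circular_mean_deg(phases_deg: Sequence[float],
                      weights: Optional[Sequence[float]] = None) -> float:
    c, s, n = _resultant(np.asarray(phases_deg), None if weights is None
                         else np.asarray(weights))
    return math.degrees(math.atan2(s, c)) % 360.0


def circular_distance_deg(a: float, b: float) -> float:
    """Absolute circular distance between two angles, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def circular_stats(phases_deg: Sequence[float],
                   weights: Optional[Sequence[float]] = None) -> PhaseStats:
    """Mean phase, mean vector length r and Rayleigh p of a phase sample."""
    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.size == 0:
        raise ValueError("circular_stats requires at least one phase")
    c, s, n = _resultant(phases_deg, None if weights is None
                         else np.asarray(weights, dtype=float))
    if n <= 0:
        raise ValueError("total weight must be positive")
    r = math.hypot(c, s) / n
    r = min(r, 1.0)
    mean = math.degrees(math.atan2(s, c)) % 360.0
    return PhaseStats(mean_phase=mean, r=r, p=rayleigh_p(n, r),
                      n=int(round(n)))


def assign_phase(train: SpikeTrain,
                 phase: "oscillations.PhaseSeries") -> Tuple[np.ndarray, int]:
    """Phase (degrees) of each covered spike; returns (phases, n_dropped).

    Spikes outside the trough-covered span are dropped with their count
    reported; raises if no spike is covered.
    """
    phases = phase.at(train.times)
    keep = ~np.isnan(phases)
    dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no spikes covered by the phase series")
    return phases[keep], dropped


@dataclass
class GammaCouplingResult:
    status: str                       # "ok" | "no_cross_frequency_coupling" | "no_spikes_in_cycles"
    stats: Optional[PhaseStats]
    n_spikes_in_cycles: int
    trough_theta_stats: Optional[PhaseStats] = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def gamma_coupling(train: SpikeTrain, lfp: Lfp,
                   theta_phase: "oscillations.PhaseSeries",
                   config: Optional[AnalysisConfig] = None,
                   gate_window_deg: float = 45.0) -> GammaCouplingResult:
    """Spike coupling to mid-gamma cycles, gated on theta-gamma coupling.

    Gate: supra-threshold gamma troughs must themselves be significantly
    coupled to the theta cycle with a mean phase within ``gate_window_deg``
    of the theta peak (180°).  Only then are spike phases measured, and only
    for spikes inside supra-threshold gamma cycles.
    """
    config = config or AnalysisConfig()
    troughs_all, supra = oscillations.gamma_cycles(lfp, config)
    supra_times = troughs_all[supra]
    if supra_times.size < 10:
        return GammaCouplingResult("no_cross_frequency_coupling", None, 0)
    tphases = theta_phase.at(supra_times)
    tphases = tphases[~np.isnan(tphases)]
    if tphases.size < 10:
        return GammaCouplingResult("no_cross_frequency_coupling", None, 0)
    tstats = circular_stats(tphases)
    if (tstats.p >= 0.05
            or circular_distance_deg(tstats.mean_phase, 180.0) > gate_window_deg):
        return GammaCouplingResult("no_cross_frequency_coupling", None, 0,
                                   trough_theta_stats=tstats)

    # gamma phase by interpolation between consecutive filtered-trace troughs;
    # keep spikes whose cycle starts at a supra-threshold trough
    gphase = oscillations.PhaseSeries(troughs_all)
    idx = np.searchsorted(troughs_all, train.times, side="right") - 1
    in_span = (idx >= 0) & (idx < troughs_all.size - 1)
    keep = np.zeros(train.times.size, dtype=bool)
    keep[in_span] = supra[idx[in_span]]
    if not keep.any():
        return GammaCouplingResult("no_spikes_in_cycles", None, 0,
                                   trough_theta_stats=tstats)
    phases = gphase.at(train.times[keep])
    phases = phases[~np.isnan(phases)]
    if phases.size == 0:
        return GammaCouplingResult("no_spikes_in_cycles", None, 0,
                                   trough_theta_stats=tstats)
    return GammaCouplingResult("ok", circular_stats(phases), int(phases.size),
                               trough_theta_stats=tstats)


def lfp_trough_coupling(target: Lfp,
                        reference_phase: "oscillations.PhaseSeries",
                        config: Optional[AnalysisConfig] = None,
                        band: Optional[Tuple[float, float]] = None) -> PhaseStats:
    """Coupling of target-LFP theta troughs to a reference phase clock.

    Detects troughs of the band-passed *target* trace and evaluates their
    circular distribution on the reference phase (e.g. entorhinal troughs on
    the CA1 theta clock).
    """
    config = config or AnalysisConfig()
    overlap = (max(target.t0, reference_phase.troughs[0]),
               min(target.t_end, reference_phase.troughs[-1]))
    if overlap[1] - overlap[0] < 10.0:
        raise ValueError("target and reference must overlap by at least 10 s")
    _, troughs = oscillations.theta_phase(target, config)
    phases = reference_phase.at(troughs.times)
    phases = phases[~np.isnan(phases)]
    if phases.size < 10:
        raise ValueError("fewer than 10 target troughs on the reference clock")
    return circular_stats(phases)


def phase_histogram(phases_deg: Sequence[float], binwidth: float = 20.0,
                    smoothing_bins: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized circular phase histogram, Gaussian-smoothed.

    Returns ``(bin_centers_deg, density)`` with the density summing to 1.
    Smoothing is a wrap-around convolution with a Gaussian of sigma
    ``smoothing_bins`` bins; 0 disables smoothing.
    """
    phases_deg = np.asarray(phases_deg, dtype=float) % 360.0
    if phases_deg.size == 0:
        raise ValueError("phase_histogram requires at least one phase")
    nbins = int(round(360.0 / binwidth))
    if not math.isclose(nbins * binwidth, 360.0):
        raise ValueError("binwidth must divide 360")
    counts, edges = np.histogram(phases_deg, bins=nbins, range=(0.0, 360.0))
    counts = counts.astype(float)
    if smoothing_bins > 0:
        k = np.arange(nbins)
        k = np.minimum(k, nbins - k)          # circular lag
        kernel = np.exp(-0.5 * (k / smoothing_bins) ** 2)
        kernel /= kernel.sum()
        counts = np.real(np.fft.ifft(np.fft.fft(counts) * np.fft.fft(kernel)))
        counts = np.clip(counts, 0.0, None)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / counts.sum()


def plot_phase_histogram(phases_deg, binwidth: float = 20.0,
                         smoothing_bins: float = 1.0, ax=None):
    """Polar plot of a phase histogram (trough at angle 0).  Returns the axes."""
    import matplotlib.pyplot as plt

    centers, dens = phase_histogram(phases_deg, binwidth, smoothing_bins)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.deg2rad(centers)
    ax.bar(theta, dens, width=np.deg2rad(binwidth), alpha=0.7,
           edgecolor="black", linewidth=0.5)
    stats = circular_stats(np.asarray(phases_deg))
    ax.annotate(f"mean {stats.mean_phase:.0f}°, r={stats.r:.2f}",
                xy=(0.5, 1.06), xycoords="axes fraction", ha="center")
    return ax
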