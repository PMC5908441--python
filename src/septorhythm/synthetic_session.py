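"""Ground-truth-annotated synthetic sessions (LFP + spikes + behavior).

The generator emulates the statistical structure the analysis assumes in a
head-fixed mouse recording:

- state-dependent 5-12 Hz theta with its amplitude and frequency highest
  during locomotion, plus 2-4 Hz delta and slow (< 5 Hz) irregular activity
  (LIA) between theta periods,
- 55-80 Hz mid-gamma whose envelope peaks at a configurable theta phase
  (default 180°, the theta peak under the trough-origin convention),
- 130-230 Hz ripple transients restricted to immobility,
- 1/f^alpha background noise,
- a unit firing rhythmic accommodating bursts phase-locked near the theta
  peak, with state-dependent mean rates (~55 Hz locomotion vs ~40 Hz
  immobility), burst incidence above 3 Hz, median burst duration in the
  60-120 ms range, intraburst frequency near 100 Hz and interburst
  intervals of 130-270 ms,
- an encoder counter and whisk flag consistent with the state schedule.

Every random element flows from one seed in :class:`SessionSpec`; the same
spec always produces the same session.  All ground-truth annotations (true
theta troughs, true high-amplitude gamma troughs, true ripple windows, true
spike phases, true bursts) are exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import AnalysisConfig
from .data_model import EpochSet, EventSet, Lfp, SpikeTrain, write_session

__all__ = ["SessionSpec", "GroundTruth", "generate_lfp", "generate_spikes",
           "generate_session", "default_schedule"]


def default_schedule(duration: float = 300.0) -> EpochSet:
    """Alternating behavioral blocks covering [0, duration)."""
    block = [("IM", 20.0), ("LM", 20.0), ("SM", 10.0), ("WS", 10.0)]
    intervals, t = [], 0.0
    i = 0
    while t < duration - 1e-9:
        label, width = block[i % len(block)]
        end = min(t + width, duration)
        intervals.append((t, end, label))
        t = end
        i += 1
    return EpochSet(intervals)


@dataclass
class SessionSpec:
    """Parameters of one synthetic session (defaults = study-like conditions)."""

    duration: float = 300.0
    rate: float = 1000.0                      # LFP sampling rate, Hz
    schedule: Optional[EpochSet] = None       # default: default_schedule(duration)

    # theta (Hz / arbitrary LFP units) per behavioral state
    theta_freq: Dict[str, float] = field(default_factory=lambda: {
        "LM": 8.0, "SM": 7.0, "WS": 6.5, "IM": 5.5})
    theta_amp: Dict[str, float] = field(default_factory=lambda: {
        "LM": 1.0, "SM": 0.7, "WS": 0.25, "IM": 0.15})
    delta_freq: float = 3.0
    delta_amp: Dict[str, float] = field(default_factory=lambda: {
        "LM": 0.1, "SM": 0.15, "WS": 0.45, "IM": 0.5})

    # mid-gamma envelope coupled to theta phase
    gamma_freq: float = 65.0
    gamma_amp: float = 0.25
    gamma_coupling_phase: float = 180.0       # deg; theta peak
    gamma_envelope_exponent: float = 4.0      # sharpness of the envelope lobe

    # ripples during immobility
    ripple_rate: float = 0.4                  # events/s during IM
    ripple_freq: float = 160.0                # Hz, inside 130-230
    ripple_duration: float = 0.060            # s
    ripple_amp: float = 1.2

    # LIA (slow irregular activity) during non-theta states
    lia_amp: Dict[str, float] = field(default_factory=lambda: {
        "LM": 0.0, "SM": 0.1, "WS": 0.5, "IM": 0.6})
    lia_band: Tuple[float, float] = (0.5, 4.0)

    # background noise
    noise_exponent: float = 1.0               # 1/f^alpha
    noise_amp: float = 0.1

    # spike model
    spike_mu: float = 178.0                   # preferred theta phase, deg
    spike_kappa: float = 8.0                  # von Mises concentration
    state_rate: Dict[str, float] = field(default_factory=lambda: {
        "LM": 55.0, "SM": 45.0, "WS": 40.0, "IM": 40.0})
    burst_prob: float = 0.72                  # burst emitted per theta cycle
    intraburst_start_freq: float = 160.0      # Hz, first ISI = 1/this
    accommodation_decay: float = 0.06         # ISI growth factor per spike
    cycle_skip_prob: float = 0.05             # burst spans two cycles
    isi_jitter: float = 0.05                  # relative s.d. on the first ISI

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = default_schedule(self.duration)
        if abs(self.schedule.duration() - self.duration) > 1e-6:
            raise ValueError("schedule must cover [0, duration)")
        min_theta = min(self.theta_freq.values())
        if self.duration < 1.0 / min_theta:
            raise ValueError("duration shorter than one theta cycle")
        for amp in (list(self.theta_amp.values()) + list(self.delta_amp.values())
                    + list(self.lia_amp.values()) + [self.gamma_amp, self.noise_amp]):
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")
        if self.spike_kappa < 0:
            raise ValueError("kappa must be >= 0")
        for st, r in self.state_rate.items():
            if r > self.intraburst_start_freq:
                raise ValueError(
                    f"state {st}: target rate {r} Hz incompatible with burst "
                    f"geometry (intraburst start frequency {self.intraburst_start_freq} Hz)")


@dataclass
class GroundTruth:
    theta_troughs: EventSet
    gamma_troughs: EventSet
    ripples: EventSet
    lia_cycles: int
    spike_phases: np.ndarray = field(default_factory=lambda: np.empty(0))
    bursts: List[np.ndarray] = field(default_factory=list)


def _state_series(spec: SessionSpec, t: np.ndarray) -> np.ndarray:
    return spec.schedule.label_at(t)


def _smooth_per_state(values: Dict[str, float], labels: np.ndarray,
                      rate: float, tau: float = 0.25) -> np.ndarray:
    """Per-sample state value, exponentially smoothed to avoid steps.

    The filter state is initialized at the boundary values, so a constant
    input passes through unchanged.
    """
    x = np.array([values[l] for l in labels], dtype=float)
    alpha = 1.0 / (tau * rate)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    from scipy.signal import lfilter, lfilter_zi
    zi = lfilter_zi(b, a)
    fwd, _ = lfilter(b, a, x, zi=zi * x[0])
    bwd, _ = lfilter(b, a, x[::-1], zi=zi * x[-1])
    return (fwd + bwd[::-1]) / 2.0


def _one_over_f_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _theta_phase_track(spec: SessionSpec, t: np.ndarray,
                       labels: np.ndarray) -> np.ndarray:
    """Continuous unwrapped theta phase (deg), frequency per state."""
    freq = _smooth_per_state(spec.theta_freq, labels, spec.rate)
    return 360.0 * np.cumsum(freq) / spec.rate


def generate_lfp(spec: SessionSpec,
                 rng: Optional[np.random.Generator] = None
                 ) -> Tuple[Lfp, GroundTruth, np.ndarray]:
    """Synthesize the LFP and exact ground-truth annotations.

    Returns ``(lfp, truth, theta_phase_track_deg)``; the phase track is the
    generator's own unwrapped theta phase at each sample (0° = trough) and
    also drives :func:`generate_spikes`.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    labels = _state_series(spec, t)

    phase = _theta_phase_track(spec, t, labels)
    theta_amp = _smooth_per_state(spec.theta_amp, labels, spec.rate)
    rad = np.deg2rad(phase)
    theta = -theta_amp * np.cos(rad)          # trough at phase 0, peak at 180

    # true theta troughs: unwrapped phase crossing multiples of 360
    k = np.floor(phase / 360.0)
    cross = np.flatnonzero(np.diff(k) > 0) + 1
    theta_troughs = EventSet(t[cross], "theta_trough")

    delta_amp = _smooth_per_state(spec.delta_amp, labels, spec.rate)
    delta = -delta_amp * np.cos(2 * np.pi * spec.delta_freq * t
                                + rng.uniform(0, 2 * np.pi))

    # mid-gamma: carrier with theta-phase-locked envelope
    gphase = 2 * np.pi * spec.gamma_freq * t
    lobe = ((1 + np.cos(rad - math.radians(spec.gamma_coupling_phase))) / 2.0
            ) ** spec.gamma_envelope_exponent
    genv = spec.gamma_amp * lobe * (theta_amp / max(spec.theta_amp.values()))
    gamma = -genv * np.cos(gphase)
    # true gamma troughs: carrier minima (phase multiple of 2*pi) in
    # high-envelope cycles (envelope above mean + 1 s.d. of trough envelopes)
    gk = np.floor(gphase / (2 * np.pi))
    gcross = np.flatnonzero(np.diff(gk) > 0) + 1
    env_at = genv[gcross]
    if env_at.size:
        gthresh = env_at.mean() + env_at.std()
        gtrue = t[gcross[env_at > gthresh]]
    else:
        gtrue = np.empty(0)
    gamma_troughs = EventSet(gtrue, "gamma_trough")

    # LIA: band-limited noise during non-theta states
    lia_amp = _smooth_per_state(spec.lia_amp, labels, spec.rate)
    from scipy.signal import butter, sosfiltfilt
    sos = butter(2, spec.lia_band, btype="bandpass", fs=spec.rate, output="sos")
    lia_carrier = sosfiltfilt(sos, rng.standard_normal(n))
    sd = lia_carrier.std()
    if sd > 0:
        lia_carrier /= sd
    lia = lia_amp * lia_carrier
    # ground-truth LIA cycle count: the cycle definition is operational
    # (smoothed, DC-removed falling zero-crossings), so apply it to the
    # noiseless LIA component and count crossings during immobility
    from .oscillations import detect_lia_cycles
    clean_ev = detect_lia_cycles(Lfp(lia, rate=spec.rate))
    count = int(np.sum(spec.schedule.contains(clean_ev.times, "IM")))

    # ripples during IM
    ripple_times, ripple_windows, ripple_wave = [], [], np.zeros(n)
    half = spec.ripple_duration / 2.0
    for s, e in spec.schedule.select("IM"):
        n_ev = rng.poisson(spec.ripple_rate * (e - s))
        starts = np.sort(rng.uniform(s + half, e - half, size=n_ev))
        for c in starts:
            if ripple_times and c - ripple_times[-1] < spec.ripple_duration * 2:
                continue
            i0 = int((c - half) * spec.rate)
            i1 = int((c + half) * spec.rate)
            if i0 < 0 or i1 >= n:
                continue
            m = i1 - i0
            env = np.hanning(m)
            ripple_wave[i0:i1] += (spec.ripple_amp * env
                                   * np.cos(2 * np.pi * spec.ripple_freq
                                            * (t[i0:i1] - c)))
            ripple_times.append(c)
            ripple_windows.append((c - half, c + half))
    ripples = EventSet(np.asarray(ripple_times), "swr",
                       windows=np.asarray(ripple_windows).reshape(-1, 2))

    noise = spec.noise_amp * _one_over_f_noise(n, spec.noise_exponent, rng)
    samples = theta + delta + gamma + lia + ripple_wave + noise
    lfp = Lfp(samples, rate=spec.rate, t0=0.0)
    truth = GroundTruth(theta_troughs=theta_troughs, gamma_troughs=gamma_troughs,
                        ripples=ripples, lia_cycles=count)
    return lfp, truth, phase


def generate_spikes(spec: SessionSpec, phase_track: np.ndarray,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[SpikeTrain, np.ndarray, List[np.ndarray]]:
    """Generate the bursting, theta-locked spike train.

    A burst is emitted per theta cycle with probability ``burst_prob``; its
    center phase is von Mises(mu, kappa).  Within a burst the ISI sequence
    starts at ``1/intraburst_start_freq`` and grows by the accommodation
    factor per spike (non-decreasing ISIs).  The spikes per burst are drawn
    so the per-state mean rate matches ``state_rate`` in expectation.

    Returns ``(train, true_spike_phases_deg, true_bursts)``.
    """
    rng = rng or np.random.default_rng(spec.rng_seed + 1)
    n = phase_track.size
    t = np.arange(n) / spec.rate
    if abs(t[-1] - spec.duration) > 1.0:
        raise ValueError("phase track does not cover the session")
    labels = _state_series(spec, t)

    # invert the unwrapped phase: time at a given cumulative phase
    def time_of_phase(p: np.ndarray) -> np.ndarray:
        return np.interp(p, phase_track, t)

    n_cycles = int(phase_track[-1] // 360.0)
    spikes: List[float] = []
    phases: List[float] = []
    bursts: List[np.ndarray] = []
    cyc = 0
    while cyc < n_cycles:
        # state at this cycle's trough
        t_cycle = time_of_phase(np.array([cyc * 360.0]))[0]
        st = spec.schedule.label_at(np.array([t_cycle]))[0] or "IM"
        f_theta = spec.theta_freq[st]
        expected_per_cycle = spec.state_rate[st] / (spec.burst_prob * f_theta)
        if rng.random() >= spec.burst_prob:
            cyc += 1
            continue
        # n_spk = 4 + Poisson keeps E[n_spk] = expected_per_cycle (for >= 4),
        # so per-state rate = burst_prob * f_theta * E[n_spk] hits the target
        n_spk = 4 + rng.poisson(max(expected_per_cycle - 4.0, 0.0))
        skip = rng.random() < spec.cycle_skip_prob
        if skip:
            n_spk *= 2
        center = rng.vonmises(math.radians(spec.spike_mu), spec.spike_kappa) \
            if spec.spike_kappa > 0 else rng.uniform(-math.pi, math.pi)
        center_deg = math.degrees(center) % 360.0
        isi0 = (1.0 / spec.intraburst_start_freq
                * math.exp(rng.normal(0.0, spec.isi_jitter)))
        isis = isi0 * (1.0 + spec.accommodation_decay) ** np.arange(n_spk - 1)
        offsets = np.concatenate([[0.0], np.cumsum(isis)])
        offsets -= offsets.mean()
        # the accommodating (front-loaded) burst skews the circular mean off
        # the time-mean; shift the placement so the burst's circular mean
        # lands exactly on the drawn von Mises phase
        phi = 2 * np.pi * f_theta * offsets
        delta = math.degrees(math.atan2(np.sin(phi).sum(), np.cos(phi).sum()))
        t_center = time_of_phase(np.array([cyc * 360.0 + center_deg - delta]))[0]
        burst_times = t_center + offsets
        burst_times = burst_times[(burst_times >= 0) & (burst_times < spec.duration)]
        if burst_times.size >= 2:
            if spikes and burst_times[0] <= spikes[-1]:
                keep = burst_times > spikes[-1] + 1e-4
                burst_times = burst_times[keep]
        if burst_times.size >= 2:
            spikes.extend(burst_times.tolist())
            bursts.append(burst_times)
        cyc += 2 if skip else 1

    times = np.asarray(spikes)
    phases = np.interp(times, t, phase_track) % 360.0
    return SpikeTrain(times, "synthetic"), phases, bursts


def generate_session(spec: Optional[SessionSpec] = None,
                     rng: Optional[np.random.Generator] = None):
    """Full synthetic session: LFP, spikes, behavior channels, ground truth.

    Returns a dict with keys ``lfp``, ``train``, ``schedule``, ``truth``,
    ``phase_track``, ``counter`` (encoder ticks at the LFP rate) and
    ``whisk`` (boolean whisk flag on the 10 ms behavioral grid).
    """
    spec = spec or SessionSpec()
    rng = rng or np.random.default_rng(spec.rng_seed)
    lfp, truth, phase = generate_lfp(spec, rng)
    train, spike_phases, bursts = generate_spikes(spec, phase, rng)
    truth.spike_phases = spike_phases
    truth.bursts = bursts

    # encoder counter: steady fast ticks during LM, sparse slow ticks in SM
    n = lfp.samples.size
    t = lfp.times
    labels = spec.schedule.label_at(t)
    tick_rate = np.where(labels == "LM", 2000.0,
                         np.where(labels == "SM", 60.0, 0.0))
    # SM emitted as brief movement pulses rather than sustained slow drift
    if (labels == "SM").any():
        sm_pulse = (np.sin(2 * np.pi * 0.8 * t) > 0.2)
        tick_rate = np.where((labels == "SM") & ~sm_pulse, 0.0, tick_rate)
        tick_rate = np.where((labels == "SM") & sm_pulse, 400.0, tick_rate)
    counter = np.cumsum(rng.poisson(tick_rate / spec.rate)).astype(np.int64)

    grid = np.arange(0.0, spec.duration, 0.010)
    whisk = spec.schedule.label_at(grid) == "WS"

    return {"lfp": lfp, "train": train, "schedule": spec.schedule,
            "truth": truth, "phase_track": phase, "counter": counter,
            "whisk": whisk, "spec": spec}


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Write ground-truth events as TSV files alongside a session directory."""
    from pathlib import Path
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ev in (("theta_trough", truth.theta_troughs),
                     ("gamma_trough", truth.gamma_troughs)):
        np.savetxt(path / f"truth_{name}.tsv", ev.times, fmt="%.6f")
    if len(truth.ripples):
        arr = np.column_stack([truth.ripples.times, truth.ripples.windows])
        np.savetxt(path / "truth_swr.tsv", arr, fmt="%.6f",
                   header="time\tstart\tend", comments="")
    else:
        (path / "truth_swr.tsv").write_text("time\tstart\tend\n")
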