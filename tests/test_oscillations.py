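"""LFP detectors: theta epochs and phase, gamma troughs, SWRs, LIA."""

import numpy as np
import pytest

from septorhythm import (AnalysisConfig, Lfp, detect_gamma_troughs,
                         detect_lia_cycles, detect_swr, detect_theta_epochs,
                         event_correlation, theta_phase)
from septorhythm.data_model import EventSet

from conftest import sine_lfp


# --- theta epochs ----------------------------------------------------------

def test_pure_theta_sinusoid_is_all_theta(theta_sine):
    ep = detect_theta_epochs(theta_sine)
    assert ep.duration("theta") == pytest.approx(theta_sine.duration, rel=0.01)


def test_pure_delta_sinusoid_is_all_non_theta():
    ep = detect_theta_epochs(sine_lfp(3.0))
    assert ep.duration("non_theta") == pytest.approx(10.0, rel=0.01)


def test_theta_epochs_partition_trace(theta_sine):
    ep = detect_theta_epochs(theta_sine)
    assert ep.duration() == pytest.approx(theta_sine.duration, abs=1e-6)


def test_short_trace_rejected():
    with pytest.raises(ValueError, match="window"):
        detect_theta_epochs(Lfp(np.zeros(100), rate=1000.0))


def test_theta_epochs_follow_generated_states(default_session):
    # theta dominates the generated locomotion / small-movement blocks
    ep = detect_theta_epochs(default_session["lfp"])
    sched = default_session["schedule"]
    grid = np.arange(0.0, 300.0, 0.01)
    det = ep.contains(grid, "theta")
    true = sched.contains(grid, "LM") | sched.contains(grid, "SM")
    jaccard = (det & true).sum() / (det | true).sum()
    assert jaccard > 0.8


# --- theta phase -----------------------------------------------------------

def test_phase_zero_at_trough_and_180_at_peak(theta_sine):
    phase, troughs = theta_phase(theta_sine)
    # troughs of x = -cos(2 pi f t) sit at multiples of 125 ms
    at_troughs = phase.at(troughs.times[1:-1])
    assert np.allclose(np.minimum(at_troughs, 360 - at_troughs), 0.0, atol=3.0)
    peaks = troughs.times[1:-2] + 0.0625       # half a cycle later
    assert np.allclose(phase.at(peaks), 180.0, atol=3.0)


def test_trough_times_within_one_sample_of_analytic(theta_sine):
    _, troughs = theta_phase(theta_sine)
    # troughs of -cos at k/8 s; the first/last second is excluded because the
    # zero-phase filter's reflective padding perturbs the very edge cycles
    analytic = np.arange(9, 72) * 0.125
    det = troughs.times
    matched = [det[np.argmin(np.abs(det - a))] for a in analytic]
    assert np.max(np.abs(np.array(matched) - analytic)) <= 1.0 / theta_sine.rate + 1e-9


def test_asymmetric_cycle_phase_is_interpolated_fraction():
    # sawtooth-like theta: maximum not at mid-cycle; its phase must equal
    # the fractional position between troughs, not 180°
    rate, f = 1000.0, 8.0
    t = np.arange(int(4 * rate)) / rate
    x = -np.cos(2 * np.pi * f * t) + 0.45 * np.cos(4 * np.pi * f * t + 0.6)
    lfp = Lfp(x, rate=rate)
    phase, troughs = theta_phase(lfp)
    tt = troughs.times
    i = len(tt) // 2
    seg = (t >= tt[i]) & (t <= tt[i + 1])
    t_max = t[seg][np.argmax(lfp.samples[seg])]
    expected = 360.0 * (t_max - tt[i]) / (tt[i + 1] - tt[i])
    assert phase.at(t_max) == pytest.approx(expected, abs=1.0)
    assert not np.isclose(expected, 180.0, atol=10.0)


def test_phase_monotone_within_cycle_and_nan_outside(theta_sine):
    phase, troughs = theta_phase(theta_sine)
    tt = troughs.times
    s = np.linspace(tt[3] + 1e-4, tt[4] - 1e-4, 50)
    vals = phase.at(s)
    assert np.all(np.diff(vals) > 0)
    assert np.isnan(phase.at(tt[0] - 0.01))


def test_detectors_offset_invariant_and_shift_equivariant(theta_sine):
    cfg = AnalysisConfig()
    _, tr0 = theta_phase(theta_sine, cfg)
    shifted = Lfp(theta_sine.samples + 100.0, rate=theta_sine.rate,
                  t0=theta_sine.t0 + 7.0)
    _, tr1 = theta_phase(shifted, cfg)
    assert np.allclose(tr1.times - 7.0, tr0.times, atol=1e-9)


# --- mid-gamma -------------------------------------------------------------

def test_constant_amplitude_gamma_yields_no_events():
    lfp = sine_lfp(65.0, duration=5.0)
    assert len(detect_gamma_troughs(lfp)) == 0


def test_only_high_amplitude_cycles_detected():
    rate = 1000.0
    t = np.arange(int(10 * rate)) / rate
    f = 65.0
    amp = np.ones_like(t)
    # boost every 10th cycle fivefold
    cycle = np.floor(t * f).astype(int)
    amp[cycle % 10 == 0] = 5.0
    lfp = Lfp(-amp * np.cos(2 * np.pi * f * t), rate=rate)
    ev = detect_gamma_troughs(lfp)
    assert len(ev) > 0
    # detections sit on (or, via filter ringing, immediately next to) the
    # boosted cycles and cover nearly all of them
    det_cycles = np.round(ev.times * f).astype(int)
    near = np.minimum(det_cycles % 10, (-det_cycles) % 10)
    assert np.all(near <= 1)
    boosted = np.arange(0, int(10 * f), 10)
    covered = np.isin(boosted, det_cycles)
    assert covered.mean() > 0.9


def test_gamma_troughs_concentrate_at_coupling_phase(default_session):
    lfp = default_session["lfp"]
    phase, _ = theta_phase(lfp)
    ev = detect_gamma_troughs(lfp)
    from septorhythm import circular_stats
    ph = phase.at(ev.times)
    st = circular_stats(ph[~np.isnan(ph)])
    # generator couples the gamma envelope to the theta peak (180 deg)
    assert abs(((st.mean_phase - 180.0) + 180) % 360 - 180) < 30.0
    assert st.r > 0.3


# --- SWR -------------------------------------------------------------------

def test_flat_trace_has_no_swr():
    assert len(detect_swr(Lfp(np.zeros(5000), rate=1000.0))) == 0


def test_injected_ripple_bursts_recovered():
    rng = np.random.default_rng(7)
    rate, dur = 1000.0, 120.0
    n = int(rate * dur)
    # 1/f background
    white = rng.standard_normal(n)
    fr = np.fft.rfftfreq(n)
    scale = np.zeros_like(fr)
    scale[1:] = fr[1:] ** -0.5
    shaped = np.fft.irfft(np.fft.rfft(white) * scale, n)
    noise = shaped / shaped.std() * 0.1
    t = np.arange(n) / rate
    centers = np.linspace(2.0, dur - 2.0, 60)
    x = noise.copy()
    for c in centers:
        m = (t >= c - 0.025) & (t < c + 0.025)
        x[m] += 0.8 * np.hanning(m.sum()) * np.cos(2 * np.pi * 150.0 * (t[m] - c))
    ev = detect_swr(Lfp(x, rate=rate))
    hits = sum(np.abs(ev.times - c).min() < 0.025 for c in centers)
    assert hits >= 54
    outside = [tt for tt in ev.times if np.abs(centers - tt).min() > 0.05]
    assert len(outside) == 0


def test_swr_windows_contain_event_time(default_session):
    ev = detect_swr(default_session["lfp"])
    assert np.all(ev.windows[:, 0] < ev.times)
    assert np.all(ev.times <= ev.windows[:, 1])


# --- LIA -------------------------------------------------------------------

def test_lia_crossings_at_slow_period():
    ev = detect_lia_cycles(sine_lfp(3.0, duration=10.0))
    spacing = np.diff(ev.times)
    assert np.allclose(spacing, 1.0 / 3.0, atol=0.02)


def test_lia_min_interval_thins_fast_crossings():
    ev = detect_lia_cycles(sine_lfp(10.0, duration=10.0))
    assert len(ev) > 0
    assert np.all(np.diff(ev.times) >= 0.2 - 1e-9)


def test_lia_cycle_count_on_synthetic_segment():
    from septorhythm import SessionSpec, generate_lfp
    from septorhythm.data_model import EpochSet
    spec = SessionSpec(duration=60.0, rng_seed=4,
                       schedule=EpochSet([(0.0, 60.0, "IM")]))
    lfp, truth, _ = generate_lfp(spec)
    ev = detect_lia_cycles(lfp)
    assert len(ev) == pytest.approx(truth.lia_cycles, rel=0.25)


# --- event correlation -----------------------------------------------------

def test_identical_event_sets_peak_at_zero_lag():
    a = EventSet(np.arange(0.5, 20.0, 0.25), "theta_trough")
    lags, counts = event_correlation(a, a, window=0.1, binwidth=0.01)
    assert counts[np.argmin(np.abs(lags))] == len(a)


def test_fixed_lag_gives_single_peak_bin():
    b = np.arange(1.0, 30.0, 0.5)
    a = EventSet(b + 0.1, "gamma_trough")
    b = EventSet(b, "theta_trough")
    lags, counts = event_correlation(a, b, window=0.25, binwidth=0.01)
    assert lags[np.argmax(counts)] == pytest.approx(0.105, abs=0.011)


def test_gamma_theta_correlogram_peaks_at_half_theta_period(default_session):
    lfp = default_session["lfp"]
    _, troughs = theta_phase(lfp)
    gamma = detect_gamma_troughs(lfp)
    lags, counts = event_correlation(gamma, troughs, window=0.15, binwidth=0.01)
    pos = (lags > 0)
    peak = lags[pos][np.argmax(counts[pos])]
    # locomotion theta ~8 Hz: gamma mass at the peak, ~ half a cycle (62 ms)
    assert peak == pytest.approx(0.0625, abs=0.021)
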