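"""Burst detection, rates and burst statistics."""

import math

import numpy as np
import pytest

from septorhythm import (AnalysisConfig, EpochSet, SpikeTrain, autocorrelogram,
                         burst_incidence, burst_statistics, detect_bursts,
                         firing_rates, hinge_quartiles, lm_im_index,
                         spikes_per_cycle)


def brute_force_bursts(times, isi_max=0.040, min_spikes=4):
    """Independent run-scanner oracle: maximal sub-isi_max runs."""
    out, run = [], [times[0]] if len(times) else []
    for a, b in zip(times, times[1:]):
        if b - a < isi_max:
            run.append(b)
        else:
            if len(run) >= min_spikes:
                out.append(list(run))
            run = [b]
    if len(run) >= min_spikes:
        out.append(list(run))
    return out


def test_four_fast_spikes_form_one_burst():
    bursts = detect_bursts(SpikeTrain(np.array([0.0, 0.010, 0.020, 0.030])))
    assert len(bursts) == 1
    assert bursts[0].duration_ms == pytest.approx(30.0)
    assert bursts[0].intraburst_freq == pytest.approx(100.0)


def test_slow_spikes_form_no_burst():
    assert detect_bursts(SpikeTrain(np.array([0.0, 0.05, 0.10, 0.15]))) == []


def test_burst_boundary_isi_is_strict():
    # 40 ms ISI does not extend a burst (criterion is ISI < 40 ms)
    tr = SpikeTrain(np.array([0.0, 0.01, 0.02, 0.03, 0.07]))
    bursts = detect_bursts(tr)
    assert len(bursts) == 1
    assert bursts[0].n_spikes == 4


def test_burst_detector_translation_invariant():
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0, 10, 200))
    b0 = detect_bursts(SpikeTrain(t))
    b1 = detect_bursts(SpikeTrain(t + 123.0))
    assert len(b0) == len(b1)
    for x, y in zip(b0, b1):
        assert np.allclose(y.spike_times - 123.0, x.spike_times)


def test_burst_detector_matches_oracle_on_random_trains():
    rng = np.random.default_rng(11)
    cfg = AnalysisConfig()
    for _ in range(500):
        n = rng.integers(2, 80)
        t = np.sort(rng.uniform(0, 2.0, n))
        t = t[np.concatenate([[True], np.diff(t) > 0])]
        got = [b.spike_times.tolist() for b in detect_bursts(SpikeTrain(t), cfg)]
        want = brute_force_bursts(t)
        assert got == want


def test_min_burst_spikes_configurable():
    cfg = AnalysisConfig(min_burst_spikes=3)
    tr = SpikeTrain(np.array([0.0, 0.01, 0.02]))
    assert len(detect_bursts(tr, cfg)) == 1
    assert detect_bursts(tr) == []


def test_hinge_quartiles_match_printed_conventions():
    # 16-sample even case: plain Tukey hinges
    lm = [187.7, 146.0, 179.6, 193.5, 135.8, 160.0, 129.0, 155.3,
          166.6, 133.1, 155.6, 147.4, 197.8, 233.8, 133.0, 163.1]
    q1, med, q3 = hinge_quartiles(lm)
    assert med == pytest.approx(157.8)
    assert q3 - q1 == pytest.approx(42.75)
    # odd case interpolates at h = n/4 + 1/2
    q1, med, q3 = hinge_quartiles([1, 2, 3, 4, 5])
    assert (q1, med, q3) == (1.75, 3.0, 4.25)
    # oracle equivalence on random vectors against a direct sort-based rule
    rng = np.random.default_rng(5)
    for _ in range(200):
        x = np.sort(rng.standard_normal(rng.integers(1, 40)))
        n = x.size
        for p, got in zip((0.25, 0.5, 0.75), hinge_quartiles(x)):
            h = np.clip(n * p + 0.5, 1, n)
            lo = int(np.floor(h)) - 1
            want = x[lo] + (h - np.floor(h)) * (x[min(lo + 1, n - 1)] - x[lo])
            assert got == pytest.approx(want)


def test_firing_rates_windowed():
    # 50 uniformly spaced spikes per second for 10 s
    t = np.arange(0, 10, 0.02)
    ep = EpochSet([(0.0, 10.0, "LM")])
    rates = firing_rates(SpikeTrain(t), ep)
    assert rates["LM"][0] == pytest.approx(50.0)
    assert rates["LM"][1] == pytest.approx(0.0)
    assert math.isnan(rates["IM"][0])


def test_empty_train_rate_zero():
    ep = EpochSet([(0.0, 5.0, "IM")])
    rates = firing_rates(SpikeTrain(np.array([])), ep)
    assert rates["IM"][0] == 0.0


def test_poisson_rate_recovery():
    rng = np.random.default_rng(2)
    t = np.cumsum(rng.exponential(1 / 40.0, 40 * 400))
    t = t[t < 300.0]
    ep = EpochSet([(0.0, 300.0, "IM")])
    mean, sd = firing_rates(SpikeTrain(t), ep)["IM"]
    assert mean == pytest.approx(40.0, rel=0.02)
    assert sd == pytest.approx(math.sqrt(40.0), rel=0.15)


def test_partial_windows_dropped():
    ep = EpochSet([(0.0, 2.5, "WS")])
    t = np.arange(0, 2.5, 0.1)
    mean, _ = firing_rates(SpikeTrain(t), ep)["WS"]
    assert mean == pytest.approx(10.0)       # 2 whole windows only


def test_interburst_intervals_within_epoch():
    bursts = detect_bursts(SpikeTrain(np.concatenate([
        0.0 + np.arange(4) * 0.01,
        0.2 + np.arange(4) * 0.01,
        0.4 + np.arange(4) * 0.01])))
    ep = EpochSet([(0.0, 1.0, "LM")])
    stats = burst_statistics(bursts, ep)
    assert stats["LM"]["interburst_median"] == pytest.approx(200.0)
    assert stats["LM"]["interburst_iqr"] == pytest.approx(0.0)


def test_single_burst_has_duration_but_no_interval():
    bursts = detect_bursts(SpikeTrain(np.arange(4) * 0.01))
    ep = EpochSet([(0.0, 1.0, "IM")])
    stats = burst_statistics(bursts, ep)
    assert stats["IM"]["burst_duration_median"] == pytest.approx(30.0)
    assert math.isnan(stats["IM"]["interburst_median"])


def test_interburst_does_not_cross_epochs():
    bursts = detect_bursts(SpikeTrain(np.concatenate([
        0.0 + np.arange(4) * 0.01,
        2.0 + np.arange(4) * 0.01])))
    ep = EpochSet([(0.0, 1.0, "LM"), (1.9, 3.0, "LM")])
    stats = burst_statistics(bursts, ep)
    assert math.isnan(stats["LM"]["interburst_median"])


def test_lm_im_index():
    assert lm_im_index(50.0, 50.0) == 0.0
    assert lm_im_index(55.2, 39.8) == pytest.approx(0.162, abs=5e-4)
    assert lm_im_index(10.0, 0.0) == 1.0
    assert math.isnan(lm_im_index(0.0, 0.0))


def test_autocorrelogram_regular_train():
    t = np.arange(0, 10, 0.1)
    lags, counts, peak = autocorrelogram(SpikeTrain(t), binwidth=0.005, max_lag=0.35)
    for k in (1, 2, 3):
        i = np.argmin(np.abs(lags - 0.1 * k))
        assert counts[i] > 0
    assert counts[np.argmin(np.abs(lags))] == 0       # zero-lag excluded
    assert peak == pytest.approx(0.1, abs=0.0075)


def test_autocorrelogram_poisson_is_flat():
    rng = np.random.default_rng(8)
    t = np.cumsum(rng.exponential(1 / 30.0, 9000))
    lags, counts, _ = autocorrelogram(SpikeTrain(t), binwidth=0.01, max_lag=0.3)
    nz = counts[np.abs(lags) > 0.01]
    assert nz.std() / nz.mean() < 0.1


def test_burst_rhythm_peak_matches_generator_period(default_session):
    # immobility theta runs at 5.5 Hz -> burst period ~182 ms
    train = default_session["train"]
    sched = default_session["schedule"]
    _, _, peak = autocorrelogram(train, binwidth=0.005, max_lag=0.3,
                                 epochs=sched, label="IM")
    assert peak == pytest.approx(1 / 5.5, abs=0.02)


def test_spikes_per_cycle():
    troughs = np.arange(0.0, 2.01, 0.125)
    spikes = troughs[:-1] + 0.06
    mean, sd = spikes_per_cycle(SpikeTrain(spikes), troughs)
    assert mean == pytest.approx(1.0)
    assert sd == pytest.approx(0.0)
    mean, sd = spikes_per_cycle(SpikeTrain(np.array([])), troughs)
    assert (mean, sd) == (0.0, 0.0)


def test_incidence_times_spikes_bounded_by_rate(default_session):
    # burst incidence x median spikes-per-burst cannot exceed the mean rate
    train, sched = default_session["train"], default_session["schedule"]
    bursts = detect_bursts(train)
    inc = burst_incidence(bursts, sched)
    rates = firing_rates(train, sched)
    for st in ("LM", "IM"):
        med_spikes = np.median([b.n_spikes for b in bursts
                                if sched.contains(np.array([b.start]), st)[0]])
        assert inc[st][0] * med_spikes <= rates[st][0] * 1.05
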