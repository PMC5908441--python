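"""Orchid classification, group statistics and stereology."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from septorhythm import (AnalysisConfig, CellMetrics, PhaseStats,
                         circular_group_compare, classify_orchid, gundersen_ce,
                         group_aggregate, ks_two_sample, load_reference_tables,
                         optical_fractionator, paired_t, sign_test)
from septorhythm.data_model import STATE_METRICS


def make_metrics(bi_lm=5.0, bi_im=4.2, bd_lm=87.0, bd_im=94.6,
                 rate_lm=48.4, rate_im=44.2, phase=159.0, r=0.37, p=1e-5,
                 cell="toy"):
    per_state = {st: {m: math.nan for m in STATE_METRICS}
                 for st in ("LM", "SM", "WS", "IM")}
    per_state["LM"].update(rate_mean=rate_lm, burst_incidence_mean=bi_lm,
                           burst_duration_median=bd_lm)
    per_state["IM"].update(rate_mean=rate_im, burst_incidence_mean=bi_im,
                           burst_duration_median=bd_im)
    return CellMetrics(cell=cell, per_state=per_state,
                       theta=PhaseStats(phase, r, p, 1000))


class TestClassification:
    def test_table_like_row_is_orchid(self):
        v = classify_orchid(make_metrics())
        assert v.verdict is True
        assert all(v.criteria.values())

    def test_low_burst_incidence_fails_first_criterion(self):
        v = classify_orchid(make_metrics(bi_im=1.5))
        assert v.verdict is False
        assert v.criteria["high_burst_incidence"] is False

    def test_trough_firing_short_burst_cell_fails_fourth_criterion(self):
        # theta-trough preferring cell with short locomotion bursts
        v = classify_orchid(make_metrics(phase=37.5, bd_lm=30.0))
        assert v.verdict is False
        assert v.criteria["theta_peak_coupling"] is False
        assert v.criteria["long_bursts"] is False

    def test_missing_fields_give_unavailable_not_false(self):
        m = make_metrics()
        m.per_state["IM"]["burst_incidence_mean"] = math.nan
        v = classify_orchid(m)
        assert v.verdict is None
        assert "high_burst_incidence" in v.missing

    def test_all_identified_fixture_cells_are_orchid(self):
        rows = load_reference_tables()
        for cm in rows:
            if cm.group == "identified":
                assert classify_orchid(cm).verdict is True, cm.cell

    def test_septo_hippocampal_fixture_cells_are_not_orchid(self):
        by = {cm.cell: cm for cm in load_reference_tables()}
        assert classify_orchid(by["TV77q"]).verdict is False
        assert classify_orchid(by["TV78l"]).verdict is False


class TestGroupAggregate:
    def test_printed_group_interburst_median(self):
        rows = [cm for cm in load_reference_tables()
                if cm.group in ("identified", "putative")]
        agg = group_aggregate(rows, "interburst_median", "LM")
        assert agg["n"] == 16
        assert agg["median"] == pytest.approx(157.8)
        assert agg["iqr"] == pytest.approx(42.7, abs=0.051)

    def test_single_row(self):
        rows = [cm for cm in load_reference_tables() if cm.cell == "TV58g"]
        agg = group_aggregate(rows, "rate_mean", "LM")
        assert agg == {"median": 48.4, "iqr": 0.0, "n": 1}

    def test_mean_aggregate_uses_sample_sd(self):
        rows = [cm for cm in load_reference_tables() if cm.group == "identified"]
        agg = group_aggregate(rows, "rate_mean", "LM", how="mean")
        assert agg["mean"] == pytest.approx(55.2)
        assert agg["sd"] == pytest.approx(14.1, abs=0.05)


class TestSignTest:
    def test_all_positive(self):
        p, kp, kn = sign_test(np.arange(16) + 1.0, np.zeros(16))
        assert (kp, kn) == (16, 0)
        assert p == pytest.approx(2 * 0.5 ** 16)

    def test_printed_examples(self):
        # 12 of 15 one-signed differences
        a = np.concatenate([np.ones(12), -np.ones(3)])
        p, _, _ = sign_test(a, np.zeros(15))
        assert p == pytest.approx(0.0352, abs=5e-5)
        a = np.concatenate([np.ones(5), -np.ones(8)])
        p, _, _ = sign_test(a, np.zeros(13))
        assert p == pytest.approx(0.5811, abs=5e-5)

    def test_exhaustive_agreement_with_binomial(self):
        for n in range(1, 31):
            for k in range(n + 1):
                a = np.concatenate([np.ones(k), -np.ones(n - k)])
                p, _, _ = sign_test(a, np.zeros(n))
                want = min(1.0, 2 * sps.binom.cdf(min(k, n - k), n, 0.5))
                assert p == pytest.approx(want, rel=1e-12)

    def test_ties_dropped(self):
        p, kp, kn = sign_test([1.0, 2.0, 3.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert kp + kn == 3
        with pytest.raises(ValueError):
            sign_test([1.0, 2.0], [1.0, 2.0])


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_printed_intraburst_t(self):
        rows = [cm for cm in load_reference_tables()
                if cm.group in ("identified", "putative")]
        a = [cm.get("LM", "intraburst_mean") for cm in rows]
        b = [cm.get("IM", "intraburst_mean") for cm in rows]
        t, df, p = paired_t(a, b)
        assert df == 15
        assert t == pytest.approx(3.14, abs=0.005)
        assert p == pytest.approx(0.0067, abs=2e-4)

    def test_closed_form_on_constructed_pairs(self):
        d = np.array([1.0, 2.0, 0.0, 3.0, -1.0, 2.0])
        a = np.arange(6, dtype=float)
        t, df, p = paired_t(a + d, a)
        want_t = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
        assert t == pytest.approx(want_t, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(want_t), 5), rel=1e-12)


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3.0], [1, 2, 3.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    def test_agrees_with_permutation_p(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.4, 1, 100)
        d, p_asym = ks_two_sample(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(2000):
            perm = rng.permutation(pooled)
            d2 = sps.ks_2samp(perm[:100], perm[100:]).statistic
            count += d2 >= d - 1e-12
        assert p_asym == pytest.approx((count + 1) / 2001, abs=0.01)


class TestCircularCompare:
    def test_identical_groups_not_significant(self):
        cfg = AnalysisConfig(n_permutations=500)
        phases = [10.0, 20.0, 350.0, 30.0, 5.0]
        _, p = circular_group_compare(phases, phases, cfg)
        assert p > 0.5

    def test_separated_von_mises_groups_detected(self):
        cfg = AnalysisConfig(n_permutations=500)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = np.degrees(rng.vonmises(np.radians(178) - np.pi, 4.0, 8)) % 360
            b = np.degrees(rng.vonmises(np.radians(38) - np.pi, 4.0, 13)) % 360
            a, b = (a + 180) % 360, (b + 180) % 360
            obs, p = circular_group_compare(a, b, cfg,
                                            rng=np.random.default_rng(seed + 100))
            hits += p < 0.05
        assert hits >= 8

    def test_statistic_is_circular_distance(self):
        obs, _ = circular_group_compare([350.0, 350.0], [10.0, 10.0],
                                        AnalysisConfig(n_permutations=10))
        assert obs == pytest.approx(20.0)


class TestStereology:
    def test_identity_fractions(self):
        assert optical_fractionator(100, 1.0, 1.0, 1.0) == 100

    def test_printed_sampling_design(self):
        est = optical_fractionator(422, 1 / 3, (120 * 80) / (240 * 160), 5 / 50)
        assert est == pytest.approx(50640.0)
        assert abs(est - 50680.0) <= 2422.0      # within one printed SEM

    def test_linearity(self):
        a = optical_fractionator(211, 1 / 3, 0.25, 0.1)
        b = optical_fractionator(422, 1 / 3, 0.25, 0.1)
        assert b == pytest.approx(2 * a)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            optical_fractionator(10, 0.0, 0.5, 0.5)

    def test_gundersen_ce_magnitude(self):
        # smooth systematic counts across ~9 sections: CE in the few-percent
        # range, as for the published per-animal errors (0.05-0.06)
        counts = [20, 35, 55, 70, 75, 68, 52, 30, 15]
        ce = gundersen_ce(counts)
        assert 0.01 < ce < 0.10
        with pytest.raises(ValueError):
            gundersen_ce([1, 2])
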