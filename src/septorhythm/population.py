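"""Orchid-cell classification, group-level statistics and stereology.

An "orchid cell" verdict requires all four signature firing features:

1. high burst incidence during both locomotion and immobility (> 3 Hz),
2. long bursts during both states (median duration > 50 ms),
3. an increase in mean firing rate from immobility to locomotion,
4. strong theta coupling around the peak (mean vector length > 0.2,
   significant Rayleigh test, mean phase inside the configured peak window).

Group statistics follow the summary-table conventions: medians with
hinge-style IQRs, means with n-1 s.d., the exact two-sided binomial sign
test, the paired t-test, the two-sample KS test, and a 10,000-permutation
test on circular group means.  The optical fractionator scales a sampled
count by the inverse section/area/thickness sampling fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig
from .data_model import CellMetrics
from .phase_coupling import circular_distance_deg, circular_mean_deg
from .spike_metrics import hinge_quartiles

__all__ = [
    "OrchidVerdict",
    "classify_orchid",
    "group_aggregate",
    "sign_test",
    "paired_t",
    "ks_two_sample",
    "circular_group_compare",
    "optical_fractionator",
    "gundersen_ce",
]


@dataclass
class OrchidVerdict:
    cell: str
    verdict: Optional[bool]            # None = unavailable, never False-by-default
    criteria: Dict[str, Optional[bool]]
    missing: List[str]

    def __bool__(self) -> bool:
        return bool(self.verdict)


def _phase_in_window(phase: float, window: Tuple[float, float]) -> bool:
    lo, hi = window[0] % 360.0, window[1] % 360.0
    phase = phase % 360.0
    if lo <= hi:
        return lo <= phase <= hi
    return phase >= lo or phase <= hi


def classify_orchid(metrics: CellMetrics,
                    config: Optional[AnalysisConfig] = None) -> OrchidVerdict:
    """Apply the 4-criterion orchid-cell test to one summary row.

    Required fields (LM/IM burst incidence and duration, LM/IM rates, theta
    phase statistics) that are unavailable yield an *unavailable* verdict
    (None), never a spurious False.
    """
    config = config or AnalysisConfig()
    crit: Dict[str, Optional[bool]] = {}
    missing: List[str] = []

    def check(name: str, values: List[float], ok: bool) -> None:
        if any(math.isnan(v) for v in values):
            crit[name] = None
            missing.append(name)
        else:
            crit[name] = ok

    bi_lm = metrics.get("LM", "burst_incidence_mean")
    bi_im = metrics.get("IM", "burst_incidence_mean")
    check("high_burst_incidence", [bi_lm, bi_im],
          bi_lm > config.orchid_burst_incidence_min
          and bi_im > config.orchid_burst_incidence_min)

    bd_lm = metrics.get("LM", "burst_duration_median")
    bd_im = metrics.get("IM", "burst_duration_median")
    check("long_bursts", [bd_lm, bd_im],
          bd_lm > config.orchid_burst_duration_min
          and bd_im > config.orchid_burst_duration_min)

    r_lm = metrics.get("LM", "rate_mean")
    r_im = metrics.get("IM", "rate_mean")
    check("rate_increase_lm", [r_lm, r_im], r_lm > r_im)

    if metrics.theta is None:
        crit["theta_peak_coupling"] = None
        missing.append("theta_peak_coupling")
    else:
        th = metrics.theta
        crit["theta_peak_coupling"] = (
            th.r > config.orchid_r_min
            and th.p < config.orchid_rayleigh_alpha
            and _phase_in_window(th.mean_phase, config.orchid_phase_window))

    if any(v is None for v in crit.values()):
        verdict: Optional[bool] = None if not any(v is False for v in crit.values()) else False
    else:
        verdict = all(crit.values())
    return OrchidVerdict(metrics.cell, verdict, crit, missing)


def group_aggregate(rows: Sequence[CellMetrics], metric: str, state: str,
                    how: str = "median") -> Dict[str, float]:
    """Aggregate one per-cell metric over a group of cells.

    ``how='median'`` returns ``{'median', 'iqr', 'n'}`` (hinge quartiles);
    ``how='mean'`` returns ``{'mean', 'sd', 'n'}`` (n-1 denominator).
    Unavailable entries are excluded and reflected in ``n``.
    """
    values = np.array([cm.get(state, metric) for cm in rows], dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"no available values for {metric}/{state}")
    if how == "median":
        q1, med, q3 = hinge_quartiles(values)
        return {"median": med, "iqr": q3 - q1, "n": int(values.size)}
    if how == "mean":
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return {"mean": float(values.mean()), "sd": sd, "n": int(values.size)}
    raise ValueError("how must be 'median' or 'mean'")


def sign_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, int, int]:
    """Exact two-sided sign test on paired values.

    Ties and pairs with unavailable entries are dropped.  Returns
    ``(p, n_positive, n_negative)`` with
    ``p = min(1, 2 * P(X <= min(k+, k-)))`` under Binomial(n, 1/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("sign test undefined: all pairs tied or unavailable")
    k_pos = int((d > 0).sum())
    k_neg = n - k_pos
    p = min(1.0, 2.0 * float(sps.binom.cdf(min(k_pos, k_neg), n, 0.5)))
    return p, k_pos, k_neg


def paired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, int, float]:
    """Paired t-test; returns (t, df, p).  Complete pairs only."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    if np.allclose(a - b, (a - b)[0]) and np.std(a - b) == 0 and (a - b)[0] != 0:
        raise ValueError("zero variance of differences")
    res = sps.ttest_rel(a, b)
    if math.isnan(res.statistic):
        raise ValueError("zero variance of differences")
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p); returns (D, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def circular_group_compare(phases_a: Sequence[float], phases_b: Sequence[float],
                           config: Optional[AnalysisConfig] = None,
                           rng: Optional[np.random.Generator] = None
                           ) -> Tuple[float, float]:
    """Permutation test on the difference of two circular group means.

    The statistic is the absolute circular distance (degrees, <= 180)
    between the unweighted circular means of the two groups; labels are
    permuted ``n_permutations`` times and the p-value uses the add-one
    correction (b+1)/(m+1).
    """
    config = config or AnalysisConfig()
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 phases")
    observed = circular_distance_deg(circular_mean_deg(a), circular_mean_deg(b))
    pooled = np.concatenate([a, b])
    rng = rng or np.random.default_rng(config.rng_seed)
    m = config.n_permutations
    count = 0
    for _ in range(m):
        perm = rng.permutation(pooled)
        stat = circular_distance_deg(circular_mean_deg(perm[:a.size]),
                                     circular_mean_deg(perm[a.size:]))
        if stat >= observed - 1e-12:
            count += 1
    return observed, (count + 1) / (m + 1)


def optical_fractionator(counted: float, section_fraction: float,
                         area_fraction: float, thickness_fraction: float) -> float:
    """Optical-fractionator total: counted / (ssf * asf * tsf).

    The sampling fractions are the section sampling fraction (e.g. 1/3 for
    every third section), the area fraction (counting frame area / grid
    area) and the thickness fraction (probe depth / section thickness).
    """
    for name, f in (("section_fraction", section_fraction),
                    ("area_fraction", area_fraction),
                    ("thickness_fraction", thickness_fraction)):
        if not 0 < f <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    if counted < 0:
        raise ValueError("counted must be >= 0")
    return counted / (section_fraction * area_fraction * thickness_fraction)


def gundersen_ce(section_counts: Sequence[float]) -> float:
    """Gundersen-Jensen coefficient of error (smoothness class m = 1).

    For per-section counts Q_i the systematic-sampling variance term is
    ``(3(A - n) - 4B + C) / 240`` with ``A = sum Q_i^2``,
    ``B = sum Q_i Q_{i+1}``, ``C = sum Q_i Q_{i+2}`` and Poisson noise
    ``n = sum Q_i``; CE = sqrt(noise + var) / n.
    """
    q = np.asarray(section_counts, dtype=float)
    if q.size < 3:
        raise ValueError("need at least 3 sections")
    n = q.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    A = float(np.sum(q * q))
    B = float(np.sum(q[:-1] * q[1:]))
    C = float(np.sum(q[:-2] * q[2:]))
    var_srs = (3.0 * (A - n) - 4.0 * B + C) / 240.0
    return math.sqrt(max(n + var_srs, 0.0)) / n
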