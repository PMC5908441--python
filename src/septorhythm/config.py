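"""Analysis configuration.

Every numeric constant of the analysis lives here with its unit, so a whole
run is reproducible from one flat mapping (YAML-friendly).  Defaults are the
values used throughout the study this package re-implements: oscillation
bands in Hz, the burst ISI criterion in seconds, detection thresholds in
standard deviations, and the treadmill encoder geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Tuple

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # oscillation bands (Hz)
    theta_band: Tuple[float, float] = (5.0, 12.0)
    delta_band: Tuple[float, float] = (2.0, 4.0)
    mid_gamma_band: Tuple[float, float] = (55.0, 80.0)
    ripple_band: Tuple[float, float] = (130.0, 230.0)
    lia_max_freq: float = 5.0

    # burst criterion: runs of >3 spikes (i.e. >= 4) with ISIs < 40 ms
    isi_max: float = 0.040          # s
    min_burst_spikes: int = 4

    # detector thresholds
    theta_delta_ratio_threshold: float = 2.0
    theta_ratio_window: float = 1.0      # s, sliding power window
    theta_merge_gap: float = 0.5         # s, morphological closing of epochs
    gamma_amp_sd_threshold: float = 1.0  # cycle amplitude > mean + 1 s.d.
    ripple_power_sd_threshold: float = 4.0
    ripple_power_smooth: float = 0.010   # s, envelope-power smoothing
    lia_smooth_window: float = 0.08      # s
    lia_dc_window: float = 0.2           # s
    lia_min_interval: float = 0.2        # s between falling zero-crossings

    # rate / burst statistics
    rate_window: float = 1.0             # s bins for rates and burst incidence

    # SWR firing-modulation test
    min_swr_count: int = 20
    n_shuffles: int = 1000

    # group statistics
    n_permutations: int = 10000

    # rotary encoder / speed
    speed_calibration: float = 0.6912    # m/s represented by 1 V
    encoder_edges_per_rev: int = 2000
    wheel_diameter: float = 0.146        # m
    speed_interval: float = 0.010        # s

    # behavioral segmentation (numeric rule; see docs/methods.md)
    lm_speed_threshold: float = 0.01     # m/s
    lm_min_duration: float = 1.0         # s

    # orchid classification
    orchid_burst_incidence_min: float = 3.0   # Hz, LM and IM
    orchid_burst_duration_min: float = 50.0   # ms, median, LM and IM
    orchid_r_min: float = 0.2
    orchid_phase_window: Tuple[float, float] = (90.0, 270.0)  # deg, "around the peak"
    orchid_rayleigh_alpha: float = 0.05

    # filter orders (forward-backward Butterworth)
    theta_filter_order: int = 4
    gamma_filter_order: int = 4
    ripple_filter_order: int = 6

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_band", "delta_band", "mid_gamma_band", "ripple_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < low < high, got ({lo}, {hi})")
        positive = (
            "isi_max", "theta_ratio_window", "theta_merge_gap", "ripple_power_smooth",
            "lia_smooth_window", "lia_dc_window", "lia_min_interval", "rate_window",
            "speed_calibration", "wheel_diameter", "speed_interval", "lm_min_duration",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_burst_spikes < 2:
            raise ValueError("min_burst_spikes must be >= 2")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
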