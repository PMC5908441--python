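"""Shared domain types and session / fixture I/O.

The in-memory containers are small frozen-ish dataclasses around numpy
arrays: an :class:`Lfp` trace, a :class:`SpikeTrain`, labeled time intervals
(:class:`EpochSet`), point events (:class:`EventSet`), detected
:class:`Burst` objects, circular-statistics results (:class:`PhaseStats`)
and a per-cell summary row (:class:`CellMetrics`).

Sessions are stored as a directory of tab-separated files:

``lfp.tsv``
    header lines ``# rate <Hz>`` and ``# t0 <s>`` followed by one column of
    samples (one channel per file; extra channels as ``lfp_<name>.tsv``).
``spikes.tsv``
    two columns ``unit`` and ``time`` (seconds, sorted within unit).
``epochs.tsv``
    three columns ``label``, ``start``, ``end`` (seconds).

Times are seconds as 64-bit floats everywhere in memory; milliseconds only
appear in reported metrics, matching the summary-table conventions.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "BEHAVIOR_STATES",
    "Lfp",
    "SpikeTrain",
    "EpochSet",
    "EventSet",
    "Burst",
    "PhaseStats",
    "CellMetrics",
    "read_session",
    "write_session",
    "load_reference_tables",
]

#: behavioral state vocabulary: locomotion, small movements, whisking/sniffing,
#: immobility
BEHAVIOR_STATES = ("LM", "SM", "WS", "IM")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Lfp:
    """Uniformly sampled continuous voltage trace.

    Sample ``i`` occurs at time ``t0 + i / rate``.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    channel: str = "lfp"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("Lfp needs a 1-D trace with at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def time_to_index(self, t: np.ndarray | float) -> np.ndarray:
        return np.clip(np.round((np.asarray(t) - self.t0) * self.rate).astype(int),
                       0, self.samples.size - 1)


@dataclass
class SpikeTrain:
    """Sorted spike time stamps (s) of one unit."""

    times: np.ndarray
    unit_id: str = "unit"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"non-monotonic spike times for unit {self.unit_id!r}")

    def __len__(self) -> int:
        return self.times.size

    def clip(self, start: float, end: float) -> Tuple["SpikeTrain", int]:
        """Restrict to [start, end]; returns (train, n_dropped)."""
        keep = (self.times >= start) & (self.times <= end)
        return SpikeTrain(self.times[keep], self.unit_id), int((~keep).sum())


@dataclass
class EpochSet:
    """Labeled, non-overlapping time intervals.

    ``intervals`` is a list of ``(start, end, label)`` with start < end.
    Intervals sharing a label must not overlap; behavioral labels
    (LM/SM/WS/IM) are mutually exclusive in time.
    """

    intervals: List[Tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), str(l)) for s, e, l in self.intervals]
        ivs.sort(key=lambda iv: (iv[0], iv[1]))
        for s, e, l in ivs:
            if not s < e:
                raise ValueError(f"epoch ({s}, {e}, {l!r}) has start >= end")
        by_label: Dict[str, float] = {}
        for s, e, l in ivs:
            if l in by_label and s < by_label[l]:
                raise ValueError(f"overlapping epochs with label {l!r}")
            by_label[l] = max(by_label.get(l, -math.inf), e)
        behav = [(s, e) for s, e, l in ivs if l in BEHAVIOR_STATES]
        for (s1, e1), (s2, e2) in zip(behav, behav[1:]):
            if s2 < e1 - 1e-9:
                raise ValueError("behavioral state epochs overlap in time")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def labels(self) -> List[str]:
        return sorted({l for _, _, l in self.intervals})

    def select(self, label: str) -> List[Tuple[float, float]]:
        return [(s, e) for s, e, l in self.intervals if l == label]

    def duration(self, label: Optional[str] = None) -> float:
        return sum(e - s for s, e, l in self.intervals
                   if label is None or l == label)

    def label_at(self, t: np.ndarray) -> np.ndarray:
        """State label for each time (object array, '' outside any epoch)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        for s, e, l in self.intervals:
            out[(t >= s) & (t < e)] = l
        return out

    def contains(self, t: np.ndarray, label: str) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for s, e in self.select(label):
            mask |= (t >= s) & (t < e)
        return mask

    def complement(self, start: float, end: float,
                   labels: Optional[Sequence[str]] = None) -> List[Tuple[float, float]]:
        """Intervals of [start, end] not covered by (selected) epochs."""
        ivs = sorted((s, e) for s, e, l in self.intervals
                     if labels is None or l in labels)
        out, cursor = [], start
        for s, e in ivs:
            if s > cursor:
                out.append((cursor, min(s, end)))
            cursor = max(cursor, e)
            if cursor >= end:
                break
        if cursor < end:
            out.append((cursor, end))
        return [(s, e) for s, e in out if e - s > 1e-12]


EVENT_KINDS = ("theta_trough", "gamma_trough", "swr", "lia_falling")


@dataclass
class EventSet:
    """Point events of one kind, optionally with (start, end) windows."""

    times: np.ndarray
    kind: str
    windows: Optional[np.ndarray] = None   # shape (n, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.times.size > 1 and not np.all(np.diff(self.times) >= 0):
            raise ValueError("event times must be increasing")
        if self.kind == "swr":
            if self.windows is None:
                raise ValueError("swr events require windows")
        if self.windows is not None:
            self.windows = np.asarray(self.windows, dtype=float).reshape(-1, 2)
            if self.windows.shape[0] != self.times.size:
                raise ValueError("one window per event required")
            if self.times.size and not (
                np.all(self.windows[:, 0] <= self.times)
                and np.all(self.times <= self.windows[:, 1])
            ):
                raise ValueError("each event time must lie inside its window")

    def __len__(self) -> int:
        return self.times.size

    @property
    def durations(self) -> np.ndarray:
        if self.windows is None:
            raise ValueError("event set has no windows")
        return self.windows[:, 1] - self.windows[:, 0]


@dataclass
class Burst:
    """A detected spike burst: >= min_burst_spikes spikes, all ISIs < isi_max."""

    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size < 2:
            raise ValueError("a burst needs at least two spikes")

    @property
    def start(self) -> float:
        return float(self.spike_times[0])

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def duration_ms(self) -> float:
        return float(self.spike_times[-1] - self.spike_times[0]) * 1e3

    @property
    def intraburst_freq(self) -> float:
        """Within-burst firing rate (Hz): (n_spikes - 1) / duration."""
        dur = self.spike_times[-1] - self.spike_times[0]
        return float((self.n_spikes - 1) / dur)


@dataclass
class PhaseStats:
    """Circular summary of a phase sample (degrees, trough = 0°)."""

    mean_phase: float   # [0, 360)
    r: float            # mean vector length in [0, 1]
    p: float            # Rayleigh p
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r <= 1 + 1e-9:
            raise ValueError("mean vector length must be in [0, 1]")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        self.mean_phase = float(self.mean_phase) % 360.0


#: per-state scalar metric names carried by CellMetrics / the fixture tables
STATE_METRICS = (
    "rate_mean", "rate_sd",
    "burst_incidence_mean", "burst_incidence_sd",
    "burst_duration_median", "burst_duration_iqr",
    "interburst_median", "interburst_iqr",
    "intraburst_mean", "intraburst_sd",
)


@dataclass
class CellMetrics:
    """One summary row per cell, mirroring the published table layout.

    ``per_state[state][metric]`` holds the per-behavioral-state numbers
    (NaN = unavailable, the tables' "u").  Rates and burst incidence are in
    Hz, burst duration and interburst interval in ms.
    """

    cell: str
    group: str = "unknown"   # identified | putative | septo_hippocampal
    per_state: Dict[str, Dict[str, float]] = field(default_factory=dict)
    theta: Optional[PhaseStats] = None
    gamma: Optional[PhaseStats] = None
    spikes_per_cycle_mean: float = math.nan
    spikes_per_cycle_sd: float = math.nan
    n_swr: int = 0
    swr_rate_inside: float = math.nan
    swr_lambda_outside: float = math.nan
    swr_p: float = math.nan

    def state(self, state: str) -> Dict[str, float]:
        return self.per_state.get(state, {m: math.nan for m in STATE_METRICS})

    def get(self, state: str, metric: str) -> float:
        return self.state(state).get(metric, math.nan)

    def to_row(self) -> Dict[str, float]:
        """Flatten to a dict of scalar columns (``<metric>_<state_lower>``)."""
        row: Dict[str, float] = {"cell": self.cell, "group": self.group}
        for st in BEHAVIOR_STATES:
            for m in STATE_METRICS:
                row[f"{m}_{st.lower()}"] = self.get(st, m)
        if self.theta is not None:
            row.update(theta_phase_deg=self.theta.mean_phase, theta_r=self.theta.r,
                       theta_p=self.theta.p, theta_n_spikes=self.theta.n)
        else:
            row.update(theta_phase_deg=math.nan, theta_r=math.nan,
                       theta_p=math.nan, theta_n_spikes=math.nan)
        if self.gamma is not None:
            row.update(gamma_phase_deg=self.gamma.mean_phase, gamma_r=self.gamma.r,
                       gamma_p=self.gamma.p, gamma_n_spikes=self.gamma.n)
        else:
            row.update(gamma_phase_deg=math.nan, gamma_r=math.nan,
                       gamma_p=math.nan, gamma_n_spikes=math.nan)
        row.update(spikes_per_cycle_mean=self.spikes_per_cycle_mean,
                   spikes_per_cycle_sd=self.spikes_per_cycle_sd,
                   n_swr=self.n_swr, swr_rate_inside=self.swr_rate_inside,
                   swr_lambda_outside=self.swr_lambda_outside, swr_p=self.swr_p)
        return row


# ---------------------------------------------------------------------------
# session directory I/O
# ---------------------------------------------------------------------------

_TIME_FMT = "%.6f"   # microsecond precision in TSV files


def write_session(path, lfps: Sequence[Lfp], trains: Sequence[SpikeTrain],
                  epochs: Optional[EpochSet] = None,
                  channels: Optional[Dict[str, np.ndarray]] = None) -> Path:
    """Write a session directory (see module docstring for the layout)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for lfp in lfps:
        name = "lfp.tsv" if lfp.channel == "lfp" else f"lfp_{lfp.channel}.tsv"
        with open(path / name, "w") as fh:
            fh.write(f"# rate {lfp.rate!r}\n# t0 {lfp.t0!r}\n")
            np.savetxt(fh, lfp.samples, fmt="%.9g")
    with open(path / "spikes.tsv", "w") as fh:
        fh.write("unit\ttime\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.unit_id}\t{_TIME_FMT % t}\n")
    if epochs is not None:
        with open(path / "epochs.tsv", "w") as fh:
            fh.write("label\tstart\tend\n")
            for s, e, l in epochs.intervals:
                fh.write(f"{l}\t{_TIME_FMT % s}\t{_TIME_FMT % e}\n")
    if channels:
        for name, arr in channels.items():
            np.savetxt(path / f"channel_{name}.tsv", np.asarray(arr), fmt="%.9g")
    return path


def _read_lfp_file(fpath: Path, channel: str) -> Lfp:
    rate = t0 = None
    with open(fpath) as fh:
        pos_lines = []
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(rate|t0)\s+(\S+)", line)
                if not m:
                    raise ValueError(f"{fpath}:{i}: malformed header line {line!r}")
                if m.group(1) == "rate":
                    rate = float(m.group(2))
                else:
                    t0 = float(m.group(2))
            else:
                try:
                    pos_lines.append(float(line))
                except ValueError:
                    raise ValueError(f"{fpath}:{i}: malformed sample {line!r}") from None
    if rate is None:
        raise ValueError(f"{fpath}: missing '# rate' header")
    return Lfp(np.array(pos_lines), rate=rate, t0=t0 or 0.0, channel=channel)


def read_session(path, config: Optional[AnalysisConfig] = None):
    """Read a session directory.

    Returns ``(lfps, trains, epochs, channels, report)`` where *report* is a
    dict with e.g. the number of spikes clipped to the session span (clipped
    spikes are reported, never silently dropped).
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"session directory {path} does not exist")
    lfps: List[Lfp] = []
    for fpath in sorted(path.glob("lfp*.tsv")):
        channel = "lfp" if fpath.name == "lfp.tsv" else fpath.stem[len("lfp_"):]
        lfps.append(_read_lfp_file(fpath, channel))
    if not lfps:
        raise FileNotFoundError(f"{path}: no lfp*.tsv found")
    span = (min(l.t0 for l in lfps), max(l.t_end for l in lfps))

    trains: List[SpikeTrain] = []
    report = {"clipped_spikes": 0}
    spath = path / "spikes.tsv"
    if spath.exists():
        per_unit: Dict[str, List[float]] = {}
        with open(spath) as fh:
            header = fh.readline()
            if header.strip() != "unit\ttime":
                raise ValueError(f"{spath}:1: expected header 'unit\\ttime'")
            for i, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{spath}:{i}: malformed row {line!r}")
                try:
                    per_unit.setdefault(parts[0], []).append(float(parts[1]))
                except ValueError:
                    raise ValueError(f"{spath}:{i}: malformed time {parts[1]!r}") from None
        for unit, times in per_unit.items():
            tr = SpikeTrain(np.array(times), unit)      # raises on non-monotonic
            tr, dropped = tr.clip(*span)
            report["clipped_spikes"] += dropped
            trains.append(tr)

    epochs = None
    epath = path / "epochs.tsv"
    if epath.exists():
        rows = []
        with open(epath) as fh:
            header = fh.readline()
            if header.strip() != "label\tstart\tend":
                raise ValueError(f"{epath}:1: expected header 'label\\tstart\\tend'")
            for i, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{epath}:{i}: malformed row {line!r}")
                try:
                    rows.append((float(parts[1]), float(parts[2]), parts[0]))
                except ValueError:
                    raise ValueError(f"{epath}:{i}: malformed interval") from None
        epochs = EpochSet(rows)

    channels = {f.stem[len("channel_"):]: np.loadtxt(f)
                for f in sorted(path.glob("channel_*.tsv"))}
    return lfps, trains, epochs, channels, report


# ---------------------------------------------------------------------------
# packaged summary-table fixtures
# ---------------------------------------------------------------------------

# sha256 of the packaged TSV transcriptions; guards against silent edits
_FIXTURE_CHECKSUMS = {
    "table1.tsv": "15b7636e7dc209d84203555170fe096eea2f0e9b6fac2a5831533ffd31f6de56",
    "table3.tsv": "8f46ff8e64a6c87b4a921ce03242fe9d1bab09d6c5fce3e9414120b1107f2d07",
    "table8.tsv": "b8a6b0373f286721e3531f22e7d81773ac6b30ce962118697f4329263fa1347f",
    "table9.tsv": "818d0f7f396400b37a646d58f88d11c7f50d4f41b6278235c01a009b8f7dc411",
    "table10.tsv": "b2091425b6d9702de03f0d6305ec6801ad084464f64c25f97de2fbcc5b91c008",
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("septorhythm.tables") / name
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _FIXTURE_CHECKSUMS[name]
    if digest != expected:
        raise RuntimeError(
            f"fixture {name} checksum mismatch: {digest} != {expected}")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw), sep="\t", index_col="field", dtype=str)


_PM_RE = re.compile(r"^\s*([<]?)\s*([0-9.]+)\s*(?:[±,]\s*([0-9.]+))?\s*$")


def _parse_cell(value: str) -> Tuple[float, float]:
    """Parse a table cell: 'm ± s', 'm, s', 'm', '<p' or 'u'.

    Returns (first, second); second is NaN for single values.  Censored
    values ('<p') are returned as their printed upper bound.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan, math.nan
    value = str(value).strip()
    if value in ("u", ""):
        return math.nan, math.nan
    m = _PM_RE.match(value)
    if not m:
        raise ValueError(f"unparseable table cell {value!r}")
    first = float(m.group(2))
    second = float(m.group(3)) if m.group(3) else math.nan
    return first, second


_PAIR_FIELDS = {
    # fixture row -> (CellMetrics state metric base, states in row name)
    "rate": ("rate_mean", "rate_sd"),
    "burst_incidence": ("burst_incidence_mean", "burst_incidence_sd"),
    "burst_duration": ("burst_duration_median", "burst_duration_iqr"),
    "interburst": ("interburst_median", "interburst_iqr"),
    "intraburst": ("intraburst_mean", "intraburst_sd"),
}


def _rows_from_tables(frames: List[pd.DataFrame], group: str) -> List[CellMetrics]:
    merged = pd.concat(frames, axis=0)
    cells = list(frames[0].columns)
    out = []
    for cell in cells:
        col = merged[cell]
        per_state: Dict[str, Dict[str, float]] = {
            st: {m: math.nan for m in STATE_METRICS} for st in BEHAVIOR_STATES}
        for base, (k1, k2) in _PAIR_FIELDS.items():
            for st in BEHAVIOR_STATES:
                key = f"{base}_{st.lower()}"
                if key in col.index:
                    v1, v2 = _parse_cell(col[key])
                    per_state[st][k1] = v1
                    per_state[st][k2] = v2
        cm = CellMetrics(cell=cell, group=group, per_state=per_state)

        def scalar(key: str) -> float:
            return _parse_cell(col[key])[0] if key in col.index else math.nan

        phase = scalar("theta_phase_deg")
        r = scalar("theta_r")
        p = scalar("theta_rayleigh_p")
        n = scalar("theta_n_spikes")
        if not math.isnan(phase) and not math.isnan(r):
            cm.theta = PhaseStats(phase, r, p if not math.isnan(p) else 1.0,
                                  int(n) if not math.isnan(n) else 0)
        gphase = scalar("gamma_phase_deg")
        gr = scalar("gamma_r")
        gp = scalar("gamma_rayleigh_p")
        gn = scalar("gamma_n_spikes")
        if not math.isnan(gphase) and not math.isnan(gr):
            cm.gamma = PhaseStats(gphase, gr, gp if not math.isnan(gp) else 1.0,
                                  int(gn) if not math.isnan(gn) else 0)
        if "spikes_per_cycle" in col.index:
            cm.spikes_per_cycle_mean, cm.spikes_per_cycle_sd = \
                _parse_cell(col["spikes_per_cycle"])
        nswr = scalar("n_swr")
        cm.n_swr = int(nswr) if not math.isnan(nswr) else 0
        cm.swr_rate_inside = scalar("swr_rate_inside")
        cm.swr_lambda_outside = scalar("swr_lambda_outside")
        cm.swr_p = scalar("swr_poisson_p")
        out.append(cm)
    return out


def load_reference_tables() -> List[CellMetrics]:
    """Load the packaged per-cell summary fixtures.

    Returns exactly 18 rows: 8 identified orchid cells, 8 putative orchid
    cells and 2 septo-hippocampal cells.  Unavailable entries are NaN.
    """
    identified = _rows_from_tables(
        [_read_fixture("table1.tsv"), _read_fixture("table3.tsv")], "identified")
    putative = _rows_from_tables(
        [_read_fixture("table8.tsv"), _read_fixture("table9.tsv")], "putative")
    septo = _rows_from_tables([_read_fixture("table10.tsv")], "septo_hippocampal")
    rows = identified + putative + septo
    assert len(rows) == 18
    return rows


def reference_tables_frame() -> pd.DataFrame:
    """The fixture rows flattened to one DataFrame (one row per cell)."""
    return pd.DataFrame([cm.to_row() for cm in load_reference_tables()]).set_index("cell")
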