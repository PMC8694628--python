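"""Recording/annotation data model and readers/writers.

The on-disk CSV dialect mirrors the device app's real-time export: one file
per BLE characteristic group — ``ecg_acc.csv`` (ECG plus 3-axis
acceleration, which share a characteristic so their time alignment is
exact) and ``ppg.csv`` (red and infrared photoplethysmogram).  Each file is
UTF-8, comma-separated, with a ``# rates:`` comment carrying the per-channel
sample rates followed by a ``time_s,<channel>,...`` header; channels with
different rates share a file by leaving slower channels' cells empty off
their sample grid.

EDF (the sleep-lab interchange format) export/import is provided by a
minimal 16-bit EDF codec.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("scoper")

__all__ = [
    "Channel",
    "Recording",
    "AnnotationTrack",
    "RunConfig",
    "load_recording",
    "write_recording",
    "read_edf",
    "write_annotations",
    "load_annotations",
]

#: canonical firmware sample rates (Hz)
CANONICAL_RATES = {
    "ecg": 128.0,
    "acc_x": 500.0,
    "acc_y": 500.0,
    "acc_z": 500.0,
    "ppg_red": 50.0,
    "ppg_ir": 50.0,
}

CHANNEL_UNITS = {
    "ecg": "mV",
    "acc_x": "g",
    "acc_y": "g",
    "acc_z": "g",
    "ppg_red": "adu",
    "ppg_ir": "adu",
}

_FILE_GROUPS = {
    "ecg_acc.csv": ["ecg", "acc_x", "acc_y", "acc_z"],
    "ppg.csv": ["ppg_red", "ppg_ir"],
}

_CSV_DECIMALS = 6


@dataclass
class Channel:
    samples: np.ndarray
    rate: float
    units: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("channel rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class Recording:
    """Synchronized multichannel recording; all channels share one time axis
    measured in seconds from `start_time`."""

    channels: dict[str, Channel]
    start_time: str = "1970-01-01T00:00:00Z"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording needs at least one channel")

    @property
    def duration(self) -> float:
        return max(ch.duration for ch in self.channels.values())

    def __getitem__(self, key: str) -> Channel:
        return self.channels[key]

    def __contains__(self, key: str) -> bool:
        return key in self.channels


@dataclass
class AnnotationTrack:
    """Ground-truth / scored labels: 30-s stage epochs and event intervals."""

    stages: list[tuple[float, str]] = field(default_factory=list)
    events: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for onset, offset, _ in self.events:
            if offset <= onset:
                raise ValueError("event offset must exceed onset")
        if any(
            self.events[i + 1][0] < self.events[i][0] for i in range(len(self.events) - 1)
        ):
            raise ValueError("events must be ordered by onset")

    def stage_at(self, t: float, epoch_len: float = 30.0) -> str | None:
        for start, label in reversed(self.stages):
            if start <= t:
                return label
        return None

    def stage_labels(self, n_epochs: int, epoch_len: float = 30.0) -> list[str]:
        return [
            self.stage_at(i * epoch_len + epoch_len / 2, epoch_len) or "wake"
            for i in range(n_epochs)
        ]


@dataclass
class RunConfig:
    """Run configuration: filter bands, epoch scheme, calibration, windows,
    classifier hyperparameters and the master seed."""

    seed: int = 0
    epoch_len: float = 30.0
    epoch_stride: float = 10.0
    bands: dict = field(
        default_factory=lambda: {
            "scg": (4.0, 24.0, 3),
            "ecg": (0.5, 50.0, 3),
            "ppg": (0.3, 7.0, 3),
            "scg_wide": (0.1, 24.0, 3),
            "resp": (0.1, 0.7, 3),
        }
    )
    spo2_calib: tuple[float, float] = (110.0, 25.0)
    spo2_delay: float = 10.0
    ao_window: tuple[float, float] = (0.02, 0.15)
    ac_window: tuple[float, float] = (0.25, 0.45)
    morse: dict = field(default_factory=lambda: {"beta": 3.0, "mu": 2.0, "gamma": 3.0})
    raster: int = 128
    cnn_blocks: int = 8
    stager_hidden: int = 120
    stager_iters: int = 500

    def validate(self, rates: dict[str, float] | None = None) -> None:
        if self.epoch_stride > self.epoch_len:
            raise ValueError("epoch stride must not exceed epoch length")
        for name, (lo, hi, order) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name}: need 0 < lo < hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["spo2_calib"] = list(self.spo2_calib)
        d["ao_window"] = list(self.ao_window)
        d["ac_window"] = list(self.ac_window)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------- CSV dialect


def _write_group_csv(path: Path, channels: dict[str, Channel]) -> None:
    names = list(channels)
    rates = {n: channels[n].rate for n in names}
    # union time axis: each channel keeps its exact sample grid; slower
    # channels leave empty cells off their grid
    ticks = {n: np.round(ch.times() * 1e6).astype(np.int64) for n, ch in channels.items()}
    union = np.unique(np.concatenate(list(ticks.values())))
    frame = {"time_s": np.array([f"{v / 1e6:.{_CSV_DECIMALS}f}" for v in union], dtype=object)}
    for n in names:
        col = np.full(union.size, "", dtype=object)
        idx = np.searchsorted(union, ticks[n])
        col[idx] = np.char.mod(f"%.{_CSV_DECIMALS}f", np.round(channels[n].samples, _CSV_DECIMALS))
        frame[n] = col
    header = "# rates: " + ",".join(f"{n}={rates[n]:g}" for n in names) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(frame).to_csv(fh, index=False)


def _read_group_csv(path: Path) -> tuple[dict[str, Channel], int]:
    first = path.open().readline()
    rates: dict[str, float] = {}
    if first.startswith("# rates:"):
        for part in first.split(":", 1)[1].strip().split(","):
            k, v = part.split("=")
            rates[k.strip()] = float(v)
        skip = 1
    else:
        skip = 0
    df = pd.read_csv(path, skiprows=skip, dtype=str, keep_default_na=False)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    dropped = 0
    channels: dict[str, Channel] = {}
    tnum = pd.to_numeric(df["time_s"], errors="coerce")
    for name in df.columns:
        if name == "time_s":
            continue
        raw = df[name]
        present = raw != ""
        vals = pd.to_numeric(raw[present], errors="coerce")
        bad = vals.isna()
        dropped += int(bad.sum())
        good = vals[~bad].to_numpy(dtype=float)
        tgood = tnum[present][~bad].to_numpy(dtype=float)
        if np.any(np.diff(tgood) <= 0):
            raise ValueError(f"{path}: timestamps not strictly increasing for {name}")
        rate = rates.get(name)
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(tgood))) if tgood.size > 1 else 1.0
        channels[name] = Channel(good, rate, CHANNEL_UNITS.get(name, ""))
    return channels, dropped


def write_recording(
    rec: Recording, path: str | Path, format: str = "csv"
) -> None:
    """Write a recording as the device CSV dialect or as EDF.

    ``csv`` writes ``ecg_acc.csv``/``ppg.csv`` (plus ``meta.json``) into the
    directory `path`; ``edf`` writes a single EDF file at `path`.
    """
    if not rec.channels:
        raise ValueError("cannot write a recording with no channels")
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for fname, members in _FILE_GROUPS.items():
            group = {n: rec.channels[n] for n in members if n in rec.channels}
            if group:
                _write_group_csv(path / fname, group)
        extra = {
            n: ch
            for n, ch in rec.channels.items()
            if not any(n in m for m in _FILE_GROUPS.values())
        }
        if extra:
            _write_group_csv(path / "other.csv", extra)
        (path / "meta.json").write_text(
            json.dumps({"start_time": rec.start_time, "meta": rec.meta}, indent=2)
        )
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_recording(
    path: str | Path,
    config: RunConfig | None = None,
    required: tuple[str, ...] = ("ecg", "acc_x", "acc_y", "acc_z"),
) -> Recording:
    """Load a device-dialect CSV directory into a Recording.

    Unparseable cells are dropped (and counted in ``meta['dropped_rows']``);
    a missing mandatory channel or an empty directory is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channels: dict[str, Channel] = {}
    dropped = 0
    csvs = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    csvs = [p for p in csvs if p.name not in ("meta.json",)]
    if not csvs:
        raise ValueError(f"{path}: no CSV files found")
    for f in csvs:
        if f.stat().st_size == 0:
            raise ValueError(f"{f}: empty file")
        chans, d = _read_group_csv(f)
        channels.update(chans)
        dropped += d
    for name in required:
        if name not in channels:
            raise ValueError(f"mandatory channel {name!r} missing from {path}")
    meta = {"dropped_rows": dropped}
    start = "1970-01-01T00:00:00Z"
    mj = path / "meta.json" if path.is_dir() else None
    if mj is not None and mj.exists():
        stored = json.loads(mj.read_text())
        meta.update(stored.get("meta", {}))
        start = stored.get("start_time", start)
    if dropped:
        log.warning("dropped %d unparseable cells while loading %s", dropped, path)
    return Recording(channels=channels, start_time=start, meta=meta)


# ------------------------------------------------------------------ EDF codec


def _edf_str(s: str, n: int) -> bytes:
    return s[:n].ljust(n).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 1-s data records, 16-bit samples, one signal per
    channel (requires integer per-second sample counts)."""
    names = list(rec.channels)
    ns = len(names)
    spr = []
    for n in names:
        r = rec.channels[n].rate
        if abs(r - round(r)) > 1e-9:
            raise ValueError("EDF export requires integer sample rates")
        spr.append(int(round(r)))
    n_records = int(np.ceil(rec.duration))
    hdr = _io.BytesIO()
    hdr.write(_edf_str("0", 8))
    hdr.write(_edf_str("X", 80))  # patient
    hdr.write(_edf_str("Startdate X", 80))  # recording
    hdr.write(_edf_str("01.01.70", 8))
    hdr.write(_edf_str("00.00.00", 8))
    hdr.write(_edf_str(str(256 * (ns + 1)), 8))
    hdr.write(_edf_str("", 44))
    hdr.write(_edf_str(str(n_records), 8))
    hdr.write(_edf_str("1", 8))  # record duration s
    hdr.write(_edf_str(str(ns), 4))
    phys_min, phys_max, scaled = [], [], []
    for n in names:
        x = rec.channels[n].samples
        lo = float(np.min(x)) if x.size else -1.0
        hi = float(np.max(x)) if x.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        pad = 0.01 * (hi - lo)
        lo, hi = lo - pad, hi + pad
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0).astype("<i2")
        scaled.append(dig)
    for n in names:
        hdr.write(_edf_str(n, 16))
    for n in names:
        hdr.write(_edf_str("", 80))  # transducer
    for n in names:
        hdr.write(_edf_str(rec.channels[n].units, 8))
    for v in phys_min:
        hdr.write(_edf_str(f"{v:.6g}"[:8], 8))
    for v in phys_max:
        hdr.write(_edf_str(f"{v:.6g}"[:8], 8))
    for _ in names:
        hdr.write(_edf_str("-32768", 8))
    for _ in names:
        hdr.write(_edf_str("32767", 8))
    for _ in names:
        hdr.write(_edf_str("", 80))  # prefiltering
    for s in spr:
        hdr.write(_edf_str(str(s), 8))
    for _ in names:
        hdr.write(_edf_str("", 32))
    body = _io.BytesIO()
    for rec_i in range(n_records):
        for ch_i, s in enumerate(spr):
            seg = scaled[ch_i][rec_i * s : (rec_i + 1) * s]
            if seg.size < s:
                seg = np.concatenate([seg, np.zeros(s - seg.size, dtype="<i2")])
            body.write(seg.tobytes())
    Path(path).write_bytes(hdr.getvalue() + body.getvalue())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file written by :func:`write_recording` (minimal codec)."""
    raw = Path(path).read_bytes()
    ns = int(raw[252:256].decode().strip())
    n_records = int(raw[236:244].decode().strip())
    rec_dur = float(raw[244:252].decode().strip())
    off = 256
    labels = [raw[off + 16 * i : off + 16 * (i + 1)].decode().strip() for i in range(ns)]
    off += 16 * ns + 80 * ns
    units = [raw[off + 8 * i : off + 8 * (i + 1)].decode().strip() for i in range(ns)]
    off += 8 * ns
    pmin = [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    off += 8 * ns
    pmax = [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    off += 8 * ns
    dmin = [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    off += 8 * ns
    dmax = [float(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    off += 8 * ns + 80 * ns
    spr = [int(raw[off + 8 * i : off + 8 * (i + 1)]) for i in range(ns)]
    off = 256 * (ns + 1)
    sigs = [np.empty(n_records * s, dtype=float) for s in spr]
    pos = off
    for r in range(n_records):
        for i, s in enumerate(spr):
            seg = np.frombuffer(raw, dtype="<i2", count=s, offset=pos)
            pos += 2 * s
            gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            sigs[i][r * s : (r + 1) * s] = (seg - dmin[i]) * gain + pmin[i]
    channels = {
        labels[i]: Channel(sigs[i], spr[i] / rec_dur, units[i]) for i in range(ns)
    }
    return Recording(channels=channels)


# -------------------------------------------------------------- annotations


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(track.stages, columns=["epoch_start_s", "stage"]).to_csv(
        path / "stages.csv", index=False
    )
    pd.DataFrame(track.events, columns=["onset_s", "offset_s", "type"]).to_csv(
        path / "events.csv", index=False
    )


def load_annotations(path: str | Path) -> AnnotationTrack:
    path = Path(path)
    stages = [
        (float(r.epoch_start_s), str(r.stage))
        for r in pd.read_csv(path / "stages.csv").itertuples()
    ]
    events = [
        (float(r.onset_s), float(r.offset_s), str(r.type))
        for r in pd.read_csv(path / "events.csv").itertuples()
    ]
    return AnnotationTrack(stages=stages, events=events)
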