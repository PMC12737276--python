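"""Shared domain types and on-disk formats.

The native container for a recording is a flat little-endian float64 sample
block (``samples.bin``) plus a JSON sidecar (``meta.json``) carrying the
sampling rate, channel identifiers and electrode layout.  Hypnograms and
event tables are plain CSV; EDF export is provided for interoperability
with standard sleep tooling.

Conventions: time is seconds from the session origin, intervals are
half-open ``[start, end)``, sample indices are 0-based.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("WAKE", "NREM", "REM")

HYPNOGRAM_COLUMNS = ("epoch", "start_s", "stage")
EVENT_COLUMNS = ("channel_id", "start_s", "end_s")


class BundleError(IOError):
    """Base class for native-bundle I/O failures."""


class MissingSidecarError(BundleError):
    pass


class ChannelMismatchError(BundleError):
    pass


class CorruptBlockError(BundleError):
    pass


@dataclass(frozen=True)
class ElectrodeLayout:
    """Assignment of channel ids to positions on a rectangular grid.

    Parameters
    ----------
    grid
        ``(n_rows, n_cols)`` array of channel ids (``None``/empty for
        unoccupied sites).
    pitch_um
        Inter-electrode spacing in micrometres.
    region_labels
        Optional map channel id -> anatomical region string.
    """

    grid: tuple[tuple[str | None, ...], ...]
    pitch_um: float = 600.0
    region_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for row in self.grid:
            for ch in row:
                if ch is None or ch == "":
                    continue
                if ch in seen:
                    raise ValueError(f"channel {ch!r} appears more than once in layout")
                seen.add(ch)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.grid), len(self.grid[0]) if self.grid else 0)

    def positions(self) -> dict[str, tuple[int, int]]:
        """Map channel id -> (row, col)."""
        out: dict[str, tuple[int, int]] = {}
        for r, row in enumerate(self.grid):
            for c, ch in enumerate(row):
                if ch is not None and ch != "":
                    out[ch] = (r, c)
        return out

    def coordinates_um(self) -> dict[str, tuple[float, float]]:
        """Map channel id -> (x, y) in micrometres (col -> x, row -> y)."""
        return {
            ch: (c * self.pitch_um, r * self.pitch_um)
            for ch, (r, c) in self.positions().items()
        }

    @classmethod
    def default_8x8(cls, pitch_um: float = 600.0) -> "ElectrodeLayout":
        """Row-major ch00..ch63 on an 8x8 grid."""
        grid = tuple(
            tuple(f"ch{r * 8 + c:02d}" for c in range(8)) for r in range(8)
        )
        return cls(grid=grid, pitch_um=pitch_um)

    def to_dict(self) -> dict:
        return {
            "grid": [list(row) for row in self.grid],
            "pitch_um": self.pitch_um,
            "region_labels": dict(self.region_labels) if self.region_labels else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ElectrodeLayout":
        return cls(
            grid=tuple(tuple(row) for row in d["grid"]),
            pitch_um=float(d.get("pitch_um", 600.0)),
            region_labels=d.get("region_labels"),
        )


@dataclass
class Recording:
    """Multichannel time series with grid geometry.

    ``samples`` is a ``(n_channels, n_samples)`` float array in arbitrary
    amplitude units.
    """

    samples: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    layout: ElectrodeLayout | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channel_ids = tuple(self.channel_ids)
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        try:
            idx = self.channel_ids.index(channel_id)
        except ValueError:
            raise KeyError(f"unknown channel {channel_id!r}") from None
        return self.samples[idx]

    def slice_time(self, start_s: float, end_s: float) -> "Recording":
        """Sub-recording over [start_s, end_s) in session time."""
        i0 = int(round((start_s - self.start_time) * self.fs))
        i1 = int(round((end_s - self.start_time) * self.fs))
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError(
                f"requested [{start_s}, {end_s}) s outside recording span "
                f"[{self.start_time}, {self.start_time + self.duration_s}) s"
            )
        return Recording(
            samples=self.samples[:, i0:i1].copy(),
            fs=self.fs,
            channel_ids=self.channel_ids,
            layout=self.layout,
            start_time=start_s,
        )


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels at fixed epoch length (default 4 s)."""

    labels: tuple[str, ...]
    epoch_len: float = 4.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if not self.labels:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted(set(self.labels) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_len

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def epoch_starts(self) -> np.ndarray:
        return self.origin + self.epoch_len * np.arange(len(self.labels))

    def stage_mask(self, stage: str, fs: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask marking epochs with the given stage."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        mask = np.zeros(n_samples, dtype=bool)
        spe = self.epoch_len * fs
        for i, lab in enumerate(self.labels):
            if lab != stage:
                continue
            a = int(round(i * spe))
            b = min(int(round((i + 1) * spe)), n_samples)
            mask[a:b] = True
        return mask

    def stage_seconds(self, stage: str) -> float:
        return self.labels.count(stage) * self.epoch_len


class EventTable:
    """Thin wrapper over a DataFrame of half-open ``[start_s, end_s)`` events."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        bad = df.index[df["end_s"].to_numpy() <= df["start_s"].to_numpy()]
        if len(bad):
            raise ValueError(
                f"event rows with end_s <= start_s at index {list(bad[:5])}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "EventTable":
        rows = list(records)
        if not rows:
            return cls(pd.DataFrame(columns=list(EVENT_COLUMNS)))
        return cls(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# native bundle
# ---------------------------------------------------------------------------

_BLOCK_NAME = "samples.bin"
_SIDECAR_NAME = "meta.json"
_MAGIC = b"ECOGSLP1"


def write_bundle(recording: Recording, path: str | Path) -> Path:
    """Write a recording as a binary block + JSON sidecar directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    block = path / _BLOCK_NAME
    with open(block, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<qq", recording.n_channels, recording.n_samples))
        fh.write(np.ascontiguousarray(recording.samples, dtype="<f8").tobytes())
    meta = {
        "fs": recording.fs,
        "channel_ids": list(recording.channel_ids),
        "start_time": recording.start_time,
        "layout": recording.layout.to_dict() if recording.layout else None,
    }
    (path / _SIDECAR_NAME).write_text(json.dumps(meta, indent=1))
    return path


def read_bundle(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = path / _SIDECAR_NAME
    if not sidecar.exists():
        raise MissingSidecarError(f"no {_SIDECAR_NAME} in {path}")
    meta = json.loads(sidecar.read_text())
    block = path / _BLOCK_NAME
    if not block.exists():
        raise CorruptBlockError(f"no {_BLOCK_NAME} in {path}")
    raw = block.read_bytes()
    header = len(_MAGIC) + 16
    if len(raw) < header or raw[: len(_MAGIC)] != _MAGIC:
        raise CorruptBlockError("bad magic or truncated header")
    n_ch, n_samp = struct.unpack("<qq", raw[len(_MAGIC) : header])
    expected = header + 8 * n_ch * n_samp
    if len(raw) != expected:
        raise CorruptBlockError(
            f"block holds {len(raw)} bytes, expected {expected}"
        )
    if n_ch != len(meta["channel_ids"]):
        raise ChannelMismatchError(
            f"block has {n_ch} channels, sidecar lists {len(meta['channel_ids'])}"
        )
    samples = np.frombuffer(raw, dtype="<f8", offset=header).reshape(n_ch, n_samp)
    layout = ElectrodeLayout.from_dict(meta["layout"]) if meta.get("layout") else None
    return Recording(
        samples=samples.copy(),
        fs=float(meta["fs"]),
        channel_ids=tuple(meta["channel_ids"]),
        layout=layout,
        start_time=float(meta.get("start_time", 0.0)),
    )


# ---------------------------------------------------------------------------
# EDF export (EDF, 16-bit; single data record holding the whole signal)
# ---------------------------------------------------------------------------


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def export_edf(recording: Recording, path: str | Path) -> Path:
    """Write the recording as a plain EDF file, one signal per channel.

    Samples are quantized to 16 bits over the per-channel physical range, so
    the round-trip error is bounded by ``range / 2**15``.
    """
    if recording.n_samples == 0 or recording.n_channels == 0:
        raise ValueError("cannot export an empty recording")
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError("cannot export non-finite samples to EDF")
    path = Path(path)
    ns = recording.n_channels
    n = recording.n_samples
    record_dur = n / recording.fs

    phys_min = recording.samples.min(axis=1)
    phys_max = recording.samples.max(axis=1)
    flat = phys_max <= phys_min
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + ns)), 8),
            _edf_field("", 44),
            _edf_field("1", 8),
            _edf_field(f"{record_dur:.6g}", 8),
            _edf_field(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(ch, 16) for ch in recording.channel_ids),
            b"".join(_edf_field("ECoG", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_min[i]:.6g}", 8) for i in range(ns)),
            b"".join(_edf_field(f"{phys_max[i]:.6g}", 8) for i in range(ns)),
            b"".join(_edf_field(str(dig_min), 8) for _ in range(ns)),
            b"".join(_edf_field(str(dig_max), 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(str(n), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for i in range(ns):
            pmin = float(f"{phys_min[i]:.6g}")  # match header precision
            pmax = float(f"{phys_max[i]:.6g}")
            gain = (dig_max - dig_min) / (pmax - pmin)
            dig = np.round((recording.samples[i] - pmin) * gain + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file written by :func:`export_edf` (single data record)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise CorruptBlockError("EDF file too short")
    ns = int(raw[252:256].decode("ascii"))
    record_dur = float(raw[244:252].decode("ascii"))

    off = 256

    def grab(width: int) -> list[str]:
        nonlocal off
        out = [
            raw[off + i * width : off + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]
        off += ns * width
        return out

    labels = grab(16)
    grab(80)  # transducer
    grab(8)  # dimension
    pmins = [float(v) for v in grab(8)]
    pmaxs = [float(v) for v in grab(8)]
    dmins = [int(v) for v in grab(8)]
    dmaxs = [int(v) for v in grab(8)]
    grab(80)  # prefilter
    counts = [int(v) for v in grab(8)]
    grab(32)

    data_off = 256 * (1 + ns)
    chans = []
    pos = data_off
    for i in range(ns):
        dig = np.frombuffer(raw, dtype="<i2", count=counts[i], offset=pos)
        pos += 2 * counts[i]
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        chans.append((dig.astype(np.float64) - dmins[i]) * gain + pmins[i])
    n = counts[0]
    fs = n / record_dur
    return Recording(
        samples=np.vstack(chans), fs=fs, channel_ids=tuple(labels)
    )


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------


def write_hypnogram_csv(hypnogram: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch": np.arange(len(hypnogram)),
            "start_s": hypnogram.epoch_starts(),
            "stage": list(hypnogram.labels),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_hypnogram_csv(path: str | Path, epoch_len: float = 4.0) -> Hypnogram:
    df = pd.read_csv(path)
    missing = [c for c in HYPNOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hypnogram CSV missing columns: {missing}")
    for i, lab in enumerate(df["stage"]):
        if lab not in STAGES:
            raise ValueError(f"unknown stage label {lab!r} at row {i}")
    origin = float(df["start_s"].iloc[0]) if len(df) else 0.0
    if len(df) > 1:
        epoch_len = float(df["start_s"].iloc[1] - df["start_s"].iloc[0])
    return Hypnogram(labels=tuple(df["stage"]), epoch_len=epoch_len, origin=origin)


def write_events_csv(events: EventTable | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = events.df if isinstance(events, EventTable) else events
    df.to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> EventTable:
    df = pd.read_csv(path)
    if df.empty and all(c in df.columns for c in EVENT_COLUMNS):
        return EventTable(df)
    return EventTable(df)
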