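"""Notch filtering, Welch PSD, band power and RBF spatial interpolation.

PSD settings follow the analysis defaults: Welch with 2-s Hann windows and
1.75-s overlap over the 0.5-150 Hz range; the 8x8 electrode band-power matrix
is upsampled to 100x100 with a thin-plate-spline RBF that is exact at the
electrode nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import RBFInterpolator

from ecogsleep.io import ElectrodeLayout, Recording

ANALYSIS_RANGE = (0.5, 150.0)
NOTCH_FREQS = (50.0, 100.0, 150.0)


@dataclass
class PSDSpectrum:
    """Welch PSD estimate with the window settings that produced it."""

    freqs: np.ndarray
    power: np.ndarray
    window_s: float = 2.0
    overlap_s: float = 1.75

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpatialPowerMap:
    """Per-electrode band power and its RBF-interpolated image."""

    raw: np.ndarray  # (rows, cols) electrode grid values
    interpolated: np.ndarray  # (out_size, out_size)
    band: tuple[float, float] | None = None
    contour_levels: np.ndarray | None = None


def apply_notch(
    x: np.ndarray,
    fs: float,
    freqs: tuple[float, ...] = NOTCH_FREQS,
    q: float = 30.0,
) -> np.ndarray:
    """Zero-phase IIR notches at each frequency (>= 20 dB at the notch)."""
    nyq = fs / 2.0
    y = np.asarray(x, dtype=float)
    for f0 in freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
        b, a = sps.iirnotch(f0, Q=q, fs=fs)
        y = sps.filtfilt(b, a, y, axis=-1)
    return y


def bandpass_1_150(x: np.ndarray, fs: float, order: int = 4,
                   band: tuple[float, float] = (1.0, 150.0)) -> np.ndarray:
    """Zero-phase Butterworth bandpass used ahead of coherence estimation."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_s: float = 1.75,
) -> PSDSpectrum:
    """Welch PSD with Hann windows (defaults: 2-s windows, 1.75-s overlap)."""
    x = np.asarray(x, dtype=float)
    if overlap_s >= window_s:
        raise ValueError("overlap_s must be smaller than window_s")
    nper = int(round(window_s * fs))
    if len(x) < nper:
        raise ValueError(
            f"signal of {len(x) / fs:.3g} s shorter than the {window_s} s window"
        )
    nover = int(round(overlap_s * fs))
    f, p = sps.welch(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nover, detrend=False
    )
    return PSDSpectrum(freqs=f, power=p, window_s=window_s, overlap_s=overlap_s)


def band_power(psd: PSDSpectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [low, high]."""
    lo, hi = band
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    if sel.sum() < 2:
        raise ValueError(f"band {band} covers fewer than two frequency bins")
    return float(np.trapezoid(psd.power[sel], psd.freqs[sel]))


def to_db(psd: PSDSpectrum, floor: float = 1e-300) -> PSDSpectrum:
    """10*log10 transform of the power values (offset so the result is a
    spectrum object; negative dB values are expected and permitted)."""
    db = 10.0 * np.log10(np.maximum(psd.power, floor))
    out = PSDSpectrum.__new__(PSDSpectrum)
    out.freqs = psd.freqs.copy()
    out.power = db
    out.window_s = psd.window_s
    out.overlap_s = psd.overlap_s
    return out


def spatial_map(
    per_channel_power: dict[str, float],
    layout: ElectrodeLayout,
    kernel: str = "thin_plate_spline",
    out_size: int = 100,
    n_contours: int = 20,
) -> SpatialPowerMap:
    """RBF-interpolate scattered electrode powers onto an out_size^2 image.

    Thin-plate spline with a linear polynomial tail: exact at nodes and
    reproduces constant fields exactly.
    """
    positions = layout.positions()
    missing = sorted(set(positions) - set(per_channel_power))
    if missing:
        raise ValueError(f"missing power values for channels: {missing}")

    rows, cols = layout.shape
    raw = np.full((rows, cols), np.nan)
    pts = []
    vals = []
    for ch, (r, c) in positions.items():
        raw[r, c] = per_channel_power[ch]
        pts.append((r, c))
        vals.append(per_channel_power[ch])
    pts = np.asarray(pts, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 electrodes for interpolation")

    interp = RBFInterpolator(pts, vals, kernel=kernel, degree=1)
    gy = np.linspace(0, rows - 1, out_size)
    gx = np.linspace(0, cols - 1, out_size)
    grid = np.stack(np.meshgrid(gy, gx, indexing="ij"), axis=-1).reshape(-1, 2)
    img = interp(grid).reshape(out_size, out_size)
    levels = np.linspace(img.min(), img.max(), n_contours)
    return SpatialPowerMap(raw=raw, interpolated=img, contour_levels=levels)


def select_segment(
    recording: Recording,
    zt_start: float,
    length_s: float = 15.0,
    lights_on_s: float = 0.0,
) -> Recording:
    """Cut a segment starting at Zeitgeber time ``zt_start`` hours.

    ZT0 corresponds to ``lights_on_s`` seconds in session time.
    """
    start_s = lights_on_s + zt_start * 3600.0
    end_s = start_s + length_s
    span_end = recording.start_time + recording.duration_s
    if start_s < recording.start_time or end_s > span_end:
        raise ValueError(
            f"segment [{start_s}, {end_s}) s outside recording span "
            f"[{recording.start_time}, {span_end}) s"
        )
    return recording.slice_time(start_s, end_s)
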