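"""WAKE/NREM/REM classification of 4-s epochs.

Epochs showing video motion are scored WAKE; otherwise the stage whose
characteristic band (wake 8-30 Hz, NREM 0.5-4 Hz, REM 6.25-9 Hz) carries the
largest summed STFT power wins, ties broken NREM > REM > WAKE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage import measure, morphology

from ecogsleep.io import Hypnogram, Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageBands:
    """Half-open [low, high) dominance bands per stage, in Hz."""

    wake: tuple[float, float] = (8.0, 30.0)
    nrem: tuple[float, float] = (0.5, 4.0)
    rem: tuple[float, float] = (6.25, 9.0)

    def __post_init__(self) -> None:
        for band in (self.wake, self.nrem, self.rem):
            if band[0] >= band[1]:
                raise ValueError(f"band {band} must have low < high")


@dataclass
class MotionSeries:
    """Per-epoch boolean motion flags plus the detection parameters used."""

    flags: np.ndarray
    diff_threshold: float
    min_blob_px: int
    roi: tuple[int, int, int, int] | None = None

    def __len__(self) -> int:
        return len(self.flags)


def detect_motion(
    frames: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    diff_threshold: float = 20.0,
    min_blob_px: int = 9,
) -> MotionSeries:
    """Frame-differencing motion detector.

    Parameters
    ----------
    frames
        ``(n_epochs, height, width)`` grayscale stack, one frame per epoch.
    roi
        ``(row0, col0, row1, col1)`` half-open crop; default whole frame.
    diff_threshold
        Absolute intensity difference above which a pixel counts as changed.
    min_blob_px
        Minimum connected-component size (after binary opening) that flags
        an epoch as moving.

    The flag for epoch ``t >= 1`` compares frames ``t-1`` and ``t``; the
    first epoch inherits the second's flag.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_epochs >= 2, h, w) frame stack")
    h, w = frames.shape[1:]
    if roi is not None:
        r0, c0, r1, c1 = roi
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"roi {roi} outside frame bounds {(h, w)}")
        frames = frames[:, r0:r1, c0:c1]

    n = frames.shape[0]
    flags = np.zeros(n, dtype=bool)
    footprint = np.ones((3, 3), dtype=bool)
    for t in range(1, n):
        diff = np.abs(frames[t] - frames[t - 1]) > diff_threshold
        opened = morphology.opening(diff, footprint=footprint)
        if opened.any():
            labels = measure.label(opened, connectivity=1)
            sizes = np.bincount(labels.ravel())[1:]
            flags[t] = bool(sizes.size and sizes.max() >= min_blob_px)
    flags[0] = flags[1]
    return MotionSeries(
        flags=flags, diff_threshold=diff_threshold, min_blob_px=min_blob_px, roi=roi
    )


def _stft_power(x: np.ndarray, fs: float, win_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared-magnitude STFT spectrum of one epoch (Hann, 50% overlap)."""
    nper = int(round(win_s * fs))
    nper = min(nper, len(x))
    f, _, Z = sps.stft(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, boundary=None
    )
    return f, np.mean(np.abs(Z) ** 2, axis=1)


def epoch_band_powers(
    recording: Recording,
    channels: list[str] | None = None,
    epoch_len: float = 4.0,
    bands: StageBands | None = None,
    stft_win_s: float = 1.0,
) -> np.ndarray:
    """Per-epoch summed STFT power in the three stage bands.

    Spectra are averaged over the selected channels (default all) before the
    in-band summation.  Returns an ``(n_epochs, 3)`` array ordered
    ``(wake, nrem, rem)``.
    """
    bands = bands or StageBands()
    spe = epoch_len * recording.fs
    if abs(spe - round(spe)) > 1e-9 or spe <= 0:
        raise ValueError("epoch_len must be a positive multiple of 1/fs")
    spe = int(round(spe))
    if recording.n_samples < spe:
        raise ValueError("recording shorter than one epoch")
    if channels is None:
        data = recording.samples
    else:
        data = np.vstack([recording.channel(c) for c in channels])
    n_epochs = recording.n_samples // spe

    out = np.empty((n_epochs, 3))
    for e in range(n_epochs):
        seg = data[:, e * spe : (e + 1) * spe]
        spectra = None
        freqs = None
        for row in seg:
            f, p = _stft_power(row, recording.fs, stft_win_s)
            spectra = p if spectra is None else spectra + p
            freqs = f
        spectra = spectra / seg.shape[0]
        for k, band in enumerate((bands.wake, bands.nrem, bands.rem)):
            sel = (freqs >= band[0]) & (freqs < band[1])
            out[e, k] = float(spectra[sel].sum())
    return out


def classify_epochs(
    band_powers: np.ndarray,
    motion: MotionSeries | None = None,
    epoch_len: float = 4.0,
) -> Hypnogram:
    """Stage each epoch from (wake, nrem, rem) band powers and motion flags.

    Motion-true epochs are WAKE regardless of spectra.  Otherwise the maximal
    band wins; ties break NREM > REM > WAKE.  All-zero epochs are labelled
    WAKE with a warning.
    """
    band_powers = np.asarray(band_powers, dtype=float)
    n = band_powers.shape[0]
    if motion is not None and len(motion) != n:
        raise ValueError(
            f"motion length {len(motion)} != {n} epochs of band powers"
        )
    labels = []
    for e in range(n):
        if motion is not None and motion.flags[e]:
            labels.append("WAKE")
            continue
        wake_p, nrem_p, rem_p = band_powers[e]
        if wake_p == nrem_p == rem_p == 0.0:
            logger.warning("epoch %d has all-zero band powers; labelling WAKE", e)
            labels.append("WAKE")
            continue
        # tie preference NREM > REM > WAKE via ordering of candidates
        ranked = sorted(
            (("NREM", nrem_p), ("REM", rem_p), ("WAKE", wake_p)),
            key=lambda kv: -kv[1],
        )
        labels.append(ranked[0][0])
    return Hypnogram(labels=tuple(labels), epoch_len=epoch_len)


def stage_proportions(hypnogram: Hypnogram) -> dict[str, float]:
    """Percentage of epochs per stage; values sum to 100."""
    n = len(hypnogram)
    return {
        stage: 100.0 * hypnogram.labels.count(stage) / n
        for stage in ("WAKE", "NREM", "REM")
    }


def staging_accuracy(predicted: Hypnogram, truth: Hypnogram) -> float:
    """Fraction of epochs with matching labels."""
    n = min(len(predicted), len(truth))
    hits = sum(
        predicted.labels[i] == truth.labels[i] for i in range(n)
    )
    return hits / n
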