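"""Sleep-spindle detection pipeline and per-event metrics.

Processing chain: downsample to 1024 Hz, excise >5 SD spikes with linear
interpolation, 0.5 Hz second-order Butterworth high-pass detrend, optional
32-component ICA, fifth-order 10-16 Hz Butterworth bandpass, then Hilbert
envelope thresholding at mean + 1.5 SD of the NREM baseline with a 0.4-3 s
duration gate restricted to NREM epochs.  Metrics: amplitude (max - min of
the sigma-band trace), duration, sigma-band power, and density
(events per second of NREM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from ecogsleep.io import Hypnogram

TARGET_FS = 1024.0
SIGMA_BAND = (10.0, 16.0)
DUR_GATE = (0.4, 3.0)


@dataclass
class SpindleEvent:
    """One detected burst on the (downsampled) timeline."""

    channel_id: str
    start_s: float
    end_s: float
    amplitude: float = np.nan
    power: float = np.nan

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have end_s > start_s")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SpindleSummary:
    n_events: int
    nrem_duration_s: float
    density: float  # events per second of NREM

    @classmethod
    def from_events(cls, events: list[SpindleEvent], nrem_duration_s: float) -> "SpindleSummary":
        return cls(
            n_events=len(events),
            nrem_duration_s=nrem_duration_s,
            density=density(events, nrem_duration_s),
        )


def despike(
    x: np.ndarray,
    fs: float,
    sd_mult: float = 5.0,
    pad_s: float = 0.002,
) -> np.ndarray:
    """Replace samples beyond ``sd_mult`` robust SDs by linear interpolation.

    The SD is 1.4826 x MAD of the whole channel so the spikes themselves do
    not inflate the threshold; flagged regions are widened by ``pad_s`` on
    each side.  Emits a warning if more than 20% of samples are flagged.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("despike requires finite input")
    med = np.median(x)
    sd = 1.4826 * np.median(np.abs(x - med))
    if sd == 0:
        return x.copy()
    bad = np.abs(x - med) > sd_mult * sd
    if not bad.any():
        return x.copy()
    pad = int(round(pad_s * fs))
    if pad:
        kernel = np.ones(2 * pad + 1, dtype=bool)
        bad = np.convolve(bad, kernel, mode="same") > 0
    frac = bad.mean()
    if frac > 0.2:
        warnings.warn(
            f"{100 * frac:.1f}% of samples flagged as spikes: channel quality "
            "is suspect",
            stacklevel=2,
        )
    good = ~bad
    if not good.any():
        return np.full_like(x, med)
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return out


def resample_1024(x: np.ndarray, fs: float) -> np.ndarray:
    """Polyphase anti-aliased downsampling to 1024 Hz."""
    if fs < TARGET_FS:
        raise ValueError(
            f"fs = {fs} Hz < {TARGET_FS} Hz: upsampling is out of contract"
        )
    if fs == TARGET_FS:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(int(round(TARGET_FS * 1000)), int(round(fs * 1000)))
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def detrend_hp(x: np.ndarray, fs: float, cutoff: float = 0.5, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass detrend (default 0.5 Hz, order 2)."""
    if fs <= 1.0:
        raise ValueError("fs must exceed 1 Hz")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def ica_decompose(
    data: np.ndarray, n_components: int = 32, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FastICA of a (channels x time) array.

    Returns ``(components, mixing, unmixing)`` with components of shape
    ``(n_components, time)`` and mixing of shape ``(channels, n_components)``
    such that ``mixing @ components + mean`` reconstructs the projection of
    the input onto the retained whitened subspace.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < n_components:
        raise ValueError(
            f"need >= {n_components} channels, got shape {data.shape}"
        )
    if np.linalg.matrix_rank(data @ data.T) < n_components:
        raise ValueError("rank-deficient input: fewer independent sources than components")
    ica = FastICA(
        n_components=n_components, random_state=seed, whiten="unit-variance",
        max_iter=1000,
    )
    comps = ica.fit_transform(data.T).T
    mixing = ica.mixing_
    unmixing = ica.components_
    return comps, mixing, unmixing


def sigma_bandpass(
    x: np.ndarray, fs: float, band: tuple[float, float] = SIGMA_BAND, order: int = 5
) -> np.ndarray:
    """Zero-phase fifth-order Butterworth bandpass (default 10-16 Hz)."""
    if fs <= 2 * band[1]:
        raise ValueError(f"fs = {fs} Hz too low for a {band} Hz bandpass")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    m = np.asarray(mask, dtype=bool).astype(np.int8)
    d = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect(
    signal_sigma: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    channel_id: str = "ch00",
    k: float = 1.5,
    dur: tuple[float, float] = DUR_GATE,
    merge_gap_s: float = 0.1,
) -> list[SpindleEvent]:
    """Envelope-threshold spindle detection restricted to NREM epochs.

    The Hilbert envelope of the sigma-band signal is compared against
    ``mean + k*SD`` computed over NREM samples only; supra-threshold runs
    closer than ``merge_gap_s`` are merged, clipped to NREM support, and kept
    when their duration falls inside ``dur``.
    """
    x = np.asarray(signal_sigma, dtype=float)
    n = len(x)
    nrem_mask = hypnogram.stage_mask("NREM", fs, n)
    if not nrem_mask.any():
        raise ValueError("baseline undefined: hypnogram contains no NREM epochs")
    env = np.abs(sps.hilbert(x))
    mu = float(env[nrem_mask].mean())
    sd = float(env[nrem_mask].std())
    thr = mu + k * sd

    supra = env > thr
    runs = _runs(supra)
    # merge runs separated by less than merge_gap_s
    merged: list[tuple[int, int]] = []
    gap = int(round(merge_gap_s * fs))
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    # clip to NREM support (a run spanning a stage boundary splits)
    events: list[SpindleEvent] = []
    for a, b in merged:
        within = np.zeros(n, dtype=bool)
        within[a:b] = True
        for s, e in _runs(within & nrem_mask):
            d = (e - s) / fs
            if dur[0] <= d <= dur[1]:
                events.append(
                    SpindleEvent(channel_id=channel_id, start_s=s / fs, end_s=e / fs)
                )
    events.sort(key=lambda ev: ev.start_s)
    return events


def event_metrics(
    events: list[SpindleEvent],
    signal_sigma: np.ndarray,
    fs: float,
    band: tuple[float, float] = SIGMA_BAND,
    power_mode: str = "band_mean",
) -> list[SpindleEvent]:
    """Fill amplitude (max - min of the sigma trace) and in-band power.

    Power is the mean PSD over the sigma band computed on the event samples:
    Welch with 2-s windows when the event is long enough, otherwise a single
    Hann periodogram (0.4-s events cannot host 2-s Welch segments).
    ``power_mode`` in {"band_mean", "band_peak", "band_total"}.
    """
    x = np.asarray(signal_sigma, dtype=float)
    out = []
    for ev in events:
        i0 = int(round(ev.start_s * fs))
        i1 = int(round(ev.end_s * fs))
        seg = x[i0:i1]
        if len(seg) == 0:
            raise ValueError(f"event {ev} is empty at fs = {fs}")
        amp = float(seg.max() - seg.min())
        nper = min(len(seg), int(round(2.0 * fs)))
        f, p = sps.welch(
            seg, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
            detrend=False,
        )
        sel = (f >= band[0]) & (f <= band[1])
        if not sel.any():
            power = float("nan")
        elif power_mode == "band_mean":
            power = float(p[sel].mean())
        elif power_mode == "band_peak":
            power = float(p[sel].max())
        elif power_mode == "band_total":
            power = float(np.trapezoid(p[sel], f[sel]))
        else:
            raise ValueError(f"unknown power_mode {power_mode!r}")
        out.append(
            SpindleEvent(
                channel_id=ev.channel_id,
                start_s=ev.start_s,
                end_s=ev.end_s,
                amplitude=amp,
                power=power,
            )
        )
    return out


def density(events: list, nrem_duration_s: float) -> float:
    """Spindle density: number of events per second of NREM."""
    if nrem_duration_s <= 0:
        raise ValueError("nrem_duration_s must be positive")
    return len(events) / nrem_duration_s


def detect_channel(
    raw: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    channel_id: str = "ch00",
    k: float = 1.5,
    merge_gap_s: float = 0.1,
) -> tuple[list[SpindleEvent], np.ndarray]:
    """Full single-channel chain: resample, despike, detrend, sigma filter,
    detect, and attach metrics.  Returns (events, sigma-band signal at
    1024 Hz)."""
    x = resample_1024(raw, fs)
    x = despike(x, TARGET_FS)
    x = detrend_hp(x, TARGET_FS)
    sig = sigma_bandpass(x, TARGET_FS)
    events = detect(
        sig, TARGET_FS, hypnogram, channel_id=channel_id, k=k,
        merge_gap_s=merge_gap_s,
    )
    events = event_metrics(events, sig, TARGET_FS)
    return events, sig


def match_events(
    detected: list[tuple[float, float]],
    planted: list[tuple[float, float]],
    min_overlap: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy interval matching; overlap >= min_overlap of the shorter event.

    Returns (true_positives, false_positives, false_negatives).
    """
    used = [False] * len(planted)
    tp = 0
    for ds, de in detected:
        best = -1
        best_ov = 0.0
        for i, (ps, pe) in enumerate(planted):
            if used[i]:
                continue
            ov = max(0.0, min(de, pe) - max(ds, ps))
            denom = min(de - ds, pe - ps)
            frac = ov / denom if denom > 0 else 0.0
            if frac > best_ov:
                best_ov = frac
                best = i
        if best >= 0 and best_ov >= min_overlap:
            used[best] = True
            tp += 1
    fp = len(detected) - tp
    fn = len(planted) - tp
    return tp, fp, fn
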