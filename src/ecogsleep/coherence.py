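"""Magnitude-squared coherence and paired before/after change statistics.

Coherence is |Pxy|^2 / (Pxx * Pyy) from segment-averaged cross- and
auto-spectra, computed after a 1-150 Hz bandpass and 50/100/150 Hz notches.
Band values are unweighted means over in-band bins; before/after changes per
channel pair and band are tested with the two-sided Wilcoxon matched-pairs
signed-rank test and Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from ecogsleep.io import Recording
from ecogsleep.spectral import apply_notch, bandpass_1_150
from ecogsleep.inference import bh_fdr

#: the six analysis bands, Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma1": (30.0, 80.0),
    "gamma2": (80.0, 150.0),
}

IN_BAND_RANGE = (1.0, 150.0)


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    msc: np.ndarray
    pxx: np.ndarray | None = None
    pyy: np.ndarray | None = None
    pxy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.msc = np.asarray(self.msc, dtype=float)
        if np.any(self.msc < -1e-9) or np.any(self.msc > 1 + 1e-9):
            raise ValueError("msc must lie in [0, 1]")
        self.msc = np.clip(self.msc, 0.0, 1.0)

    def in_band(self, band: tuple[float, float] = IN_BAND_RANGE) -> "CoherenceSpectrum":
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        return CoherenceSpectrum(freqs=self.freqs[sel], msc=self.msc[sel])


def preprocess(x: np.ndarray, fs: float) -> np.ndarray:
    """1-150 Hz bandpass followed by 50/100/150 Hz notches."""
    return apply_notch(bandpass_1_150(x, fs), fs)


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
    pre_filter: bool = True,
) -> CoherenceSpectrum:
    """Segment-averaged magnitude-squared coherence of two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    nper = int(round(window_s * fs))
    nover = int(round(overlap_s * fs))
    if nover >= nper:
        raise ValueError("overlap_s must be smaller than window_s")
    step = nper - nover
    n_segments = 1 + max(len(x) - nper, -1) // step if len(x) >= nper else 0
    if n_segments < 2:
        raise ValueError(
            "need at least 2 averaging segments; coherence of one segment is "
            "degenerately 1"
        )
    if pre_filter:
        x = preprocess(x, fs)
        y = preprocess(y, fs)
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nover,
                       detrend=False)
    _, pyy = sps.welch(y, fs=fs, window="hann", nperseg=nper, noverlap=nover,
                       detrend=False)
    _, pxy = sps.csd(x, y, fs=fs, window="hann", nperseg=nper, noverlap=nover,
                     detrend=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(pxy) ** 2 / (pxx * pyy)
    c = np.where(np.isfinite(c), c, 0.0)
    return CoherenceSpectrum(
        freqs=f, msc=np.clip(c, 0.0, 1.0), pxx=pxx, pyy=pyy, pxy=pxy
    )


def band_coherence(spec: CoherenceSpectrum, band: tuple[float, float]) -> float:
    """Unweighted mean msc over bins in [low, high]."""
    lo, hi = band
    if hi < IN_BAND_RANGE[0] or lo > IN_BAND_RANGE[1]:
        raise ValueError(f"band {band} outside analysis range {IN_BAND_RANGE}")
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins")
    return float(spec.msc[sel].mean())


def pairwise_band_matrix(
    recording: Recording,
    band: tuple[float, float],
    segment: tuple[float, float] | None = None,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
) -> pd.DataFrame:
    """Symmetric channel x channel matrix of band-mean coherence.

    ``segment`` is an optional (start_s, end_s) slice in session time; the
    default uses the full recording.
    """
    rec = recording if segment is None else recording.slice_time(*segment)
    ids = rec.channel_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 channels")
    filtered = np.vstack([preprocess(rec.samples[i], rec.fs) for i in range(n)])
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            spec = msc(
                filtered[i], filtered[j], rec.fs,
                window_s=window_s, overlap_s=overlap_s, pre_filter=False,
            )
            val = band_coherence(spec, band)
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=list(ids), columns=list(ids))


@dataclass
class PairBandChange:
    pair: tuple[str, str]
    band: str
    before: np.ndarray
    after: np.ndarray
    p_raw: float
    p_fdr: float = np.nan
    direction: str = "none"  # increase | decrease | none
    stars: str = "ns"


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(
    before: Mapping[tuple[tuple[str, str], str], Sequence[float]],
    after: Mapping[tuple[tuple[str, str], str], Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon signed-rank + BH-FDR over all (pair, band) coherence series.

    ``before`` and ``after`` map ``((ch_i, ch_j), band_name)`` to per-segment
    band coherences; keys must match and each series must hold >= 5 paired
    observations.  Returns a table with raw and adjusted p-values, a
    direction from the median paired difference, and significance stars.
    """
    if set(before) != set(after):
        raise ValueError("before/after must contain the same (pair, band) keys")
    keys = sorted(before.keys(), key=str)
    results: list[PairBandChange] = []
    for key in keys:
        b = np.asarray(before[key], dtype=float)
        a = np.asarray(after[key], dtype=float)
        if len(b) != len(a):
            raise ValueError(f"unmatched segment counts for {key}")
        if len(b) < 5:
            raise ValueError(f"need >= 5 paired observations for {key}")
        diffs = a - b
        if np.all(diffs == 0):
            p = 1.0  # degenerate: no information, treated as no change
        else:
            n_eff = int(np.sum(diffs != 0))
            method = "exact" if n_eff <= 25 else "approx"
            res = stats.wilcoxon(
                b, a, zero_method="wilcox", correction=(method == "approx"),
                alternative="two-sided", method=method,
            )
            p = float(res.pvalue)
        results.append(
            PairBandChange(pair=key[0], band=key[1], before=b, after=a, p_raw=p)
        )

    adj = bh_fdr([r.p_raw for r in results])
    rows = []
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
        med = float(np.median(r.after - r.before))
        if r.p_fdr < alpha and med != 0:
            r.direction = "increase" if med > 0 else "decrease"
        else:
            r.direction = "none"
        r.stars = _stars(r.p_fdr)
        rows.append(
            {
                "channel_i": r.pair[0],
                "channel_j": r.pair[1],
                "band": r.band,
                "median_diff": med,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "direction": r.direction,
                "stars": r.stars,
            }
        )
    return pd.DataFrame(rows)


def segment_band_coherences(
    recording: Recording,
    pairs: Sequence[tuple[str, str]],
    n_segments: int = 12,
    segment_len_s: float = 15.0,
    bands: Mapping[str, tuple[float, float]] | None = None,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
) -> dict[tuple[tuple[str, str], str], np.ndarray]:
    """Band coherence per pair over consecutive fixed-length segments."""
    bands = dict(bands) if bands is not None else BANDS
    avail = int(recording.duration_s // segment_len_s)
    if avail < n_segments:
        raise ValueError(
            f"recording holds {avail} segments of {segment_len_s} s, "
            f"requested {n_segments}"
        )
    out: dict[tuple[tuple[str, str], str], np.ndarray] = {
        (tuple(p), b): np.empty(n_segments) for p in pairs for b in bands
    }
    for s in range(n_segments):
        t0 = recording.start_time + s * segment_len_s
        seg = recording.slice_time(t0, t0 + segment_len_s)
        for p in pairs:
            x = seg.channel(p[0])
            y = seg.channel(p[1])
            spec = msc(x, y, seg.fs, window_s=window_s, overlap_s=overlap_s)
            for bname, brange in bands.items():
                out[(tuple(p), bname)][s] = band_coherence(spec, brange)
    return out
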