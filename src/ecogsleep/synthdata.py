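"""Ground-truth synthetic recording generator.

Produces multichannel recordings whose statistical structure matches what the
analysis stages assume: stage-dependent spectral dominance (delta for NREM,
6.25-9 Hz for REM, 8-30 Hz for wake) over a 1/f background, Hann-windowed
10-16 Hz spindle bursts planted only in NREM, line noise at 50/100/150 Hz,
biphasic transient spikes, linearly mixed channel pairs with a closed-form
expected coherence, and per-epoch video frames whose blob moves only in WAKE
epochs.  Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from ecogsleep.io import ElectrodeLayout, Hypnogram, Recording, STAGES

EPOCH_LEN = 4.0

#: stage -> (oscillation band low, high) used for the dominant rhythm
_STAGE_OSC_BAND = {
    "WAKE": (12.0, 25.0),  # inside 8-30, clear of the REM band overlap at 8-9
    "NREM": (1.0, 3.5),
    "REM": (6.5, 8.5),
}

DEFAULT_TRANSITIONS = {
    #           WAKE  NREM   REM
    "WAKE": (0.70, 0.25, 0.05),
    "NREM": (0.20, 0.70, 0.10),
    "REM": (0.35, 0.10, 0.55),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic recording.

    Amplitudes are arbitrary units; the background 1/f process has unit RMS
    per channel before oscillations are added.
    """

    n_channels: int = 64
    fs: float = 2048.0
    duration: float = 600.0
    stage_transition_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS)
    )
    initial_stage: str = "WAKE"
    osc_amp: float = 2.0  # stage-band oscillation RMS relative to background RMS
    spindle_rate: float = 0.05  # events per second of NREM, per channel
    spindle_freq: float = 13.0
    spindle_amp_snr: float = 4.0  # burst peak amplitude / background RMS
    spindle_dur_range: tuple[float, float] = (0.5, 2.0)
    line_noise_amp: dict[int, float] = field(
        default_factory=lambda: {50: 0.2, 100: 0.1, 150: 0.05}
    )
    spike_rate: float = 1.0  # events per minute, per channel
    coupling_pairs: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < EPOCH_LEN:
            raise ValueError(f"duration must be >= one epoch ({EPOCH_LEN} s)")
        if self.fs <= 300:
            raise ValueError("fs must exceed 300 Hz so 150 Hz content exists")
        if not (10.0 <= self.spindle_freq <= 16.0):
            raise ValueError("spindle_freq must lie in [10, 16] Hz")
        lo, hi = self.spindle_dur_range
        if not (0.4 <= lo < hi <= 3.0):
            raise ValueError("spindle_dur_range must lie within [0.4, 3.0] s")
        for stage, row in self.stage_transition_weights.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r} in transition weights")
            if abs(sum(row) - 1.0) > 1e-9 or min(row) < 0:
                raise ValueError(f"transition row for {stage} is not stochastic")
        for i, j, a in self.coupling_pairs:
            if not (0.0 <= a <= 1.0):
                raise ValueError("mixing coefficient must lie in [0, 1]")
            if i == j:
                raise ValueError("coupling pair must name two distinct channels")


@dataclass
class GroundTruth:
    """What the generator actually planted; the acceptance surface."""

    hypnogram: Hypnogram
    #: list of (channel_index, start_s, end_s, planted peak amplitude)
    spindle_events: list[tuple[int, float, float, float]]
    #: (i, j) -> (freqs, expected magnitude-squared coherence per frequency)
    pair_coherence: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    #: True exactly where the hypnogram says WAKE
    motion_epochs: np.ndarray
    #: list of (channel_index, spike_time_s)
    spike_events: list[tuple[int, float]] = field(default_factory=list)


def transition_matrix(weights: dict[str, tuple[float, float, float]]) -> np.ndarray:
    """Stage transition weights as a row-stochastic matrix in STAGES order."""
    return np.array([weights[s] for s in STAGES], dtype=float)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_hypnogram(config: SimConfig, rng: np.random.Generator | None = None) -> Hypnogram:
    """Sample 4-s epoch labels from the stage Markov chain."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_epochs = int(config.duration // EPOCH_LEN)
    P = transition_matrix(config.stage_transition_weights)
    labels = [config.initial_stage]
    idx = {s: i for i, s in enumerate(STAGES)}
    state = idx[config.initial_stage]
    for _ in range(n_epochs - 1):
        state = rng.choice(3, p=P[state])
        labels.append(STAGES[state])
    return Hypnogram(labels=tuple(labels), epoch_len=EPOCH_LEN)


def one_over_f_noise(
    n_samples: int, fs: float, rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # zero mean
    x = np.fft.irfft(spec * shaping, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _bandlimited_oscillation(
    band: tuple[float, float], n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS narrowband Gaussian oscillation via FFT-domain masking."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs < band[1])
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synth_stage_signal(
    stage: str,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    osc_amp: float = 2.0,
) -> np.ndarray:
    """1/f background plus a stage-band oscillation that dominates its band.

    The oscillation RMS is ``osc_amp`` times the (unit) background RMS, which
    makes the stage band carry the largest summed spectral power of the three
    staging bands.
    """
    if stage not in _STAGE_OSC_BAND:
        raise ValueError(f"unknown stage {stage!r}")
    background = one_over_f_noise(n_samples, fs, rng)
    osc = _bandlimited_oscillation(_STAGE_OSC_BAND[stage], n_samples, fs, rng)
    x = background + osc_amp * osc
    return x - x.mean()


def spindle_burst(
    duration_s: float, freq: float, peak_amp: float, fs: float, phase: float = 0.0
) -> np.ndarray:
    """Tapered-cosine (Tukey) windowed sinusoid with the given peak amplitude.

    The flat top keeps the Hilbert envelope above a detection threshold for
    most of the planted duration while the cosine tapers keep onset and
    offset smooth.
    """
    n = max(int(round(duration_s * fs)), 2)
    t = np.arange(n) / fs
    win = sps.windows.tukey(n, alpha=0.4)
    return peak_amp * win * np.sin(2 * np.pi * freq * t + phase)


def embed_spindles(
    signal: np.ndarray,
    hypnogram: Hypnogram,
    config: SimConfig,
    rng: np.random.Generator,
    channel: int = 0,
) -> tuple[np.ndarray, list[tuple[int, float, float, float]]]:
    """Add spindle bursts inside NREM epochs; return the planted intervals.

    The number of bursts is Poisson(rate x NREM seconds).  Candidate start
    times are drawn uniformly over NREM time; candidates that would overlap an
    already-planted burst or leave NREM support are rejected and resampled.
    """
    fs = config.fs
    n = len(signal)
    out = signal.copy()
    nrem_mask = hypnogram.stage_mask("NREM", fs, n)
    nrem_seconds = float(nrem_mask.sum()) / fs
    events: list[tuple[int, float, float, float]] = []
    if nrem_seconds <= 0:
        if config.spindle_rate > 0:
            warnings.warn("no NREM epochs: no spindles planted", stacklevel=2)
        return out, events

    n_target = int(rng.poisson(config.spindle_rate * nrem_seconds))
    nrem_idx = np.flatnonzero(nrem_mask)
    occupied = np.zeros(n, dtype=bool)
    lo, hi = config.spindle_dur_range
    planted = 0
    attempts = 0
    max_attempts = 50 * max(n_target, 1)
    while planted < n_target and attempts < max_attempts:
        attempts += 1
        dur = float(rng.uniform(lo, hi))
        start_idx = int(rng.choice(nrem_idx))
        stop_idx = start_idx + int(round(dur * fs))
        if stop_idx > n:
            continue
        # burst must sit entirely inside NREM and not touch a prior burst
        if not nrem_mask[start_idx:stop_idx].all():
            continue
        if occupied[start_idx:stop_idx].any():
            continue
        amp = config.spindle_amp_snr
        phase = float(rng.uniform(0, 2 * np.pi))
        burst = spindle_burst(dur, config.spindle_freq, amp, fs, phase)
        out[start_idx : start_idx + len(burst)] += burst
        occupied[start_idx:stop_idx] = True
        events.append((channel, start_idx / fs, stop_idx / fs, amp))
        planted += 1
    events.sort(key=lambda e: e[1])
    return out, events


class ExpectedCoherence:
    """Closed-form magnitude-squared coherence of a two-channel mixture.

    For x = s + n1, y = a*s + n2 with independent noises,

        msc(f) = a^2 Ps(f)^2 / ((Ps(f) + Pn1(f)) (a^2 Ps(f) + Pn2(f)))

    evaluated from the known per-frequency spectra of source and noises.
    """

    def __init__(
        self,
        a: float,
        source_psd: Callable[[np.ndarray], np.ndarray],
        noise1_psd: Callable[[np.ndarray], np.ndarray],
        noise2_psd: Callable[[np.ndarray], np.ndarray],
    ):
        self.a = a
        self._ps = source_psd
        self._pn1 = noise1_psd
        self._pn2 = noise2_psd

    def __call__(self, freqs: np.ndarray | float) -> np.ndarray:
        f = np.atleast_1d(np.asarray(freqs, dtype=float))
        ps = self._ps(f)
        pn1 = self._pn1(f)
        pn2 = self._pn2(f)
        a2 = self.a**2
        num = a2 * ps**2
        den = (ps + pn1) * (a2 * ps + pn2)
        with np.errstate(divide="ignore", invalid="ignore"):
            msc = np.where(den > 0, num / den, 0.0)
        return np.clip(msc, 0.0, 1.0)


def make_coupled_pair(
    base: np.ndarray,
    a: float,
    noise_sd: float,
    rng: np.random.Generator,
    fs: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, ExpectedCoherence]:
    """Mix a common source into two noisy channels with known coherence.

    ``base`` is treated as a white source (flat spectrum at its variance per
    unit bandwidth); the returned :class:`ExpectedCoherence` evaluates the
    analytic magnitude-squared coherence on any frequency grid.
    """
    if a < 0 or a > 1:
        raise ValueError("mixing coefficient a must lie in [0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    base = np.asarray(base, dtype=float)
    n = len(base)
    x = base + noise_sd * rng.standard_normal(n)
    y = a * base + noise_sd * rng.standard_normal(n)
    nyq = fs / 2.0
    ps_level = float(np.var(base)) / nyq  # flat density integrating to var
    pn_level = noise_sd**2 / nyq
    expected = ExpectedCoherence(
        a,
        source_psd=lambda f: np.full_like(f, ps_level, dtype=float),
        noise1_psd=lambda f: np.full_like(f, pn_level, dtype=float),
        noise2_psd=lambda f: np.full_like(f, pn_level, dtype=float),
    )
    return x, y, expected


def _spike_waveform(fs: float, amp: float) -> np.ndarray:
    """Biphasic 5-ms transient."""
    n = max(int(round(0.005 * fs)), 4)
    t = np.linspace(0, 1, n)
    return amp * np.sin(2 * np.pi * t) * np.hanning(n)


def _welch_psd_fn(x: np.ndarray, fs: float) -> Callable[[np.ndarray], np.ndarray]:
    """Interpolable Welch PSD of a known component signal."""
    nper = min(len(x), int(2 * fs))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    return lambda q: np.interp(np.asarray(q, dtype=float), f, p)


def simulate_recording(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Assemble the full synthetic recording plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    hyp = simulate_hypnogram(config, rng)
    n_epochs = len(hyp)
    n = int(n_epochs * EPOCH_LEN * config.fs)
    fs = config.fs
    spe = int(EPOCH_LEN * fs)

    samples = np.empty((config.n_channels, n))
    all_spindles: list[tuple[int, float, float, float]] = []
    all_spikes: list[tuple[int, float]] = []

    for ch in range(config.n_channels):
        # stage-dependent content, epoch by epoch
        x = np.empty(n)
        for e, stage in enumerate(hyp.labels):
            x[e * spe : (e + 1) * spe] = synth_stage_signal(
                stage, spe, fs, rng, osc_amp=config.osc_amp
            )
        x, events = embed_spindles(x, hyp, config, rng, channel=ch)
        all_spindles.extend(events)

        # line noise with channel-specific phases
        t = np.arange(n) / fs
        for f0, amp in config.line_noise_amp.items():
            x += amp * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))

        # biphasic transients at 8x channel SD
        n_spikes = int(rng.poisson(config.spike_rate * (n / fs) / 60.0))
        wave = _spike_waveform(fs, 8.0 * float(np.std(x)))
        for _ in range(n_spikes):
            i0 = int(rng.integers(0, n - len(wave)))
            x[i0 : i0 + len(wave)] += wave
            all_spikes.append((ch, i0 / fs))

        samples[ch] = x

    # shared-source coupling with a closed-form expected coherence
    pair_msc: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for i, j, a in config.coupling_pairs:
        source = one_over_f_noise(n, fs, rng) * 1.5
        bg_i = samples[i].copy()
        bg_j = samples[j].copy()
        samples[i] = bg_i + source
        samples[j] = bg_j + a * source
        ps = _welch_psd_fn(source, fs)
        pi = _welch_psd_fn(bg_i, fs)
        pj = _welch_psd_fn(bg_j, fs)
        expected = ExpectedCoherence(a, ps, pi, pj)
        freqs = np.arange(1.0, 150.5, 0.5)
        pair_msc[(i, j)] = (freqs, expected(freqs))

    all_spindles.sort(key=lambda e: (e[0], e[1]))
    layout = None
    if config.n_channels == 64:
        layout = ElectrodeLayout.default_8x8()
    rec = Recording(
        samples=samples,
        fs=fs,
        channel_ids=tuple(f"ch{c:02d}" for c in range(config.n_channels)),
        layout=layout,
    )
    truth = GroundTruth(
        hypnogram=hyp,
        spindle_events=all_spindles,
        pair_coherence=pair_msc,
        motion_epochs=np.array([s == "WAKE" for s in hyp.labels]),
        spike_events=all_spikes,
    )
    return rec, truth


def simulate_motion_frames(
    hypnogram: Hypnogram,
    frame_size: tuple[int, int] = (64, 64),
    rng: np.random.Generator | None = None,
    noise_amp: float = 2.0,
    blob_intensity: float = 200.0,
) -> np.ndarray:
    """One grayscale frame per epoch; the blob moves only into WAKE epochs.

    Frame ``t`` differs from frame ``t-1`` by a blob displacement exactly when
    epoch ``t`` is WAKE; otherwise only pixel noise differs.
    """
    h, w = frame_size
    if h < 32 or w < 32:
        raise ValueError("frame_size must be at least 32x32")
    if rng is None:
        rng = np.random.default_rng(0)
    n_epochs = len(hypnogram)
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = min(h, w) / 12.0

    def blob(cy: float, cx: float) -> np.ndarray:
        return blob_intensity * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )

    margin = 4 * sigma
    cy = float(rng.uniform(margin, h - margin))
    cx = float(rng.uniform(margin, w - margin))
    frames = np.empty((n_epochs, h, w))
    for t in range(n_epochs):
        if t > 0 and hypnogram.labels[t] == "WAKE":
            # displace by at least 2 sigma so the frame difference is clear;
            # resample the direction if clipping at the margin eats the step
            for _ in range(100):
                step = rng.uniform(2 * sigma, 4 * sigma)
                ang = rng.uniform(0, 2 * np.pi)
                ny = float(np.clip(cy + step * np.sin(ang), margin, h - margin))
                nx = float(np.clip(cx + step * np.cos(ang), margin, w - margin))
                if np.hypot(ny - cy, nx - cx) >= 2 * sigma:
                    cy, cx = ny, nx
                    break
        frames[t] = blob(cy, cx) + noise_amp * rng.standard_normal((h, w))
    return frames
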