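"""Synthetic multi-channel extracellular recordings with known ground truth.

The generator emulates the signal regime of a 20 kHz, 9-bit multi-channel
recording front-end: Poisson trains of stereotyped 64-sample action-potential
templates, additive Gaussian background noise, and an optional spatially
correlated low-frequency (< 300 Hz) LFP component shared across channels.
Every random draw is controlled by a single seed so any fixture is exactly
reproducible.

Amplitudes are expressed in ADC counts.  With the modeled front-end's least
significant bit of ~3.9 uV, the default noise level of 3 counts corresponds
to ~12 uV RMS background and the default template peaks (80-130 counts) to
large, well-isolated units of a few hundred uV — a high-SNR but plausible
extracellular regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _sig

from .recording import Recording

__all__ = [
    "SpikeTemplate",
    "GeneratorConfig",
    "InsertedSpike",
    "default_templates",
    "generate_recording",
    "generate_lfp_pair",
    "generate_lfp_group",
]

WINDOW = 64  # samples per action-potential window


@dataclass(frozen=True)
class SpikeTemplate:
    """A stereotyped 64-sample action-potential waveform in ADC counts."""

    waveform: np.ndarray
    template_id: int

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=np.int64)
        if wf.shape != (WINDOW,):
            raise ValueError(f"template waveform must have exactly {WINDOW} samples")
        if np.abs(wf).max() == 0:
            raise ValueError("template peak amplitude must be nonzero")
        object.__setattr__(self, "waveform", wf)


@dataclass(frozen=True)
class InsertedSpike:
    """Ground-truth record of one inserted template occurrence."""

    channel: int
    onset: int  # sample index of the 64-sample window start
    template_id: int


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic recording generator.

    ``firing_rate_hz`` is either a scalar applied to every template or a
    sequence with one rate per template.  ``lfp_spatial_mixing`` in [0, 1]
    controls inter-channel LFP correlation: 0 gives independent channels,
    values near 1 give a nearly common LFP across the array.
    """

    n_channels: int = 1
    duration_s: float = 1.0
    firing_rate_hz: float | Sequence[float] = 60.0
    noise_sd: float = 3.0
    lfp_amplitude: float = 0.0
    lfp_spatial_mixing: float = 0.9
    seed: int = 0
    fs: float = 20_000.0
    bit_depth: int = 9
    refractory_s: float = 0.0  # per-template dead time after each onset

    def __post_init__(self) -> None:
        rates = np.atleast_1d(np.asarray(self.firing_rate_hz, dtype=float))
        if np.any(rates < 0):
            raise ValueError("firing rates must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.lfp_spatial_mixing <= 1.0:
            raise ValueError("lfp_spatial_mixing must lie in [0, 1]")
        if not 2 <= self.bit_depth <= 16:
            raise ValueError(f"invalid bit depth {self.bit_depth}")
        if self.n_channels < 1 or self.duration_s < 0 or self.fs <= 0:
            raise ValueError("n_channels must be >= 1, duration_s >= 0, fs > 0")


def _biphasic(peak: float, width: float, ahp_frac: float, peak_idx: int = 36) -> np.ndarray:
    """Gaussian depolarization plus slower opposite-sign after-wave.

    The main deflection is placed at ``peak_idx`` so that the steep edge
    falls near sample 32 of the window, mirroring the 32-sample pre-buffer
    of the detection/compression chain.
    """
    t = np.arange(WINDOW, dtype=float)
    main = peak * np.exp(-((t - peak_idx) ** 2) / (2.0 * width**2))
    ahp = -peak * ahp_frac * np.exp(-((t - peak_idx - 2.5 * width) ** 2) / (2.0 * (2.2 * width) ** 2))
    wave = main + ahp
    # taper so the window starts and ends at baseline
    edge = np.minimum(t / 6.0, (WINDOW - 1 - t) / 6.0)
    wave *= np.clip(edge, 0.0, 1.0)
    return np.round(wave).astype(np.int64)


def default_templates(n: int = 3) -> list[SpikeTemplate]:
    """Up to five stock templates with distinct amplitude, width and polarity."""
    params = [
        (-110.0, 2.2, 0.30),
        (-80.0, 3.2, 0.45),
        (95.0, 2.6, 0.35),
        (-130.0, 1.8, 0.25),
        (70.0, 4.0, 0.50),
    ]
    if not 1 <= n <= len(params):
        raise ValueError(f"n must be in [1, {len(params)}]")
    return [
        SpikeTemplate(waveform=_biphasic(p, w, a), template_id=i)
        for i, (p, w, a) in enumerate(params[:n])
    ]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float = 300.0) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed below ``cutoff_hz``."""
    white = rng.standard_normal(n + 200)
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        out = white[200:]
    else:
        b, a = _sig.butter(4, cutoff_hz / nyq)
        out = _sig.lfilter(b, a, white)[200:]
    sd = out.std()
    return out / sd if sd > 0 else out


def _poisson_onsets(
    rng: np.random.Generator, rate_hz: float, n_samples: int, fs: float, refractory: int
) -> np.ndarray:
    """Poisson onset times (sample indices) leaving room for a full window."""
    horizon = n_samples - WINDOW
    if rate_hz <= 0 or horizon <= 0:
        return np.empty(0, dtype=np.int64)
    count = rng.poisson(rate_hz * n_samples / fs)
    onsets = np.sort(rng.integers(0, horizon + 1, size=count))
    if refractory > 0 and onsets.size:
        keep = [int(onsets[0])]
        for t in onsets[1:]:
            if t - keep[-1] >= refractory:
                keep.append(int(t))
        onsets = np.asarray(keep, dtype=np.int64)
    return onsets.astype(np.int64)


def generate_recording(
    config: GeneratorConfig, templates: Sequence[SpikeTemplate] | None = None
) -> tuple[Recording, list[InsertedSpike]]:
    """Generate a recording plus the exact list of inserted spikes.

    The recording is the sum of (a) Poisson-placed template waveforms per
    channel, (b) white Gaussian noise of ``noise_sd`` counts, and (c) the
    spatially mixed LFP component, rounded and clipped to the signed
    ``bit_depth`` range.  Identical config (including seed) gives
    bit-identical output.
    """
    rates = np.atleast_1d(np.asarray(config.firing_rate_hz, dtype=float))
    if templates is None:
        templates = default_templates(len(rates)) if rates.max(initial=0.0) > 0 else []
    if rates.size == 1 and len(templates) > 1:
        rates = np.full(len(templates), rates[0])
    if np.any(rates > 0) and len(templates) == 0:
        raise ValueError("templates required when any firing rate is positive")
    if len(templates) and rates.size != len(templates):
        raise ValueError("need one firing rate per template")

    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    data = np.zeros((config.n_channels, n), dtype=float)
    ground_truth: list[InsertedSpike] = []
    refractory = int(round(config.refractory_s * config.fs))

    for ch in range(config.n_channels):
        for tmpl, rate in zip(templates, rates):
            for onset in _poisson_onsets(rng, float(rate), n, config.fs, refractory):
                data[ch, onset : onset + WINDOW] += tmpl.waveform
                ground_truth.append(InsertedSpike(channel=ch, onset=int(onset), template_id=tmpl.template_id))

    if config.noise_sd > 0 and n > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)

    if config.lfp_amplitude > 0 and n > 0:
        raw = np.stack([_bandlimited_noise(rng, n, config.fs) for _ in range(config.n_channels)])
        m = config.lfp_spatial_mixing
        idx = np.arange(config.n_channels)
        weights = m ** np.abs(idx[:, None] - idx[None, :])
        weights /= np.sqrt((weights**2).sum(axis=1, keepdims=True))  # keep unit variance
        data += config.lfp_amplitude * (weights @ raw)

    lo, hi = -(1 << (config.bit_depth - 1)), (1 << (config.bit_depth - 1)) - 1
    samples = np.clip(np.round(data), lo, hi).astype(np.int16)
    ground_truth.sort(key=lambda ev: (ev.channel, ev.onset, ev.template_id))
    rec = Recording(samples=samples, fs=config.fs, bit_depth=config.bit_depth)
    return rec, ground_truth


def generate_lfp_pair(
    n: int,
    gamma_true: float,
    seed: int,
    *,
    parent_sd: float = 60.0,
    noise_sd: float = 1.0,
    fs: float = 20_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Parent/child series pair with a planted spatial-decorrelation factor.

    ``child = gamma_true * parent + noise``, both quantized to integer ADC
    counts; intended for recovery tests of the closed-form gamma estimator.
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    rng = np.random.default_rng(seed)
    parent = parent_sd * _bandlimited_noise(rng, n, fs)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    child = gamma_true * parent + noise
    return np.round(parent).astype(np.int64), np.round(child).astype(np.int64)


def generate_lfp_group(
    n_channels: int,
    n: int,
    mixing: float,
    seed: int,
    *,
    amplitude: float = 40.0,
    noise_sd: float = 1.0,
    fs: float = 20_000.0,
    bit_depth: int = 9,
) -> Recording:
    """Spatially correlated LFP-only recording for the cross-channel codec."""
    cfg = GeneratorConfig(
        n_channels=n_channels,
        duration_s=n / fs,
        firing_rate_hz=0.0,
        noise_sd=noise_sd,
        lfp_amplitude=amplitude,
        lfp_spatial_mixing=mixing,
        seed=seed,
        fs=fs,
        bit_depth=bit_depth,
    )
    rec, _ = generate_recording(cfg, templates=[])
    return rec
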