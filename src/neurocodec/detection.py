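"""Two-stage spike detection with an adaptive threshold estimator.

Stage 1 flags samples whose absolute amplitude exceeds an adaptive amplitude
threshold; stage 2 confirms a spike only where the absolute output of the
nonlinear energy operator (NEO),

    psi[n] = x(n)^2 - x(n-1) * x(n+1),

exceeds a dynamically estimated threshold.  The adaptive threshold estimator
(ATE) re-estimates both thresholds once per 64-sample window from two
statistics of the NEO output: a zero-crossing count (a firing-rate proxy,
log2-compressed) and a low-pass noise-level estimate.  A confirmed detection
emits a 64-sample spike window with 32 pre- and 32 post-samples around the
detection index, with a 64-sample refractory lockout per channel.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import Recording

__all__ = [
    "AteConfig",
    "ThresholdState",
    "SpikeEvent",
    "neo",
    "zero_crossing_log_rate",
    "noise_estimate",
    "compute_threshold",
    "detect_spikes",
    "events_to_csv",
]

WINDOW = 64
PRE_SAMPLES = 32


@dataclass(frozen=True)
class SpikeEvent:
    """One detected (or ground-truth-framed) action potential.

    ``waveform`` is exactly the 64 recording samples in
    ``[onset, onset + 64)``; ``detect_index`` is the sample at which the
    detector fired, 32 samples into the window.
    """

    channel: int
    onset: int
    waveform: np.ndarray
    detect_index: int

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=np.int64)
        if wf.shape != (WINDOW,):
            raise ValueError(f"waveform must have exactly {WINDOW} samples")
        if not self.onset <= self.detect_index < self.onset + WINDOW:
            raise ValueError("detect_index must fall inside the event window")
        object.__setattr__(self, "waveform", wf)


@dataclass
class AteConfig:
    """Tunables of the adaptive threshold estimator.

    ``k_neo``/``k_amp`` are the noise multipliers of the NEO and amplitude
    thresholds; ``beta`` scales the log2 firing-rate term; ``alpha`` is the
    per-sample smoothing factor of the noise estimators.  The noise-estimator
    input is clipped at ``clip_factor`` times the current estimate (floored
    at ``clip_floor``) so that spike-dominated excursions are attenuated
    rather than averaged in.
    """

    window_len: int = WINDOW
    alpha: float = 1.0 / 64.0
    k_neo: float = 8.0
    beta: float = 0.125
    floor: float = 1.0
    k_amp: float = 5.0
    amp_floor: float = 1.0
    clip_factor: float = 4.0
    clip_floor: float = 16.0
    amp_clip_floor: float = 4.0
    warmup_windows: int = 2


@dataclass
class ThresholdState:
    """Running ATE state, updated once per window."""

    noise_level: float = 0.0
    zc_count: int = 0
    log_rate: int = 0
    threshold: float = 1.0
    window_len: int = WINDOW


def neo(x: np.ndarray) -> np.ndarray:
    """NEO series psi[n] = x(n)^2 - x(n-1)*x(n+1) for interior samples.

    Returns an array of length ``len(x) - 2`` aligned to input indices
    ``1 .. n-2`` (empty for inputs shorter than 3); exact integer arithmetic.
    """
    x = np.asarray(x, dtype=np.int64)
    if x.size < 3:
        return np.empty(0, dtype=np.int64)
    return x[1:-1] * x[1:-1] - x[:-2] * x[2:]


def _neo_full(x: np.ndarray) -> np.ndarray:
    """NEO padded with zeros at both ends, aligned to the input indices."""
    out = np.zeros(len(x), dtype=np.int64)
    if len(x) >= 3:
        out[1:-1] = neo(x)
    return out


def zero_crossing_log_rate(psi_window: np.ndarray) -> tuple[int, int]:
    """Count sign-bit changes between adjacent samples, plus its log2 proxy.

    Zero counts as positive (two's-complement sign-bit convention);
    ``log_rate = floor(log2(zc_count + 1))``.
    """
    w = np.asarray(psi_window)
    if w.size == 0:
        raise ValueError("window must be non-empty")
    sign_bits = (w < 0).astype(np.int8)
    zc = int(np.count_nonzero(np.diff(sign_bits)))
    return zc, int(math.floor(math.log2(zc + 1)))


def noise_estimate(psi_window: np.ndarray, state: ThresholdState, config: AteConfig | None = None) -> float:
    """Update the low-pass noise level with one window of |psi| samples.

    Single-pole exponential smoothing with per-sample factor ``alpha``;
    each input is clipped at ``max(clip_factor * level, clip_floor)`` so a
    spike transient perturbs the estimate only marginally while a sustained
    level change is still tracked (the clip bound grows with the estimate).
    """
    cfg = config or AteConfig()
    level = state.noise_level
    for v in np.abs(np.asarray(psi_window, dtype=float)):
        bound = max(cfg.clip_factor * level, cfg.clip_floor)
        level += cfg.alpha * (min(v, bound) - level)
    state.noise_level = level
    return level


def compute_threshold(noise_level: float, log_rate: int, k: float, *, beta: float = 0.125, floor: float = 1.0) -> float:
    """Threshold = max(floor, k * noise_level * (1 + beta * log_rate)).

    Monotone nondecreasing in both the noise level and the firing-rate
    proxy; reduces to the classic ``k * noise`` scaling at low rates.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be nonnegative")
    return max(floor, k * noise_level * (1.0 + beta * log_rate))


def detect_spikes(rec: Recording, channel: int, ate_config: AteConfig | None = None) -> list[SpikeEvent]:
    """Run the two-stage detector on one channel.

    Thresholds are re-estimated every ``window_len`` samples and applied
    causally to the following window; the first ``warmup_windows`` windows
    only train the estimator.  A detection requires both
    ``|x| > amplitude threshold`` (stage 1) and ``|psi| > NEO threshold``
    (stage 2), needs full 32-sample context on both sides, and imposes a
    64-sample lockout.
    """
    cfg = ate_config or AteConfig()
    x = rec.channel(channel).astype(np.int64)
    n = x.size
    psi = _neo_full(x)
    abs_x = np.abs(x)
    abs_psi = np.abs(psi)

    neo_state = ThresholdState(window_len=cfg.window_len)
    amp_state = ThresholdState(window_len=cfg.window_len)
    neo_thr = math.inf
    amp_thr = math.inf

    events: list[SpikeEvent] = []
    next_allowed = PRE_SAMPLES
    wlen = cfg.window_len
    for w, start in enumerate(range(0, n, wlen)):
        end = min(start + wlen, n)
        if w >= cfg.warmup_windows:
            lo = max(start, next_allowed)
            for i in range(lo, end):
                if i + PRE_SAMPLES > n or i < next_allowed:
                    continue
                if abs_x[i] > amp_thr and abs_psi[i] > neo_thr:
                    onset = i - PRE_SAMPLES
                    events.append(
                        SpikeEvent(channel=channel, onset=onset, waveform=x[onset : onset + WINDOW], detect_index=i)
                    )
                    next_allowed = i + WINDOW
        # update estimators with the window just scanned, then re-threshold
        zc, log_rate = zero_crossing_log_rate(psi[start:end])
        neo_state.zc_count, neo_state.log_rate = zc, log_rate
        noise_estimate(psi[start:end], neo_state, cfg)
        amp_cfg = AteConfig(alpha=cfg.alpha, clip_factor=cfg.clip_factor, clip_floor=cfg.amp_clip_floor)
        noise_estimate(x[start:end], amp_state, amp_cfg)
        neo_thr = compute_threshold(neo_state.noise_level, log_rate, cfg.k_neo, beta=cfg.beta, floor=cfg.floor)
        neo_state.threshold = neo_thr
        amp_thr = compute_threshold(amp_state.noise_level, log_rate, cfg.k_amp, beta=cfg.beta, floor=cfg.amp_floor)
        amp_state.threshold = amp_thr
    return events


def events_to_csv(events: list[SpikeEvent], path: str | Path) -> None:
    """Write events as CSV with columns channel, onset_sample, detect_sample."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "onset_sample", "detect_sample"])
        for ev in events:
            writer.writerow([ev.channel, ev.onset, ev.detect_index])
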