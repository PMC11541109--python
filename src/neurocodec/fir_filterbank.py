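"""Bit-accurate model of a 16-channel, order-15 fixed-point FIR filterbank.

Each tap computes ``y[n] = sum_{i=0..15} c_i * x[n-i]`` with 16-bit signed
coefficients and a 26-bit signed accumulator: the final sum saturates at
``[-2^25, 2^25 - 1]``.  Missing pre-history is treated as zeros.  Saturation
is applied to the final accumulated sum only, so below saturation the filter
agrees exactly with a plain integer convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .recording import Recording

__all__ = ["FirCoeffs", "fir_filter", "filterbank", "ACC_MIN", "ACC_MAX"]

N_TAPS = 16
COEFF_MIN, COEFF_MAX = -(1 << 15), (1 << 15) - 1
ACC_MIN, ACC_MAX = -(1 << 25), (1 << 25) - 1
MAX_CHANNELS = 16


@dataclass(frozen=True)
class FirCoeffs:
    """Exactly 16 signed 16-bit integer filter coefficients c_0 .. c_15."""

    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.int64)
        if c.shape != (N_TAPS,):
            raise ValueError(f"need exactly {N_TAPS} coefficients, got shape {c.shape}")
        if c.min() < COEFF_MIN or c.max() > COEFF_MAX:
            raise ValueError(f"coefficients must lie in [{COEFF_MIN}, {COEFF_MAX}]")
        object.__setattr__(self, "c", c)

    @classmethod
    def identity(cls) -> "FirCoeffs":
        c = np.zeros(N_TAPS, dtype=np.int64)
        c[0] = 1
        return cls(c)

    @classmethod
    def from_file(cls, path: str | Path) -> "list[FirCoeffs]":
        """Load per-channel coefficient rows from a JSON or CSV file."""
        path = Path(path)
        if path.suffix == ".json":
            rows = json.loads(path.read_text())
        else:
            rows = [
                [int(v) for v in line.split(",")]
                for line in path.read_text().strip().splitlines()
                if line.strip()
            ]
        return [cls(np.asarray(row)) for row in rows]


def fir_filter(x: np.ndarray, coeffs: FirCoeffs) -> np.ndarray:
    """Filter one sample series through the fixed-point FIR tap.

    Exact integer convolution followed by saturation of each output sample
    to the 26-bit accumulator range.
    """
    x = np.asarray(x, dtype=np.int64)
    if x.size == 0:
        return x.copy()
    acc = np.convolve(x, coeffs.c)[: x.size]
    return np.clip(acc, ACC_MIN, ACC_MAX)


def filterbank(
    rec: Recording,
    coeffs: Sequence[FirCoeffs] | FirCoeffs,
    channels: Sequence[int] | None = None,
) -> Recording:
    """Apply per-channel FIR taps to up to 16 channels of a recording.

    ``coeffs`` is either a single tap shared by all selected channels or a
    sequence with one tap per selected channel.  Output samples occupy the
    26-bit accumulator range and keep the input length.
    """
    ids = list(rec.channel_ids) if channels is None else list(channels)
    if len(ids) > MAX_CHANNELS:
        raise ValueError(f"filterbank handles at most {MAX_CHANNELS} channels, got {len(ids)}")
    if isinstance(coeffs, FirCoeffs):
        coeffs = [coeffs] * len(ids)
    if len(coeffs) != len(ids):
        raise ValueError("need one coefficient set per selected channel")
    out = np.stack([fir_filter(rec.channel(cid), c) for cid, c in zip(ids, coeffs)])
    return Recording(samples=out, fs=rec.fs, bit_depth=26, channel_ids=np.asarray(ids))
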