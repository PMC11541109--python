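"""Multi-channel integer recording container and its on-disk format.

A :class:`Recording` is the universal input of every engine in this package:
an integer sample matrix (channels x time) in ADC counts, together with the
sampling rate and the ADC bit depth.  Samples are stored as ``int16`` but are
constrained to the signed range of ``bit_depth`` bits (9 bits for the
front-end modeled here, i.e. [-256, 255]).

On disk a recording is a flat little-endian ``int16`` payload, interleaved by
sample (frame-major: ``s[ch0,t0], s[ch1,t0], ..., s[ch0,t1], ...``), plus a
JSON sidecar carrying ``n_channels``, ``fs_hz``, ``bit_depth``, ``dtype``,
``byte_order`` and ``channel_ids``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Recording", "write_recording", "read_recording", "FormatError"]


class FormatError(ValueError):
    """Raised for a malformed or inconsistent recording file pair."""


def _signed_range(bit_depth: int) -> tuple[int, int]:
    return -(1 << (bit_depth - 1)), (1 << (bit_depth - 1)) - 1


@dataclass
class Recording:
    """Integer sample matrix with sampling metadata.

    Parameters
    ----------
    samples
        Integer array of shape ``(n_channels, n_samples)`` in ADC counts.
    fs
        Sampling frequency in Hz; must be positive.
    bit_depth
        Bits per sample; every sample must lie in the signed
        ``bit_depth``-bit range.
    channel_ids
        Ordered channel indices; defaults to ``0..n_channels-1``.
    """

    samples: np.ndarray
    fs: float
    bit_depth: int = 9
    channel_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if not 2 <= self.bit_depth <= 32:
            raise ValueError(f"bit_depth must be in [2, 32], got {self.bit_depth}")
        dtype = np.int16 if self.bit_depth <= 16 else np.int32
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=dtype))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        lo, hi = _signed_range(self.bit_depth)
        if self.samples.size and (self.samples.min() < lo or self.samples.max() > hi):
            raise ValueError(
                f"samples exceed the signed {self.bit_depth}-bit range [{lo}, {hi}]"
            )
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.samples.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
            if self.channel_ids.shape != (self.samples.shape[0],):
                raise ValueError("channel_ids length must match the channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: int) -> np.ndarray:
        """Samples of one channel, looked up by channel id."""
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise KeyError(f"unknown channel id {channel_id}")
        return self.samples[idx[0]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.bit_depth == other.bit_depth
            and np.array_equal(self.channel_ids, other.channel_ids)
            and np.array_equal(self.samples, other.samples)
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as raw ``.bin`` payload plus ``.json`` sidecar."""
    path = Path(path)
    wire = "<i2" if rec.bit_depth <= 16 else "<i4"
    payload = np.ascontiguousarray(rec.samples.T, dtype=wire)  # frame-major
    path.write_bytes(payload.tobytes())
    meta = {
        "n_channels": int(rec.n_channels),
        "fs_hz": float(rec.fs),
        "bit_depth": int(rec.bit_depth),
        "dtype": "int16" if rec.bit_depth <= 16 else "int32",
        "byte_order": "little",
        "channel_ids": [int(c) for c in rec.channel_ids],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    FormatError
        If the sidecar is missing or the payload length is inconsistent
        with the declared channel count.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        n_channels = int(meta["n_channels"])
        fs = float(meta["fs_hz"])
        bit_depth = int(meta["bit_depth"])
        channel_ids = meta["channel_ids"]
    except KeyError as exc:
        raise FormatError(f"sidecar {sidecar} lacks required key {exc}") from exc
    dtype_name = meta.get("dtype", "int16")
    wire = {"int16": "<i2", "int32": "<i4"}.get(dtype_name)
    if wire is None:
        raise FormatError(f"unsupported payload dtype {dtype_name!r}")
    itemsize = 2 if wire == "<i2" else 4
    raw = path.read_bytes()
    if len(raw) % itemsize != 0:
        raise FormatError(f"payload length is not a whole number of {dtype_name} samples")
    flat = np.frombuffer(raw, dtype=wire)
    if n_channels <= 0 or flat.size % n_channels != 0:
        raise FormatError(
            f"payload of {flat.size} samples is not divisible by {n_channels} channels"
        )
    samples = flat.reshape(-1, n_channels).T
    return Recording(samples=samples, fs=fs, bit_depth=bit_depth, channel_ids=np.asarray(channel_ids))
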