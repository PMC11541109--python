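"""Intra-channel action-potential compression engine (lossless / near-lossless).

The encoding chain mirrors a per-channel hardware compression engine:

* **DPCM2** second-order temporal decorrelation,
  ``r(i) = s(i) - 2 s(i-1) + s(i-2)``, which concentrates the sample
  distribution around zero;
* **zigzag mapping** of signed residuals to naturals
  (0, -1, 1, -2, 2, ... -> 0, 1, 2, 3, 4, ...), since the back-end coders
  want small non-negative inputs;
* one of two entropy back ends: **Golomb/Rice coding** with a zero-fraction
  driven adaptation of the Rice parameter, or **semi-adaptive arithmetic
  coding** against a trained, shared symbol table that fits a 2 KiB budget;
* in **near-lossless** mode, a run-length framing stage: everything between
  detected spikes is treated as zero, and the stream becomes alternating
  (zero-run length, 64-sample spike) frames whose run length is split
  bitwise into 2 or 3 one-byte components.  Spike waveforms and spike
  timing reconstruct exactly; inter-spike samples decode to zero.

Both back ends are bit-exact: ``decompress(compress(x))`` recovers the
input exactly in lossless mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._bitio import BitReader, BitstreamError, BitWriter
from .detection import SpikeEvent
from .recording import Recording

__all__ = [
    "ResidualStream",
    "SymbolTable",
    "Bitstream",
    "NllFrame",
    "dpcm2_encode",
    "dpcm2_decode",
    "map_to_nonneg",
    "map_from_nonneg",
    "golomb_encode",
    "golomb_decode",
    "adapt_rice_parameter",
    "train_symbol_table",
    "ac_encode",
    "ac_decode",
    "compress_channel",
    "decompress_channel",
    "ssr",
]

WINDOW = 64
RLE_COMPONENT_BITS = 8  # width w of each bitwise run-length component
RICE_ADAPT_WINDOW = 256
RICE_K_MAX = 7
AC_ALPHABET = 1024  # explicit symbols 0..1023; index 1024 is the escape
AC_ESCAPE = AC_ALPHABET
AC_LITERAL_BITS = 12
TABLE_BYTE_BUDGET = 2048


# ---------------------------------------------------------------------------
# DPCM2 and data mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidualStream:
    """DPCM2 output: two warm-up samples plus second-difference residuals."""

    warmup: tuple[int, int]
    residuals: np.ndarray

    def __len__(self) -> int:
        return 2 + len(self.residuals)


def dpcm2_encode(s: np.ndarray) -> ResidualStream:
    """Second-order DPCM: r(i) = s(i) - 2 s(i-1) + s(i-2) for i >= 2."""
    s = np.asarray(s, dtype=np.int64)
    if s.size < 2:
        raise ValueError("DPCM2 needs at least 2 samples")
    residuals = s[2:] - 2 * s[1:-1] + s[:-2]
    return ResidualStream(warmup=(int(s[0]), int(s[1])), residuals=residuals)


def dpcm2_decode(r: ResidualStream) -> np.ndarray:
    """Exact inverse of :func:`dpcm2_encode` (double cumulative sum)."""
    n = len(r)
    out = np.empty(n, dtype=np.int64)
    out[0], out[1] = r.warmup
    if n > 2:
        # s(i) = r(i) + 2 s(i-1) - s(i-2); equivalent to two cumsums
        first_diff = np.empty(n - 1, dtype=np.int64)
        first_diff[0] = r.warmup[1] - r.warmup[0]
        np.cumsum(r.residuals, out=first_diff[1:])
        first_diff[1:] += first_diff[0]
        out[1:] = r.warmup[0] + np.cumsum(first_diff)
    return out


def map_to_nonneg(v: int | np.ndarray) -> int | np.ndarray:
    """Zigzag interleave: 0->0, -1->1, 1->2, -2->3, 2->4, ..."""
    v = np.asarray(v, dtype=np.int64)
    out = np.where(v > 0, 2 * v, -2 * v - 1)
    out = np.where(v == 0, 0, out)
    return int(out) if out.ndim == 0 else out


def map_from_nonneg(u: int | np.ndarray) -> int | np.ndarray:
    """Inverse zigzag."""
    u = np.asarray(u, dtype=np.int64)
    out = np.where(u % 2 == 0, u // 2, -(u + 1) // 2)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Bitstream container
# ---------------------------------------------------------------------------

_MODES = ("raw", "lossless", "near_lossless")
_BACKENDS = ("gc", "ac")
HEADER_BITS = 48  # 1 byte mode/backend + 1 byte channel + 4 bytes sample count


@dataclass
class Bitstream:
    """Entropy-coded payload plus framing header."""

    payload: bytes
    payload_bits: int
    mode: str = "raw"
    backend: str = "gc"
    channel: int = 0
    n_samples: int = 0
    bit_depth: int = 9
    n_frames: int = 0
    rice_k: int = 0  # fixed Rice parameter for mode="raw" streams

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.backend not in _BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def header_bits(self) -> int:
        return HEADER_BITS

    @property
    def total_bits(self) -> int:
        return self.payload_bits + self.header_bits

    def to_bytes(self) -> bytes:
        """File container: fixed header then the payload bytes."""
        head = bytes(
            [
                _MODES.index(self.mode) | (_BACKENDS.index(self.backend) << 4),
                self.channel & 0xFF,
            ]
        )
        head += int(self.n_samples).to_bytes(4, "little")
        head += bytes([self.bit_depth, self.rice_k])
        head += int(self.n_frames).to_bytes(4, "little")
        head += int(self.payload_bits).to_bytes(4, "little")
        return head + self.payload

    @classmethod
    def from_bytes(cls, blob: bytes) -> "Bitstream":
        if len(blob) < 16:
            raise BitstreamError("truncated bitstream container")
        mode_backend = blob[0]
        payload_bits = int.from_bytes(blob[12:16], "little")
        payload = blob[16:]
        if len(payload) * 8 < payload_bits:
            raise BitstreamError("payload shorter than declared bit length")
        return cls(
            payload=payload,
            payload_bits=payload_bits,
            mode=_MODES[mode_backend & 0xF],
            backend=_BACKENDS[mode_backend >> 4],
            channel=blob[1],
            n_samples=int.from_bytes(blob[2:6], "little"),
            bit_depth=blob[6],
            rice_k=blob[7],
            n_frames=int.from_bytes(blob[8:12], "little"),
        )


# ---------------------------------------------------------------------------
# Golomb/Rice back end
# ---------------------------------------------------------------------------


def golomb_encode(values: Sequence[int] | np.ndarray, k: int) -> Bitstream:
    """Rice code (M = 2^k): quotient in unary, remainder in ``k`` bits."""
    if not 0 <= k <= 31:
        raise ValueError("Rice parameter k must be in [0, 31]")
    w = BitWriter()
    for v in np.asarray(values, dtype=np.int64):
        if v < 0:
            raise ValueError("Rice coding requires non-negative values")
        _rice_write(w, int(v), k)
    return Bitstream(payload=w.getvalue(), payload_bits=w.bit_length, mode="raw", backend="gc", rice_k=k)


def golomb_decode(bits: Bitstream | bytes, k: int, n: int | None = None) -> np.ndarray:
    """Decode Rice-coded values; reads to end of stream unless ``n`` given."""
    if isinstance(bits, Bitstream):
        reader = BitReader(bits.payload, bits.payload_bits)
    else:
        reader = BitReader(bits)
    out = []
    while reader.bits_left > 0 if n is None else len(out) < n:
        out.append(_rice_read(reader, k))
    return np.asarray(out, dtype=np.int64)


def _rice_write(w: BitWriter, v: int, k: int) -> None:
    w.write_unary(v >> k)
    if k:
        w.write_bits(v & ((1 << k) - 1), k)


def _rice_read(r: BitReader, k: int) -> int:
    q = r.read_unary()
    return (q << k) | (r.read_bits(k) if k else 0)


def adapt_rice_parameter(zero_fraction: float) -> int:
    """Monotone map from the running zero-sample proportion to the Rice k.

    A peakier distribution (more zeros) calls for a smaller divisor; the
    mapping targets the mean ``(1 - zf) / zf`` of a geometric source whose
    zero probability is ``zf`` and rounds its log2, clipped to [0, 7].
    """
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must lie in [0, 1]")
    if zero_fraction >= 1.0:
        return 0
    if zero_fraction <= 0.0:
        return RICE_K_MAX
    mean = (1.0 - zero_fraction) / zero_fraction
    if mean <= 0.75:
        return 0
    return int(np.clip(round(np.log2(mean)), 0, RICE_K_MAX))


class _RiceAdapter:
    """Causal zero-fraction tracker shared bit-exactly by encoder and decoder.

    ``k`` is re-derived every :data:`RICE_ADAPT_WINDOW` values from the
    zero fraction over all values seen so far; the first block uses the
    configurable initial k.
    """

    def __init__(self, k_init: int = 4) -> None:
        self.k = k_init
        self._zeros = 0
        self._count = 0

    def update(self, value: int) -> None:
        self._zeros += value == 0
        self._count += 1
        if self._count % RICE_ADAPT_WINDOW == 0:
            self.k = adapt_rice_parameter(self._zeros / self._count)


# ---------------------------------------------------------------------------
# Arithmetic-coding back end
# ---------------------------------------------------------------------------


@dataclass
class SymbolTable:
    """Trained, quantized symbol frequencies for the arithmetic coder.

    ``counts`` holds one count (>= 1) per explicit mapped-residual symbol
    0..1023; the escape symbol's count is implicitly 1 and is not stored, so
    the serialized table is exactly 1024 uint16 = 2048 bytes.
    """

    counts: np.ndarray

    cum: np.ndarray = field(init=False, repr=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (AC_ALPHABET,):
            raise ValueError(f"table must have exactly {AC_ALPHABET} counts")
        if counts.min() < 1 or counts.max() > 0xFFFF:
            raise ValueError("counts must lie in [1, 65535]")
        self.counts = counts
        full = np.append(counts, 1)  # implicit escape count
        self.cum = np.concatenate(([0], np.cumsum(full)))
        self.total = int(self.cum[-1])

    def serialize(self) -> bytes:
        blob = self.counts.astype("<u2").tobytes()
        assert len(blob) <= TABLE_BYTE_BUDGET
        return blob

    @classmethod
    def deserialize(cls, blob: bytes) -> "SymbolTable":
        if len(blob) != TABLE_BYTE_BUDGET:
            raise ValueError(f"expected exactly {TABLE_BYTE_BUDGET} bytes")
        return cls(counts=np.frombuffer(blob, dtype="<u2").astype(np.int64))


# fixed 50/50 model used for frame flags and escape-literal bits
_BINARY_CUM = np.array([0, 1, 2], dtype=np.int64)

_TOTAL_TARGET = 1 << 16  # quantized count mass of a trained table


def train_symbol_table(residual_streams: Iterable[np.ndarray | ResidualStream]) -> SymbolTable:
    """Histogram mapped residuals from one or more channels into a table.

    Counts are scaled to a fixed total mass, floored at 1 per symbol so no
    alphabet member gets probability zero, and fit the 2 KiB budget by
    construction.  Deterministic for fixed input.
    """
    hist = np.zeros(AC_ALPHABET, dtype=np.int64)
    n_seen = 0
    for stream in residual_streams:
        if isinstance(stream, ResidualStream):
            values = map_to_nonneg(np.concatenate(([stream.warmup[0], stream.warmup[1]], stream.residuals)))
        else:
            arr = np.asarray(stream, dtype=np.int64)
            values = map_to_nonneg(arr) if arr.size and arr.min() < 0 else arr
        values = np.asarray(values, dtype=np.int64)
        n_seen += values.size
        in_range = values[(values >= 0) & (values < AC_ALPHABET)]
        hist += np.bincount(in_range, minlength=AC_ALPHABET)
    if n_seen < 1000:
        raise ValueError(f"need at least 1000 residuals to train a table, got {n_seen}")
    scale = (_TOTAL_TARGET - AC_ALPHABET) / max(1, hist.sum())
    counts = np.maximum(1, np.floor(hist * scale).astype(np.int64))
    return SymbolTable(counts=np.minimum(counts, 0xFFFF))


class _ArithmeticEncoder:
    """Integer arithmetic coder, 32-bit state with pending-bit carry handling."""

    _HALF = 1 << 31
    _QUARTER = 1 << 30
    _MASK = (1 << 32) - 1

    def __init__(self, writer: BitWriter) -> None:
        self._w = writer
        self._low = 0
        self._high = self._MASK
        self._pending = 0

    def _emit(self, bit: int) -> None:
        self._w.write_bit(bit)
        inv = bit ^ 1
        for _ in range(self._pending):
            self._w.write_bit(inv)
        self._pending = 0

    def encode(self, cum: np.ndarray, total: int, sym: int) -> None:
        span = self._high - self._low + 1
        self._high = self._low + (span * int(cum[sym + 1])) // total - 1
        self._low = self._low + (span * int(cum[sym])) // total
        while True:
            if self._high < self._HALF:
                self._emit(0)
            elif self._low >= self._HALF:
                self._emit(1)
                self._low -= self._HALF
                self._high -= self._HALF
            elif self._low >= self._QUARTER and self._high < 3 * self._QUARTER:
                self._pending += 1
                self._low -= self._QUARTER
                self._high -= self._QUARTER
            else:
                break
            self._low = (self._low << 1) & self._MASK
            self._high = ((self._high << 1) | 1) & self._MASK

    def encode_bits(self, value: int, width: int) -> None:
        for shift in range(width - 1, -1, -1):
            self.encode(_BINARY_CUM, 2, (value >> shift) & 1)

    def finish(self) -> None:
        self._pending += 1
        self._emit(0 if self._low < self._QUARTER else 1)


class _ArithmeticDecoder:
    _HALF = 1 << 31
    _QUARTER = 1 << 30
    _MASK = (1 << 32) - 1

    def __init__(self, reader: BitReader) -> None:
        self._r = reader
        self._low = 0
        self._high = self._MASK
        self._value = 0
        for _ in range(32):
            self._value = (self._value << 1) | self._next_bit()

    def _next_bit(self) -> int:
        return self._r.read_bit() if self._r.bits_left > 0 else 0

    def decode(self, cum: np.ndarray, total: int) -> int:
        span = self._high - self._low + 1
        scaled = ((self._value - self._low + 1) * total - 1) // span
        sym = int(np.searchsorted(cum, scaled, side="right")) - 1
        self._high = self._low + (span * int(cum[sym + 1])) // total - 1
        self._low = self._low + (span * int(cum[sym])) // total
        while True:
            if self._high < self._HALF:
                pass
            elif self._low >= self._HALF:
                self._low -= self._HALF
                self._high -= self._HALF
                self._value -= self._HALF
            elif self._low >= self._QUARTER and self._high < 3 * self._QUARTER:
                self._low -= self._QUARTER
                self._high -= self._QUARTER
                self._value -= self._QUARTER
            else:
                break
            self._low = (self._low << 1) & self._MASK
            self._high = ((self._high << 1) | 1) & self._MASK
            self._value = ((self._value << 1) | self._next_bit()) & self._MASK
        return sym

    def decode_bits(self, width: int) -> int:
        value = 0
        for _ in range(width):
            value = (value << 1) | self.decode(_BINARY_CUM, 2)
        return value


def _ac_put(enc: _ArithmeticEncoder, table: SymbolTable, v: int) -> None:
    if v < 0:
        raise ValueError("arithmetic coder takes non-negative mapped values")
    if v < AC_ALPHABET:
        enc.encode(table.cum, table.total, v)
    elif v < AC_ALPHABET + (1 << AC_LITERAL_BITS):
        enc.encode(table.cum, table.total, AC_ESCAPE)
        enc.encode_bits(v - AC_ALPHABET, AC_LITERAL_BITS)
    else:
        raise ValueError(f"value {v} exceeds the escape literal range")


def _ac_get(dec: _ArithmeticDecoder, table: SymbolTable) -> int:
    sym = dec.decode(table.cum, table.total)
    if sym == AC_ESCAPE:
        return AC_ALPHABET + dec.decode_bits(AC_LITERAL_BITS)
    return sym


def ac_encode(values: Sequence[int] | np.ndarray, table: SymbolTable) -> Bitstream:
    """Arithmetic-code mapped (non-negative) values against a trained table.

    Out-of-alphabet values are routed through the escape symbol followed by
    a 12-bit literal.
    """
    w = BitWriter()
    enc = _ArithmeticEncoder(w)
    for v in np.asarray(values, dtype=np.int64):
        _ac_put(enc, table, int(v))
    enc.finish()
    return Bitstream(payload=w.getvalue(), payload_bits=w.bit_length, mode="raw", backend="ac")


def ac_decode(bits: Bitstream | bytes, table: SymbolTable, n: int) -> np.ndarray:
    """Decode exactly ``n`` values written by :func:`ac_encode`."""
    reader = BitReader(bits.payload, bits.payload_bits) if isinstance(bits, Bitstream) else BitReader(bits)
    dec = _ArithmeticDecoder(reader)
    return np.asarray([_ac_get(dec, table) for _ in range(n)], dtype=np.int64)


# ---------------------------------------------------------------------------
# Channel compression (lossless and near-lossless)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NllFrame:
    """One near-lossless frame: a zero-run length followed by a 64-sample spike."""

    run_length: int
    spike: np.ndarray

    def __post_init__(self) -> None:
        if self.run_length < 0:
            raise ValueError("run length must be nonnegative")
        spike = np.asarray(self.spike, dtype=np.int64)
        if spike.shape != (WINDOW,):
            raise ValueError(f"spike must have exactly {WINDOW} samples")
        object.__setattr__(self, "spike", spike)

    def components(self) -> list[int]:
        """Bitwise split of the run length into 2 or 3 byte-wide symbols."""
        w = RLE_COMPONENT_BITS
        if self.run_length < 1 << (2 * w):
            return [self.run_length >> w, self.run_length & ((1 << w) - 1)]
        if self.run_length < 1 << (3 * w):
            return [
                self.run_length >> (2 * w),
                (self.run_length >> w) & ((1 << w) - 1),
                self.run_length & ((1 << w) - 1),
            ]
        raise ValueError(f"zero run of {self.run_length} samples exceeds 3-component capacity")


class _SymbolSink:
    """Backend-agnostic symbol writer (adaptive Rice or arithmetic)."""

    def __init__(self, backend: str, table: SymbolTable | None):
        self.backend = backend
        self._writer = BitWriter()
        if backend == "ac":
            if table is None:
                raise ValueError("the AC backend requires a trained symbol table")
            self._enc = _ArithmeticEncoder(self._writer)
            self._table = table
        else:
            self._rice = _RiceAdapter()

    def put(self, v: int) -> None:
        if self.backend == "ac":
            _ac_put(self._enc, self._table, v)
        else:
            _rice_write(self._writer, v, self._rice.k)
            self._rice.update(v)

    def put_flag(self, bit: int) -> None:
        if self.backend == "ac":
            self._enc.encode(_BINARY_CUM, 2, bit)
        else:
            self._writer.write_bit(bit)

    def finish(self) -> tuple[bytes, int]:
        if self.backend == "ac":
            self._enc.finish()
        return self._writer.getvalue(), self._writer.bit_length


class _SymbolSource:
    """Backend-agnostic symbol reader mirroring :class:`_SymbolSink`."""

    def __init__(self, backend: str, reader: BitReader, table: SymbolTable | None):
        self.backend = backend
        if backend == "ac":
            if table is None:
                raise ValueError("the AC backend requires a trained symbol table")
            self._dec = _ArithmeticDecoder(reader)
            self._table = table
        else:
            self._reader = reader
            self._rice = _RiceAdapter()

    def get(self) -> int:
        if self.backend == "ac":
            return _ac_get(self._dec, self._table)
        v = _rice_read(self._reader, self._rice.k)
        self._rice.update(v)
        return v

    def get_flag(self) -> int:
        if self.backend == "ac":
            return self._dec.decode(_BINARY_CUM, 2)
        return self._reader.read_bit()


def _spike_frame_residuals(spike: np.ndarray) -> np.ndarray:
    """DPCM2 within a frame, with zero history before the first sample."""
    padded = np.concatenate(([0, 0], spike))
    return padded[2:] - 2 * padded[1:-1] + padded[:-2]


def _spike_frame_reconstruct(residuals: np.ndarray) -> np.ndarray:
    out = np.empty(WINDOW, dtype=np.int64)
    prev2 = prev1 = 0
    for i, r in enumerate(residuals):
        cur = int(r) + 2 * prev1 - prev2
        out[i] = cur
        prev2, prev1 = prev1, cur
    return out


def _merge_events(events: Sequence[SpikeEvent], n_samples: int) -> list[SpikeEvent]:
    """Sort by onset and drop events overlapping the previous window."""
    kept: list[SpikeEvent] = []
    for ev in sorted(events, key=lambda e: e.onset):
        if ev.onset < 0 or ev.onset + WINDOW > n_samples:
            raise ValueError(f"event window [{ev.onset}, {ev.onset + WINDOW}) outside recording")
        if kept and ev.onset < kept[-1].onset + WINDOW:
            continue
        kept.append(ev)
    return kept


def compress_channel(
    rec: Recording,
    channel: int,
    mode: str = "lossless",
    backend: str = "gc",
    events: Sequence[SpikeEvent] | None = None,
    table: SymbolTable | None = None,
) -> Bitstream:
    """Compress one channel of a recording.

    Lossless mode codes the full DPCM2 residual stream.  Near-lossless mode
    requires detected spike events: the stream becomes alternating
    (zero-run, spike) frames, with each run length split into 2 or 3
    byte-wide components (a per-frame flag distinguishes the split) and each
    64-sample spike DPCM2-coded within its frame.  For the AC backend a
    trained :class:`SymbolTable` must be supplied; it is shared state of
    encoder and decoder and is not embedded in the stream.
    """
    if mode not in ("lossless", "near_lossless"):
        raise ValueError(f"unknown mode {mode!r}")
    x = rec.channel(channel).astype(np.int64)
    if backend == "ac" and table is None:
        raise ValueError("the AC backend requires a trained symbol table (see train_symbol_table)")
    sink = _SymbolSink(backend, table)

    n_frames = 0
    if mode == "lossless":
        if x.size >= 2:
            stream = dpcm2_encode(x)
            values = np.concatenate(([stream.warmup[0], stream.warmup[1]], stream.residuals))
        else:
            values = x
        for v in map_to_nonneg(values) if values.size else []:
            sink.put(int(v))
    else:
        if events is None:
            raise ValueError("near-lossless mode requires detected spike events")
        cursor = 0
        for ev in _merge_events(events, x.size):
            frame = NllFrame(run_length=ev.onset - cursor, spike=x[ev.onset : ev.onset + WINDOW])
            comps = frame.components()
            sink.put_flag(1 if len(comps) == 3 else 0)
            for c in comps:
                sink.put(c)
            for v in map_to_nonneg(_spike_frame_residuals(frame.spike)):
                sink.put(int(v))
            cursor = ev.onset + WINDOW
            n_frames += 1

    payload, nbits = sink.finish()
    return Bitstream(
        payload=payload,
        payload_bits=nbits,
        mode=mode,
        backend=backend,
        channel=int(channel),
        n_samples=x.size,
        bit_depth=rec.bit_depth,
        n_frames=n_frames,
    )


def decompress_channel(bits: Bitstream, table: SymbolTable | None = None) -> np.ndarray:
    """Exactly invert :func:`compress_channel` for either mode.

    Returns the reconstructed sample series; in near-lossless mode,
    inter-spike samples are zero and every spike window is exact.
    """
    reader = BitReader(bits.payload, bits.payload_bits)
    source = _SymbolSource(bits.backend, reader, table)
    n = bits.n_samples
    if bits.mode == "lossless":
        if n == 0:
            return np.empty(0, dtype=np.int64)
        values = np.asarray([source.get() for _ in range(n)], dtype=np.int64)
        values = np.asarray(map_from_nonneg(values))
        if n < 2:
            return values
        return dpcm2_decode(ResidualStream(warmup=(int(values[0]), int(values[1])), residuals=values[2:]))
    if bits.mode == "near_lossless":
        out = np.zeros(n, dtype=np.int64)
        cursor = 0
        for _ in range(bits.n_frames):
            three = source.get_flag()
            comps = [source.get() for _ in range(3 if three else 2)]
            run = 0
            for c in comps:
                run = (run << RLE_COMPONENT_BITS) | c
            residuals = np.asarray(map_from_nonneg(np.asarray([source.get() for _ in range(WINDOW)])))
            cursor += run
            if cursor + WINDOW > n:
                raise BitstreamError("frame decodes past end of recording")
            out[cursor : cursor + WINDOW] = _spike_frame_reconstruct(residuals)
            cursor += WINDOW
        return out
    raise ValueError(f"cannot decompress mode {bits.mode!r}")


def near_lossless_symbols(rec: Recording, channel: int, events: Sequence[SpikeEvent]) -> np.ndarray:
    """The mapped symbol stream near-lossless framing would emit.

    Useful for training a shared :class:`SymbolTable` on exactly the
    distribution the near-lossless AC path encodes (run-length components
    plus per-frame spike residuals).
    """
    x = rec.channel(channel).astype(np.int64)
    symbols: list[int] = []
    cursor = 0
    for ev in _merge_events(events, x.size):
        frame = NllFrame(run_length=ev.onset - cursor, spike=x[ev.onset : ev.onset + WINDOW])
        symbols.extend(frame.components())
        symbols.extend(int(v) for v in map_to_nonneg(_spike_frame_residuals(frame.spike)))
        cursor = ev.onset + WINDOW
    return np.asarray(symbols, dtype=np.int64)


def ssr(original_bits: int, compressed_bits: int) -> float:
    """Space saving ratio in percent: 100 * (1 - compressed / original)."""
    if original_bits <= 0:
        raise ValueError("original_bits must be positive")
    return 100.0 * (1.0 - compressed_bits / original_bits)
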