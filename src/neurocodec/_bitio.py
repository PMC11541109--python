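"""Minimal MSB-first bit writer/reader used by both entropy coders."""

from __future__ import annotations

__all__ = ["BitWriter", "BitReader", "BitstreamError"]


class BitstreamError(ValueError):
    """Raised on malformed or truncated bitstreams."""


class BitWriter:
    """Accumulates bits MSB-first into a bytearray."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0
        self.bit_length = 0

    def write_bit(self, bit: int) -> None:
        self._acc = (self._acc << 1) | (bit & 1)
        self._nbits += 1
        self.bit_length += 1
        if self._nbits == 8:
            self._buf.append(self._acc)
            self._acc = 0
            self._nbits = 0

    def write_bits(self, value: int, width: int) -> None:
        """Write ``width`` bits of ``value``, most significant first."""
        for shift in range(width - 1, -1, -1):
            self.write_bit((value >> shift) & 1)

    def write_unary(self, q: int) -> None:
        """``q`` one-bits followed by a terminating zero."""
        for _ in range(q):
            self.write_bit(1)
        self.write_bit(0)

    def getvalue(self) -> bytes:
        """Byte string padded with zero bits to a whole byte."""
        out = bytearray(self._buf)
        if self._nbits:
            out.append(self._acc << (8 - self._nbits))
        return bytes(out)


class BitReader:
    """Reads bits MSB-first from a byte string."""

    def __init__(self, data: bytes, bit_length: int | None = None) -> None:
        self._data = data
        self._pos = 0
        self.bit_length = 8 * len(data) if bit_length is None else bit_length

    @property
    def bits_left(self) -> int:
        return self.bit_length - self._pos

    def read_bit(self) -> int:
        if self._pos >= self.bit_length:
            raise BitstreamError("read past end of bitstream")
        byte = self._data[self._pos >> 3]
        bit = (byte >> (7 - (self._pos & 7))) & 1
        self._pos += 1
        return bit

    def read_bits(self, width: int) -> int:
        value = 0
        for _ in range(width):
            value = (value << 1) | self.read_bit()
        return value

    def read_unary(self, limit: int = 1 << 26) -> int:
        q = 0
        while self.read_bit():
            q += 1
            if q > limit:
                raise BitstreamError("unbounded unary run; corrupt stream")
        return q
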