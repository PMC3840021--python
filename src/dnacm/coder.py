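"""Bit-level I/O and the binary arithmetic coder.

The coder is a carry-correct binary range coder in the LZMA style:

* 32-bit ``range`` register, 33-bit ``low`` accumulator with a cache byte
  and a pending-0xFF counter for carry propagation,
* probabilities quantized to 16-bit fixed point (``p16 = round(p * 2**16)``,
  clamped to ``[1, 65535]``),
* the split point is computed at full precision, ``bound = (range * p16) >> 16``,
  so the per-bit redundancy beyond ``-log2 p`` is below ``1/(bound * ln 2)``
  bits (≤ 1e-5 bits per bit for any probability above 1%),
* renormalization emits whole bytes once ``range < 2**24``,
* flushing emits exactly 5 bytes, so the total overhead of a payload over
  the ideal code length is a constant 40 bits plus the accumulated
  quantization slack.

All probabilities entering the coder are clamped to the open interval
``(PROB_EPS, 1 - PROB_EPS)`` with ``PROB_EPS = 2**-12``; the clamp is part
of the frozen stream format.  Convention: ``bit == 1`` occupies the lower
part of the interval.

The per-bit kernels are numba-compiled and shared verbatim with the fast
pass-2 engine (:mod:`dnacm.engine`), so the payload format has a single
implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "PROB_EPS",
    "BitWriter",
    "BitReader",
    "ArithEncoder",
    "ArithDecoder",
]

PROB_EPS = 2.0 ** -12
#: flush cost in bits; asserted by the contract tests
FLUSH_OVERHEAD_BITS = 40



# ---------------------------------------------------------------------------
# range-coder kernels (state = int64[4]: low, range, cache, cache_size for
# the encoder; int64[2]: range, code for the decoder).  int64 holds every
# intermediate comfortably: low < 2^33, range < 2^32, range*p16 < 2^48.

@njit(cache=True)
def _rc_enc_init(st):
    st[0] = 0          # low
    st[1] = 0xFFFFFFFF  # range
    st[2] = 0          # cache byte
    st[3] = 1          # pending byte count


@njit(cache=True)
def _rc_shift_low(st, buf, pos):
    low = st[0]
    if low < 0xFF000000 or low > 0xFFFFFFFF:
        carry = low >> 32
        temp = st[2]
        cs = st[3]
        while cs > 0:
            buf[pos] = (temp + carry) & 0xFF
            pos += 1
            temp = 0xFF
            cs -= 1
        st[3] = 0
        st[2] = (low >> 24) & 0xFF
    st[3] += 1
    st[0] = (low << 8) & 0xFFFFFFFF
    return pos


@njit(cache=True)
def _rc_encode_bit(st, buf, pos, p16, bit):
    r = st[1]
    bound = (r * p16) >> 16
    if bit == 1:
        st[1] = bound
    else:
        st[0] = st[0] + bound
        st[1] = r - bound
    while st[1] < 0x1000000:
        pos = _rc_shift_low(st, buf, pos)
        st[1] = (st[1] << 8) & 0xFFFFFFFF
    return pos


@njit(cache=True)
def _rc_enc_flush(st, buf, pos):
    for _ in range(5):
        pos = _rc_shift_low(st, buf, pos)
    return pos


@njit(cache=True)
def _rc_dec_init(st, buf, pos):
    st[0] = 0xFFFFFFFF  # range
    st[1] = 0           # code
    for _ in range(5):
        if pos >= buf.shape[0]:
            raise ValueError("truncated arithmetic payload")
        st[1] = ((st[1] << 8) | buf[pos]) & 0xFFFFFFFF
        pos += 1
    return pos


@njit(cache=True)
def _rc_decode_bit(st, buf, pos, p16):
    r = st[0]
    bound = (r * p16) >> 16
    if st[1] < bound:
        bit = 1
        st[0] = bound
    else:
        bit = 0
        st[1] = st[1] - bound
        st[0] = r - bound
    while st[0] < 0x1000000:
        if pos >= buf.shape[0]:
            raise ValueError("truncated arithmetic payload")
        st[1] = ((st[1] << 8) | buf[pos]) & 0xFFFFFFFF
        pos += 1
        st[0] = (st[0] << 8) & 0xFFFFFFFF
    return bit, pos


@njit(cache=True)
def _p_to_p16(p):
    """Quantize a clamped probability to the coder's 16-bit fixed point."""
    q = int(p * 65536.0 + 0.5)
    if q < 1:
        q = 1
    elif q > 65535:
        q = 65535
    return q


def _clamp_prob(p1: float) -> float:
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"probability {p1} outside [0, 1]")
    return min(max(p1, PROB_EPS), 1.0 - PROB_EPS)


# ---------------------------------------------------------------------------
# python-facing wrappers

class ArithEncoder:
    """Streaming binary arithmetic encoder.

    >>> enc = ArithEncoder()
    >>> enc.encode_bit(0.9, 1)
    >>> payload = enc.flush()
    """

    def __init__(self) -> None:
        self._st = np.zeros(4, dtype=np.int64)
        _rc_enc_init(self._st)
        self._buf = np.zeros(256, dtype=np.uint8)
        self._pos = 0
        self._flushed = False
        self.nbits = 0

    def _reserve(self, extra: int) -> None:
        if self._pos + extra > self._buf.shape[0]:
            grown = np.zeros(max(self._buf.shape[0] * 2, self._pos + extra), dtype=np.uint8)
            grown[: self._pos] = self._buf[: self._pos]
            self._buf = grown

    def encode_bit(self, p1: float, bit: int) -> None:
        """Narrow the interval by ``p1`` (bit 1) or ``1 - p1`` (bit 0)."""
        if self._flushed:
            raise RuntimeError("encoder already flushed")
        if bit not in (0, 1):
            raise ValueError(f"bit must be 0 or 1, got {bit}")
        self._reserve(8)
        p16 = _p_to_p16(_clamp_prob(p1))
        self._pos = _rc_encode_bit(self._st, self._buf, self._pos, p16, bit)
        self.nbits += 1

    def flush(self) -> bytes:
        """Emit the disambiguating tail; may be called exactly once."""
        if self._flushed:
            raise RuntimeError("double flush")
        self._reserve(8)
        self._pos = _rc_enc_flush(self._st, self._buf, self._pos)
        self._flushed = True
        return bytes(self._buf[: self._pos])


class ArithDecoder:
    """Mirror of :class:`ArithEncoder`; must be fed the identical
    probability sequence that drove the encoder."""

    def __init__(self, payload: bytes) -> None:
        self._buf = np.frombuffer(payload, dtype=np.uint8)
        self._st = np.zeros(2, dtype=np.int64)
        self._pos = _rc_dec_init(self._st, self._buf, 0)

    def decode_bit(self, p1: float) -> int:
        p16 = _p_to_p16(_clamp_prob(p1))
        bit, self._pos = _rc_decode_bit(self._st, self._buf, self._pos, p16)
        return int(bit)


# ---------------------------------------------------------------------------
# plain bit streams (token side-band); MSB-first within each byte

class BitWriter:
    """Accumulates '0'/'1' strings; final byte is zero-padded."""

    def __init__(self) -> None:
        self._chunks: list[str] = []
        self.nbits = 0

    def write(self, bits: str) -> None:
        if bits:
            self._chunks.append(bits)
            self.nbits += len(bits)

    def write_bit(self, bit: int) -> None:
        self.write("1" if bit else "0")

    def to_bytes(self) -> bytes:
        bits = "".join(self._chunks)
        pad = (-len(bits)) % 8
        bits += "0" * pad
        if not bits:
            return b""
        return int(bits, 2).to_bytes(len(bits) // 8, "big")


class BitReader:
    """Reads bits written by :class:`BitWriter` (MSB-first)."""

    def __init__(self, data: bytes, nbits: int | None = None) -> None:
        total = len(data) * 8
        if nbits is None:
            nbits = total
        if nbits > total:
            raise ValueError("nbits exceeds available data")
        bits = bin(int.from_bytes(data, "big"))[2:].zfill(total) if data else ""
        self.bits = bits[:nbits]
        self.pos = 0

    def read(self, k: int) -> str:
        if self.pos + k > len(self.bits):
            raise ValueError("bit stream exhausted")
        out = self.bits[self.pos : self.pos + k]
        self.pos += k
        return out

    def read_bit(self) -> int:
        return int(self.read(1))
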