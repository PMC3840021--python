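"""Prefix-free integer codes used by the first-pass token streams.

Two codes are used, mirroring the asymmetry between the two first passes:

* **Elias gamma** — ``floor(log2 v)`` zeros followed by the binary
  representation of ``v``.  Cheap for small values, ``2*floor(log2 v)+1``
  bits overall.
* **log-skewed** — an Elias-delta-style code: the bit length of ``v`` is
  itself gamma-coded, then the mantissa of ``v`` (without its leading 1)
  follows.  Its length, ``floor(log2 v) + 2*floor(log2(floor(log2 v)+1)) + 1``
  bits, grows more slowly than gamma for large values while still assigning
  the fewest bits to the smallest values.

Both codes are defined on positive integers only and are part of the frozen
container format.  Bit strings are plain ``str`` of ``'0'``/``'1'``
(token streams are tiny relative to the arithmetic payload, so clarity wins
over packing here; :class:`dnacm.coder.BitWriter` does the packing).
"""

from __future__ import annotations

__all__ = [
    "gamma_encode",
    "gamma_decode",
    "log_skewed_encode",
    "log_skewed_decode",
]


def gamma_encode(v: int) -> str:
    """Elias gamma code of ``v >= 1`` as a '0'/'1' string."""
    if v < 1:
        raise ValueError(f"gamma code is defined for v >= 1, got {v}")
    b = bin(int(v))[2:]
    return "0" * (len(b) - 1) + b


def gamma_decode(bits: str, start: int = 0) -> tuple[int, int]:
    """Decode one gamma codeword from ``bits[start:]``.

    Returns ``(value, bits_consumed)``.
    """
    n = len(bits)
    i = start
    while i < n and bits[i] == "0":
        i += 1
    nz = i - start
    if i >= n or i + nz + 1 > n:
        raise ValueError("truncated gamma codeword")
    v = int(bits[i : i + nz + 1], 2)
    return v, (i + nz + 1) - start


def log_skewed_encode(v: int, bound: int = 1 << 62) -> str:
    """Log-skewed (Elias-delta-style) code of ``1 <= v <= bound``."""
    if v < 1 or v > bound:
        raise ValueError(f"log-skewed code requires 1 <= v <= bound, got v={v} bound={bound}")
    b = bin(int(v))[2:]
    return gamma_encode(len(b)) + b[1:]


def log_skewed_decode(bits: str, bound: int = 1 << 62, start: int = 0) -> tuple[int, int]:
    """Decode one log-skewed codeword from ``bits[start:]``.

    Returns ``(value, bits_consumed)``; raises on malformed/truncated input
    or a decoded value above ``bound``.
    """
    nbits, used = gamma_decode(bits, start)
    i = start + used
    if i + nbits - 1 > len(bits):
        raise ValueError("truncated log-skewed codeword")
    mant = bits[i : i + nbits - 1]
    v = (1 << (nbits - 1)) | (int(mant, 2) if mant else 0)
    if v > bound:
        raise ValueError(f"decoded value {v} exceeds bound {bound}")
    return v, used + nbits - 1
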