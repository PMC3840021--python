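"""Numba-compiled pass-2 codec: the full model bank, logistic mixer and
range coder fused into one per-bit loop.

Semantics are those of the reference modules: context keys as in
:func:`dnacm.models.context_id` and the three bit-history maps of
:mod:`dnacm.models`, with each model contributing its three map
probabilities to the mixer (weight vector length ``3 * n_models``).
Per-context state lives in fixed-size hash tables (``2**table_bits`` slots
per model) with a lossy collision policy: each slot carries a 6-bit
checksum of the full context key and is reset when the checksum disagrees.

Engine-internal representation choices (frozen parts of the stream format):

* one packed ``int64`` per slot —
  ``s0[0:16) s1[16:32) n0[32:40) n1[40:48) runl[48:56) runb[56] chk[57:63)``,
* model stretches come from a 65536-entry lookup table
  (``stretch((i + 0.5) / 65536)``), i.e. probabilities are quantized to 16
  bits before mixing, matching the coder's own probability resolution.

The item stream interleaves three channels:

1. an adaptive order-0 *exception flag* bit per item,
2. for exceptions, an order-1 byte model (context = previous exception
   byte, bitwise tree decomposition) — byte 0 is the reserved repeat-token
   marker, any other value is a literal non-ACGT symbol,
3. for ordinary bases, two mixed binary decisions through the model bank.

Only bases enter the packed bit history, so non-ACGT symbols never disturb
the context models.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .coder import (
    _rc_dec_init,
    _rc_decode_bit,
    _rc_enc_flush,
    _rc_enc_init,
    _rc_encode_bit,
)
from .models import DEFAULT_MASKS, DEFAULT_ORDERS, expand_mask

__all__ = ["pass2_encode", "pass2_decode", "bank_arrays", "DEFAULT_TABLE_BITS"]

DEFAULT_TABLE_BITS = 18

_PEPS = 2.0 ** -12
_WCLIP = 20.0

# stretch(p) over the coder's 16-bit probability grid; built once,
# deterministically, at import
_IDX = (np.arange(65536, dtype=np.float64) + 0.5) / 65536.0
STRETCH_LUT = np.log(_IDX / (1.0 - _IDX))
del _IDX


def bank_arrays(
    orders=DEFAULT_ORDERS, masks=DEFAULT_MASKS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a bank configuration for the kernels: sequential orders,
    concatenated mask bit-offsets and their start indices."""
    orders = np.asarray(orders, dtype=np.int64)
    offs: list[int] = []
    starts = [0]
    for m in masks:
        offs.extend(expand_mask(int(m)))
        starts.append(len(offs))
    return orders, np.asarray(offs, dtype=np.int64), np.asarray(starts, dtype=np.int64)


@njit(cache=True, inline="always")
def _hash_key(key, tmask):
    # 35-bit key -> (slot, 6-bit checksum); staged 32-bit mixing, int64-safe
    a = key & 0xFFFF
    b = (key >> 16) & 0xFFFF
    c = key >> 32
    z = a * 0x9E3779B1 + b * 0x85EBCA77 + c * 0xC2B2AE3D
    z ^= z >> 17
    z &= 0xFFFFFFFF
    z *= 0x2545F491
    z ^= z >> 15
    slot = z & tmask
    chk = (z >> 24) & 0x3F
    return slot, chk


@njit(cache=True, inline="always")
def _model_key(mi, ns, orders, moffs, mstart, h, bases_seen, bitpos, b0):
    """Context key for model mi; 0 is the reserved cold-start key."""
    if mi < ns:
        o = orders[mi]
        if bases_seen < o:
            return 0
        ctx = h & ((1 << (2 * o)) - 1)
    else:
        if bases_seen < 16:
            return 0
        j = mi - ns
        ctx = 0
        for t in range(mstart[j + 1] - 1, mstart[j] - 1, -1):
            ctx = (ctx << 1) | ((h >> moffs[t]) & 1)
    b0bit = b0 if bitpos == 1 else 0
    return ((ctx << 2) | (bitpos << 1) | b0bit) + 1


@njit(cache=True, inline="always")
def _p_idx(p):
    q = int(p * 65536.0)
    if q < 16:          # PROB_EPS * 2**16
        q = 16
    elif q > 65519:
        q = 65519
    return q


@njit(cache=True, inline="always")
def _gather(mi, slot, chk, tab, T, st, lut):
    """Validate the slot checksum, stage its packed value, and write the
    three stretched map probabilities into st[3*mi:3*mi+3]."""
    v = tab[mi * T + slot]
    if (v >> 57) & 0x3F != chk:
        v = chk << 57
        tab[mi * T + slot] = v
    s0 = v & 0xFFFF
    s1 = (v >> 16) & 0xFFFF
    a0 = (v >> 32) & 0xFF
    a1 = (v >> 40) & 0xFF
    rl = (v >> 48) & 0xFF
    rb = (v >> 56) & 1
    if rl == 0:
        p_run = 0.5
    else:
        conf = 1.0 / (rl + 2.0)
        p_run = 1.0 - conf if rb == 1 else conf
    p_stat = (s1 + 0.5) / (s0 + s1 + 1.0)
    p_non = (a1 + 0.5) / (a0 + a1 + 1.0)
    st[3 * mi] = lut[_p_idx(p_run)]
    st[3 * mi + 1] = lut[_p_idx(p_stat)]
    st[3 * mi + 2] = lut[_p_idx(p_non)]
    return v


@njit(cache=True, inline="always")
def _slot_update(v, bit):
    """Advance the packed slot state for an observed bit."""
    s0 = v & 0xFFFF
    s1 = (v >> 16) & 0xFFFF
    a0 = (v >> 32) & 0xFF
    a1 = (v >> 40) & 0xFF
    rl = (v >> 48) & 0xFF
    rb = (v >> 56) & 1
    if bit == 1:
        s1 += 1
        a1 += 1
    else:
        s0 += 1
        a0 += 1
    if a0 + a1 > 255:
        a0 = (a0 + 1) // 2
        a1 = (a1 + 1) // 2
    if s0 + s1 > 65534:
        s0 = (s0 + 1) // 2
        s1 = (s1 + 1) // 2
    if bit == rb and rl > 0:
        if rl < 255:
            rl += 1
    else:
        rb = bit
        rl = 1
    chkbits = v & (0x3F << 57)
    return (
        s0
        | (s1 << 16)
        | (a0 << 32)
        | (a1 << 40)
        | (rl << 48)
        | (rb << 56)
        | chkbits
    )


@njit(cache=True, inline="always")
def _mix(w, st, m_inputs):
    dot = 0.0
    for j in range(m_inputs):
        dot += w[j] * st[j]
    p = 1.0 / (1.0 + np.exp(-dot))
    if p < _PEPS:
        p = _PEPS
    elif p > 1.0 - _PEPS:
        p = 1.0 - _PEPS
    q = int(p * 65536.0 + 0.5)
    if q < 1:
        q = 1
    elif q > 65535:
        q = 65535
    return p, q


@njit(cache=True, inline="always")
def _mixer_update(w, st, m_inputs, bit, p, eta):
    err = eta * (bit - p)
    for j in range(m_inputs):
        wj = w[j] + err * st[j]
        if wj > _WCLIP:
            wj = _WCLIP
        elif wj < -_WCLIP:
            wj = -_WCLIP
        w[j] = wj


@njit(cache=True, inline="always")
def _adapt_p16(c0, c1):
    p = (c1 + 1.0) / (c0 + c1 + 2.0)
    q = int(p * 65536.0 + 0.5)
    if q < 1:
        q = 1
    elif q > 65535:
        q = 65535
    return q


@njit(cache=True)
def pass2_encode(kinds, codes, orders, moffs, mstart, table_bits, eta):
    """Encode an item stream.  kinds[i]: 0 = base, 1 = exception;
    codes[i]: 2-bit base code or the exception byte.  Returns the payload."""
    n = kinds.shape[0]
    ns = orders.shape[0]
    nm = mstart.shape[0] - 1
    K = ns + nm
    M = 3 * K
    T = 1 << table_bits
    tmask = T - 1
    lut = STRETCH_LUT

    tab = np.zeros(K * T, dtype=np.int64)
    w = np.zeros(M, dtype=np.float64)
    st = np.zeros(M, dtype=np.float64)
    slots = np.zeros(K, dtype=np.int64)
    vals = np.zeros(K, dtype=np.int64)

    e0 = np.zeros((256, 256), dtype=np.uint16)
    e1 = np.zeros((256, 256), dtype=np.uint16)
    f0 = 0
    f1 = 0
    prev_exc = 0

    buf = np.zeros(16 * n + 64, dtype=np.uint8)
    rc = np.zeros(4, dtype=np.int64)
    _rc_enc_init(rc)
    pos = 0

    h = 0
    bases_seen = 0
    for i in range(n):
        is_exc = kinds[i]
        pos = _rc_encode_bit(rc, buf, pos, _adapt_p16(f0, f1), is_exc)
        if is_exc == 1:
            f1 += 1
        else:
            f0 += 1
        if f0 + f1 > 65535:
            f0 = (f0 + 1) // 2
            f1 = (f1 + 1) // 2
        if is_exc == 1:
            byte = codes[i]
            nd = 1
            for k in range(8):
                bit = (byte >> (7 - k)) & 1
                c0 = np.int64(e0[prev_exc, nd])
                c1 = np.int64(e1[prev_exc, nd])
                pos = _rc_encode_bit(rc, buf, pos, _adapt_p16(c0, c1), bit)
                if bit == 1:
                    c1 += 1
                else:
                    c0 += 1
                if c0 + c1 > 65500:
                    c0 = (c0 + 1) // 2
                    c1 = (c1 + 1) // 2
                e0[prev_exc, nd] = c0
                e1[prev_exc, nd] = c1
                nd = nd * 2 + bit
            prev_exc = byte
        else:
            code = codes[i]
            b0 = 0
            for bitpos in range(2):
                bit = (code >> (1 - bitpos)) & 1
                for mi in range(K):
                    key = _model_key(mi, ns, orders, moffs, mstart, h,
                                     bases_seen, bitpos, b0)
                    slot, chk = _hash_key(key, tmask)
                    slots[mi] = slot
                    vals[mi] = _gather(mi, slot, chk, tab, T, st, lut)
                p, q = _mix(w, st, M)
                pos = _rc_encode_bit(rc, buf, pos, q, bit)
                _mixer_update(w, st, M, bit, p, eta)
                for mi in range(K):
                    tab[mi * T + slots[mi]] = _slot_update(vals[mi], bit)
                if bitpos == 0:
                    b0 = bit
            h = ((h << 2) | code) & 0xFFFFFFFF
            bases_seen += 1
    pos = _rc_enc_flush(rc, buf, pos)
    return buf[:pos].copy()


@njit(cache=True)
def pass2_decode(payload, n_items, orders, moffs, mstart, table_bits, eta):
    """Mirror of :func:`pass2_encode`; replays the identical model
    trajectory and returns (kinds, codes)."""
    ns = orders.shape[0]
    nm = mstart.shape[0] - 1
    K = ns + nm
    M = 3 * K
    T = 1 << table_bits
    tmask = T - 1
    lut = STRETCH_LUT

    tab = np.zeros(K * T, dtype=np.int64)
    w = np.zeros(M, dtype=np.float64)
    st = np.zeros(M, dtype=np.float64)
    slots = np.zeros(K, dtype=np.int64)
    vals = np.zeros(K, dtype=np.int64)

    e0 = np.zeros((256, 256), dtype=np.uint16)
    e1 = np.zeros((256, 256), dtype=np.uint16)
    f0 = 0
    f1 = 0
    prev_exc = 0

    kinds = np.zeros(n_items, dtype=np.uint8)
    codes = np.zeros(n_items, dtype=np.uint8)

    rc = np.zeros(2, dtype=np.int64)
    pos = _rc_dec_init(rc, payload, 0)

    h = 0
    bases_seen = 0
    for i in range(n_items):
        is_exc, pos = _rc_decode_bit(rc, payload, pos, _adapt_p16(f0, f1))
        if is_exc == 1:
            f1 += 1
        else:
            f0 += 1
        if f0 + f1 > 65535:
            f0 = (f0 + 1) // 2
            f1 = (f1 + 1) // 2
        kinds[i] = is_exc
        if is_exc == 1:
            nd = 1
            for k in range(8):
                c0 = np.int64(e0[prev_exc, nd])
                c1 = np.int64(e1[prev_exc, nd])
                bit, pos = _rc_decode_bit(rc, payload, pos, _adapt_p16(c0, c1))
                if bit == 1:
                    c1 += 1
                else:
                    c0 += 1
                if c0 + c1 > 65500:
                    c0 = (c0 + 1) // 2
                    c1 = (c1 + 1) // 2
                e0[prev_exc, nd] = c0
                e1[prev_exc, nd] = c1
                nd = nd * 2 + bit
            byte = nd - 256
            codes[i] = byte
            prev_exc = byte
        else:
            code = 0
            b0 = 0
            for bitpos in range(2):
                for mi in range(K):
                    key = _model_key(mi, ns, orders, moffs, mstart, h,
                                     bases_seen, bitpos, b0)
                    slot, chk = _hash_key(key, tmask)
                    slots[mi] = slot
                    vals[mi] = _gather(mi, slot, chk, tab, T, st, lut)
                p, q = _mix(w, st, M)
                bit, pos = _rc_decode_bit(rc, payload, pos, q)
                _mixer_update(w, st, M, bit, p, eta)
                for mi in range(K):
                    tab[mi * T + slots[mi]] = _slot_update(vals[mi], bit)
                if bitpos == 0:
                    b0 = bit
                code = (code << 1) | bit
            codes[i] = code
            h = ((h << 2) | code) & 0xFFFFFFFF
            bases_seen += 1
    return kinds, codes
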