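"""Self-referential first pass: exact-repeat and reverse-complement
removal over a sliding window (exact matching coding / decoding).

A greedy left-to-right scan keeps a window of the last ``W`` coded symbols.
At each cursor position the longest exact match of the lookahead against
the window is sought, in both orientations: *forward* (lookahead prefix
equals a window substring) and *reverse-complement* (lookahead prefix
equals the reverse complement of a window substring).  A match of length
at least ``L`` is replaced by a :class:`Quadruplet` token — (substitution
flag, orientation bit, offset from the window start, length) — otherwise a
single literal is emitted and the cursor advances by one.

Rules, frozen as part of the format:

* matches lie entirely inside the coded window (no overlap with the
  lookahead), so ``p_offset ∈ [0, W - m_length]``;
* ties on length prefer forward over reverse-complement, then the match
  whose start is nearest the cursor;
* symbols outside uppercase {A,C,G,T} never participate in matches (the
  reverse complement is undefined for them); they break extensions and are
  passed to the second pass through the escape channel.

Serialization of a quadruplet in the token side-band: orientation bit,
``log_skewed(p_offset + 1)``, ``gamma(m_length - L + 1)``.  The
substitution flag itself travels in the pass-2 symbol stream as the
reserved marker, not in the side-band.

The production scan (`emc_encode`) uses a numba hash-chain index over
``k = min(L, 12)``-mers; :func:`find_longest_match` is the plain
brute-force definition and doubles as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .coder import BitReader, BitWriter
from .intcodes import gamma_decode, gamma_encode, log_skewed_decode, log_skewed_encode

__all__ = [
    "MatchParams",
    "Quadruplet",
    "TokenStream",
    "FORWARD",
    "REVCOMP",
    "find_longest_match",
    "emc_encode",
    "emc_decode",
    "encode_sequence",
    "seq_to_codes",
]

DEFAULT_L = 25
DEFAULT_W = 1 << 16

FORWARD = 0
REVCOMP = 1

# uppercase A/C/G/T -> 2-bit code (T-00, A-01, G-10, C-11); everything else 255
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"TAGC", range(4)):
    _CODE_TABLE[_b] = _c
_COMP = np.array([1, 0, 3, 2], dtype=np.uint8)  # T<->A, G<->C in code space


@dataclass(frozen=True)
class MatchParams:
    """First-pass thresholds: minimum match length ``L`` and window ``W``
    (both in bases)."""

    L: int = DEFAULT_L
    W: int = DEFAULT_W

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.W < self.L:
            raise ValueError("W must be >= L")


@dataclass(frozen=True)
class Quadruplet:
    """One repeat token.  ``p_offset`` is the distance from the window
    start to the match's first symbol; ``m_length`` the match length in
    bases; ``m_type`` the orientation."""

    m_type: int
    p_offset: int
    m_length: int

    def serialize(self, params: MatchParams) -> str:
        return (
            ("1" if self.m_type == REVCOMP else "0")
            + log_skewed_encode(self.p_offset + 1, params.W)
            + gamma_encode(self.m_length - params.L + 1)
        )


@dataclass
class TokenStream:
    """Ordered pass-1 output: items are literal symbols (1-char str) or
    :class:`Quadruplet` tokens."""

    items: list = field(default_factory=list)
    params: MatchParams = field(default_factory=MatchParams)

    @property
    def n_quadruplets(self) -> int:
        return sum(1 for it in self.items if isinstance(it, Quadruplet))

    def serialize_tokens(self) -> tuple[bytes, int]:
        """Pack all quadruplets' side-band bits; returns (bytes, nbits)."""
        w = BitWriter()
        for it in self.items:
            if isinstance(it, Quadruplet):
                w.write(it.serialize(self.params))
        return w.to_bytes(), w.nbits

    @staticmethod
    def deserialize_tokens(data: bytes, nbits: int, n_quads: int,
                           params: MatchParams) -> list["Quadruplet"]:
        r = BitReader(data, nbits)
        out = []
        for _ in range(n_quads):
            m_type = r.read_bit()
            off1, used = log_skewed_decode(r.bits, params.W, r.pos)
            r.pos += used
            len1, used = gamma_decode(r.bits, r.pos)
            r.pos += used
            out.append(Quadruplet(m_type, off1 - 1, len1 + params.L - 1))
        return out


def seq_to_codes(seq: str | bytes) -> np.ndarray:
    """Map a symbol string to 2-bit codes (255 for non-ACGT)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE_TABLE[np.frombuffer(seq, dtype=np.uint8)]


def find_longest_match(
    window: str, lookahead: str, params: MatchParams
) -> tuple[int, int, int] | None:
    """Longest match of a lookahead prefix inside the window, both
    orientations; the brute-force definition (also the test oracle for the
    indexed scan).

    Returns ``(m_type, p_offset, m_length)`` or ``None`` if the best match
    is shorter than ``params.L``.
    """
    if len(window) > params.W:
        raise ValueError("window longer than W")
    wcodes = seq_to_codes(window)
    lcodes = seq_to_codes(lookahead)
    nw, nl = len(wcodes), len(lcodes)
    cap = min(nl, params.W)
    best = None  # (m, type, start)
    for j in range(nw):
        # forward: window[j:j+m] == lookahead[:m], fully inside the window
        m = 0
        while m < cap and j + m < nw:
            a, b = wcodes[j + m], lcodes[m]
            if a >= 4 or b >= 4 or a != b:
                break
            m += 1
        if m >= params.L:
            cand = (m, FORWARD, j)
            if best is None or _better(cand, best):
                best = cand
        # reverse-complement anchored at region end e=j: comp(window[e-t]) ==
        # lookahead[t]; region start j-m+1 must stay in the window
        e = j
        m = 0
        while m < cap and e - m >= 0:
            a, b = wcodes[e - m], lcodes[m]
            if a >= 4 or b >= 4 or _COMP[a] != b:
                break
            m += 1
        if m >= params.L:
            cand = (m, REVCOMP, e - m + 1)
            if best is None or _better(cand, best):
                best = cand
    if best is None:
        return None
    m, t, start = best
    return (t, start, m)


def _better(cand: tuple[int, int, int], best: tuple[int, int, int]) -> bool:
    """Longest wins; ties prefer forward, then the start nearest the
    window end."""
    m, t, s = cand
    bm, bt, bs = best
    if m != bm:
        return m > bm
    if t != bt:
        return t < bt
    return s > bs


@njit(cache=True)
def _emc_scan(codes, L, W, k):
    """Greedy indexed scan; returns parallel arrays of quadruplets
    (cursor positions, types, offsets, lengths)."""
    n = codes.shape[0]
    HB = 20
    HSIZE = 1 << HB
    HMASK = HSIZE - 1
    head = np.full(HSIZE, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    comp = np.array([1, 0, 3, 2], dtype=np.uint8)

    q_pos = []
    q_typ = []
    q_off = []
    q_len = []

    kshift = 2 * (k - 1)
    kmask = (1 << (2 * k)) - 1

    ins = 0  # next position to index
    c = 0
    while c < n:
        ws = c - W
        if ws < 0:
            ws = 0
        # index every k-mer starting at positions < c
        while ins < c and ins + k <= n:
            ok = True
            key = 0
            for t in range(k):
                v = codes[ins + t]
                if v >= 4:
                    ok = False
                    break
                key = ((key << 2) | v) & kmask
            if ok:
                hh = (key * 0x9E3779B1) & 0xFFFFFFFF
                hh = (hh ^ (hh >> 13)) & HMASK
                nxt[ins] = head[hh]
                head[hh] = ins
            ins += 1

        best_m = 0
        best_t = 0
        best_s = -1
        # lookahead prefix k-mer (forward key and revcomp key)
        if c + k <= n:
            ok = True
            fkey = 0
            rkey = 0
            for t in range(k):
                v = codes[c + t]
                if v >= 4:
                    ok = False
                    break
                fkey = ((fkey << 2) | v) & kmask
                rkey = (rkey >> 2) | (np.int64(comp[v]) << kshift)
            if ok:
                cap = n - c
                if cap > W:
                    cap = W
                # forward candidates
                hh = (fkey * 0x9E3779B1) & 0xFFFFFFFF
                hh = (hh ^ (hh >> 13)) & HMASK
                j = head[hh]
                while j >= 0:
                    if j < ws:
                        break
                    if j <= c - L:  # no-overlap: m <= c - j and m >= L
                        m = 0
                        mcap = cap
                        if mcap > c - j:
                            mcap = c - j
                        while m < mcap:
                            a = codes[j + m]
                            b = codes[c + m]
                            if a >= 4 or b >= 4 or a != b:
                                break
                            m += 1
                        if m >= L and (m > best_m or (m == best_m and
                                                      (best_t == 1 or j > best_s))):
                            best_m = m
                            best_t = 0
                            best_s = j
                    j = nxt[j]
                # reverse-complement candidates: chain entry j2 is the start
                # of the k-mer ending the matched region at e = j2 + k - 1
                hh = (rkey * 0x9E3779B1) & 0xFFFFFFFF
                hh = (hh ^ (hh >> 13)) & HMASK
                j2 = head[hh]
                while j2 >= 0:
                    if j2 < ws:
                        break
                    e = j2 + k - 1
                    if e <= c - 1:
                        m = 0
                        while m < cap and e - m >= ws:
                            a = codes[e - m]
                            b = codes[c + m]
                            if a >= 4 or b >= 4 or comp[a] != b:
                                break
                            m += 1
                        s = e - m + 1
                        if m >= L and (m > best_m or (m == best_m and
                                                      best_t == 1 and s > best_s)):
                            best_m = m
                            best_t = 1
                            best_s = s
                    j2 = nxt[j2]
        if best_m >= L:
            q_pos.append(c)
            q_typ.append(best_t)
            q_off.append(best_s - ws)
            q_len.append(best_m)
            c += best_m
        else:
            c += 1
    return (
        np.array(q_pos, dtype=np.int64),
        np.array(q_typ, dtype=np.int64),
        np.array(q_off, dtype=np.int64),
        np.array(q_len, dtype=np.int64),
    )


def emc_encode(seq: str, params: MatchParams | None = None) -> TokenStream:
    """Greedy repeat-removal scan; literal symbols and quadruplets."""
    params = params or MatchParams()
    codes = seq_to_codes(seq)
    k = min(params.L, 12)
    q_pos, q_typ, q_off, q_len = _emc_scan(codes, params.L, params.W, k)
    items: list = []
    c = 0
    for p, t, o, m in zip(q_pos, q_typ, q_off, q_len):
        items.extend(seq[c:p])
        items.append(Quadruplet(int(t), int(o), int(m)))
        c = int(p) + int(m)
    items.extend(seq[c:])
    return TokenStream(items=items, params=params)


_RC_MAP = str.maketrans("ACGT", "TGCA")
_RC_BYTES = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC_MAP)[::-1]


def emc_decode(tokens: TokenStream, params: MatchParams | None = None) -> str:
    """Exact inverse of :func:`emc_encode`."""
    params = params or tokens.params
    out = bytearray()
    for it in tokens.items:
        if isinstance(it, Quadruplet):
            ws = max(0, len(out) - params.W)
            start = ws + it.p_offset
            end = start + it.m_length
            if start < 0 or end > len(out):
                raise ValueError("corrupt token: match outside reconstructed window")
            region = bytes(out[start:end])
            if it.m_type == FORWARD:
                out += region
            else:
                out += region.translate(_RC_BYTES)[::-1]
        else:
            out += it.encode("ascii")
    return out.decode("ascii")


def encode_sequence(seq: str, params: MatchParams | None = None) -> TokenStream:
    """Alias kept for symmetry with the reference pass."""
    return emc_encode(seq, params)
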