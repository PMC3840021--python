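"""Reference-based first pass: windowed bidirectional exact matching
against a tracked reference cursor (relative-LZ style).

Within-species resequencing data diverges from its reference by roughly
one change per thousand bases, so a target position usually continues an
exact copy of the reference just past the last match.  The encoder tracks
a reference cursor ``c`` (initially 0, moved to one past each match's
end) and, at each target position, searches reference start positions
``[c + left, c + right]`` for the longest exact match of length >= L;
ties prefer the smallest ``|offset|`` ("longest and nearest"), and at
equal distance the downstream (positive) side.  The asymmetric window —
a short look-back and a longer look-ahead — tracks substitutions,
insertions and deletions at close range.

The window pair is chosen adaptively from the *difference percentage*
between target and reference symbol counts:

    < 0.65%          -> [-12, 650]
    0.65% .. < 5%    -> [-12, 812]
    >= 5%            -> [-12, 11560]

Match tokens store (length, signed offset from the cursor); lengths here
are long and offsets small — the opposite of the self-referential pass —
so the codes are swapped: length is log-skewed coded, the zigzag-folded
offset gamma coded.  Matching is over raw symbols (case- and
symbol-exact), so extended alphabets participate.  Unmatched symbols are
literals: they go to pass 2 and leave the cursor unchanged.

Decoding only replays match positions — no search — so it is much cheaper
than encoding.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .coder import BitReader, BitWriter
from .intcodes import gamma_decode, gamma_encode, log_skewed_decode, log_skewed_encode
from .noref import MatchParams

__all__ = [
    "WindowRange",
    "DiffStats",
    "RefMatchToken",
    "RefTokenStream",
    "DEFAULT_WINDOWS",
    "diff_stats",
    "diff_percentage",
    "select_window",
    "rlz_encode",
    "rlz_decode",
]

@dataclass(frozen=True)
class WindowRange:
    """Signed search window around the reference cursor, inclusive ends."""

    left: int = -12
    right: int = 650

    def __post_init__(self) -> None:
        if not (self.left <= 0 <= self.right):
            raise ValueError("window must satisfy left <= 0 <= right")


DEFAULT_WINDOWS = (
    WindowRange(-12, 650),
    WindowRange(-12, 812),
    WindowRange(-12, 11560),
)

#: difference-percentage thresholds for the adaptive window rule
WINDOW_THRESHOLDS = (0.0065, 0.05)


@dataclass(frozen=True)
class RefMatchToken:
    """One reference match: length in bases and signed displacement of the
    match start from the current reference cursor."""

    m_length: int
    offset: int

    def serialize(self, params: MatchParams) -> str:
        return log_skewed_encode(self.m_length) + gamma_encode(_zigzag(self.offset) + 1)


@dataclass
class RefTokenStream:
    """Ordered pass-1 output in reference mode: literal symbols or
    :class:`RefMatchToken` items."""

    items: list = field(default_factory=list)
    params: MatchParams = field(default_factory=MatchParams)
    window: WindowRange = field(default_factory=WindowRange)

    @property
    def n_tokens(self) -> int:
        return sum(1 for it in self.items if isinstance(it, RefMatchToken))

    def serialize_tokens(self) -> tuple[bytes, int]:
        w = BitWriter()
        for it in self.items:
            if isinstance(it, RefMatchToken):
                w.write(it.serialize(self.params))
        return w.to_bytes(), w.nbits

    @staticmethod
    def deserialize_tokens(data: bytes, nbits: int, n_tokens: int) -> list["RefMatchToken"]:
        r = BitReader(data, nbits)
        out = []
        for _ in range(n_tokens):
            m, used = log_skewed_decode(r.bits, start=r.pos)
            r.pos += used
            z1, used = gamma_decode(r.bits, r.pos)
            r.pos += used
            out.append(RefMatchToken(m, _unzigzag(z1 - 1)))
        return out


def _zigzag(v: int) -> int:
    """0,-1,1,-2,... -> 0,1,2,3,... (gamma needs positive integers)."""
    return 2 * v if v >= 0 else -2 * v - 1


def _unzigzag(z: int) -> int:
    return z // 2 if z % 2 == 0 else -(z + 1) // 2


@dataclass(frozen=True)
class DiffStats:
    """Per-symbol absolute count differences between target and reference,
    and their sum over the target length."""

    per_symbol: dict
    percentage: float


def diff_stats(target: str, reference: str) -> DiffStats:
    """Count-difference summary over the union alphabet (uppercase,
    lowercase and ambiguity symbols all count)."""
    if not target:
        raise ValueError("empty target")
    if not reference:
        raise ValueError("empty reference")
    ct = Counter(target)
    cr = Counter(reference)
    per = {s: abs(ct.get(s, 0) - cr.get(s, 0)) for s in sorted(set(ct) | set(cr))}
    return DiffStats(per_symbol=per, percentage=sum(per.values()) / len(target))


def diff_percentage(target: str, reference: str) -> float:
    """Σ_sym |count_target − count_ref| / len(target); drives the adaptive
    window rule."""
    return diff_stats(target, reference).percentage


def select_window(pct: float) -> WindowRange:
    """Adaptive window rule from the difference percentage."""
    if pct < 0:
        raise ValueError("difference percentage cannot be negative")
    if pct < WINDOW_THRESHOLDS[0]:
        return DEFAULT_WINDOWS[0]
    if pct < WINDOW_THRESHOLDS[1]:
        return DEFAULT_WINDOWS[1]
    return DEFAULT_WINDOWS[2]


@njit(cache=True)
def _rlz_scan(tgt, ref, left, right, L):
    """Greedy scan; returns (kinds, match_lens, match_offs) where kinds[i]
    marks item i as literal (0) or match (1); literal bytes are recovered
    from the target directly."""
    nt = tgt.shape[0]
    nr = ref.shape[0]
    kinds = []
    lens = []
    offs = []
    c = 0
    i = 0
    while i < nt:
        lo = c + left
        if lo < 0:
            lo = 0
        hi = c + right
        if hi > nr - 1:
            hi = nr - 1
        best_m = 0
        best_off = 0
        for s in range(lo, hi + 1):
            if ref[s] != tgt[i]:
                continue
            m = 1
            while i + m < nt and s + m < nr and ref[s + m] == tgt[i + m]:
                m += 1
            off = s - c
            ao = off if off >= 0 else -off
            ab = best_off if best_off >= 0 else -best_off
            if m > best_m or (m == best_m and (ao < ab or (ao == ab and off > best_off))):
                best_m = m
                best_off = off
        if best_m >= L:
            kinds.append(1)
            lens.append(best_m)
            offs.append(best_off)
            c = c + best_off + best_m
            i += best_m
        else:
            kinds.append(0)
            lens.append(0)
            offs.append(i)  # literal: remember target position
            i += 1
    return (
        np.array(kinds, dtype=np.int64),
        np.array(lens, dtype=np.int64),
        np.array(offs, dtype=np.int64),
    )


def rlz_encode(
    target: str,
    reference: str,
    window: WindowRange | None = None,
    params: MatchParams | None = None,
) -> RefTokenStream:
    """Tokenize ``target`` against ``reference``; window defaults to the
    adaptive rule."""
    if not reference:
        raise ValueError("empty reference")
    params = params or MatchParams()
    if window is None:
        window = select_window(diff_percentage(target, reference)) if target else DEFAULT_WINDOWS[0]
    tgt = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    kinds, lens, offs = _rlz_scan(tgt, ref, window.left, window.right, params.L)
    items: list = []
    for k, m, o in zip(kinds, lens, offs):
        if k == 1:
            items.append(RefMatchToken(int(m), int(o)))
        else:
            items.append(target[int(o)])
    return RefTokenStream(items=items, params=params, window=window)


def rlz_decode(
    tokens: RefTokenStream,
    reference: str,
    window: WindowRange | None = None,
    params: MatchParams | None = None,
) -> str:
    """Replay tokens against the reference; no searching."""
    ref = reference
    out = []
    c = 0
    for it in tokens.items:
        if isinstance(it, RefMatchToken):
            s = c + it.offset
            if s < 0 or s + it.m_length > len(ref):
                raise ValueError("corrupt token: match outside reference bounds")
            out.append(ref[s : s + it.m_length])
            c = s + it.m_length
        else:
            out.append(it)
    return "".join(out)
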