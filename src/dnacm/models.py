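"""Bitwise context models: binarization, sequential and sparse contexts,
bit-history maps, and a Krichevsky–Trofimov code-length oracle.

Each DNA base is mapped to two bits (T→00, A→01, G→10, C→11, emitted
MSB-first) and compressed as two binary decisions.  A context model predicts
each bit from a function of the preceding bits:

* a *sequential* model of order ``n`` uses the last ``2n`` bits (the last
  ``n`` bases),
* a *sparse* (non-sequential) model uses a 32-bit pick mask over the last
  four packed bytes = last 16 bases; mask bit 0 refers to the bit
  immediately preceding the current base.

The default bank holds eleven sequential orders
``1, 2, 4, 6, 8, 10, 11, 12, 13, 14, 16`` and eleven sparse masks; sparse
models capture periodic structure (e.g. a base two positions back being
informative while the intervening base is noise) that contiguous contexts
dilute across many states.

Per context, a :class:`BitHistory` feeds three lookup maps:

* **run map** — (last bit, run length), confidence grows with the run,
* **stationary map** — KT-style add-½ ratio over unbounded counts,
* **nonstationary map** — the same ratio over counts halved whenever their
  sum exceeds 255, so old evidence decays.

This module is the transparent, dictionary-backed reference used by tests
and by :func:`kt_code_length`; the production codec in :mod:`dnacm.engine`
implements the identical context conventions over flat hash tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BASE_CODE",
    "CODE_BASE",
    "DEFAULT_ORDERS",
    "DEFAULT_MASKS",
    "MAX_ORDER",
    "ContextSpec",
    "BitHistory",
    "Prediction",
    "base_to_bits",
    "bits_to_base",
    "expand_mask",
    "context_id",
    "predict",
    "update",
    "kt_code_length",
    "default_bank",
]

BASE_CODE = {"T": 0, "A": 1, "G": 2, "C": 3}
CODE_BASE = {v: k for k, v in BASE_CODE.items()}

DEFAULT_ORDERS = (1, 2, 4, 6, 8, 10, 11, 12, 13, 14, 16)
DEFAULT_MASKS = (
    0x00F0F0F0,
    0xF0F0F0F0,
    0x00F8F8F8,
    0xF8F8F8F8,
    0x00E0E0E0,
    0xE0E0E0E0,
    0x00F0F0FE,
    0xAAAAAAAA,
    0xF00F00FA,
    0xF000F0FD,
    0xF0000F00,
)
MAX_ORDER = 16  # bases; 32 bits = the four packed history bytes

#: nonstationary counts are halved once their sum exceeds this
NONSTATIONARY_LIMIT = 255
#: stationary counts are halved only at the storage cap
STATIONARY_LIMIT = 65534

_PEPS = 2.0 ** -12


@dataclass(frozen=True)
class ContextSpec:
    """One context model: ``kind`` is 'sequential' (with ``order`` in bases)
    or 'sparse' (with a 32-bit pick ``mask``)."""

    kind: str
    order: int = 0
    mask: int = 0

    def __post_init__(self) -> None:
        if self.kind == "sequential":
            if not 1 <= self.order <= MAX_ORDER:
                raise ValueError(f"sequential order must be in [1, {MAX_ORDER}]")
        elif self.kind == "sparse":
            if not 0 < self.mask <= 0xFFFFFFFF:
                raise ValueError("sparse mask must be a nonzero 32-bit pattern")
        else:
            raise ValueError(f"unknown context kind {self.kind!r}")

    @property
    def history_bases(self) -> int:
        """Bases of history required before the model leaves cold start."""
        return self.order if self.kind == "sequential" else MAX_ORDER


@dataclass
class BitHistory:
    """Adaptive per-context state behind the three probability maps."""

    n0: int = 0  # nonstationary counts (decayed)
    n1: int = 0
    s0: int = 0  # stationary counts
    s1: int = 0
    run_bit: int = 0
    run_len: int = 0


@dataclass(frozen=True)
class Prediction:
    """Per-model output: the three map probabilities and their combination."""

    p1: float
    p_run: float
    p_stationary: float
    p_nonstationary: float


def base_to_bits(base: str) -> str | None:
    """2-bit code of a base, MSB first; ``None`` signals the escape channel
    for symbols outside {A,C,G,T} (never an exception)."""
    if len(base) == 1:
        code = BASE_CODE.get(base)
        if code is None:
            return None
        return format(code, "02b")
    out = []
    for b in base:
        code = BASE_CODE.get(b)
        if code is None:
            return None
        out.append(format(code, "02b"))
    return "".join(out)


def bits_to_base(bits: str) -> str:
    if len(bits) != 2 or any(c not in "01" for c in bits):
        raise ValueError(f"expected two bits, got {bits!r}")
    return CODE_BASE[int(bits, 2)]


def expand_mask(mask: int) -> list[int]:
    """Offsets (into the 32 preceding bits; 0 = most recent) picked by
    ``mask``, ascending."""
    if mask == 0:
        raise ValueError("zero mask selects an empty context")
    if not 0 < mask <= 0xFFFFFFFF:
        raise ValueError("mask must fit in 32 bits")
    return [k for k in range(32) if (mask >> k) & 1]


def _extract_context(spec: ContextSpec, h: int) -> int:
    if spec.kind == "sequential":
        return h & ((1 << (2 * spec.order)) - 1)
    ctx = 0
    for off in reversed(expand_mask(spec.mask)):  # oldest picked bit first
        ctx = (ctx << 1) | ((h >> off) & 1)
    return ctx


def context_id(
    spec: ContextSpec,
    h: int,
    bases_seen: int,
    bitpos: int,
    b0: int = 0,
) -> int:
    """Hashable context key for the bit at ``bitpos`` (0 or 1) of the
    current base.

    ``h`` packs the preceding bases two bits each (bit 0 = most recent
    preceding bit); ``b0`` is the already-coded first bit of the current
    base, part of every model's context when ``bitpos == 1``.  Positions
    with fewer than the model's required bases of history share the
    reserved cold-start key 0.
    """
    if bases_seen < spec.history_bases:
        return 0
    ctx = _extract_context(spec, h)
    key = (ctx << 2) | (bitpos << 1) | (b0 if bitpos else 0)
    return key + 1  # 0 is reserved for cold start


def _maps(hist: BitHistory) -> tuple[float, float, float]:
    p_stat = (hist.s1 + 0.5) / (hist.s0 + hist.s1 + 1.0)
    p_non = (hist.n1 + 0.5) / (hist.n0 + hist.n1 + 1.0)
    if hist.run_len == 0:
        p_run = 0.5
    else:
        conf = 1.0 / (hist.run_len + 2.0)
        p_run = 1.0 - conf if hist.run_bit == 1 else conf
    return p_run, p_stat, p_non


def predict(spec: ContextSpec, hist: BitHistory) -> Prediction:
    """Map the bit history to probabilities; a fresh context yields 0.5."""
    p_run, p_stat, p_non = _maps(hist)
    p1 = (p_run + p_stat + p_non) / 3.0
    p1 = min(max(p1, _PEPS), 1.0 - _PEPS)
    return Prediction(p1=p1, p_run=p_run, p_stationary=p_stat, p_nonstationary=p_non)


def update(spec: ContextSpec, hist: BitHistory, bit: int) -> BitHistory:
    """Advance counts and run state after observing ``bit``."""
    if bit not in (0, 1):
        raise ValueError("bit must be 0 or 1")
    if bit:
        hist.n1 += 1
        hist.s1 += 1
    else:
        hist.n0 += 1
        hist.s0 += 1
    if hist.n0 + hist.n1 > NONSTATIONARY_LIMIT:
        hist.n0 = (hist.n0 + 1) // 2
        hist.n1 = (hist.n1 + 1) // 2
    if hist.s0 + hist.s1 > STATIONARY_LIMIT:
        hist.s0 = (hist.s0 + 1) // 2
        hist.s1 = (hist.s1 + 1) // 2
    if bit == hist.run_bit and hist.run_len > 0:
        hist.run_len = min(hist.run_len + 1, 255)
    else:
        hist.run_bit = bit
        hist.run_len = 1
    return hist


def kt_code_length(bits: str, spec: ContextSpec) -> float:
    """Ideal code length (bits) of a binary string under ``spec`` with the
    KT estimator ``P(b) = (n_b + 1/2) / (n0 + n1 + 1)``, counts accumulated
    sequentially per context.

    Transparent oracle used to compare sequential vs sparse contexts on the
    same data; not part of the production codec.
    """
    counts: dict[int, list[int]] = {}
    cost = 0.0
    h = 0
    b0 = 0
    for i, ch in enumerate(bits):
        bit = 1 if ch == "1" else 0
        bitpos = i & 1
        key = context_id(spec, h, i // 2, bitpos, b0)
        n = counts.setdefault(key, [0, 0])
        p1 = (n[1] + 0.5) / (n[0] + n[1] + 1.0)
        cost -= math.log2(p1 if bit else 1.0 - p1)
        n[bit] += 1
        if bitpos == 0:
            b0 = bit
        else:
            h = ((h << 2) | (b0 << 1) | bit) & 0xFFFFFFFF
    return cost


def default_bank() -> list[ContextSpec]:
    """The frozen default bank: 11 sequential + 11 sparse models."""
    bank = [ContextSpec("sequential", order=n) for n in DEFAULT_ORDERS]
    bank += [ContextSpec("sparse", mask=m) for m in DEFAULT_MASKS]
    return bank
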