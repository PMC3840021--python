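"""Synthetic DNA generators emulating the statistical structure the
compressor targets, plus the reference-mutation model for ref-mode pairs.

Three generators, all driven by a single seeded PCG64 stream so a
:class:`GenSpec` maps to exactly one sequence on every platform:

* :func:`gen_iid` — uniform i.i.d. bases, the incompressible null model
  (~2 bits/base), optionally salted with non-ACGT symbols;
* :func:`gen_repeats` — an i.i.d. backbone interleaved with copies of
  earlier material: dispersed/tandem repeats of geometric length, a stated
  fraction reverse-complemented, each copy independently point-mutated.
  This mimics the repeat content that the first pass removes from real
  genomes;
* :func:`mutate_reference` — derives a resequencing-style target from a
  reference by per-position substitution/insertion/deletion, the regime
  (~0.1% divergence within species) that reference-based compression
  exploits.

Default rates are chosen to resemble repeat-rich genomic sequence:
repeat_fraction 0.5, mean repeat length 300, 30% of copies
reverse-complemented, 1% point mutation within copies.  What these
generators do *not* emulate: long approximate repeats with indels inside
the copy, GC skew, isochore structure, or positional composition bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GenSpec", "gen_iid", "gen_repeats", "mutate_reference"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_EXT_SYMBOLS = np.frombuffer(b"NnacgtRYKMSW", dtype=np.uint8)
_RC = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


@dataclass(frozen=True)
class GenSpec:
    """Parameters of one synthetic sequence (same spec ⇒ same sequence)."""

    length: int
    seed: int = 0
    repeat_fraction: float = 0.5
    repeat_len_mean: float = 300.0
    revcomp_fraction: float = 0.3
    sub_rate: float = 0.01
    ins_rate: float = 0.0
    del_rate: float = 0.0
    ext_prob: float = 0.0  # probability a position carries a non-ACGT symbol

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be >= 0")
        for name in ("repeat_fraction", "revcomp_fraction", "sub_rate",
                     "ins_rate", "del_rate", "ext_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _salt_extended(arr: np.ndarray, ext_prob: float, rng: np.random.Generator) -> np.ndarray:
    if ext_prob > 0 and arr.size:
        hit = rng.random(arr.size) < ext_prob
        arr[hit] = rng.choice(_EXT_SYMBOLS, size=int(hit.sum()))
    return arr


def gen_iid(spec: GenSpec) -> str:
    """Uniform i.i.d. sequence; the 2-bits-per-base null model."""
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    arr = rng.choice(_BASES, size=spec.length)
    arr = _salt_extended(arr, spec.ext_prob, rng)
    return arr.tobytes().decode("ascii")


def gen_repeats(spec: GenSpec) -> str:
    """Repeat-rich sequence: i.i.d. stretches plus mutated forward and
    reverse-complement copies of earlier material.

    With ``repeat_fraction`` 0 this reduces to :func:`gen_iid` (same seed,
    different draw pattern but the same null statistics).
    """
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    if spec.repeat_fraction == 0.0:
        return gen_iid(spec)
    out = bytearray()
    seed_len = min(spec.length, max(200, int(spec.repeat_len_mean)))
    out += rng.choice(_BASES, size=seed_len).tobytes()
    while len(out) < spec.length:
        if rng.random() < spec.repeat_fraction:
            m = max(30, int(rng.geometric(1.0 / spec.repeat_len_mean)))
            m = min(m, len(out))
            start = int(rng.integers(0, len(out) - m + 1))
            seg = bytearray(out[start : start + m])
            # point-mutate the copy
            if spec.sub_rate > 0:
                hits = np.nonzero(rng.random(m) < spec.sub_rate)[0]
                for h in hits:
                    seg[h] = int(rng.choice(_BASES))
            if rng.random() < spec.revcomp_fraction:
                seg = bytearray(bytes(seg).translate(_RC)[::-1])
            out += seg
        else:
            n = int(rng.geometric(1.0 / 200.0))
            out += rng.choice(_BASES, size=n).tobytes()
    arr = np.frombuffer(bytes(out[: spec.length]), dtype=np.uint8).copy()
    arr = _salt_extended(arr, spec.ext_prob, rng)
    return arr.tobytes().decode("ascii")


def mutate_reference(reference: str, spec: GenSpec | None = None, *,
                     sub_rate: float | None = None, ins_rate: float | None = None,
                     del_rate: float | None = None, seed: int = 0) -> str:
    """Target derived from ``reference`` by independent per-position
    substitutions, insertions and deletions at the stated rates."""
    if spec is None:
        spec = GenSpec(length=len(reference), seed=seed,
                       sub_rate=0.001 if sub_rate is None else sub_rate,
                       ins_rate=0.0 if ins_rate is None else ins_rate,
                       del_rate=0.0 if del_rate is None else del_rate)
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    n = len(reference)
    ref_b = np.frombuffer(reference.encode("latin-1"), dtype=np.uint8)

    def _sub(old: int) -> int:
        # substitutions always change the symbol, so sub_rate is the
        # realized per-position divergence
        choices = _BASES[_BASES != old]
        if choices.size == 0:
            choices = _BASES
        return int(rng.choice(choices))

    if spec.ins_rate == 0.0 and spec.del_rate == 0.0:
        out = ref_b.copy()
        hits = np.nonzero(rng.random(n) < spec.sub_rate)[0]
        for i in hits:
            out[i] = _sub(int(out[i]))
        return out.tobytes().decode("latin-1")

    u = rng.random(n)
    out = bytearray()
    for i in range(n):
        r = u[i]
        if r < spec.del_rate:
            continue
        r -= spec.del_rate
        if r < spec.ins_rate:
            out.append(int(rng.choice(_BASES)))
            out.append(int(ref_b[i]))
            continue
        r -= spec.ins_rate
        if r < spec.sub_rate:
            out.append(_sub(int(ref_b[i])))
        else:
            out.append(int(ref_b[i]))
    return out.decode("latin-1")
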