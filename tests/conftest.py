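"""Shared fixtures: seeded random sequence builders."""

from __future__ import annotations

import random

import pytest

ALPHABET_EXT = "NnacgtRYKM"


def random_dna(rng: random.Random, n: int, ext_prob: float = 0.0) -> str:
    """Uniform random sequence, optionally salted with non-ACGT symbols."""
    out = []
    for _ in range(n):
        if ext_prob and rng.random() < ext_prob:
            out.append(rng.choice(ALPHABET_EXT))
        else:
            out.append(rng.choice("ACGT"))
    return "".join(out)


def structured_dna(rng: random.Random, n: int, ext_prob: float = 0.02) -> str:
    """Repeat-rich sequence with forward and reverse-complement copies,
    built directly so tests do not depend on the synth module."""
    rc = str.maketrans("ACGT", "TGCA")
    s = "".join(rng.choice("ACGT") for _ in range(max(60, n // 5)))
    while len(s) < n:
        r = rng.random()
        if r < 0.4 and len(s) > 80:
            a = rng.randrange(0, len(s) - 50)
            m = rng.randrange(30, 70)
            seg = s[a : a + m]
            if rng.random() < 0.4:
                seg = seg.translate(rc)[::-1]
            s += seg
        elif r < 0.4 + ext_prob:
            s += rng.choice(ALPHABET_EXT)
        else:
            s += "".join(rng.choice("ACGT") for _ in range(rng.randrange(5, 40)))
    return s[:n]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(0xDCA)
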