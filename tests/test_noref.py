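"""Self-referential first pass: matcher semantics, greedy scan vs the
brute-force definition, losslessness, serialization layout."""

import random

import pytest

from dnacm.intcodes import gamma_encode, log_skewed_encode
from dnacm.noref import (
    FORWARD,
    REVCOMP,
    MatchParams,
    Quadruplet,
    TokenStream,
    emc_decode,
    emc_encode,
    find_longest_match,
)

from conftest import random_dna, structured_dna


class TestFindLongestMatch:
    def test_forward_match(self):
        # j=0 and j=4 both give length 4; nearest the window end wins
        assert find_longest_match("ACGTACGT", "ACGTTT", MatchParams(L=3, W=64)) == (
            FORWARD, 4, 4,
        )

    def test_reverse_complement_match(self):
        # revcomp("AACCCC") == "GGGGTT": the full 6-symbol prefix matches
        assert find_longest_match("AAAACCCC", "GGGGTT", MatchParams(L=3, W=64)) == (
            REVCOMP, 2, 6,
        )

    def test_empty_window(self):
        assert find_longest_match("", "ACGTACGT", MatchParams(L=3, W=64)) is None

    def test_below_threshold(self):
        assert find_longest_match("ACGTACGT", "ACGTTT", MatchParams(L=5, W=64)) is None

    def test_forward_beats_revcomp_at_equal_length(self):
        # window holds both "ACGT" and its revcomp source for lookahead ACGT
        win = "ACGTTTTT" + "ACGT"  # revcomp("ACGT") == "ACGT" (palindrome)
        t, off, m = find_longest_match(win, "ACGTCCAA", MatchParams(L=4, W=64))
        assert t == FORWARD

    def test_non_acgt_breaks_matches(self):
        assert (
            find_longest_match("ACGNACGN", "ACGNACGN", MatchParams(L=4, W=64)) is None
        )


class TestEmcGreedy:
    def test_all_a_structure(self):
        ts = emc_encode("A" * 10_000, MatchParams(L=25, W=1 << 16))
        literals = [i for i in ts.items if isinstance(i, str)]
        quads = [i for i in ts.items if isinstance(i, Quadruplet)]
        assert literals == ["A"] * 25
        # no-overlap greedy: match lengths can at most double each step
        assert len(quads) == 9
        assert sum(q.m_length for q in quads) == 10_000 - 25
        assert emc_decode(ts) == "A" * 10_000

    def test_iid_1kb_produces_no_quadruplets(self):
        seq = random_dna(random.Random(99), 1000)
        ts = emc_encode(seq, MatchParams(L=25, W=1 << 16))
        assert ts.n_quadruplets == 0

    def test_single_forward_quadruplet_decode(self):
        params = MatchParams(L=4, W=64)
        ts = TokenStream(
            items=list("ACGTT") + [Quadruplet(FORWARD, 0, 4)], params=params
        )
        assert emc_decode(ts) == "ACGTT" + "ACGT"

    def test_single_revcomp_quadruplet_decode(self):
        params = MatchParams(L=4, W=64)
        ts = TokenStream(
            items=list("AACCG") + [Quadruplet(REVCOMP, 0, 4)], params=params
        )
        # revcomp of window[0:4] == revcomp("AACC") == "GGTT"
        assert emc_decode(ts) == "AACCG" + "GGTT"

    def test_corrupt_token_raises(self):
        params = MatchParams(L=4, W=64)
        ts = TokenStream(items=list("ACG") + [Quadruplet(FORWARD, 0, 4)], params=params)
        with pytest.raises(ValueError):
            emc_decode(ts)

    @pytest.mark.parametrize("case", range(10))
    def test_roundtrip_structured(self, case):
        rng = random.Random(1000 + case)
        seq = structured_dna(rng, rng.randrange(200, 4000), ext_prob=0.03)
        params = MatchParams(L=rng.choice([8, 15, 25]), W=rng.choice([256, 1 << 16]))
        ts = emc_encode(seq, params)
        assert emc_decode(ts) == seq

    def test_greedy_equals_bruteforce_definition(self):
        # the indexed scan must reproduce the brute-force greedy exactly
        for case in range(25):
            rng = random.Random(300 + case)
            seq = structured_dna(rng, rng.randrange(100, 700), ext_prob=0.05)
            params = MatchParams(L=rng.choice([5, 10, 25]), W=rng.choice([128, 1 << 16]))
            assert emc_encode(seq, params).items == _brute_greedy(seq, params)

    def test_raising_L_never_increases_quadruplets(self):
        seq = structured_dna(random.Random(77), 5000)
        counts = [
            emc_encode(seq, MatchParams(L=L)).n_quadruplets for L in (10, 15, 25, 40, 80)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def _brute_greedy(seq: str, params: MatchParams) -> list:
    items: list = []
    c = 0
    while c < len(seq):
        ws = max(0, c - params.W)
        r = find_longest_match(seq[ws:c], seq[c:], params)
        if r:
            t, off, m = r
            items.append(Quadruplet(t, off, m))
            c += m
        else:
            items.append(seq[c])
            c += 1
    return items


class TestTokenSerialization:
    def test_documented_bit_layout(self):
        params = MatchParams(L=25, W=1 << 16)
        q = Quadruplet(REVCOMP, 37, 60)
        expected = "1" + log_skewed_encode(38, params.W) + gamma_encode(60 - 25 + 1)
        assert q.serialize(params) == expected

    def test_stream_roundtrip(self):
        rng = random.Random(5)
        params = MatchParams(L=10, W=1 << 16)
        quads = [
            Quadruplet(
                rng.choice([FORWARD, REVCOMP]),
                rng.randrange(0, 60_000),
                rng.randrange(10, 5000),
            )
            for _ in range(200)
        ]
        ts = TokenStream(items=list("ACGT") + quads, params=params)
        data, nbits = ts.serialize_tokens()
        assert TokenStream.deserialize_tokens(data, nbits, len(quads), params) == quads
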