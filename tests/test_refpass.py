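"""Reference-based first pass: window rule, bidirectional matching,
losslessness across mutation regimes."""

import random

import pytest

from dnacm.container import compress
from dnacm.fasta import SequenceRecord
from dnacm.intcodes import gamma_encode, log_skewed_encode
from dnacm.noref import MatchParams
from dnacm.refpass import (
    RefMatchToken,
    RefTokenStream,
    WindowRange,
    diff_percentage,
    rlz_decode,
    rlz_encode,
    select_window,
)
from dnacm.synth import GenSpec, gen_iid, mutate_reference


class TestDiffPercentage:
    def test_identical_is_zero(self):
        assert diff_percentage("ACGTN", "ACGTN") == 0.0

    def test_counts_example(self):
        assert diff_percentage("AACC", "AAGG") == 1.0

    def test_length_mismatch_example(self):
        assert diff_percentage("ACGT", "ACGTACGT") == 1.0

    def test_case_sensitive_counts(self):
        assert diff_percentage("acgt", "ACGT") == 2.0

    def test_empty_target_raises(self):
        with pytest.raises(ValueError):
            diff_percentage("", "ACGT")


class TestSelectWindow:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (0.0, WindowRange(-12, 650)),
            (0.0064, WindowRange(-12, 650)),
            (0.0065, WindowRange(-12, 812)),
            (0.01, WindowRange(-12, 812)),
            (0.0499, WindowRange(-12, 812)),
            (0.05, WindowRange(-12, 11560)),
            (0.20, WindowRange(-12, 11560)),
        ],
    )
    def test_threshold_rule(self, pct, expected):
        assert select_window(pct) == expected

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            select_window(-0.1)

    def test_window_invariant(self):
        with pytest.raises(ValueError):
            WindowRange(5, 10)


class TestRlz:
    def test_identical_target_single_token(self):
        ref = gen_iid(GenSpec(100_000, seed=8))
        ts = rlz_encode(ref, ref)
        assert len(ts.items) == 1
        assert ts.items[0] == RefMatchToken(100_000, 0)
        assert rlz_decode(ts, ref) == ref

    def test_single_substitution_two_tokens_one_literal(self):
        ref = gen_iid(GenSpec(10_000, seed=9))
        ch = "A" if ref[5000] != "A" else "C"
        tgt = ref[:5000] + ch + ref[5001:]
        ts = rlz_encode(tgt, ref)
        tokens = [i for i in ts.items if isinstance(i, RefMatchToken)]
        literals = [i for i in ts.items if isinstance(i, str)]
        assert len(tokens) == 2 and literals == [ch]
        assert rlz_decode(ts, ref) == tgt

    def test_disjoint_composition_all_literals(self):
        ts = rlz_encode("T" * 40, "ACGT" * 10, params=MatchParams(L=25))
        assert ts.n_tokens == 0 and len(ts.items) == 40
        assert rlz_decode(ts, "ACGT" * 10) == "T" * 40

    @pytest.mark.parametrize("sub", [0.0, 0.001, 0.01, 0.1])
    @pytest.mark.parametrize("indel", [0.0, 0.001, 0.01])
    def test_roundtrip_across_mutation_regimes(self, sub, indel):
        ref = gen_iid(GenSpec(20_000, seed=13))
        tgt = mutate_reference(
            ref, sub_rate=sub, ins_rate=indel, del_rate=indel, seed=17
        )
        ts = rlz_encode(tgt, ref)
        assert rlz_decode(ts, ref) == tgt

    def test_extended_alphabet_participates_in_matches(self):
        ref = gen_iid(GenSpec(5000, seed=21, ext_prob=0.05))
        ts = rlz_encode(ref, ref, params=MatchParams(L=25))
        assert len(ts.items) == 1  # non-ACGT symbols match byte-exactly
        assert rlz_decode(ts, ref) == ref

    def test_token_outside_reference_raises(self):
        ts = RefTokenStream(items=[RefMatchToken(10, 5)])
        with pytest.raises(ValueError):
            rlz_decode(ts, "ACGT")

    def test_compressed_size_nondecreasing_in_mutation_rate(self):
        rates = (0.0, 0.001, 0.01, 0.1)
        mean_sizes = []
        for rate in rates:
            sizes = []
            for rep in range(10):
                ref = gen_iid(GenSpec(8000, seed=100 + rep))
                tgt = mutate_reference(ref, sub_rate=rate, seed=200 + rep)
                c = compress(
                    [SequenceRecord("t", tgt)], mode="ref", reference=ref
                )
                sizes.append(c.size)
            mean_sizes.append(sum(sizes) / len(sizes))
        assert all(a <= b for a, b in zip(mean_sizes, mean_sizes[1:])), mean_sizes

    def test_identical_1mb_tiny_token_and_payload_blocks(self):
        ref = gen_iid(GenSpec(1_000_000, seed=31))
        c = compress([SequenceRecord("t", ref)], mode="ref", reference=ref)
        tok, pay = c.blocks[0]
        assert c.header["records"][0]["n_quads"] == 1
        assert len(tok) + len(pay) < 200  # container overhead aside


class TestRefTokenSerialization:
    def test_documented_bit_layout(self):
        # length log-skewed, zigzag(offset)+1 gamma coded — swapped vs noref
        t = RefMatchToken(m_length=1000, offset=-3)
        expected = log_skewed_encode(1000) + gamma_encode(2 * 3 - 1 + 1)
        assert t.serialize(MatchParams()) == expected

    def test_stream_roundtrip_with_signed_offsets(self):
        rng = random.Random(4)
        toks = [
            RefMatchToken(rng.randrange(25, 100_000), rng.randrange(-12, 651))
            for _ in range(300)
        ]
        ts = RefTokenStream(items=toks)
        data, nbits = ts.serialize_tokens()
        assert RefTokenStream.deserialize_tokens(data, nbits, len(toks)) == toks
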