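"""Context models: binarization, masks, context keys, history maps, and
the KT code-length comparison between sparse and sequential contexts."""

import random

import pytest

from dnacm.models import (
    DEFAULT_MASKS,
    DEFAULT_ORDERS,
    MAX_ORDER,
    BitHistory,
    ContextSpec,
    base_to_bits,
    bits_to_base,
    context_id,
    default_bank,
    expand_mask,
    kt_code_length,
    predict,
    update,
)


class TestBinarization:
    def test_known_mapping(self):
        assert base_to_bits("ATCAT") == "0100110100"
        assert base_to_bits("T") == "00"
        assert base_to_bits("A") == "01"
        assert base_to_bits("G") == "10"
        assert base_to_bits("C") == "11"

    def test_bijective_on_acgt(self):
        for b in "ACGT":
            assert bits_to_base(base_to_bits(b)) == b

    def test_unmapped_symbol_signals_escape(self):
        assert base_to_bits("N") is None
        assert base_to_bits("ACGN") is None  # escape applies to the block

    def test_bits_to_base_rejects_malformed(self):
        with pytest.raises(ValueError):
            bits_to_base("0")
        with pytest.raises(ValueError):
            bits_to_base("012")


class TestMasks:
    def test_popcounts(self):
        assert len(expand_mask(0x00F0F0F0)) == 12
        offs = expand_mask(0xAAAAAAAA)
        assert len(offs) == 16
        assert offs == list(range(1, 32, 2))  # every second bit
        assert expand_mask(0xFFFFFFFF) == list(range(32))

    def test_zero_mask_rejected(self):
        with pytest.raises(ValueError):
            expand_mask(0)

    def test_bank_composition(self):
        bank = default_bank()
        seq = [s for s in bank if s.kind == "sequential"]
        sparse = [s for s in bank if s.kind == "sparse"]
        assert len(seq) == 11 and len(sparse) == 11
        assert tuple(s.order for s in seq) == DEFAULT_ORDERS
        assert max(s.order for s in seq) == MAX_ORDER == 16
        assert tuple(s.mask for s in sparse) == DEFAULT_MASKS


class TestContextId:
    def test_order1_hand_trace(self):
        # history "...A": h = 0b01; first bit of next base
        spec = ContextSpec("sequential", order=1)
        assert context_id(spec, h=0b01, bases_seen=5, bitpos=0) == (0b01 << 2) + 1

    def test_second_bit_includes_first(self):
        spec = ContextSpec("sequential", order=1)
        k0 = context_id(spec, 0b01, 5, bitpos=1, b0=0)
        k1 = context_id(spec, 0b01, 5, bitpos=1, b0=1)
        assert k0 != k1

    def test_cold_start_reserved_key(self):
        assert context_id(ContextSpec("sequential", order=4), 0b1111, 3, 0) == 0
        assert context_id(ContextSpec("sparse", mask=0xF0), 0xFFFF, 15, 0) == 0

    def test_distinct_masks_usually_distinct_keys(self):
        h = 0b11011000101
        a = context_id(ContextSpec("sparse", mask=0x0F), h, 20, 0)
        b = context_id(ContextSpec("sparse", mask=0xF0), h, 20, 0)
        assert a != b
        # masks whose picked bits coincide on this history collide
        c = context_id(ContextSpec("sparse", mask=0b0101), h, 20, 0)
        d = context_id(ContextSpec("sparse", mask=0b0011), h, 20, 0)
        assert (c == d) == (
            [(h >> o) & 1 for o in reversed(expand_mask(0b0101))]
            == [(h >> o) & 1 for o in reversed(expand_mask(0b0011))]
        )


class TestHistoryMaps:
    def test_fresh_context_is_half(self):
        p = predict(ContextSpec("sequential", order=1), BitHistory())
        assert p.p1 == 0.5

    def test_many_ones_confident(self):
        spec = ContextSpec("sequential", order=1)
        h = BitHistory()
        for _ in range(30):
            update(spec, h, 1)
        assert predict(spec, h).p1 > 0.9

    def test_balanced_stationary_near_half(self):
        spec = ContextSpec("sequential", order=1)
        h = BitHistory()
        for _ in range(20):
            update(spec, h, 0)
            update(spec, h, 1)
        assert 0.45 <= predict(spec, h).p_stationary <= 0.55

    def test_update_counts_and_run(self):
        spec = ContextSpec("sequential", order=1)
        h = BitHistory()
        update(spec, h, 1)
        assert (h.n1, h.s1) == (1, 1)
        update(spec, h, 1)
        assert h.run_len == 2
        update(spec, h, 0)
        assert (h.run_bit, h.run_len) == (0, 1)

    def test_nonstationary_halving(self):
        spec = ContextSpec("sequential", order=1)
        h = BitHistory(n0=200, n1=55)
        update(spec, h, 1)  # 200 + 56 > 255 -> halve (ceil)
        assert (h.n0, h.n1) == (100, 28)
        assert h.s1 == 1  # stationary counts unaffected at this scale


class TestKtCodeLength:
    def test_first_bit_costs_one(self):
        assert kt_code_length("0", ContextSpec("sequential", order=1)) == 1.0
        assert kt_code_length("1", ContextSpec("sequential", order=1)) == 1.0

    def test_all_zeros_order1_frozen_value(self):
        # two contexts (bit-position tag), 100 zero bits; value from the
        # direct KT recursion
        got = kt_code_length("0" * 100, ContextSpec("sequential", order=1))
        assert got == pytest.approx(8.689, abs=0.01)

    def test_sparse_beats_sequential_on_lag2_source(self):
        # s[i] = perm(s[i-2]) with prob 0.9; the matched sparse context
        # (base two back) concentrates the counts the contiguous order-2
        # context dilutes over the noisy intervening base
        perm = {"A": "C", "C": "G", "G": "T", "T": "A"}
        rng = random.Random(5)
        s = [rng.choice("ACGT"), rng.choice("ACGT")]
        for i in range(2, 4000):
            s.append(perm[s[i - 2]] if rng.random() < 0.9 else rng.choice("ACGT"))
        bits = base_to_bits("".join(s))
        cost_seq = kt_code_length(bits, ContextSpec("sequential", order=2))
        cost_sparse = kt_code_length(bits, ContextSpec("sparse", mask=0x0C))
        assert cost_sparse < cost_seq

    def test_structured_source_well_below_two_bits(self):
        bits = base_to_bits("ACGT" * 500)
        cost = kt_code_length(bits, ContextSpec("sequential", order=2))
        assert cost < 0.25 * len(bits)
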