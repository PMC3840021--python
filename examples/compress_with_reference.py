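"""Reference-based compression of a resequencing-style target.

Derives a target from a 500 kb reference at 0.1% substitution divergence
(the within-species regime), compresses it against the reference, and
compares with compressing the same target alone.  The adaptive window rule
picks the search range from the symbol-count difference percentage."""

from dnacm import (
    GenSpec,
    SequenceRecord,
    compress,
    decompress,
    diff_percentage,
    gen_iid,
    mutate_reference,
    select_window,
)

ref = gen_iid(GenSpec(length=500_000, seed=11))
tgt = mutate_reference(ref, sub_rate=0.001, seed=12)
record = SequenceRecord("sample vs reference", tgt)

pct = diff_percentage(tgt, ref)
win = select_window(pct)
print(f"difference percentage: {100 * pct:.3f}%  ->  window [{win.left}, {win.right}]")

with_ref = compress([record], mode="ref", reference=ref)
alone = compress([record])
restored = decompress(with_ref.to_bytes(), reference=ref)
assert restored[0].sequence == tgt

print(f"with reference:    {with_ref.size:,} bytes "
      f"({8 * with_ref.size / len(tgt):.4f} bpb)")
print(f"without reference: {alone.size:,} bytes "
      f"({8 * alone.size / len(tgt):.4f} bpb)")
print(f"ratio:             {100 * with_ref.size / alone.size:.2f}% "
      f"(mismatch literals + match tokens only)")
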