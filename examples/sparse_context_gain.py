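"""Why sparse (non-sequential) context models are in the bank.

On a source where the base two positions back determines the next base
(through a noisy permutation) and the intervening base is noise, a sparse
context that picks only the informative base concentrates its counts,
while the contiguous order-2 context dilutes them over the noise.  The
Krichevsky–Trofimov code length makes the advantage concrete."""

import random

from dnacm import ContextSpec, base_to_bits, kt_code_length

perm = {"A": "C", "C": "G", "G": "T", "T": "A"}
rng = random.Random(5)
s = [rng.choice("ACGT"), rng.choice("ACGT")]
for i in range(2, 4000):
    s.append(perm[s[i - 2]] if rng.random() < 0.9 else rng.choice("ACGT"))
bits = base_to_bits("".join(s))

sequential = kt_code_length(bits, ContextSpec("sequential", order=2))
sparse = kt_code_length(bits, ContextSpec("sparse", mask=0x0C))  # base 2 back only

print(f"lag-2 source, {len(s):,} bases ({len(bits):,} bits)")
print(f"sequential order-2 context: {sequential:.1f} bits")
print(f"sparse mask 0x0C context:   {sparse:.1f} bits")
print(f"sparse saves {sequential - sparse:.1f} bits by skipping the noisy base")
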