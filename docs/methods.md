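# Methods

This note records the model, the frozen format choices, the tunable
parameters, and what the synthetic evaluation does and does not show.

## The two-pass model

DNA carries two kinds of redundancy the two passes split between them:
long exact duplications (repeats, reverse-complement palindromes,
between-individual identity) and short-range statistical structure.
Pass 1 is substitutional — exact matches become tokens; pass 2 is
statistical — everything left is coded bit by bit under a mixture of
context models. The split matters because statistics-only coders pay for
long repeats symbol by symbol, while dictionary-only coders leave the
residue at nearly 2 bits/base.

### Pass 1, no reference

Greedy left-to-right scan; window = last `W` coded bases; at each cursor
the longest match of the lookahead in the window is taken over both
orientations if it reaches `L`, else one literal is emitted. Frozen rules:

* Matches lie entirely inside the coded window. No overlap into the
  lookahead: this keeps the offset invariant `p_offset ∈ [0, W − M]`, makes
  the reverse-complement copy well-defined at decode time, and costs little
  (a run of period *p* is still covered by matches that double in length
  each token).
* Ties: longest, then forward over reverse-complement, then the start
  nearest the cursor.
* Non-ACGT symbols never match (reverse complement is undefined for them);
  they break extensions and ride the pass-2 escape channel.
* Serialization per token: orientation bit, log-skewed(`p_offset + 1`),
  gamma(`M − L + 1`). The token flag itself is a reserved symbol in the
  pass-2 stream, so its cost adapts with the token density.

The production scan indexes `k = min(L, 12)`-mers with hash chains and is
verified against the brute-force definition exhaustively in the tests.
Defaults: `L = 25`, `W = 2^16` (both header parameters; `W` bounds offsets
and memory, and the format stores it, so any window can be chosen at
compression time).

### Pass 1, with reference

Within-species targets sit near their reference (human-scale divergence
~0.1%), so matching is anchored: a reference cursor advances past each
match's end, and the search covers reference starts in `[c + left,
c + right]`. The asymmetric default windows and the adaptive rule on the
symbol-count difference percentage (thresholds 0.65% and 5%; windows
[−12, 650], [−12, 812], [−12, 11560]) are format constants. Ties prefer
the smallest |offset| (downstream on a tie), matching the "longest and
nearest" intent; after a literal the cursor stays put. Matching is over
raw bytes, so extended alphabets and case participate; offsets are
zigzag-folded (0, −1, 1, −2, … → 1, 2, 3, 4, …) then gamma-coded, lengths
log-skewed — the mirror image of the no-reference pass, because here
lengths are long and offsets small. Decoding replays match positions
without searching, so it is far cheaper than encoding.

## Pass 2: the model bank

Bases are 2-bit packed (T 00, A 01, G 10, C 11; four bases per byte), so
the "last four bytes" of history are the last 16 bases and the maximum
sequential order is 16. Eleven sequential orders {1, 2, 4, 6, 8, 10, 11,
12, 13, 14, 16} and eleven 32-bit sparse pick-masks make up the default
bank; the masks are taken as fixed configuration. Both bits of a base are
separate binary decisions; the already-coded first bit and a bit-position
tag are part of every context, and positions with insufficient history
share a reserved cold-start context per model.

Each context's bit history drives three maps, all exposed to the mixer:

* run map — (last bit, run length), `p = 1 − 1/(r + 2)` on the run side;
* stationary map — KT add-½ ratio over uncapped counts;
* nonstationary map — the same ratio over counts halved (ceiling) when
  their sum exceeds 255, so stale evidence decays.

State lives in per-model hash tables of `2^table_bits` slots (default 18,
a header parameter) with a lossy policy: a 6-bit key checksum per slot,
reset on mismatch. At the ≤1 Mb scales this package targets, growing the
tables further showed no measurable rate change, while per-call
allocation stays a few tens of MB. Sparse-mask bit numbering (mask bit 0 =
most recent preceding bit) is a frozen convention; the masks are
self-consistent under either byte order.

## Mixer

`p_mix = σ(Σ wᵢ stretch(pᵢ))` with `stretch(p) = ln(p/(1−p))`; weights
start at zero (initial prediction exactly ½) and take an online gradient
step `wᵢ += η (bit − p_mix) stretch(pᵢ)`, clipped to ±20. A constant-rate
streamed update replaces batch Newton–Raphson refitting because the
decoder must replay the identical weight trajectory symbol by symbol.

η defaults to 0.002, calibrated on synthetic null and structured sources:
with 66 inputs (22 models × 3 maps), larger rates let the weights random-
walk on incompressible data — at η = 0.02 the measured overhead is ~0.10
bpb on uniform i.i.d. input, and structured sources are also coded worse.
η is a header parameter; the weight clip and the probability clamp
ε = 2⁻¹² are format constants. Engine detail: stretches are read from a
65536-entry lookup table, i.e. map probabilities are quantized to 16 bits
before mixing — the same resolution the coder itself uses.

## Arithmetic coder

A carry-correct binary range coder: 32-bit range, 33-bit low with cache
byte and pending-0xFF counter, probabilities quantized to 16-bit fixed
point, full-precision split `bound = (range · p16) >> 16`, byte-wise
renormalization below 2²⁴, 5-byte flush. Total overhead over the ideal
code length is 40 flush bits plus per-bit quantization slack below
`1/(bound · ln 2)` bits; the tests assert payload ≤ Σ −log₂ p + 64 bits
throughout. Bit 1 occupies the lower subinterval; MSB-first bit order in
the plain (token) bit streams.

## Escape channel

Each pass-1 item is either a base or an exception: an adaptive order-0
binary model codes the exception flag, and an order-1 byte model (context
= previous exception byte, bitwise tree decomposition) codes the byte.
Byte 0 is the reserved repeat-token marker; any other value is a literal
non-ACGT symbol. Exceptions never enter the bit-model history, so rare Ns
cannot corrupt base contexts; the worst case (no ACGT at all) degrades to
the order-1 byte model, bounded at 8 bpb.

## Container

`magic | version | JSON header | per-record token bits + payload`. The
header stores mode, `L`, `W` or per-record window, η, `table_bits`,
orders, masks, verbatim FASTA layout (header text, run-length-encoded
line widths, newline convention), per-record sizes and CRC32s, and in
reference mode the reference's name/length/CRC32, verified before
decoding. Records compress independently (state resets), matching
per-chromosome usage; FASTA metadata is stored uncompressed because the
sequence payload dominates and byte-exact file round trip is the
contract. Offsets are 0-based; all windows inclusive. Compression is
bit-deterministic: integer state throughout, fixed-order float64
arithmetic in the mixer, no fast-math.

## Krichevsky–Trofimov oracle

`kt_code_length` scores a bit string under any single context spec with
the KT estimator `(n_b + ½)/(n₀ + n₁ + 1)`, counts accumulated
sequentially. It exists to make claims about contexts testable without
the codec in the way. The sparse-beats-sequential property is verified on
a lag-2 source (`s[i] = g(s[i−2])` w.p. 0.9, noise otherwise): the mask
picking only the informative base concentrates counts the contiguous
context spreads over the noisy intervening base. Note the construction
must keep every position under the same lag-2 law — sources that are
periodic in *value* (alternating fixed/random positions) do not show the
effect, because dropping the intervening base also drops position parity
and the sparse context then pools statistically different positions.

## Synthetic data: what it shows and what it does not

`gen_iid` (uniform null, ~2 bpb), `gen_repeats` (i.i.d. backbone plus
dispersed/tandem copies, geometric lengths around 300, 30%
reverse-complemented, 1% point mutation inside copies, repeat mass ~50%),
and `mutate_reference` (independent per-position substitution/indel;
substitutions always change the symbol, so the rate is the realized
divergence). All draws come from one seeded PCG64 stream per spec.

Passing on these corpora demonstrates losslessness over the full symbol
space, correct repeat/palindrome discovery, the bracketed rates (i.i.d.
~2.04 bpb including container overhead; repeat-rich 1 Mb ~1.4 bpb;
reference mode at 0.1% divergence ~1.5% of the no-reference size), and
the qualitative parameter responses (rate falls with model order on
approximate-repeat corpora; rate is non-monotone in `L`). It does not
demonstrate rates on real genomes: the generators carry no approximate
long repeats with indels, no GC/isochore structure, and no positional
bias, and real-corpus rates additionally depend on corpus-specific repeat
content.

## Problem sizes

The test battery and the acceptance script run on synthetic inputs up to
1 Mb, with round-trip batteries drawing lengths log-uniformly up to
100 kb (tests) / 50 kb (script) — sizes chosen so the full evaluation
completes in minutes on one core while still exercising window wrap,
table collisions and multi-record containers.

## Known limitations

* Only exact repeats are substituted; approximate repeats are left to the
  context models (inherent to the design; visible on divergent
  duplications).
* The reference-mode encoder's window scan is O(window · literals) in
  diverged regions; the [−12, 11560] window on highly diverged pairs is
  slow by design (decoding is unaffected).
* One global weight vector; per-context weight sets are a known extension.
* Case-insensitive reference matching with a case mask is not
  implemented; matching is case-sensitive.
* Streaming/chunked compression of unbounded inputs is out of scope; a
  record is held in memory.
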