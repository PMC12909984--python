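# Methods

## The constellation and its entropy structure

A composite letter is the distribution σ = (σ_A, σ_T, σ_G, σ_C) realised by
mixing phosphoramidite monomers at one synthesis position. The package fixes
the axis order (A, T, G, C) everywhere. Restricting to equimolar mixtures of
k ∈ {1, 2, 3, 4} bases yields the 15 IUPAC letters, partitioned by support
size into four subsets — vertices {A,T,G,C}, edge centres {R,Y,M,K,S,W}, face
centres {H,B,V,D} and the centroid {N} — with theoretical Shannon entropies
log₂ k ∈ {0, 1, log₂ 3 ≈ 1.585, 2} bits. `CompositeLetter.theoretical_entropy`
stores the exact value. Four alphabets are built in: three 8-letter subsets
(mapped 3 bits → 1 letter, efficiency 100%) and the full 15-letter set
(15 bits → 4 base-15 digits, efficiency 15/(4·log₂15) ≈ 96%). Letter distance
is Euclidean on σ (configurable); it satisfies the metric axioms on all pairs.

ε-smoothing replaces exact zeros of σ with ε and renormalises; the default
ε = 10⁻⁶ keeps log-likelihoods finite without visibly moving the simplex
point.

## Coding layer

* **Outer code.** Shortened systematic Reed–Solomon over GF(2^m), narrow
  sense (generator roots α¹..α^{n−k}), with primitive polynomials
  x¹²+x⁶+x⁴+x+1 and x¹⁵+x+1 for the two production fields. Decoding follows
  the classical errors-and-erasures chain — syndromes, erasure locator,
  Forney syndromes, Berlekamp–Massey, Chien search, Forney magnitudes, then a
  syndrome re-check — and returns a typed failure (never a silent
  miscorrection beyond standard RS behaviour) whenever 2e + f > n − k.
  Shortening is implicit leading zeros; the shortened code is test-verified
  to agree with its parent code.
* **Interleaving.** A seeded uniform permutation of each codeword's n
  symbols (numpy PCG64, one seed per block, recorded in the sidecar). A lost
  strand erases 15 consecutive stream symbols; interleaving spreads them
  across the codeword.
* **Indices.** Small pools (≤126 strands): the double-end scheme — 5′ end
  BCH(15,7) codeword of the 7-bit address plus an even parity bit; 3′ end
  `p | address | p | rotl1(address)`. BCH(15,7) uses
  g(x) = x⁸+x⁷+x⁶+x⁴+1 (d = 5, t = 2; the standard narrow-sense generator —
  the generator is otherwise unconstrained: any d ≥ 5 cyclic (15,7) code meets the
  contract). Decoding corrects ≤ 2 bit errors, then requires each observed
  end to lie within one substituted nucleotide of the reconstructed reference
  indices for the candidate address; ends decoding to different addresses are
  rejected (crosstalk elimination; zero false accepts under exhaustive
  single-substitution audit). Both parity bits of the 3′ index derive from
  the original address. Bit pairs map to bases MSB-first: 00→A, 01→T, 10→G,
  11→C. Large pools use a generic, length-configurable codec (15-bit address,
  CRC-8 0x07, parity, zero pad per end; 3′ end address rotated left by one)
  with single-substitution correction by nearest-codeword lookup; it is *not*
  a reconstruction of any particular synthesized pool's index design.

## Channel model

Per-strand copy counts are negative binomial (Poisson–Gamma) with mean M
(the average coverage) and shape r; `dispersion=inf` selects the Poisson
limit. Fitted per-coverage (r, p) values from real pools are platform-specific
and not built in, so the default is r = 4 — over-dispersion well beyond Poisson (variance
M + M²/r) but short of collapse — and `fit_copy_distribution` (profile MLE
over r, Poisson fallback when variance ≤ mean) lets users calibrate r from
any real read set. Coverage-threshold results are therefore reported as a
sensitivity band over r ∈ {2, 4, 8} rather than a single number.

Composite positions are instantiated i.i.d. from σ. Errors are per position,
mutually exclusive: substitution (uniform over the other three bases) with
probability P_sub, deletion P_del, insertion of a uniform base after the
position P_ins; the expected event count over k positions is
k·(P_ins+P_del+P_sub). Placement of insertions and the substitution target
distribution are unspecified upstream; these are the simplest symmetric
choices. The default error preset is (P_ins, P_del, P_sub) =
(0.001, 0.001, 0.002). Strand breakage (`break_rate`) truncates a read at a
uniform point strictly between the primer segments, keeping either side with
probability ½, so every broken read retains exactly one intact primer — an
in-silico analogue of thermal degradation in which ~14% single-primer reads
correspond to `break_rate=0.14`. Qualities are constant placeholders; the
pipeline never reads them.

What the simulator does *not* emulate: PCR-bias mechanisms beyond NB
over-dispersion, platform quality profiles, context-dependent error rates,
chimeras, and synthesis failures of whole strands. Passing tests therefore
show correctness of the pipeline under a clean, symmetric channel, not
performance on any particular instrument's reads.

## Detection

Stage 1 computes P_{i,α} = r_{i,α}/Σr and h_i = −ΣP log₂ P (0·log 0 = 0,
entropy on raw frequencies, no smoothing) and assigns the nearest decision
level, ties toward the lower level. The decision levels are (0, 1, 1.5, 2)
bits — the procedure's working comparison values — rather than the
exact (0, 1, log₂ 3, 2): the plug-in entropy estimator is biased downward by
≈ (k−1)/(2n ln 2) bits at support n, and the 1.5 level partially compensates
exactly where subset confusion occurs (it measurably reduces subset-3/4
misassignment at 20–30 reads). The exact levels remain available via the
`levels` argument. Stage 2 maximises l(σ, r_i) = Σ r_{i,α} ln σ_α over the
assigned subset's letters intersected with the configured alphabet (natural
log; argmax-invariant; ties broken by alphabet order). An empty intersection
(sub-alphabets without 3- or 4-base letters) falls back to full-alphabet MLE
and is counted. Zero-support positions are erasures, not guesses — erasures
cost the RS budget 1 where errors cost 2 — and no minimum-support threshold
is applied beyond support > 0.

Comparators: `map_detect` is the whole-alphabet argmax of log-likelihood plus
log prior (uniform prior by default, i.e. global MLE); `kl_detect` minimises
KL(P̂‖σ) with both distributions ε-smoothed. On a shared pileup, minimum-KL
and maximum-likelihood are argmax-equivalent (the entropy term is constant in
the candidate), so the two differ only through observed-frequency smoothing.
A meaningful three-way comparison — MAP best, SP close behind at a quarter of
the cost, KL clearly worst — emerges when the MAP comparator is made
noise-aware, standing in for a soft-decision decoder: `compare_detectors`
runs MAP with channel-matched smoothing ε = P_sub/3, which is exactly the
first-order emission probability of a foreign base under uniform three-way
substitution, while SP and KL keep ε = 10⁻⁶. With ε = 10⁻⁶ for all three,
plain MLE is instead *worse* than SP at low support, because a single
substituted base incurs a ln ε ≈ −13.8 penalty that overturns any pure
letter for supports below ~20 — the set-partitioning stage is precisely what
shields the pure letters from this failure mode.

## Readout pipeline

Merging is a naive longest-overlap consensus (≥20 nt, ≤10% mismatch, R1 wins
conflicts) — simulation reads are well-behaved; real paired data can be
merged externally and fed as single-end FASTQ. Primer location is a
substitution-only Hamming scan (≤2 mismatches) within ±4 nt of the expected
positions with a global-scan fallback, on both orientations; reads with
indels inside a primer are intentionally lost either here or at the next
step. The exact-length filter keeps only regions of the designed interior
length — cancelling insertion+deletion pairs are a documented residual risk.
Grouping decodes both indices, requires agreement, and accumulates per-strand
pileups. After detection, letters map back to bits; any 4-letter group with
an erased letter, or whose base-15 value exceeds 2¹⁵−1, becomes an erased RS
symbol. Per block: de-interleave, errors-and-erasures decode, re-check
syndromes; a failed block is reported, never silently wrong. Zero padding
(recorded at encode time in the YAML sidecar, since the stored files sit
slightly under capacity) is stripped at the end.

## Problem sizes and reproducibility

Every stochastic stage takes an explicit seed; a full pipeline run is
deterministic given (data seed, channel seed, interleaver seed). The test
suite exercises the production-scale configuration — 32,767 strands,
RS(32767, 27767) over GF(2¹⁵), ~10⁶ simulated reads — once per dispersion
value at 30× coverage; the remaining statistical properties use the
126-strand column preset (10–12 seeds per condition) and a 50-strand
15-letter pool (6 seeds), sizes at which the asserted orderings are stable
across seeds. The acceptance script encodes the two large-pool files
(234,375 and 780,713 bytes) in full.

## Known limitations

* The 30× recovery claim for the 15-letter simulation configuration is
  dispersion-sensitive: byte-exact recovery holds at r = 8 (letter error
  ≈ 1.6%), while r = 4 (≈ 2.5%) and r = 2 (≈ 5.0%) exceed the RS budget at
  that coverage. No fitted per-coverage dispersion is available to pin the channel; the test suite asserts recovery at r = 8 and
  the monotone dependence on r.
* NB-LDPC decoding is out of scope: the `8col-ldpc` preset carries the frame
  layout and capacity arithmetic only, and the decode path raises for
  non-RS outer codes rather than pretending.
* The detector is hard-decision letter-by-letter; no soft information is
  passed to the RS decoder.
* Experimental coverage thresholds (9×/14×/33×) and read-retention fractions
  depend on the real pools' copy-count distributions and error profiles and
  are not asserted; their qualitative counterparts (monotone success curves,
  filter benefit, index pass rates) are.
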