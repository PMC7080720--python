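# Methods

## The detection model

The screening question is binary per vector position: does the test read
set contain more copies of this position's k-mer than a vector-free
wild-type read set of the same organism would? All k-mers of all reads on
both strands are matched **exactly** — no alignment, no mismatch
tolerance, no reference genome — against the vector, whose circular
topology is handled by appending its first k−1 bases before windowing so
every one of its L bases carries a window and boundary-spanning k-mers are
captured. Exactness is the point: unlike heuristic read mappers, any two
correct implementations of string identity agree, which makes results
reproducible across laboratories.

Per position the 2×2 table (matching vs all other k-mers × test vs
contrast) is tested with the likelihood-ratio G statistic,

    G = 2 Σ_cells O ln(O/E),  df = 1,

under a design with both margins free (Model II in the Sokal & Rohlf
taxonomy). The marginals n₁, n₂ are each sample's *global* k-mer totals,
identical for every position — the test compares "identical k-mers"
against "all the other k-mers". Significance is one-sided by adoption: a
position is called only if G ≥ the chi-square(1) critical value (6.634 at
α = 0.01, always recomputed from α) *and* the excess lies in the test
sample. A simulated insert of length L′ is *detected* when at least one of
its eligible positions — k-windows fully inside the source interval, the
only windows that physically exist in the edited genome — is significant;
k > L′ is undefined (no such window exists). Significant positions outside
the eligible region are false positives.

Assumptions worth stating: reads are pre-trimmed (qualities are parsed and
discarded); k-mer identity is only meaningful over {A,C,G,T}, so windows
containing N are skipped on both the read and vector side, and other IUPAC
ambiguity codes are rejected (strict mode, default) or mapped to N
(lenient); the contrast genuinely carries no vector DNA.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| k | 20 | nt | shortest word length at which crop-scale genomes occupy a negligible fraction of the 4^k pattern space; k = 10 is saturated and unusable, k ≥ 25 is typically disjoint from the host |
| α | 0.01 | — | per-position significance level; G threshold 6.634 follows from it |
| williams | off | — | Williams' correction G/q, q = 1 + (n/n₁+n/n₂−1)(n/m₁+n/m₂−1)/6n; at realistic totals it shifts the borderline count threshold from 5 to 6 matching reads |
| read_length | 100 | nt | short-read (SBS) regime |
| fragment_mean / sd | 500 / 50 | nt | paired-end library insert size |
| error_rate | 0.003 | subst/base | idealized SBS substitution rate |
| coverage | 50 | × | total read nt / genome nt |
| iterations | 1000 | — | Monte-Carlo campaign size |

## Statistical behaviour at the detection margin

With b = 0 in the contrast and huge totals, G → 2a·ln 2, so raw G crosses
6.634 at a = 5 matching k-mers, and Williams-corrected G (q → 1 + 1/2a) at
a = 6. Matching k-mers for a planted L′ = k = 20 segment arrive
approximately as Poisson with mean 0.81·c·(1−e)^20 (81 window offsets per
100-nt read, depth c, error rate e), i.e. ≈ 7.6 at 10×. The two count
thresholds therefore produce visibly different shallow-depth accuracies
(≈ 88% raw vs ≈ 77% corrected at 10×), converging above 20×; the campaign
harness always reports both columns. Uncorrected G with the 0·ln 0 = 0
convention remains the default because the stated critical value 6.634 is
the raw chi-square quantile; an all-zero table is defined as G = 0 (no
evidence), and a tie at exactly the threshold counts as significant.

False positives at k ≥ 20 on a vector-free-genome simulation are dominated
not by chance sequence sharing but by **junction extension**: the genome
base flanking the inserted segment equals the adjacent vector base with
probability 1/4, making the neighbouring (overlapping) vector window a
genuine match of the edited genome. Expected junction calls per run are
≈ 2·Σ_{d≥1} 4^-d = 2/3, which is what the campaigns measure — below the
1-per-run design bound, and irreducible without changing the
position-based false-positive definition.

## What the simulator emulates — and what it does not

The generator produces i.i.d. uniform random genomes, uniform fragment
starts, Normal(500, 50) fragment lengths (rounded, clipped to
[read_length, genome_end]), FR-oriented mates, and uniform substitution
errors (an erroneous base is always changed; N never is). It deliberately
omits GC/fragmentation bias, PCR duplicates, quality decay, indels and
real genome composition. Consequences: passing calibration tests show the
*statistical machinery* behaves as designed under ideal sampling, and
true-positive power transfers to real data because it is locus-local; they
do **not** bound false-positive rates on real genomes at small k, which
are composition-driven (a real crop genome shares orders of magnitude more
10/15-mers with a vector than the uniform null predicts). Small-k cells of
the campaigns are therefore genome-dependent and only meaningful with a
real host genome supplied.

## Numerical choices

- Bases are 2-bit codes; a k-mer is an integer built by a rolling 2-bit
  shift, exact in int64 for k ≤ 31. No canonicalization: a palindromic
  k-mer seen from both strands legitimately counts twice, and both strands
  are folded into one scan by indexing each vector position under its
  forward *and* reverse-complement pattern (provably the same counts).
- Matching streams read windows through a coarse presence table over the
  top bits of the code space, then binary-searches survivors in the sorted
  vector pattern array; a pattern occurring at m vector positions
  increments all m.
- G is computed cell-wise as 2·Σ O ln(O/E) with `xlogy` so O/E stays near
  1 and the statistic is well conditioned even at 10^10-scale totals
  (an n·ln n regrouping loses ~1e-9 there); zero margins are handled by
  zero-weight substitution; tiny negative rounding residue is clipped at 0.
- Campaign RNG streams derive as base_seed + iteration (mod 2^31), so any
  single trial is reproducible in isolation from the persisted trial table.
- Degenerate inputs: reads shorter than k yield no k-mers (not an error);
  an empty read set is an error ("empty sample"); k > vector length is an
  error; k > insert length is undefined by construction and reported as
  such per campaign cell, never raised mid-campaign.

## Design choices that were genuinely open

- **Contrast depth** equals test depth in all simulations (the symmetric
  choice; nothing in the method requires it).
- **One insert per iteration**; concurrent inserts are out of scope.
- **False positives are counted as positions**, not as merged runs of
  consecutive significant windows.
- **Census strands**: pattern sets include both strands (the detector is
  strand-agnostic), so censuses are closed under reverse complement and
  the shared-set expectation uses both-strand distinct counts,
  E = n_g·n_v/4^k.
- **Fragment starts** are uniform over [0, genome − read_length]; lengths
  below read_length are clipped up, not resampled (negligible at 500±50).
- **Problem sizes**: the bundled campaigns run on a 100-kb synthetic
  genome with a synthetic 6,646-bp circular vector — large enough that
  detection power (locus-local) and the junction false-positive mechanism
  are unchanged from crop scale, small enough for a desk-scale run; the
  pattern-census saturation demonstration uses a 10-Mb genome, the size at
  which the expected number of missing 10-mers (4^10·e^(−2L/4^10)) drops
  below 10^-2.

## Known limitations

- Exact matching cannot see inserts carrying even one sequencing- or
  editing-induced substitution inside every window (mitigated by depth:
  with 0.3% errors a 20-window is clean with probability 0.94 per read).
- The per-position tests are strongly dependent (adjacent windows share
  k−1 bases); α controls the per-position rate, not a family-wise one —
  deliberately, since the judgement needs only one true position.
- Circular-origin-wrapping inserts are represented on the extended
  coordinate; reporting maps them back modulo L.
- Real-data contrasts carry their own contamination risk (library kits);
  an unexpectedly large number of wild-type hits is a signal to change
  kits, not a detector failure.
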