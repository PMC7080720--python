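"""k-mer pattern census: saturation against 4^k and genome/vector sharing.

How many of the 4^k possible k-nucleotide patterns does a sequence set
actually contain?  For small k any sizeable genome saturates the space
(every pattern occurs), which is why very short foreign segments are
statistically invisible; as k grows the occupied fraction collapses and
sharing between unrelated sequences becomes rare.  Patterns are collected
from both strands (the detection method is strand-agnostic), so the pattern
set is closed under reverse complement and a census of a sequence equals
the census of its reverse complement.

The shared-pattern null expectation between a genome and a vector with
``n_g`` and ``n_v`` distinct patterns is ``n_g * n_v / 4**k`` (each vector
pattern lands in the genome's set with probability n_g / 4^k under a
uniform-random null).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .kmer_engine import window_codes
from .seqio import NucleotideSequence, decode_bases

__all__ = [
    "PatternCensus",
    "SharedPatternResult",
    "pattern_census",
    "shared_patterns",
    "expected_pattern_occurrences",
]

#: above this k the dense 4^k presence table would not fit; use sorted codes
DENSE_K_MAX = 13
#: refuse full distinct-pattern counts above this many windows unless forced
LARGE_WINDOW_LIMIT = 200_000_000


@dataclass(frozen=True)
class PatternCensus:
    k: int
    distinct_count: int
    theoretical_total: int

    @property
    def fraction(self) -> float:
        return self.distinct_count / self.theoretical_total


@dataclass(frozen=True)
class SharedPatternResult:
    k: int
    observed: int
    expected: float
    n_genome: int
    n_vector: int
    #: pattern -> (genome positions, vector positions); forward-strand
    #: left-end coordinates of either orientation of the pattern
    patterns: dict


def expected_pattern_occurrences(sequence_length: int, k: int) -> float:
    """Expected occurrences of one specific k-mer in an i.i.d. random
    sequence of the given length (single strand): (L - k + 1) / 4^k."""
    return max(0, sequence_length - k + 1) / float(4**k)


def _both_strand_codes(seqs: Iterable[NucleotideSequence], k: int) -> list[np.ndarray]:
    """Valid window codes of every sequence and its reverse complement."""
    chunks: list[np.ndarray] = []
    for s in seqs:
        codes = s.codes()
        if codes.shape[0] < k:
            continue
        for strand in (codes, np.where(codes == 4, 4, 3 - codes)[::-1].astype(np.uint8)):
            win, valid = window_codes(strand, k)
            chunks.append(win[valid])
    return chunks


def _distinct(chunks: list[np.ndarray], k: int) -> np.ndarray:
    if not chunks:
        return np.empty(0, dtype=np.int64)
    if k <= DENSE_K_MAX:
        table = np.zeros(4**k, dtype=bool)
        for c in chunks:
            table[c] = True
        return np.flatnonzero(table)
    return np.unique(np.concatenate(chunks))


def pattern_census(
    seqs: Sequence[NucleotideSequence] | NucleotideSequence,
    k: int,
    force: bool = False,
) -> PatternCensus:
    """Distinct k-mer patterns over all sequences, both strands, N-skipped.

    For k > 13 with very large inputs this is a big sort; such runs must be
    explicitly allowed with ``force=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    total_windows = sum(2 * max(0, len(s) - k + 1) for s in seqs)
    if k > DENSE_K_MAX and total_windows > LARGE_WINDOW_LIMIT and not force:
        raise MemoryError(
            f"census at k={k} over {total_windows} windows is a large-memory "
            "operation; pass force=True to run it"
        )
    chunks = _both_strand_codes(seqs, k)
    distinct = _distinct(chunks, k)
    return PatternCensus(k=k, distinct_count=int(distinct.size), theoretical_total=4**k)


def _code_to_pattern(code: int, k: int) -> str:
    digits = np.empty(k, dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        digits[i] = code & 3
        code >>= 2
    return decode_bases(digits)


def _positions_of(seqs: Iterable[NucleotideSequence], k: int, targets: np.ndarray) -> dict:
    """1-based forward-strand left ends where any target code's pattern (in
    either orientation) occurs, keyed by target code."""
    hits: dict[int, list] = {int(c): [] for c in targets}
    tset = np.sort(targets)
    for s in seqs:
        codes = s.codes()
        if codes.shape[0] < k:
            continue
        fwd, fvalid = window_codes(codes, k)
        rc_full = np.where(codes == 4, 4, 3 - codes)[::-1].astype(np.uint8)
        rcw, _ = window_codes(rc_full, k)
        rc_at = rcw[::-1]  # RC pattern of the forward window at each position
        for arr in (fwd, rc_at):
            idx = np.searchsorted(tset, arr)
            ok = fvalid & (idx < tset.size) & (tset[np.minimum(idx, tset.size - 1)] == arr)
            for p in np.flatnonzero(ok):
                hits[int(arr[p])].append((s.id, int(p) + 1))
    return hits


def shared_patterns(
    genome_seqs: Sequence[NucleotideSequence] | NucleotideSequence,
    vector: NucleotideSequence,
    k: int,
    force: bool = False,
    collect_positions: bool = True,
) -> SharedPatternResult:
    """Distinct patterns present in both the genome set and the vector.

    The genome is streamed against the (small) vector pattern set, so only
    the *distinct genome count* needed for the null expectation requires the
    full census; positions of the shared patterns in both sequences are
    reported (both orientations, forward-strand coordinates).
    """
    if k > len(vector):
        raise ValueError(f"k={k} exceeds vector length {len(vector)}")
    if isinstance(genome_seqs, NucleotideSequence):
        genome_seqs = [genome_seqs]
    vec_ext = [vector] if not vector.is_circular else [
        NucleotideSequence(vector.id, vector.bases + vector.bases[: k - 1], "linear")
    ]
    vec_distinct = _distinct(_both_strand_codes(vec_ext, k), k)
    n_v = int(vec_distinct.size)

    gen_distinct = _distinct(_both_strand_codes(genome_seqs, k), k)
    n_g = int(gen_distinct.size)
    shared = np.intersect1d(gen_distinct, vec_distinct, assume_unique=True)
    expected = n_g * n_v / float(4**k)

    patterns: dict = {}
    if collect_positions and shared.size:
        gpos = _positions_of(genome_seqs, k, shared)
        vpos = _positions_of(vec_ext, k, shared)
        patterns = {
            _code_to_pattern(int(c), k): (gpos[int(c)], vpos[int(c)]) for c in shared
        }
    return SharedPatternResult(
        k=k,
        observed=int(shared.size),
        expected=expected,
        n_genome=n_g,
        n_vector=n_v,
        patterns=patterns,
    )
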