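"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: counting
is a double loop of string comparisons, and the G oracle is the
two-binomial versus pooled-binomial log-likelihood ratio.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from kmerscreen import NucleotideSequence, build_vector_index, KmerConfig


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def string_revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(s))


def oracle_count_positions(reads: list[str], vector: NucleotideSequence, k: int):
    """Brute-force per-position count: compare every read-strand window with
    every vector window by string equality.  Returns (counts, total_kmers)."""
    ext = vector.bases + (vector.bases[: k - 1] if vector.is_circular else "")
    n_pos = len(vector) if vector.is_circular else len(vector) - k + 1
    counts = np.zeros(len(vector), dtype=np.int64)
    total = 0
    for read in reads:
        for strand in (read, string_revcomp(read)):
            for i in range(len(strand) - k + 1):
                w = strand[i : i + k]
                if "N" in w:
                    continue
                total += 1
                for p in range(n_pos):
                    vw = ext[p : p + k]
                    if "N" not in vw and vw == w:
                        counts[p] += 1
    return counts, total


def oracle_g(a: int, b: int, n1: int, n2: int) -> float:
    """2 x (log-likelihood of two free binomials minus pooled binomial)."""

    def ll(x: int, n: int, p: float) -> float:
        out = 0.0
        if x > 0:
            out += x * math.log(p)
        if n - x > 0:
            out += (n - x) * math.log(1.0 - p)
        return out

    p1, p2 = a / n1, b / n2
    pp = (a + b) / (n1 + n2)
    return 2.0 * (ll(a, n1, p1) + ll(b, n2, p2) - ll(a, n1, pp) - ll(b, n2, pp))


@pytest.fixture(scope="session")
def colE1_like_vector() -> NucleotideSequence:
    """A synthetic circular 6,646-bp stand-in for the ColE1 model vector
    (same length and topology, i.i.d. random composition)."""
    rng = np.random.default_rng(6646)
    return NucleotideSequence("synthetic_colE1_like", random_dna(rng, 6646), "circular")


@pytest.fixture(scope="session")
def vector_index_k20(colE1_like_vector) -> object:
    return build_vector_index(colE1_like_vector, KmerConfig(20))
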