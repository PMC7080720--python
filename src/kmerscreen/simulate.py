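"""Synthetic data engine: genomes, vector-segment insertion, paired-end reads.

Emulates an ideal short-read run of the kind the detection method is
calibrated against: 100-nt paired-end reads from fragments of length
Normal(500, 50), sampled uniformly over the genome, with 0.3% uniform
substitution errors (an idealized sequencing-by-synthesis error rate; no
indels, no quality profile, no GC or fragmentation bias).  Coverage is
defined as total read nucleotides divided by genome length.

The foreign-DNA scenario inserts a segment excised uniformly at random from
the (circular) vector into a uniformly random genome position, recording
the ground truth so detection outcomes can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .seqio import NucleotideSequence, ReadPair, decode_bases

__all__ = [
    "ReadSimConfig",
    "InsertTruth",
    "random_genome",
    "insert_segment",
    "insert_segment_codes",
    "simulate_reads",
    "simulate_read_codes",
]


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters (defaults are the calibration conditions)."""

    read_length: int = 100
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    error_rate: float = 0.003
    coverage: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def n_pairs(self, genome_length: int) -> int:
        return int(round(self.coverage * genome_length / (2.0 * self.read_length)))


@dataclass(frozen=True)
class InsertTruth:
    """Ground truth of one simulated insertion.

    ``vector_start``/``vector_end`` are 1-based inclusive on the vector
    forward coordinate; a segment wrapping the circular origin is kept on
    the extended coordinate (``vector_end`` may exceed the vector length;
    positions map back modulo the length).  ``genome_position`` is the
    1-based coordinate of the first inserted base in the modified genome.
    """

    vector_start: int
    vector_end: int
    genome_position: int

    @property
    def length(self) -> int:
        return self.vector_end - self.vector_start + 1


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_genome(length: int, seed, id: str = "synthetic_genome") -> NucleotideSequence:
    """I.i.d. uniform A/C/G/T genome of the given length, reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    codes = _rng(seed).integers(0, 4, size=length, dtype=np.uint8)
    return NucleotideSequence(id, decode_bases(codes), "linear")


def insert_segment_codes(
    genome_codes: np.ndarray, vector_codes: np.ndarray, L: int, rng: np.random.Generator,
    circular: bool = True,
) -> tuple[np.ndarray, InsertTruth]:
    """Code-array core of :func:`insert_segment` (used by the campaign loop)."""
    vlen = vector_codes.shape[0]
    if not 1 <= L <= vlen:
        raise ValueError(f"insert length {L} must be in 1..{vlen}")
    start = int(rng.integers(1, vlen + 1)) if circular else int(rng.integers(1, vlen - L + 2))
    end = start + L - 1
    if end <= vlen:
        seg = vector_codes[start - 1 : end]
    else:  # wraps the circular origin
        seg = np.concatenate([vector_codes[start - 1 :], vector_codes[: end - vlen]])
    gpos = int(rng.integers(0, genome_codes.shape[0] + 1))  # insert after gpos bases
    modified = np.concatenate([genome_codes[:gpos], seg, genome_codes[gpos:]])
    return modified, InsertTruth(start, end, gpos + 1)


def insert_segment(
    genome: NucleotideSequence, vector: NucleotideSequence, L: int, seed
) -> tuple[NucleotideSequence, InsertTruth]:
    """Excise a random L-nt vector segment and insert it at a random genome
    position; returns the modified genome and the ground truth."""
    rng = _rng(seed)
    mod, truth = insert_segment_codes(
        genome.codes(), vector.codes(), L, rng, circular=vector.is_circular
    )
    return (
        NucleotideSequence(genome.id + "_ins", decode_bases(mod), "linear"),
        truth,
    )


def simulate_read_codes(
    genome_codes: np.ndarray, cfg: ReadSimConfig, rng: np.random.Generator,
    return_layout: bool = False,
):
    """All reads of a run as one uint8 code array, shape (2*n_pairs, read_length).

    Rows 0..n_pairs-1 are R1 (forward fragment start), rows n_pairs.. are R2
    (reverse complement of the fragment end) — the standard FR orientation.
    Substitution errors flip each base to a uniformly chosen different base.
    With ``return_layout`` also returns the 0-based fragment starts and the
    realized fragment lengths.
    """
    G = genome_codes.shape[0]
    rl = cfg.read_length
    if G < cfg.fragment_mean:
        raise ValueError(f"genome length {G} is shorter than fragment_mean {cfg.fragment_mean}")
    n = cfg.n_pairs(G)
    starts = rng.integers(0, G - rl + 1, size=n)
    flen = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n)).astype(np.int64)
    flen = np.clip(flen, rl, G - starts)
    offs = np.arange(rl, dtype=np.int64)
    r1 = genome_codes[starts[:, None] + offs]
    ends = starts + flen
    r2f = genome_codes[(ends - rl)[:, None] + offs]
    r2 = np.where(r2f == 4, 4, 3 - r2f)[:, ::-1].astype(np.uint8)
    reads = np.concatenate([r1, r2]).astype(np.uint8, copy=False)
    if cfg.error_rate > 0:
        total = reads.size
        n_err = rng.binomial(total, cfg.error_rate)
        if n_err:
            flat = reads.reshape(-1)
            pos = rng.integers(0, total, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            tmpl = flat[pos]
            flat[pos] = np.where(tmpl == 4, 4, (tmpl + shift) % 4)  # N stays N
    if return_layout:
        return reads, starts, flen
    return reads


def simulate_reads(
    genome: NucleotideSequence, cfg: ReadSimConfig, seed
) -> Iterator[ReadPair]:
    """Stream simulated read pairs (string API over :func:`simulate_read_codes`)."""
    rng = _rng(seed)
    codes = simulate_read_codes(genome.codes(), cfg, rng)
    n = codes.shape[0] // 2
    for i in range(n):
        r1 = NucleotideSequence(f"sim_{i}/1", decode_bases(codes[i]), "linear")
        r2 = NucleotideSequence(f"sim_{i}/2", decode_bases(codes[n + i]), "linear")
        yield ReadPair(r1, r2, pair_id=f"sim_{i}")
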