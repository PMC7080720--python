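"""Sequence containers and FASTA/FASTQ I/O.

Sequences are held as plain upper-case strings over the alphabet
``{A, C, G, T, N}`` together with an explicit topology flag: the cloning
vector is circular, genomes and reads are linear.  Circularity is never
inferred from the data — it is declared by the caller.

Quality strings are parsed and discarded: the detection method operates on
bases only, and reads are assumed to be already quality-trimmed upstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "ReadPair",
    "AlphabetError",
    "FastaParseError",
    "PairingError",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "reverse_complement",
    "encode_bases",
    "decode_bases",
]

STRICT_ALPHABET = frozenset("ACGTN")
#: IUPAC one-letter ambiguity codes accepted in lenient mode (mapped to N).
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 2-bit base codes used by the numeric k-mer machinery; N is the sentinel 4.
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE_OF[ord(_b)] = _i
    _CODE_OF[ord(_b.lower())] = _i
_BASE_OF = np.frombuffer(b"ACGTN", dtype=np.uint8)


class AlphabetError(ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input (empty record, blank header, ...)."""


class PairingError(ValueError):
    """Paired FASTQ files disagree (record counts, truncation)."""


def _normalize(bases: str, strict: bool) -> str:
    up = bases.upper()
    bad = set(up) - STRICT_ALPHABET
    if not bad:
        return up
    if strict:
        raise AlphabetError(
            "sequence contains characters outside {A,C,G,T,N}: "
            + ", ".join(sorted(bad))
        )
    non_iupac = bad - IUPAC_AMBIGUITY
    if non_iupac:
        raise AlphabetError(
            "sequence contains non-IUPAC characters: " + ", ".join(sorted(non_iupac))
        )
    return up.translate(str.maketrans({c: "N" for c in bad}))


@dataclass
class NucleotideSequence:
    """A named DNA sequence with explicit topology.

    Parameters
    ----------
    id:
        Free-text identifier.
    bases:
        Sequence string; lower case is accepted and upcased.  In strict mode
        (default) only ``{A,C,G,T,N}`` are allowed; in lenient mode other
        IUPAC ambiguity codes are mapped to ``N``.
    topology:
        ``"linear"`` (genomes, reads) or ``"circular"`` (vector).
    """

    id: str
    bases: str
    topology: str = "linear"
    strict: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        self.bases = _normalize(self.bases, self.strict)
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def codes(self) -> np.ndarray:
        """2-bit base codes (A=0, C=1, G=2, T=3, N=4) as a uint8 array."""
        return encode_bases(self.bases)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, reverse_complement(self.bases), self.topology)


@dataclass
class ReadPair:
    """Two mates of a paired-end read, paired by file order."""

    r1: NucleotideSequence
    r2: NucleotideSequence
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not self.pair_id:
            self.pair_id = self.r1.id


def reverse_complement(s: str) -> str:
    """Reverse complement of a base string; N maps to N."""
    up = s.upper()
    bad = set(up) - STRICT_ALPHABET
    if bad:
        raise AlphabetError(
            "cannot reverse-complement characters: " + ", ".join(sorted(bad))
        )
    return up.translate(_COMPLEMENT)[::-1]


def encode_bases(bases: str) -> np.ndarray:
    arr = _CODE_OF[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise AlphabetError("sequence contains characters outside {A,C,G,T,N}")
    return arr


def decode_bases(codes: np.ndarray) -> str:
    return _BASE_OF[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def _open_text(path) -> "object":
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    # sniff gzip magic so misnamed files still work
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, topology: str = "linear", strict: bool = True) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file into a list of sequences, in file order.

    Topology defaults to linear; pass ``topology="circular"`` when reading a
    circular vector — circularity is a declaration, never auto-detected.
    """
    out: list[NucleotideSequence] = []
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            if not rec.id:
                raise FastaParseError(f"{path}: record {i} has an empty header")
            bases = str(rec.seq)
            if not bases:
                raise FastaParseError(f"{path}: record {i} ({rec.id}) is empty")
            try:
                out.append(NucleotideSequence(rec.id, bases, topology, strict=strict))
            except AlphabetError as e:
                raise AlphabetError(f"{path}: record {rec.id}: {e}") from e
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA (canonical line width 70)."""
    with open(path, "wt") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def _fastq_records(path, strict: bool):
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq"), start=1):
            bases = str(rec.seq)
            if not bases:
                raise PairingError(f"{path}: FASTQ record {i} ({rec.id}) is empty")
            yield NucleotideSequence(rec.id, bases, "linear", strict=strict)


def read_fastq_pairs(path_r1, path_r2, strict: bool = True) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files (optionally gzipped).

    Mates are paired by file order; a record-count mismatch raises
    :class:`PairingError` reporting both counts.  Quality strings are
    discarded.
    """
    it1 = _fastq_records(path_r1, strict)
    it2 = _fastq_records(path_r2, strict)
    n1 = n2 = 0
    sentinel = object()
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            # drain the longer file to report true counts
            if a is sentinel:
                n2 += 1 + sum(1 for _ in it2)
            else:
                n1 += 1 + sum(1 for _ in it1)
            raise PairingError(
                f"paired FASTQ record counts differ: {n1} vs {n2} "
                f"({path_r1} vs {path_r2})"
            )
        n1 += 1
        n2 += 1
        yield ReadPair(a, b)  # type: ignore[arg-type]
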