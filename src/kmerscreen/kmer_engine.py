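"""Vector k-mer index and per-position exact-match counting.

The vector (a circular plasmid) is indexed by the 1-based left end of every
k-nucleotide window on its forward strand; for a circular vector the first
k-1 bases are appended before windowing so boundary-spanning windows are
captured and every position 1..L carries a window.  Read k-mers from *both*
strands are then matched exactly against the index and every occurrence
position of a matching pattern is incremented.

Strand handling is folded for speed: instead of extracting windows from a
read and its reverse complement and comparing both against forward vector
patterns, the index stores, for every vector position, the window pattern
*and* its reverse complement, and only forward read windows are scanned.
The two formulations count exactly the same events (reverse-strand windows
of a read are the reverse complements of its forward windows), including
the double count a palindromic k-mer legitimately receives.

Internally bases are 2-bit codes and a k-mer is the integer
``sum(code[i] * 4**(k-1-i))``, computed with a rolling 2-bit shift, so k up
to 31 fits exactly in int64.  No canonicalization and no mismatch tolerance anywhere:
identity is the whole point of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .seqio import NucleotideSequence, ReadPair, decode_bases

__all__ = [
    "KmerConfig",
    "VectorKmerIndex",
    "PositionCountTable",
    "build_vector_index",
    "extract_read_kmers",
    "count_positions",
    "window_codes",
]

N_CODE = 4
MAX_K = 31  # 2k bits must fit an int64 code


@dataclass(frozen=True)
class KmerConfig:
    """Word length for the analysis (useful screening range is roughly 10-50)."""

    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all length-k windows of one or more base-code rows.

    Parameters
    ----------
    codes:
        uint8 array, shape (length,) or (n_rows, length), values 0..3 plus
        the N sentinel 4.
    k:
        window length, ``k <= length``.

    Returns
    -------
    (win, valid):
        int64 window codes of shape (..., length-k+1) and a boolean mask of
        the same shape that is False where the window contains an N.
    """
    arr = np.asarray(codes, dtype=np.uint8)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    n, length = arr.shape
    w = length - k + 1
    if w < 1:
        empty = np.empty((n, 0), dtype=np.int64)
        mask = np.empty((n, 0), dtype=bool)
        return (empty[0], mask[0]) if squeeze else (empty, mask)
    has_n = bool((arr == N_CODE).any())
    base = arr.astype(np.int64) if not has_n else np.where(arr == N_CODE, 0, arr).astype(np.int64)
    # 2-bit Horner over the k offsets, vectorized across all positions:
    # exact in int64 for k <= 31
    win = np.zeros((n, w), dtype=np.int64)
    for j in range(k):
        np.left_shift(win, 2, out=win)
        np.bitwise_or(win, base[:, j : j + w], out=win)
    if has_n:
        isn = (arr == N_CODE).astype(np.uint8)
        csum = np.zeros((n, length + 1), dtype=np.int64)
        np.cumsum(isn, axis=1, out=csum[:, 1:])
        valid = (csum[:, k:] - csum[:, :-k]) == 0
    else:
        valid = np.ones((n, w), dtype=bool)
    return (win[0], valid[0]) if squeeze else (win, valid)


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement of a base-code array (N stays N)."""
    arr = np.asarray(codes, dtype=np.uint8)
    out = np.where(arr == N_CODE, N_CODE, 3 - arr).astype(np.uint8)
    return out[..., ::-1]


@dataclass
class VectorKmerIndex:
    """Pattern -> sorted 1-based left-end positions on the vector forward strand.

    ``_codes`` / ``_pos`` hold the strand-folded numeric index (forward and
    reverse-complement pattern of every position, sorted by code);
    ``_bucket`` is a coarse presence table over the high bits of the code
    used to discard the overwhelming majority of non-matching read k-mers
    with a single gather before the binary search.
    """

    k: int
    vector_length: int
    positions: dict[str, list[int]]
    _codes: np.ndarray = field(repr=False)
    _pos: np.ndarray = field(repr=False)
    _bucket: np.ndarray = field(repr=False)
    _shift: int = field(repr=False)
    _unique_spans: bool = field(repr=False)

    def lookup(self, pattern: str) -> list[int]:
        """Forward-strand positions of a forward-strand pattern ('' -> [])."""
        return self.positions.get(pattern.upper(), [])


def build_vector_index(vector: NucleotideSequence, cfg: KmerConfig) -> VectorKmerIndex:
    """Index every k-window left end of the vector forward strand.

    A circular vector is extended by its first k-1 bases so the windows
    spanning the origin are captured: positions 1..L all exist.  A linear
    vector yields positions 1..L-k+1.  Windows containing N are skipped.
    """
    k = cfg.k
    L = len(vector)
    if k > L:
        raise ValueError(f"k={k} exceeds vector length {L}")
    codes = vector.codes()
    ext = np.concatenate([codes, codes[: k - 1]]) if vector.is_circular else codes
    fwd, fvalid = window_codes(ext, k)
    n_win = fwd.shape[0]  # == L for circular, L-k+1 for linear
    pos1 = np.arange(1, n_win + 1, dtype=np.int64)

    # reverse-complement pattern of the window at each forward position
    rc_ext = _rc_codes(ext)
    rcw, _ = window_codes(rc_ext, k)
    rc_at_pos = rcw[::-1]  # window j of RC(ext) is RC of window (n_win-1-j)

    all_codes = np.concatenate([fwd[fvalid], rc_at_pos[fvalid]])
    all_pos = np.concatenate([pos1[fvalid], pos1[fvalid]])
    order = np.argsort(all_codes, kind="stable")
    codes_sorted = all_codes[order]
    pos_sorted = all_pos[order]

    # coarse presence filter over the top bits of the 2k-bit code space
    shift = max(0, 2 * k - 22)
    table = np.zeros(1 << (2 * k - shift), dtype=bool)
    if codes_sorted.size:
        table[codes_sorted >> shift] = True

    uniq = bool(codes_sorted.size == 0 or (np.diff(codes_sorted) != 0).all())

    patterns: dict[str, list[int]] = {}
    ext_str = decode_bases(ext)
    for p, ok in zip(pos1, fvalid):
        if not ok:
            continue
        pat = ext_str[p - 1 : p - 1 + k]
        patterns.setdefault(pat, []).append(int(p))
    return VectorKmerIndex(
        k=k,
        vector_length=L,
        positions=patterns,
        _codes=codes_sorted,
        _pos=pos_sorted,
        _bucket=table,
        _shift=shift,
        _unique_spans=uniq,
    )


def extract_read_kmers(read: NucleotideSequence, cfg: KmerConfig) -> list[str]:
    """All k-windows of a read and of its reverse complement, N-free only.

    A read shorter than k yields an empty list.  Palindromic k-mers appear
    once per strand, i.e. twice.
    """
    k = cfg.k
    s = read.bases
    if len(s) < k:
        return []
    from .seqio import reverse_complement

    out: list[str] = []
    for strand in (s, reverse_complement(s)):
        for i in range(len(strand) - k + 1):
            w = strand[i : i + k]
            if "N" not in w:
                out.append(w)
    return out


@dataclass
class PositionCountTable:
    """Per-vector-position match counts for one read set.

    ``counts[p-1]`` is the number of read k-mers (both strands) identical to
    the vector window at position p; ``total_kmers`` is the number of N-free
    k-mers extracted from the read set on both strands — the marginal
    against which matches are tested.
    """

    counts: np.ndarray
    total_kmers: int

    @property
    def vector_length(self) -> int:
        return int(self.counts.shape[0])


def count_codes_batch(
    read_codes: np.ndarray, index: VectorKmerIndex, counts: np.ndarray
) -> int:
    """Accumulate matches of one batch of equal-length reads; returns the
    number of valid k-mers extracted (both strands).

    Streams the window codes column-by-column with an in-place rolling
    2-bit update and discards non-candidates through the coarse presence
    table, so the full read x window code matrix is never materialized.
    """
    arr = np.asarray(read_codes, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr[None, :]
    n, length = arr.shape
    k = index.k
    w = length - k + 1
    if w < 1 or n == 0:
        return 0
    has_n = bool((arr == N_CODE).any())
    clean = np.where(arr == N_CODE, 0, arr) if has_n else arr
    cols = np.ascontiguousarray(clean.T).astype(np.int64)  # (length, n)
    valid_t = None
    if has_n:
        isn = (arr == N_CODE).astype(np.int64)
        csum = np.zeros((n, length + 1), dtype=np.int64)
        np.cumsum(isn, axis=1, out=csum[:, 1:])
        valid_t = np.ascontiguousarray(((csum[:, k:] - csum[:, :-k]) == 0).T)  # (w, n)
        n_valid = int(valid_t.sum())
    else:
        n_valid = n * w
    acc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        np.left_shift(acc, 2, out=acc)
        np.bitwise_or(acc, cols[j], out=acc)
    mask = (np.int64(1) << (2 * (k - 1))) - 1
    bucket, shift = index._bucket, index._shift
    tmp = np.empty(n, dtype=np.int64)
    chunks: list[np.ndarray] = []
    for j in range(w):
        if j:
            np.bitwise_and(acc, mask, out=acc)
            np.left_shift(acc, 2, out=acc)
            np.bitwise_or(acc, cols[k - 1 + j], out=acc)
        np.right_shift(acc, shift, out=tmp)
        m = bucket[tmp]
        if has_n:
            m &= valid_t[j]
        if m.any():
            chunks.append(acc[m])
    if chunks:
        cand = np.concatenate(chunks)
        lo = np.searchsorted(index._codes, cand, side="left")
        hit = (lo < index._codes.size) & (index._codes[np.minimum(lo, index._codes.size - 1)] == cand)
        lo = lo[hit]
        if lo.size:
            if index._unique_spans:
                np.add.at(counts, index._pos[lo] - 1, 1)
            else:
                hi = np.searchsorted(index._codes, cand[hit], side="right")
                for a, b in zip(lo, hi):
                    # a span may repeat a position (palindromic window):
                    # np.add.at honors the repeats, fancy += would not
                    np.add.at(counts, index._pos[a:b] - 1, 1)
    # both strands were folded into the forward scan: each valid forward
    # window stands for itself and its reverse-strand twin
    return 2 * n_valid


def count_positions(
    reads: Iterable[ReadPair] | np.ndarray,
    index: VectorKmerIndex,
    batch_size: int = 50_000,
) -> PositionCountTable:
    """Count identical k-mers per vector position over a read set.

    ``reads`` may be a stream of :class:`ReadPair` or a pre-encoded uint8
    array of shape (n_reads, read_length).  Every extracted N-free k-mer,
    matching or not, contributes to ``total_kmers``.
    """
    counts = np.zeros(index.vector_length, dtype=np.int64)
    total = 0
    if isinstance(reads, np.ndarray):
        for start in range(0, reads.shape[0], batch_size):
            total += count_codes_batch(reads[start : start + batch_size], index, counts)
        return PositionCountTable(counts, total)

    by_len: dict[int, list[np.ndarray]] = {}
    pending = 0

    def flush() -> int:
        nonlocal pending
        t = 0
        for _, rows in by_len.items():
            t += count_codes_batch(np.stack(rows), index, counts)
        by_len.clear()
        pending = 0
        return t

    for pair in reads:
        for mate in (pair.r1, pair.r2):
            c = mate.codes()
            by_len.setdefault(c.shape[0], []).append(c)
            pending += 1
        if pending >= batch_size:
            total += flush()
    total += flush()
    return PositionCountTable(counts, total)
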