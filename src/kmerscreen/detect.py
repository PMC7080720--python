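"""Detection orchestration: per-position profile, judgement, false positives.

``profile`` counts identical k-mers per vector position in a test read set
and a wild-type contrast read set against the same circular index, tests
every position with the one-sided G-test, and returns the full per-position
report (one row per vector position).  When a simulation ground truth is
supplied, ``judge`` applies the detection rule: the insert is *detected* if
at least one position of the eligible region — the k-windows lying fully
inside the inserted segment's source interval — is significant; any other
significant position is a false positive.

Windows that only partially overlap the source interval span an
insert/genome junction in the edited genome, so their sequence cannot match
the vector; they are excluded from the eligible region by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .kmer_engine import (
    KmerConfig,
    PositionCountTable,
    VectorKmerIndex,
    build_vector_index,
    count_positions,
)
from .seqio import NucleotideSequence
from .simulate import InsertTruth
from .stats import PositionTestResult, SignificanceConfig, g_statistic_arrays

__all__ = [
    "DetectionReport",
    "profile",
    "eligible_region",
    "judge",
    "write_profile_tsv",
]

TSV_COLUMNS = [
    "position",
    "vector_kmer",
    "count_test",
    "count_contrast",
    "total_test",
    "total_contrast",
    "G",
    "direction",
    "significant",
]


@dataclass
class DetectionReport:
    """Per-position test results for one test/contrast comparison."""

    vector_length: int
    k: int
    counts_test: np.ndarray
    counts_contrast: np.ndarray
    total_test: int
    total_contrast: int
    G: np.ndarray
    significant: np.ndarray  # bool per position
    direction: np.ndarray  # int8: 1 test_excess, -1 contrast_excess, 0 none
    sig_config: SignificanceConfig
    index: Optional[VectorKmerIndex] = field(default=None, repr=False)
    truth: Optional[InsertTruth] = None
    detected: Optional[bool] = None
    false_positive_count: Optional[int] = None

    @property
    def significant_positions(self) -> list[int]:
        return [int(p) + 1 for p in np.flatnonzero(self.significant)]

    def result_at(self, position: int) -> PositionTestResult:
        i = position - 1
        dirs = {1: "test_excess", -1: "contrast_excess", 0: "none"}
        return PositionTestResult(
            position=position,
            count_test=int(self.counts_test[i]),
            count_contrast=int(self.counts_contrast[i]),
            total_test=self.total_test,
            total_contrast=self.total_contrast,
            G=float(self.G[i]),
            significant=bool(self.significant[i]),
            direction=dirs[int(self.direction[i])],
        )

    @property
    def results(self) -> list[PositionTestResult]:
        return [self.result_at(p) for p in range(1, self.vector_length + 1)]


def test_tables(
    table_test: PositionCountTable,
    table_contrast: PositionCountTable,
    sig: SignificanceConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-position G, significance and direction from two count
    tables (the array core shared by :func:`profile` and the campaigns)."""
    a = table_test.counts
    b = table_contrast.counts
    n1 = table_test.total_kmers
    n2 = table_contrast.total_kmers
    g = np.zeros(a.shape[0], dtype=np.float64)
    nz = (a > 0) | (b > 0)
    if nz.any():
        g[nz] = g_statistic_arrays(a[nz], b[nz], n1, n2, williams=sig.williams)
    pa = a / n1
    pb = b / n2
    direction = np.zeros(a.shape[0], dtype=np.int8)
    direction[pa > pb] = 1
    direction[pb > pa] = -1
    significant = (g >= sig.g_threshold) & (direction == 1)
    return g, significant, direction


def profile(
    test_reads: Iterable,
    contrast_reads: Iterable,
    vector: NucleotideSequence,
    cfg: KmerConfig,
    sig: SignificanceConfig = SignificanceConfig(),
    truth: Optional[InsertTruth] = None,
    index: Optional[VectorKmerIndex] = None,
) -> DetectionReport:
    """Count, test and report every vector position for a test/contrast pair.

    ``test_reads``/``contrast_reads`` may be ReadPair streams or pre-encoded
    uint8 read arrays.  With a :class:`InsertTruth` the detection judgement
    and the false-positive count are filled in.
    """
    if index is None:
        index = build_vector_index(vector, cfg)
    tab_t = count_positions(test_reads, index)
    tab_c = count_positions(contrast_reads, index)
    if tab_t.total_kmers == 0 or tab_c.total_kmers == 0:
        raise ValueError("empty sample: a read set produced no k-mers")
    g, significant, direction = test_tables(tab_t, tab_c, sig)
    # a linear vector has no windows at the trailing k-1 positions; their
    # counts stay 0 and their G stays 0, so the report always spans 1..L
    report = DetectionReport(
        vector_length=len(vector),
        k=cfg.k,
        counts_test=tab_t.counts,
        counts_contrast=tab_c.counts,
        total_test=tab_t.total_kmers,
        total_contrast=tab_c.total_kmers,
        G=g,
        significant=significant,
        direction=direction,
        sig_config=sig,
        index=index,
        truth=truth,
    )
    if truth is not None:
        det, fp = judge(report.significant_positions, truth, cfg.k, len(vector))
        report.detected = det
        report.false_positive_count = fp
    return report


def eligible_region(truth: InsertTruth, k: int, vector_length: int) -> set[int]:
    """Vector positions whose k-window lies fully inside the insert's source
    interval, mapped back to 1..vector_length across the circular origin.

    Undefined (error) when k exceeds the insert length: no window of the
    edited genome can then match the vector at all.
    """
    L = truth.length
    if k > L:
        raise ValueError(
            f"k={k} exceeds insert length {L} - combination undefined in the method"
        )
    return {
        (p - 1) % vector_length + 1
        for p in range(truth.vector_start, truth.vector_end - k + 2)
    }


def judge(
    significant_positions: Iterable[int],
    truth: InsertTruth,
    k: int,
    vector_length: int,
) -> tuple[bool, int]:
    """Detection rule: detected iff >=1 significant position falls in the
    eligible region; all other significant positions are false positives."""
    eligible = eligible_region(truth, k, vector_length)
    sig = set(int(p) for p in significant_positions)
    true_hits = sig & eligible
    return bool(true_hits), len(sig - eligible)


def write_profile_tsv(report: DetectionReport, path) -> None:
    """Serialize the per-position profile as TSV (one row per position)."""
    import csv

    patterns = [""] * report.vector_length
    if report.index is not None:
        for pat, poss in report.index.positions.items():
            for p in poss:
                if p <= report.vector_length:
                    patterns[p - 1] = pat
    dirs = {1: "test_excess", -1: "contrast_excess", 0: "none"}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for i in range(report.counts_test.shape[0]):
            w.writerow(
                [
                    i + 1,
                    patterns[i],
                    int(report.counts_test[i]),
                    int(report.counts_contrast[i]),
                    report.total_test,
                    report.total_contrast,
                    f"{report.G[i]:.6g}",
                    dirs[int(report.direction[i])],
                    int(report.significant[i]),
                ]
            )
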