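"""Monte-Carlo campaigns: detection power, false positives, coverage sweep.

One *trial* = excise a random L-nt segment from the vector, insert it at a
random genome position, simulate a test read set from the edited genome and
an independent contrast read set from the unmodified genome at the same
coverage, profile every vector position with the one-sided G-test, and
judge detection against the ground truth.  Campaigns repeat this (default
1,000 iterations) per cell of a (insert length, k) grid or of a coverage
grid, and summarize successes and false-positive counts (mean and n-1 sd).

Cells with k > L are undefined — no k-window of the edited genome can match
the vector — and are reported as such, not as failures.

Every trial derives its RNG stream from ``base_seed + iteration`` so any
single iteration is independently reproducible.  Both raw-G and
Williams-corrected-G calls are evaluated on the same counts, because the
borderline-count detection threshold (and hence measured power at shallow
coverage) is sensitive to that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import eligible_region, judge, test_tables
from .kmer_engine import KmerConfig, PositionCountTable, build_vector_index, count_positions
from .seqio import NucleotideSequence
from .simulate import ReadSimConfig, insert_segment_codes, simulate_read_codes
from .stats import SignificanceConfig

__all__ = [
    "TrialConfig",
    "TrialOutcome",
    "ExperimentSummary",
    "run_trial",
    "run_power_experiment",
    "run_coverage_sweep",
    "expected_null_hits",
    "poisson_uncovered_probability",
]

SEED_MOD = 2**31


@dataclass(frozen=True)
class TrialConfig:
    """Full configuration of a simulation campaign."""

    vector: NucleotideSequence
    genome: Optional[NucleotideSequence] = None
    genome_length: int = 100_000
    insert_lengths: Sequence[int] = (15, 20, 30, 50)
    k_values: Sequence[int] = (10, 15, 20, 25, 30)
    coverages: Sequence[float] = (50.0,)
    iterations: int = 1000
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)
    alpha: float = 0.01
    base_seed: int = 1

    def genome_codes(self) -> np.ndarray:
        if self.genome is not None:
            return self.genome.codes()
        rng = np.random.default_rng((self.base_seed * 7919 + 11) % SEED_MOD)
        return rng.integers(0, 4, size=self.genome_length, dtype=np.uint8)


@dataclass(frozen=True)
class TrialOutcome:
    """One iteration's ground truth and detection result (both G variants)."""

    iteration: int
    seed: int
    L: int
    k: int
    coverage: float
    vector_start: int
    vector_end: int
    genome_position: int
    detected: bool
    false_positives: int
    detected_williams: bool
    false_positives_williams: int


@dataclass
class ExperimentSummary:
    """Per-cell summary, recomputable from the persisted per-trial table."""

    trials: pd.DataFrame
    summary: pd.DataFrame

    def to_dir(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)


def run_trial(
    genome_codes: np.ndarray,
    vector_codes: np.ndarray,
    index,
    L: int,
    k: int,
    coverage: float,
    read_sim: ReadSimConfig,
    sig_raw: SignificanceConfig,
    sig_wil: SignificanceConfig,
    seed: int,
    iteration: int = 0,
    vector_circular: bool = True,
) -> TrialOutcome:
    """One simulate-and-judge iteration (shared core of all campaigns)."""
    rng = np.random.default_rng(seed)
    cfg = replace(read_sim, coverage=coverage)
    modified, truth = insert_segment_codes(
        genome_codes, vector_codes, L, rng, circular=vector_circular
    )
    test_reads = simulate_read_codes(modified, cfg, rng)
    contrast_reads = simulate_read_codes(genome_codes, cfg, rng)
    tab_t = count_positions(test_reads, index)
    tab_c = count_positions(contrast_reads, index)
    vlen = index.vector_length
    _, sig_r, _ = test_tables(tab_t, tab_c, sig_raw)
    _, sig_w, _ = test_tables(tab_t, tab_c, sig_wil)
    pos_r = [int(p) + 1 for p in np.flatnonzero(sig_r)]
    pos_w = [int(p) + 1 for p in np.flatnonzero(sig_w)]
    det_r, fp_r = judge(pos_r, truth, k, vlen)
    det_w, fp_w = judge(pos_w, truth, k, vlen)
    return TrialOutcome(
        iteration=iteration,
        seed=seed,
        L=L,
        k=k,
        coverage=coverage,
        vector_start=truth.vector_start,
        vector_end=truth.vector_end,
        genome_position=truth.genome_position,
        detected=det_r,
        false_positives=fp_r,
        detected_williams=det_w,
        false_positives_williams=fp_w,
    )


def _summarize(rows: list[TrialOutcome]) -> dict:
    det = np.array([r.detected for r in rows])
    fp = np.array([r.false_positives for r in rows], dtype=float)
    detw = np.array([r.detected_williams for r in rows])
    fpw = np.array([r.false_positives_williams for r in rows], dtype=float)
    n = len(rows)
    return {
        "iterations": n,
        "successes": int(det.sum()),
        "accuracy": det.mean(),
        "fp_mean": fp.mean(),
        "fp_sd": fp.std(ddof=1) if n > 1 else 0.0,
        "successes_williams": int(detw.sum()),
        "accuracy_williams": detw.mean(),
        "fp_mean_williams": fpw.mean(),
        "fp_sd_williams": fpw.std(ddof=1) if n > 1 else 0.0,
    }


def _run_cells(
    cfg: TrialConfig, cells: list[tuple[int, int, float]]
) -> ExperimentSummary:
    genome_codes = cfg.genome_codes()
    vector_codes = cfg.vector.codes()
    sig_raw = SignificanceConfig(alpha=cfg.alpha, williams=False)
    sig_wil = SignificanceConfig(alpha=cfg.alpha, williams=True)
    indexes: dict[int, object] = {}
    trial_rows: list[TrialOutcome] = []
    summary_rows: list[dict] = []
    for L, k, cov in cells:
        base = {"L": L, "k": k, "coverage": cov}
        if k > L:
            summary_rows.append({**base, "status": "undefined (k > L)"})
            continue
        if k not in indexes:
            indexes[k] = build_vector_index(cfg.vector, KmerConfig(k))
        rows = []
        for it in range(cfg.iterations):
            seed = (cfg.base_seed + it) % SEED_MOD
            rows.append(
                run_trial(
                    genome_codes,
                    vector_codes,
                    indexes[k],
                    L,
                    k,
                    cov,
                    cfg.read_sim,
                    sig_raw,
                    sig_wil,
                    seed,
                    iteration=it,
                    vector_circular=cfg.vector.is_circular,
                )
            )
        trial_rows.extend(rows)
        summary_rows.append({**base, "status": "ok", **_summarize(rows)})
    trials = pd.DataFrame([r.__dict__ for r in trial_rows])
    return ExperimentSummary(trials=trials, summary=pd.DataFrame(summary_rows))


def run_power_experiment(cfg: TrialConfig) -> ExperimentSummary:
    """Detection-success / false-positive grid over (insert length, k) at a
    fixed coverage (first entry of ``cfg.coverages``)."""
    cov = cfg.coverages[0]
    cells = [(L, k, cov) for L in cfg.insert_lengths for k in cfg.k_values]
    return _run_cells(cfg, cells)


def run_coverage_sweep(cfg: TrialConfig) -> ExperimentSummary:
    """Detection accuracy vs mean depth at fixed insert length and k (first
    entries of ``cfg.insert_lengths`` / ``cfg.k_values``)."""
    L, k = cfg.insert_lengths[0], cfg.k_values[0]
    cells = [(L, k, cov) for cov in cfg.coverages]
    return _run_cells(cfg, cells)


def expected_null_hits(vector_length: int, alpha: float) -> float:
    """Expected count of per-position false rejections over a whole vector
    at level alpha under a position-wise null: vector_length * alpha."""
    if alpha < 0 or alpha >= 1:
        raise ValueError("alpha must be in [0, 1)")
    return vector_length * alpha


def poisson_uncovered_probability(coverage: float) -> float:
    """Probability a given nucleotide is never sequenced when per-base depth
    is Poisson with the given mean: exp(-coverage)."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return math.exp(-coverage)
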