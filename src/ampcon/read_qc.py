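"""Read quality/length filtering, seeded subsetting, and run statistics.

Mean read quality is computed on the error-probability scale
(``Q = -10*log10(mean_i 10^(-q_i/10))``), the convention of nanopore QC
tools: averaging Phred values arithmetically would systematically overstate
read accuracy and silently loosen the filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .seq_io import SequenceRead

__all__ = [
    "FilterConfig",
    "RunStats",
    "mean_read_quality",
    "filter_reads",
    "subset_reads",
    "compute_stats",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Quality and length bounds for read retention (bounds inclusive).

    Defaults keep reads with mean quality >= Q7 and trimmed length within a
    100 bp buffer around the 421 bp target insert (321-521 bp).
    """

    min_mean_q: float = 7.0
    min_len: int = 321
    max_len: int = 521

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")


def mean_read_quality(read: SequenceRead) -> float:
    """Error-probability-averaged Phred quality of a read."""
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    q = np.asarray(read.quals, dtype=float)
    return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))


def filter_reads(
    reads: Sequence[SequenceRead], cfg: FilterConfig = FilterConfig()
) -> Tuple[List[SequenceRead], pd.DataFrame]:
    """Keep reads passing both quality and length bounds; log rejections.

    Idempotent: filtering already-filtered reads changes nothing.
    """
    kept: List[SequenceRead] = []
    rejected = []
    for read in reads:
        n = len(read)
        if n == 0:
            rejected.append((read.read_id, "empty", 0, float("nan")))
            continue
        q = mean_read_quality(read)
        if q < cfg.min_mean_q:
            rejected.append((read.read_id, "low_quality", n, q))
        elif n < cfg.min_len:
            rejected.append((read.read_id, "too_short", n, q))
        elif n > cfg.max_len:
            rejected.append((read.read_id, "too_long", n, q))
        else:
            kept.append(read)
    log = pd.DataFrame(
        rejected, columns=["read_id", "reason", "length", "mean_quality"]
    )
    return kept, log


def subset_reads(
    reads: Sequence[SequenceRead], k: int, seed: int = 0
) -> List[SequenceRead]:
    """Uniform sample of ``min(k, n)`` reads without replacement.

    Input order is preserved among the selected reads; the same seed always
    selects the same subset.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(reads):
        if k > len(reads):
            logger.warning(
                "requested subset of %d from only %d reads; returning all", k, len(reads)
            )
        return list(reads)
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(reads), size=k, replace=False)
    picked.sort()
    return [reads[i] for i in picked]


@dataclass
class RunStats:
    """Per-stage read counts and summary statistics for one pipeline run."""

    table: pd.DataFrame

    def retention(self, stage: str) -> float:
        row = self.table[self.table["stage"] == stage]
        if row.empty:
            raise KeyError(f"no stage named {stage!r}")
        return float(row["pct_of_previous"].iloc[0])


def compute_stats(stages: Dict[str, Sequence[SequenceRead]]) -> RunStats:
    """Counts, mean length, mean quality, and stage-to-stage retention.

    ``stages`` maps stage name to its read snapshot, in pipeline order
    (e.g. raw -> demultiplexed -> filtered -> subset).
    """
    rows = []
    prev_n = None
    for stage, reads in stages.items():
        n = len(reads)
        if n:
            mean_len = float(np.mean([len(r) for r in reads]))
            mean_q = float(np.mean([mean_read_quality(r) for r in reads if len(r)]))
        else:
            mean_len = 0.0
            mean_q = 0.0
        pct = 100.0 * n / prev_n if prev_n else float("nan")
        rows.append(
            {
                "stage": stage,
                "n_reads": n,
                "mean_length": mean_len,
                "mean_quality": mean_q,
                "pct_of_previous": pct,
            }
        )
        prev_n = n
    return RunStats(pd.DataFrame(rows))
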