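"""Nanopore-style amplicon read simulator with known truth.

Emulates the statistical structure of basecalled MinION amplicon reads: a
~421 bp barcode insert flanked by a primer pair and dual 24-nt sample
indexes, corrupted by per-base substitutions, insertions, and deletions,
with deletions enriched inside homopolymer runs (the dominant nanopore
failure mode) and per-read mean Phred qualities centred near 10.5 — i.e.
roughly a 9% total per-base error rate.  Reads are emitted on both strands.

The simulator exists so the whole pipeline can be exercised, at desk scale,
against a truth table recording which template, strand, and sample every
read came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seq_io import SequenceRead, reverse_complement

__all__ = ["AmpliconTemplate", "ErrorModel", "simulate_reads", "mix_contamination"]

_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_TO_BASE = np.array(list("ACGT"))


@dataclass
class AmpliconTemplate:
    """One indexed amplicon: indexes and primers flanking a barcode insert.

    The full molecule, 5'→3' on the forward strand, is::

        forward_index + forward_primer + insert + rc(reverse_primer) + rc(reverse_index)
    """

    name: str
    insert: str
    forward_primer: str
    reverse_primer: str
    forward_index: str
    reverse_index: str
    sample_label: str = ""

    def __post_init__(self) -> None:
        if not self.insert:
            raise ValueError(f"template {self.name!r}: empty insert")
        for label, seq in (
            ("forward_primer", self.forward_primer),
            ("reverse_primer", self.reverse_primer),
            ("forward_index", self.forward_index),
            ("reverse_index", self.reverse_index),
        ):
            if not seq or not set(seq) <= set("ACGT"):
                raise ValueError(f"template {self.name!r}: invalid {label}")
        if not self.sample_label:
            self.sample_label = self.name

    @property
    def full_sequence(self) -> str:
        return (
            self.forward_index
            + self.forward_primer
            + self.insert
            + reverse_complement(self.reverse_primer)
            + reverse_complement(self.reverse_index)
        )


@dataclass
class ErrorModel:
    """Per-base independent error process with homopolymer-biased deletions.

    ``homopolymer_del_multiplier`` scales ``del_rate`` at every position
    inside a homopolymer run of length >= ``hp_min_len``.  Per-read mean
    quality is drawn Normal(``mean_read_quality``, ``quality_sd``), clamped
    to [2, 40], and applied uniformly across the read (basecallers report
    per-read means far more reliably than per-base values at this scale).
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.03
    del_rate: float = 0.03
    homopolymer_del_multiplier: float = 3.0
    hp_min_len: int = 3
    mean_read_quality: float = 10.5
    quality_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1): got {rate}")
        if self.homopolymer_del_multiplier < 1.0:
            raise ValueError("homopolymer_del_multiplier must be >= 1")


def homopolymer_mask(seq: str, min_len: int = 3) -> np.ndarray:
    """Boolean mask of positions lying inside a homopolymer run >= min_len."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    start = 0
    for i in range(1, len(arr) + 1):
        if i == len(arr) or arr[i] != arr[start]:
            if i - start >= min_len:
                mask[start:i] = True
            start = i
    return mask


def _corrupt(
    idx: np.ndarray,
    del_rates: np.ndarray,
    model: ErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one draw of the error process to a template (as base indices)."""
    n = len(idx)
    sub_mask = rng.random(n) < model.sub_rate
    del_mask = rng.random(n) < del_rates
    ins_mask = rng.random(n) < model.ins_rate

    out = idx.copy()
    if sub_mask.any():
        # offset 1-3 guarantees a *different* base
        out[sub_mask] = (out[sub_mask] + rng.integers(1, 4, sub_mask.sum())) % 4
    ins_pos = np.flatnonzero(ins_mask)
    if len(ins_pos):
        out = np.insert(out, ins_pos + 1, rng.integers(0, 4, len(ins_pos)))
        # shift deletion coordinates into post-insertion space
        del_pos = np.flatnonzero(del_mask)
        del_pos = del_pos + np.searchsorted(ins_pos, del_pos, side="left")
        keep = np.ones(len(out), dtype=bool)
        keep[del_pos] = False
        out = out[keep]
    elif del_mask.any():
        out = out[~del_mask]
    return out


def simulate_reads(
    template: AmpliconTemplate,
    n: int,
    model: Optional[ErrorModel] = None,
    strand_fraction: float = 0.5,
    seed: int = 0,
    chimera_rate: float = 0.0,
    read_id_prefix: Optional[str] = None,
) -> Tuple[List[SequenceRead], pd.DataFrame]:
    """Simulate ``n`` reads from one template; returns (reads, truth table).

    Each read is the full indexed amplicon (or its reverse complement with
    probability ``1 - strand_fraction``) passed through the error model.
    With probability ``chimera_rate`` two template copies are concatenated
    before corruption, producing an out-of-length-window artefact.  The same
    seed always yields byte-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or ErrorModel()
    rng = np.random.default_rng(seed)
    prefix = read_id_prefix or template.name

    full = template.full_sequence
    idx = np.array([_BASE_TO_IDX[b] for b in full], dtype=np.int64)
    del_rates = np.full(len(full), model.del_rate)
    hp = homopolymer_mask(full, model.hp_min_len)
    del_rates[hp] = min(0.999, model.del_rate * model.homopolymer_del_multiplier)

    reads: List[SequenceRead] = []
    truth_rows = []
    for i in range(n):
        chimeric = chimera_rate > 0 and rng.random() < chimera_rate
        tmpl_idx = np.concatenate([idx, idx]) if chimeric else idx
        tmpl_del = np.concatenate([del_rates, del_rates]) if chimeric else del_rates
        out = _corrupt(tmpl_idx, tmpl_del, model, rng)
        bases = "".join(_IDX_TO_BASE[out])
        forward = rng.random() < strand_fraction
        if not forward:
            bases = reverse_complement(bases)
        q = float(np.clip(rng.normal(model.mean_read_quality, model.quality_sd), 2, 40))
        quals = [int(round(q))] * len(bases)
        read_id = f"{prefix}_{i:06d}"
        reads.append(SequenceRead(read_id, bases, quals))
        truth_rows.append(
            {
                "read_id": read_id,
                "template": template.name,
                "strand": "forward" if forward else "reverse",
                "sample_label": template.sample_label,
                "forward_index": template.forward_index,
                "reverse_index": template.reverse_index,
                "chimeric": chimeric,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def mix_contamination(
    primary: Sequence[SequenceRead],
    contaminant: Sequence[SequenceRead],
    fraction: float,
    seed: int = 0,
    primary_truth: Optional[pd.DataFrame] = None,
    contaminant_truth: Optional[pd.DataFrame] = None,
) -> Tuple[List[SequenceRead], Optional[pd.DataFrame]]:
    """Replace ``round(fraction * len(primary))`` primary reads by contaminants.

    Models within-sample contamination arising during library preparation:
    both read sets must carry the same index pair, so contamination survives
    demultiplexing.  Output size equals ``len(primary)``; the mixture is
    shuffled deterministically.  ``fraction=0`` returns the primary set
    unchanged.  Truth tables, when given, are subset and reordered in step
    with the reads.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1): got {fraction}")
    truth_given = primary_truth is not None and contaminant_truth is not None
    if fraction == 0.0:
        return list(primary), primary_truth.copy() if truth_given else None

    total = len(primary)
    n_cont = int(round(fraction * total))
    if n_cont > len(contaminant):
        raise ValueError(
            f"need {n_cont} contaminant reads but only {len(contaminant)} supplied"
        )
    rng = np.random.default_rng(seed)
    keep_primary = rng.choice(total, size=total - n_cont, replace=False)
    keep_primary.sort()
    pick_cont = rng.choice(len(contaminant), size=n_cont, replace=False)
    pick_cont.sort()

    mixed = [primary[i] for i in keep_primary] + [contaminant[i] for i in pick_cont]
    order = rng.permutation(total)
    mixed = [mixed[i] for i in order]
    truth = None
    if truth_given:
        truth = pd.concat(
            [primary_truth.iloc[keep_primary], contaminant_truth.iloc[pick_cont]],
            ignore_index=True,
        ).iloc[order].reset_index(drop=True)
    return mixed, truth
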