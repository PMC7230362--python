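"""Bundled synthetic reference set for simulation, examples, and tests.

Real mitochondrial cytochrome-b barcodes are database accessions rather than
sequences a package can ship, so the toolkit carries a deterministic
*synthetic* stand-in: two 421-bp inserts with ~75% mutual identity (stand-ins
for two distantly related vertebrate barcodes), one primer pair, and a small
panel of 24-nt dual index pairs.  Everything is generated once from fixed
internal seeds, so the sequences are identical on every install.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .seq_io import ReferenceSequence

__all__ = [
    "toy_inserts",
    "toy_primers",
    "toy_index_panel",
    "INSERT_LENGTH",
    "INDEX_LENGTH",
]

INSERT_LENGTH = 421
INDEX_LENGTH = 24

_BASES = np.array(list("ACGT"))

# Fixed generator seeds: the bundled references are fixtures, not samples.
_INSERT_SEED = 20_200_417
_PANEL_SEED = 11_0445


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _embed_homopolymers(seq: str, rng: np.random.Generator) -> str:
    """Splice a few homopolymer runs (4-6 nt) into a sequence, preserving length.

    Nanopore indel errors concentrate in homopolymers, so the synthetic
    barcode must contain some for the error model to act on.
    """
    seq = list(seq)
    for run_len in (4, 5, 6, 4):
        pos = int(rng.integers(20, len(seq) - 20))
        base = str(rng.choice(_BASES))
        seq[pos : pos + run_len] = base * run_len
    return "".join(seq)


def _mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ``fraction`` of positions with a different base."""
    seq = list(seq)
    n_mut = int(round(fraction * len(seq)))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = str(rng.choice(alternatives))
    return "".join(seq)


def toy_inserts() -> Tuple[ReferenceSequence, ReferenceSequence]:
    """Two 421-bp synthetic barcode inserts at ~75% mutual identity.

    ``insert_A`` plays the focal species, ``insert_B`` a contaminant species
    distant enough (<80% identity) that their reads never co-cluster.
    """
    rng = np.random.default_rng(_INSERT_SEED)
    a = _embed_homopolymers(_random_dna(rng, INSERT_LENGTH), rng)
    b = _mutate(a, 0.25, rng)
    return (
        ReferenceSequence("insert_A", a, role="amplicon_reference"),
        ReferenceSequence("insert_B", b, role="amplicon_reference"),
    )


def toy_primers() -> Tuple[ReferenceSequence, ReferenceSequence]:
    """A synthetic barcode primer pair (25 and 26 nt)."""
    rng = np.random.default_rng(_INSERT_SEED + 1)
    fwd = _random_dna(rng, 25)
    rev = _random_dna(rng, 26)
    return (
        ReferenceSequence("primer_fwd", fwd, role="primer"),
        ReferenceSequence("primer_rev", rev, role="primer"),
    )


def toy_index_panel(n_pairs: int = 4) -> List[Dict[str, str]]:
    """A panel of dual 24-nt index pairs, pairwise edit distance >= 10.

    Returns a list of dicts with keys ``sample_label``, ``forward_index``,
    ``reverse_index`` (the layout of the demux panel TSV).
    """
    import edlib

    rng = np.random.default_rng(_PANEL_SEED)
    sequences: List[str] = []
    while len(sequences) < 2 * n_pairs:
        candidate = _random_dna(rng, INDEX_LENGTH)
        if all(
            edlib.align(candidate, other, mode="NW")["editDistance"] >= 10
            for other in sequences
        ):
            sequences.append(candidate)
    panel = []
    for i in range(n_pairs):
        panel.append(
            {
                "sample_label": f"sample_{i + 1:02d}",
                "forward_index": sequences[2 * i],
                "reverse_index": sequences[2 * i + 1],
            }
        )
    return panel
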