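"""Pairwise global alignment helpers shared by the merge and reporting steps.

Thin wrappers around biotite's optimal global aligner with free terminal
gaps.  Two identity conventions are exposed:

``identity_shortest``
    matches / length of the shorter sequence — the convention of global
    nucleotide clustering tools, used for the consensus merge cutoff.

``identity_global``
    matches / alignment length (gaps count against), used for reporting
    percent identity against a reference.
"""

from __future__ import annotations

from typing import Tuple

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .seq_io import reverse_complement

__all__ = [
    "global_alignment_stats",
    "identity_shortest",
    "identity_global",
    "best_orientation_identity",
]

_MATRIX = balign.SubstitutionMatrix.std_nucleotide_matrix()


def global_alignment_stats(a: str, b: str, gap_penalty: int = -4) -> Tuple[int, int]:
    """(matches, alignment_length) of an optimal global alignment of a and b.

    Terminal gaps are free, so a short overhang does not drag identity down.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    seq_a = bseq.NucleotideSequence(a)
    seq_b = bseq.NucleotideSequence(b)
    aln = balign.align_optimal(
        seq_a, seq_b, _MATRIX, gap_penalty=gap_penalty, terminal_penalty=False,
        max_number=1,
    )[0]
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    codes_a = seq_a.code[trace[both, 0]]
    codes_b = seq_b.code[trace[both, 1]]
    matches = int((codes_a == codes_b).sum())
    return matches, len(trace)


def identity_shortest(a: str, b: str) -> float:
    """matches / min(len(a), len(b)) for the optimal global alignment."""
    matches, _ = global_alignment_stats(a, b)
    return matches / min(len(a), len(b))


def identity_global(a: str, b: str) -> Tuple[float, int, int]:
    """(matches/alignment_length, matches, alignment_length)."""
    matches, length = global_alignment_stats(a, b)
    return matches / length, matches, length


def best_orientation_identity(a: str, b: str, mode: str = "global"):
    """Identity of ``a`` vs ``b`` taking the better of the two orientations.

    Returns ``(identity, matches, alignment_length, flipped)`` for
    ``mode="global"`` or ``(identity, flipped)`` for ``mode="shortest"``.
    """
    if mode == "shortest":
        fwd = identity_shortest(a, b)
        rev = identity_shortest(a, reverse_complement(b))
        return (fwd, False) if fwd >= rev else (rev, True)
    fwd = identity_global(a, b)
    rev = identity_global(a, reverse_complement(b))
    if fwd[0] >= rev[0]:
        return (*fwd, False)
    return (*rev, True)
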