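"""Primer trimming, reference comparison, and the identification report.

The final consensus is trimmed back to the barcode insert (primers and any
sequence outside them removed), compared by exhaustive global pairwise
alignment against the supplied reference panel in both orientations, and
scored on three criteria: percent identity above 99%, matching length close
to the expected insert length, and the fraction of filtered reads behind
the consensus (below 75% flags the sample for investigation of error or
contaminant read clusters).  Exhaustive alignment against a small panel
replaces a database search: identity and alignment-length semantics are the
same, with no external binary or database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import edlib

from .align import best_orientation_identity
from .seq_io import ReferenceSequence, reverse_complement

__all__ = [
    "IdentityReport",
    "trim_primers",
    "identity_to_reference",
    "evaluate_criteria",
]


@dataclass
class IdentityReport:
    """Species-identification summary for one sample's consensus."""

    sample_label: str
    best_reference: str
    percent_identity: float
    matching_length: int
    consensus_length: int
    fraction_reads_clustered: float
    flags: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.percent_identity > 100.0:
            raise ValueError("percent_identity cannot exceed 100")


@dataclass
class TrimResult:
    bases: str
    forward_trimmed: bool
    reverse_trimmed: bool
    flipped: bool


def _locate(query: str, window: str, offset: int) -> Tuple[int, int, int]:
    if not window:
        return (offset, offset, len(query))
    hit = edlib.align(query, window, mode="HW", task="locations")
    start, stop = min(hit["locations"])
    return (offset + start, offset + stop + 1, hit["editDistance"])


def trim_primers(
    consensus: str,
    forward_primer: str,
    reverse_primer: str,
    max_edits: int = 11,
    max_edit_fraction: float = 0.25,
) -> TrimResult:
    """Cut both primers (and anything outside them) off a consensus.

    Each primer — or its reverse complement, if the consensus is in the
    opposite orientation — is located by semi-global alignment near the
    appropriate end; a primer found within ``max_edits`` is removed together
    with everything outside it, and a primer that cannot be located leaves
    that end untouched and is flagged.

    ``max_edit_fraction`` is an absence guard: the best match of a ~25-nt
    primer against *unrelated* sequence sits around half the primer length,
    well inside a raw ``max_edits`` of 11, so a hit is only trusted when its
    distance is also at most ``max_edit_fraction * primer_length``.  A
    consensus that never contained primers (e.g. already trimmed during
    demultiplexing) is therefore returned unchanged rather than truncated.
    """
    if not consensus:
        raise ValueError("empty consensus")
    margin = 15

    def _cap(primer: str) -> int:
        return min(max_edits, int(max_edit_fraction * len(primer)))

    def _end_hits(seq: str):
        head_w = seq[: len(forward_primer) + margin]
        rc_rev = reverse_complement(reverse_primer)
        tail_off = max(0, len(seq) - len(rc_rev) - margin)
        head = _locate(forward_primer, head_w, 0)
        tail = _locate(rc_rev, seq[tail_off:], tail_off)
        return head, tail

    fwd_head, fwd_tail = _end_hits(consensus)
    flipped_seq = reverse_complement(consensus)
    rev_head, rev_tail = _end_hits(flipped_seq)
    if fwd_head[2] + fwd_tail[2] <= rev_head[2] + rev_tail[2]:
        seq, head, tail, flipped = consensus, fwd_head, fwd_tail, False
    else:
        seq, head, tail, flipped = flipped_seq, rev_head, rev_tail, True

    a, b = 0, len(seq)
    fwd_ok = head[2] <= _cap(forward_primer)
    rev_ok = tail[2] <= _cap(reverse_primer)
    if fwd_ok:
        a = head[1]
    if rev_ok:
        b = tail[0]
    if a >= b:  # primers overlap or crossed: refuse to trim
        return TrimResult(seq, False, False, flipped)
    return TrimResult(seq[a:b], fwd_ok, rev_ok, flipped)


def identity_to_reference(
    consensus: str,
    references: Sequence[ReferenceSequence],
    sample_label: str = "",
    fraction_reads_clustered: float = 1.0,
) -> IdentityReport:
    """Best-hit comparison of a consensus against a reference panel.

    Every reference is aligned globally (free end gaps) in both
    orientations; the best hit by percent identity
    (``100 * matches / alignment_length``) is reported, with
    ``matching_length`` = the number of identical aligned positions.
    """
    if not consensus:
        raise ValueError("empty consensus")
    if not references:
        raise ValueError("reference panel is empty")
    best = None
    for ref in references:
        ident, matches, aln_len, _flipped = best_orientation_identity(
            consensus, ref.bases, mode="global"
        )
        key = (ident, matches)
        if best is None or key > best[0]:
            best = (key, ref.name, matches)
    (ident, _), name, matches = best
    return IdentityReport(
        sample_label=sample_label,
        best_reference=name,
        percent_identity=100.0 * ident,
        matching_length=matches,
        consensus_length=len(consensus),
        fraction_reads_clustered=fraction_reads_clustered,
    )


def evaluate_criteria(
    report: IdentityReport,
    min_identity: float = 99.0,
    expected_length: int = 421,
    length_tolerance: int = 5,
    min_read_fraction: float = 0.75,
) -> Dict[str, bool]:
    """Pass/fail flags for the three identification criteria.

    identity_pass: percent identity strictly above ``min_identity``.
    length_pass: matching length within ``length_tolerance`` of the
    expected insert length.  investigate: raised when fewer than
    ``min_read_fraction`` of filtered reads support the consensus,
    signalling possible sequence error or contaminant clusters.
    """
    flags = {
        "identity_pass": report.percent_identity > min_identity,
        "length_pass": abs(report.matching_length - expected_length)
        <= length_tolerance,
        "investigate": report.fraction_reads_clustered < min_read_fraction,
    }
    report.flags.update(flags)
    return flags
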