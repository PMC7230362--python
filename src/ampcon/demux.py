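"""Dual-index demultiplexing in two selectable modes.

Each amplicon carries the sample's forward index at its 5' end and the
reverse complement of the reverse index at its 3' end, so a read (on either
strand) is assigned by locating both indexes of a pair near the read ends
with semi-global alignment.  Two modes mirror the behaviour of the two
demultiplexers commonly used for this protocol:

``score``
    Per-index score ``100 * (index_length - edits) / index_length``, taken
    as the worse of the two indexes.  With the default ``min_score=99`` and
    24-nt indexes only exact index matches are assigned (a score of 100
    means every index nucleotide is correct).  Indexes are trimmed; primers
    are retained.

``edit``
    Both indexes must match within ``max_index_edits`` (default 2).  Primers
    are additionally trimmed when found within ``max_primer_edits`` (default
    11); when primer localisation fails the read is deliberately
    under-trimmed (primer retained) rather than discarded.

Both indexes of a pair must be located — single-end hits are UNASSIGNED —
and ties between the best two index pairs are UNASSIGNED as ambiguous.
Assigned reads are re-oriented so the forward index side is at the 5' end,
making downstream processing strand-uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import edlib
import pandas as pd

from .seq_io import SequenceRead, reverse_complement

__all__ = [
    "IndexPair",
    "DemuxAssignment",
    "locate_index",
    "demux_score_mode",
    "demux_edit_mode",
    "demux_reads",
    "load_index_panel",
    "UNASSIGNED",
]

UNASSIGNED = "UNASSIGNED"

DEFAULT_SEARCH_WINDOW = 150


@dataclass(frozen=True)
class IndexPair:
    """One sample's dual index pair."""

    sample_label: str
    forward_index: str
    reverse_index: str

    def __post_init__(self) -> None:
        for seq in (self.forward_index, self.reverse_index):
            if not seq or not set(seq) <= set("ACGT"):
                raise ValueError(
                    f"index pair {self.sample_label!r}: indexes must be "
                    "non-empty unambiguous DNA"
                )


@dataclass
class DemuxAssignment:
    """Outcome of demultiplexing one read."""

    read_id: str
    sample_label: str  # or UNASSIGNED
    mode: str  # "score" | "edit"
    score: float  # percent (score mode) or total index edits (edit mode)
    edits: Tuple[int, int]  # (head index edits, tail index edits)
    strand: str  # "forward" | "reverse"
    trim_start: int = -1  # 0-based half-open, original read coordinates
    trim_end: int = -1

    @property
    def assigned(self) -> bool:
        return self.sample_label != UNASSIGNED


def _validate_panel(panel: Sequence[IndexPair]) -> None:
    if not panel:
        raise ValueError("index panel is empty")
    labels = [p.sample_label for p in panel]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels in index panel")
    seqs = [s for p in panel for s in (p.forward_index, p.reverse_index)]
    if len(set(seqs)) != len(seqs):
        raise ValueError("index sequences within a panel must be unique")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all indexes within a panel must have equal length")


def locate_index(
    read: Union[SequenceRead, str],
    index: str,
    search_window: int = DEFAULT_SEARCH_WINDOW,
    end: str = "head",
) -> Tuple[int, int, int]:
    """Best semi-global hit of ``index`` in one end window of a read.

    Aligns the index against the first (``end="head"``) or last
    (``end="tail"``) ``search_window`` bases with free gaps at the window
    ends, and returns ``(start, stop, edit_distance)`` in original read
    coordinates (0-based half-open).  Ties on distance are broken by the
    smallest start position.  Absence is signalled by a large distance, not
    an error.
    """
    bases = read.bases if isinstance(read, SequenceRead) else read
    if search_window < len(index):
        raise ValueError("search_window must be >= index length")
    if end == "head":
        window, offset = bases[:search_window], 0
    elif end == "tail":
        offset = max(0, len(bases) - search_window)
        window = bases[offset:]
    else:
        raise ValueError(f"end must be 'head' or 'tail': got {end!r}")
    if not window:
        return (0, 0, len(index))
    result = edlib.align(index, window, mode="HW", task="locations")
    dist = result["editDistance"]
    start, stop = min(result["locations"])  # smallest start wins ties
    return (offset + start, offset + stop + 1, dist)


def _locate_pair(
    bases: str, pair: IndexPair, strand: str, search_window: int
) -> Tuple[Tuple[int, int, int], Tuple[int, int, int]]:
    """Locate both indexes of a pair for one assumed read strand."""
    if strand == "forward":
        head_query = pair.forward_index
        tail_query = reverse_complement(pair.reverse_index)
    else:
        head_query = pair.reverse_index
        tail_query = reverse_complement(pair.forward_index)
    head = locate_index(bases, head_query, search_window, end="head")
    tail = locate_index(bases, tail_query, search_window, end="tail")
    return head, tail


def _oriented_trim(
    read: SequenceRead, strand: str, trim_start: int, trim_end: int
) -> SequenceRead:
    """Extract the retained segment, oriented forward-index-first."""
    seg = SequenceRead(
        read.read_id,
        read.bases[trim_start:trim_end],
        read.quals[trim_start:trim_end],
        orientation="forward",
    )
    if strand == "reverse":
        seg = seg.reverse_complemented()
        seg.orientation = "forward"
    return seg


def _per_pair_best(bases: str, panel: Sequence[IndexPair], search_window: int):
    """For each pair, its best hit over both strands.

    Returns a list of ``(pair, strand, head, tail, worst_edits, total_edits)``
    with one entry per panel pair; the forward strand wins within-pair ties.
    """
    out = []
    for pair in panel:
        best = None
        for strand in ("forward", "reverse"):
            head, tail = _locate_pair(bases, pair, strand, search_window)
            worst = max(head[2], tail[2])
            total = head[2] + tail[2]
            key = (worst, total, 0 if strand == "forward" else 1)
            if best is None or key < best[0]:
                best = (key, strand, head, tail)
        _, strand, head, tail = best
        out.append(
            (pair, strand, head, tail, max(head[2], tail[2]), head[2] + tail[2])
        )
    return out


def demux_score_mode(
    read: SequenceRead,
    panel: Sequence[IndexPair],
    min_score: float = 99.0,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> Tuple[DemuxAssignment, Optional[SequenceRead]]:
    """Assign a read by per-index percent score; trim indexes only.

    Score of a pair = ``100 * (L - edits) / L`` for the *worse* of its two
    indexes.  The best-scoring pair wins if its score is >= ``min_score``;
    a tie between two distinct pairs is ambiguous and left unassigned.
    """
    _validate_panel(panel)
    index_len = len(panel[0].forward_index)
    hits = _per_pair_best(read.bases, panel, search_window)
    hits_sorted = sorted(
        enumerate(hits), key=lambda item: (item[1][4], item[1][5], item[0])
    )
    pair, strand, head, tail, worst_edits, _ = hits_sorted[0][1]
    tied = len(hits_sorted) > 1 and hits_sorted[1][1][4] == worst_edits
    score = 100.0 * (index_len - min(worst_edits, index_len)) / index_len
    edits = (head[2], tail[2])
    trim_start, trim_end = head[1], tail[0]
    ok = (
        not tied
        and 100 * (index_len - worst_edits) >= min_score * index_len - 1e-9
        and trim_start < trim_end
    )
    assignment = DemuxAssignment(
        read_id=read.read_id,
        sample_label=pair.sample_label if ok else UNASSIGNED,
        mode="score",
        score=score,
        edits=edits,
        strand=strand,
        trim_start=trim_start if ok else -1,
        trim_end=trim_end if ok else -1,
    )
    if not ok:
        return assignment, None
    return assignment, _oriented_trim(read, strand, trim_start, trim_end)


def _trim_primers_oriented(
    seg: SequenceRead,
    forward_primer: str,
    reverse_primer: str,
    max_primer_edits: int,
) -> SequenceRead:
    """Trim primers off an already-oriented index-trimmed segment.

    A primer that cannot be located within ``max_primer_edits`` is retained
    (under-trimming is preferred over cutting real barcode sequence).
    """
    bases = seg.bases
    a, b = 0, len(bases)
    margin = 15
    head_window = bases[: len(forward_primer) + margin]
    if head_window:
        hit = edlib.align(forward_primer, head_window, mode="HW", task="locations")
        if hit["editDistance"] <= max_primer_edits:
            a = min(hit["locations"])[1] + 1
    rc_rev = reverse_complement(reverse_primer)
    tail_off = max(0, len(bases) - len(rc_rev) - margin)
    tail_window = bases[tail_off:]
    if tail_window:
        hit = edlib.align(rc_rev, tail_window, mode="HW", task="locations")
        if hit["editDistance"] <= max_primer_edits:
            b = tail_off + min(hit["locations"])[0]
    if a >= b:  # degenerate (primers overlap): keep index-trimmed segment
        return seg
    return SequenceRead(seg.read_id, bases[a:b], seg.quals[a:b], orientation="forward")


def demux_edit_mode(
    read: SequenceRead,
    panel: Sequence[IndexPair],
    primers: Tuple[str, str],
    max_index_edits: int = 2,
    max_primer_edits: int = 11,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> Tuple[DemuxAssignment, Optional[SequenceRead]]:
    """Assign a read by index edit distance; trim indexes and primers.

    Assignment requires both indexes of one pair within ``max_index_edits``.
    The best pair (smallest total edits) wins; ties between pairs are
    ambiguous.  Primers are trimmed only when located within
    ``max_primer_edits``, otherwise retained.
    """
    _validate_panel(panel)
    forward_primer, reverse_primer = primers
    hits = [
        h
        for h in _per_pair_best(read.bases, panel, search_window)
        if h[2][2] <= max_index_edits and h[3][2] <= max_index_edits
    ]
    hits.sort(key=lambda h: h[5])
    tied = len(hits) > 1 and hits[1][5] == hits[0][5]
    if not hits or tied:
        return (
            DemuxAssignment(
                read_id=read.read_id,
                sample_label=UNASSIGNED,
                mode="edit",
                score=-1.0,
                edits=(-1, -1),
                strand="forward",
            ),
            None,
        )
    pair, strand, head, tail, _, total = hits[0]
    trim_start, trim_end = head[1], tail[0]
    if trim_start >= trim_end:
        return (
            DemuxAssignment(
                read_id=read.read_id,
                sample_label=UNASSIGNED,
                mode="edit",
                score=float(total),
                edits=(head[2], tail[2]),
                strand=strand,
            ),
            None,
        )
    assignment = DemuxAssignment(
        read_id=read.read_id,
        sample_label=pair.sample_label,
        mode="edit",
        score=float(total),
        edits=(head[2], tail[2]),
        strand=strand,
        trim_start=trim_start,
        trim_end=trim_end,
    )
    seg = _oriented_trim(read, strand, trim_start, trim_end)
    seg = _trim_primers_oriented(seg, forward_primer, reverse_primer, max_primer_edits)
    return assignment, seg


def demux_reads(
    reads: Sequence[SequenceRead],
    panel: Sequence[IndexPair],
    mode: str = "score",
    primers: Optional[Tuple[str, str]] = None,
    min_score: float = 99.0,
    max_index_edits: int = 2,
    max_primer_edits: int = 11,
    search_window: int = DEFAULT_SEARCH_WINDOW,
) -> Tuple[Dict[str, List[SequenceRead]], List[DemuxAssignment]]:
    """Demultiplex a read set; returns per-sample trimmed reads + assignments.

    Every read lands in at most one sample (a partition of the assigned
    reads); unassigned reads appear only in the assignment log.
    """
    if mode not in ("score", "edit"):
        raise ValueError(f"mode must be 'score' or 'edit': got {mode!r}")
    if mode == "edit" and primers is None:
        raise ValueError("edit mode requires primers")
    by_sample: Dict[str, List[SequenceRead]] = {p.sample_label: [] for p in panel}
    log: List[DemuxAssignment] = []
    for read in reads:
        if mode == "score":
            assignment, seg = demux_score_mode(read, panel, min_score, search_window)
        else:
            assignment, seg = demux_edit_mode(
                read, panel, primers, max_index_edits, max_primer_edits, search_window
            )
        log.append(assignment)
        if assignment.assigned and seg is not None and len(seg) > 0:
            by_sample[assignment.sample_label].append(seg)
    return by_sample, log


def load_index_panel(path: Union[str, Path]) -> List[IndexPair]:
    """Load an index panel TSV (sample_label, forward_index, reverse_index)."""
    table = pd.read_csv(path, sep="\t")
    required = {"sample_label", "forward_index", "reverse_index"}
    if not required <= set(table.columns):
        raise ValueError(f"panel TSV must have columns {sorted(required)}")
    panel = [
        IndexPair(row.sample_label, row.forward_index.upper(), row.reverse_index.upper())
        for row in table.itertuples()
    ]
    _validate_panel(panel)
    return panel


def summarize_demux(log: Sequence[DemuxAssignment]) -> pd.DataFrame:
    """Reads-per-sample summary table for a demultiplexing run."""
    counts: Dict[str, int] = {}
    for a in log:
        counts[a.sample_label] = counts.get(a.sample_label, 0) + 1
    rows = [
        {"sample_label": k, "n_reads": v, "pct_of_total": 100.0 * v / len(log)}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
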