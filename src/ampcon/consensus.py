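"""Per-cluster consensus, reverse-complement-aware merging, and polishing.

The stage chain mirrors the clustering-based barcoding workflow: a partial
order alignment consensus is drafted per retained cluster; drafts whose
global identity (matches / shorter sequence length, the convention of
global nucleotide clustering tools) reaches the merge cutoff in either
orientation are grouped, reuniting the forward- and reverse-strand clusters
of one template; the group with the most supporting reads is selected as
the majority; and its draft is polished by rounds of alignment-pileup
majority voting over all supporting reads.

Pileup polishing stands in for neural-network polishing: at amplicon scale
a per-column majority over dozens-to-thousands of reads removes essentially
all draft errors outside of systematically biased positions (deep
homopolymers), which is exactly the residual failure mode reported for
nanopore barcode consensus generally.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import edlib
import numpy as np

from .align import best_orientation_identity
from .clustering import ReadCluster
from .poa import poa_consensus
from .seq_io import SequenceRead

__all__ = [
    "MergeConfig",
    "ConsensusRecord",
    "MergedGroup",
    "cluster_consensus",
    "merge_rc_consensus",
    "select_majority",
    "polish_consensus",
]

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XMID])")


@dataclass
class MergeConfig:
    """Reverse-complement-aware consensus merge parameters."""

    consensus_identity_cutoff: float = 0.90

    def __post_init__(self) -> None:
        if not 0.5 < self.consensus_identity_cutoff <= 1.0:
            raise ValueError("consensus_identity_cutoff must be in (0.5, 1]")


@dataclass
class ConsensusRecord:
    """Final consensus for one sample."""

    sample_label: str
    bases: str
    n_supporting_reads: int
    fraction_of_filtered_reads: float
    polished: bool = False

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("consensus bases must be non-empty")
        if not 0.0 < self.fraction_of_filtered_reads <= 1.0:
            raise ValueError("fraction_of_filtered_reads must be in (0, 1]")


@dataclass
class MergedGroup:
    """Clusters whose draft consensuses merged into one strand-reconciled group."""

    group_id: int
    clusters: List[ReadCluster] = field(default_factory=list)
    consensuses: List[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def read_ids(self) -> List[str]:
        return [rid for c in self.clusters for rid in c.read_ids]

    @property
    def mean_quality(self) -> float:
        sizes = np.array([c.size for c in self.clusters], dtype=float)
        quals = np.array([c.mean_quality for c in self.clusters], dtype=float)
        return float((sizes * quals).sum() / sizes.sum())

    def lead_consensus(self) -> str:
        """Draft of the largest member cluster (ties: lowest cluster id)."""
        best = max(
            range(len(self.clusters)),
            key=lambda i: (self.clusters[i].size, -self.clusters[i].cluster_id),
        )
        return self.consensuses[best]


def cluster_consensus(
    cluster: ReadCluster,
    reads_by_id: Dict[str, SequenceRead],
    max_reads: int = 100,
    match: int = 2,
    mismatch: int = -4,
    gap: int = -4,
) -> str:
    """POA draft consensus of one cluster.

    Members are already in descending quality order (the clustering
    processing order); only the top ``max_reads`` enter the graph — the
    draft saturates well before that and polishing later uses every read.
    """
    seqs = [reads_by_id[rid].bases for rid in cluster.read_ids[:max_reads]]
    return poa_consensus(seqs, match=match, mismatch=mismatch, gap=gap)


def merge_rc_consensus(
    items: Sequence[Tuple[ReadCluster, str]],
    cfg: MergeConfig = MergeConfig(),
) -> List[MergedGroup]:
    """Single-linkage grouping of cluster consensuses, either orientation.

    Two drafts join when ``max(identity(a, b), identity(a, rc(b)))`` reaches
    the cutoff, with identity = matches / shorter sequence length of a
    free-end-gap global alignment.  Groups union their clusters' read sets.
    """
    if not items:
        raise ValueError("merge_rc_consensus requires at least one consensus")
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident, _flipped = best_orientation_identity(
                items[i][1], items[j][1], mode="shortest"
            )
            if ident >= cfg.consensus_identity_cutoff:
                parent[find(j)] = find(i)

    roots: Dict[int, MergedGroup] = {}
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = MergedGroup(group_id=len(roots))
        roots[r].clusters.append(items[i][0])
        roots[r].consensuses.append(items[i][1])
    return list(roots.values())


def select_majority(
    groups: Sequence[MergedGroup], total_filtered_reads: int
) -> Tuple[MergedGroup, float]:
    """The group with the most supporting reads, and its read fraction.

    The fraction's denominator is the number of reads that entered
    clustering.  A tie on read count is broken by higher mean read quality
    (and then lower group id), and logged.
    """
    if not groups:
        raise ValueError("select_majority requires at least one group")
    best = max(
        groups, key=lambda g: (g.n_reads, g.mean_quality, -g.group_id)
    )
    ties = [g for g in groups if g.n_reads == best.n_reads and g is not best]
    if ties:
        logger.info(
            "majority tie on %d reads broken by mean quality (group %d wins)",
            best.n_reads,
            best.group_id,
        )
    return best, best.n_reads / total_filtered_reads


def _pileup_round(
    draft: str, seqs: Sequence[str], tie_keeps_draft: bool = True
) -> str:
    """One round of per-column majority voting of reads against the draft."""
    length = len(draft)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
    votes = np.zeros((length, 5), dtype=np.int64)  # A C G T deletion
    insertions: Dict[int, Counter] = {}
    n_aligned = 0
    for seq in seqs:
        result = edlib.align(seq, draft, mode="NW", task="path")
        cigar = result.get("cigar")
        if cigar is None:
            continue
        n_aligned += 1
        tpos = qpos = 0
        for m in _CIGAR_RE.finditer(cigar):
            run, op = int(m.group(1)), m.group(2)
            if op in "=XM":
                for i in range(run):
                    votes[tpos + i, base_idx[seq[qpos + i]]] += 1
                tpos += run
                qpos += run
            elif op == "D":  # draft base absent from the read
                votes[tpos : tpos + run, 4] += 1
                tpos += run
            else:  # 'I': read bases absent from the draft
                insertions.setdefault(tpos, Counter())[seq[qpos : qpos + run]] += 1
                qpos += run
    if n_aligned == 0:
        logger.warning("no reads aligned to draft; returning draft unchanged")
        return draft

    out: List[str] = []
    symbols = "ACGT-"
    for col in range(length):
        counts = votes[col]
        top = counts.max()
        winners = {symbols[i] for i in range(5) if counts[i] == top}
        draft_call = draft[col]
        if tie_keeps_draft and draft_call in winners:
            call = draft_call
        else:
            bases_won = sorted(w for w in winners if w != "-")
            call = bases_won[0] if bases_won else "-"
        ins = insertions.get(col)
        if ins:
            ins_seq, ins_count = sorted(ins.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if 2 * ins_count > n_aligned:
                out.append(ins_seq)
        if call != "-":
            out.append(call)
    ins = insertions.get(length)
    if ins:
        ins_seq, ins_count = sorted(ins.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if 2 * ins_count > n_aligned:
            out.append(ins_seq)
    return "".join(out)


def polish_consensus(
    draft: str,
    reads: Sequence[SequenceRead],
    rounds: int = 2,
) -> str:
    """Polish a draft by rounds of alignment-pileup majority voting.

    Each round globally aligns every supporting read to the current draft
    and takes a per-column majority over {A, C, G, T, deletion}, plus
    strictly-majority-supported insertions.  A tied column keeps the draft
    call: at an even split the reads carry no usable signal (deep
    homopolymers can split evenly either way), so the partial-order draft,
    built from whole-read context, stands.  Error-free reads are a fixed
    point.  Stops early once a round changes nothing.
    """
    if not draft:
        raise ValueError("draft consensus is empty")
    if not reads:
        logger.warning("polish_consensus called with zero reads; draft returned")
        return draft
    seqs = [r.bases for r in reads]
    current = draft
    for _ in range(rounds):
        new = _pileup_round(current, seqs)
        if not new:
            logger.warning("polishing emptied the consensus; keeping previous draft")
            return current
        if new == current:
            break
        current = new
    return current
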