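"""Greedy minimizer clustering: sketches, partitions, strand behaviour, gate."""

import edlib

import pytest

from ampcon.clustering import (
    NoClusterSurvivesError,
    ReadCluster,
    gate_clusters,
    greedy_cluster,
    minimizer_sketch,
)
from ampcon.seq_io import SequenceRead
from ampcon.simulate import ErrorModel, simulate_reads


def _reads(seqs, prefix="r", q=12):
    return [SequenceRead(f"{prefix}{i}", s, [q] * len(s)) for i, s in enumerate(seqs)]


def _partition(clusters):
    return {frozenset(c.read_ids) for c in clusters}


class TestMinimizerSketch:
    def test_identical_strings_identical_sketches(self, inserts):
        assert minimizer_sketch(inserts[0].bases) == minimizer_sketch(inserts[0].bases)

    def test_one_substitution_shares_most_minimizers(self, inserts):
        seq = inserts[0].bases
        mutated = seq[:200] + ("A" if seq[200] != "A" else "C") + seq[201:]
        a = {m for m, _ in minimizer_sketch(seq)}
        b = {m for m, _ in minimizer_sketch(mutated)}
        assert len(a & b) / len(a) > 0.8

    def test_string_shorter_than_k_yields_empty_sketch(self):
        assert minimizer_sketch("ACGTACGTACGT", k=13) == []

    def test_short_reads_left_unassigned(self):
        reads = _reads(["ACGT" * 120, "ACGTACG"])
        clusters, unassigned = greedy_cluster(reads)
        assert unassigned == ["r1"]
        assert _partition(clusters) == {frozenset({"r0"})}


class TestGreedyCluster:
    def test_clean_same_strand_reads_form_one_cluster(self, template_a):
        reads, _ = simulate_reads(
            template_a, 40, ErrorModel(0, 0, 0), 1.0, seed=2
        )
        clusters, unassigned = greedy_cluster(reads)
        assert len(clusters) == 1 and not unassigned
        assert clusters[0].size == 40

    def test_strands_form_separate_clusters(self, template_a):
        reads, truth = simulate_reads(
            template_a, 60, ErrorModel(0, 0, 0), 0.5, seed=3
        )
        clusters, _ = greedy_cluster(reads)
        assert len(clusters) == 2
        by_strand = dict(zip(truth["read_id"], truth["strand"]))
        for cluster in clusters:
            assert len({by_strand[rid] for rid in cluster.read_ids}) == 1

    def test_two_templates_never_mix_and_match_brute_force(
        self, template_a, template_b
    ):
        """Partition equals brute-force all-pairs identity clustering.

        Reads are trimmed to the insert (as demultiplexing would) before
        clustering: the shared index/primer flanks are identical between
        templates and only the barcode insert carries the species signal.
        """
        low = ErrorModel(sub_rate=0.02, ins_rate=0, del_rate=0)
        head = len(template_a.forward_index) + len(template_a.forward_primer)
        tail = len(template_a.reverse_primer) + len(template_a.reverse_index)
        ra, _ = simulate_reads(template_a, 25, low, 1.0, seed=4, read_id_prefix="a")
        rb, _ = simulate_reads(template_b, 25, low, 1.0, seed=5, read_id_prefix="b")
        reads = [
            SequenceRead(r.read_id, r.bases[head:-tail], r.quals[head:-tail])
            for r in ra + rb
        ]
        clusters, _ = greedy_cluster(reads)

        # oracle: connected components of the >=90%-identity graph
        n = len(reads)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                d = edlib.align(reads[i].bases, reads[j].bases, mode="NW")[
                    "editDistance"
                ]
                ident = 1 - d / max(len(reads[i]), len(reads[j]))
                if ident >= 0.9:
                    parent[find(j)] = find(i)
        oracle = {}
        for i in range(n):
            oracle.setdefault(find(i), set()).add(reads[i].read_id)
        assert _partition(clusters) == {frozenset(v) for v in oracle.values()}

    def test_reads_partitioned_exactly_once(self, noisy_reads_a):
        reads, _ = noisy_reads_a
        clusters, unassigned = greedy_cluster(reads)
        seen = [rid for c in clusters for rid in c.read_ids] + unassigned
        assert sorted(seen) == sorted(r.read_id for r in reads)

    def test_reverse_complementing_all_reads_preserves_partition(self, template_a):
        """Mirrored input gives the mirrored partition (strands swapped).

        Checked on clean reads: lexicographic minimizer selection is not
        strand-symmetric, so a read sitting exactly at the join threshold
        could legitimately flip its decision under rc; away from the
        threshold the structure is exactly mirrored.
        """
        reads, truth = simulate_reads(
            template_a, 50, ErrorModel(0, 0, 0), 0.5, seed=6
        )
        flipped = [r.reverse_complemented() for r in reads]
        original = _partition(greedy_cluster(reads)[0])
        mirrored = _partition(greedy_cluster(flipped)[0])
        assert original == mirrored
        by_strand = dict(zip(truth["read_id"], truth["strand"]))
        for cluster in greedy_cluster(flipped)[0]:
            assert len({by_strand[rid] for rid in cluster.read_ids}) == 1


class TestGateClusters:
    def _clusters(self, sizes):
        out = []
        for i, size in enumerate(sizes):
            c = ReadCluster(cluster_id=i, representative_id=f"c{i}r0")
            c.read_ids = [f"c{i}r{j}" for j in range(size)]
            c.strands = ["forward"] * size
            out.append(c)
        return out

    def test_exactly_ten_percent_is_excluded(self):
        retained = gate_clusters(self._clusters([850, 100, 50]), 1000, 0.10)
        assert [c.size for c in retained] == [850]

    def test_all_above_threshold_retained(self):
        retained = gate_clusters(self._clusters([400, 350, 250]), 1000, 0.10)
        assert [c.size for c in retained] == [400, 350, 250]

    def test_single_total_cluster_retained(self):
        retained = gate_clusters(self._clusters([77]), 77, 0.10)
        assert retained[0].size_fraction == pytest.approx(1.0)

    def test_no_survivor_is_hard_error(self):
        with pytest.raises(NoClusterSurvivesError, match="lowering"):
            gate_clusters(self._clusters([10, 10]), 1000, 0.10)
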