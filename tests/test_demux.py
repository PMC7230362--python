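"""Dual-index demultiplexing: localisation, both modes, partition property."""

import edlib
import numpy as np
import pytest

from ampcon.demux import (
    UNASSIGNED,
    IndexPair,
    demux_edit_mode,
    demux_reads,
    demux_score_mode,
    locate_index,
)
from ampcon.seq_io import SequenceRead, reverse_complement
from ampcon.simulate import AmpliconTemplate, ErrorModel, simulate_reads

Q = 12  # constant per-base quality for constructed reads


def _read(bases, read_id="r"):
    return SequenceRead(read_id, bases, [Q] * len(bases))


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def _brute_force_best(index, window):
    """Oracle: minimal edit distance of index against every window substring."""
    best = len(index)
    for i in range(len(window)):
        for j in range(i + 1, min(len(window), i + 2 * len(index)) + 1):
            best = min(best, edlib.align(index, window[i:j], mode="NW")["editDistance"])
    return best


class TestLocateIndex:
    def test_exact_index_at_read_start(self, panel):
        index = panel[0].forward_index
        read = _read(index + "ACGT" * 40)
        start, stop, dist = locate_index(read, index)
        assert (start, stop, dist) == (0, len(index), 0)

    def test_single_substitution_matches_brute_force(self, panel):
        index = panel[0].forward_index
        planted = _mutate(index, [5])
        read = _read("ACT" + planted + "ACGT" * 40)
        start, stop, dist = locate_index(read, index)
        assert dist == 1
        assert dist == _brute_force_best(index, read.bases[:150])
        assert start == 3

    def test_random_reads_have_high_distance(self, panel):
        rng = np.random.default_rng(99)
        index = panel[0].forward_index
        for _ in range(20):
            read = _read("".join(rng.choice(list("ACGT"), 200)))
            *_, dist = locate_index(read, index)
            assert dist == _brute_force_best(index, read.bases[:150])
            assert dist > 2

    def test_tail_end_search(self, panel):
        index = panel[0].forward_index
        read = _read("ACGT" * 50 + index)
        start, stop, dist = locate_index(read, index, end="tail")
        assert dist == 0
        assert (start, stop) == (200, 200 + len(index))


class TestScoreMode:
    def test_exact_dual_index_scores_100(self, template_a, panel):
        read = _read(template_a.full_sequence)
        assignment, trimmed = demux_score_mode(read, panel)
        assert assignment.assigned
        assert assignment.score == 100.0
        assert assignment.sample_label == template_a.sample_label
        # indexes trimmed, primers retained
        assert trimmed.bases == (
            template_a.forward_primer
            + template_a.insert
            + reverse_complement(template_a.reverse_primer)
        )

    def test_one_index_edit_scores_below_99(self, template_a, panel):
        full = template_a.full_sequence
        read = _read(_mutate(full, [2]))  # one substitution inside forward index
        assignment, trimmed = demux_score_mode(read, panel)
        assert assignment.sample_label == UNASSIGNED
        assert trimmed is None
        assert assignment.score == pytest.approx(100 * 23 / 24)

    def test_unrecognizable_read_unassigned(self, panel):
        rng = np.random.default_rng(7)
        read = _read("".join(rng.choice(list("ACGT"), 450)))
        assignment, trimmed = demux_score_mode(read, panel)
        assert assignment.sample_label == UNASSIGNED and trimmed is None

    def test_orientation_invariance(self, template_a, panel):
        read = _read(template_a.full_sequence)
        flipped = read.reverse_complemented()
        a1, t1 = demux_score_mode(read, panel)
        a2, t2 = demux_score_mode(flipped, panel)
        assert a1.sample_label == a2.sample_label == template_a.sample_label
        assert t1.bases == t2.bases
        assert (a1.strand, a2.strand) == ("forward", "reverse")


class TestEditMode:
    def test_two_edits_per_index_still_assigned(self, template_a, panel, primers):
        full = template_a.full_sequence
        # two substitutions in each index region
        read = _read(_mutate(full, [2, 9, len(full) - 3, len(full) - 10]))
        assignment, trimmed = demux_edit_mode(read, panel, primers)
        assert assignment.assigned
        assert assignment.edits == (2, 2)
        # primers trimmed too: the insert remains
        assert trimmed.bases == template_a.insert

    def test_three_edits_unassigned(self, template_a, panel, primers):
        full = template_a.full_sequence
        read = _read(_mutate(full, [2, 9, 15]))  # 3 edits in forward index
        assignment, trimmed = demux_edit_mode(read, panel, primers)
        assert assignment.sample_label == UNASSIGNED and trimmed is None

    def test_battered_primer_is_retained_not_trimmed(self, template_a, panel, primers):
        """A primer beyond the edit budget leads to index-only trimming."""
        full = template_a.full_sequence
        n_idx = len(template_a.forward_index)
        # mutate ever more of the forward primer until no alignment within
        # the 11-edit budget remains (substitution count != edit distance)
        for n_mut in range(12, len(primers[0]) + 1):
            mutated = _mutate(full, [n_idx + i for i in range(n_mut)])
            window = mutated[n_idx : n_idx + len(primers[0]) + 15]
            if edlib.align(primers[0], window, mode="HW")["editDistance"] > 11:
                break
        else:
            pytest.fail("could not construct a >11-edit primer")
        read = _read(mutated)
        assignment, trimmed = demux_edit_mode(read, panel, primers)
        assert assignment.assigned
        # reverse primer trimmed, battered forward primer retained
        assert trimmed.bases.endswith(template_a.insert)
        assert len(trimmed.bases) == len(template_a.insert) + len(primers[0])

    def test_ambiguous_tie_between_pairs_unassigned(self, primers):
        fwd_a, rev_a = "A" * 10 + "C" * 14, "G" * 10 + "T" * 14
        # pair B differs from pair A at 4 positions in each index
        fwd_b = "T" * 2 + "A" * 8 + "C" * 12 + "G" * 2
        rev_b = "C" * 2 + "G" * 8 + "T" * 12 + "A" * 2
        panel = [IndexPair("sa", fwd_a, rev_a), IndexPair("sb", fwd_b, rev_b)]
        # read indexes halfway between A and B: edit distance 2 to both
        fwd_mid = "T" * 1 + "A" * 9 + "C" * 13 + "G" * 1
        rev_mid = "C" * 1 + "G" * 9 + "T" * 13 + "A" * 1
        insert = "ACGT" * 100
        read = _read(fwd_mid + insert + reverse_complement(rev_mid))
        assignment, trimmed = demux_edit_mode(read, panel, primers)
        assert assignment.sample_label == UNASSIGNED


class TestPartitionProperty:
    @pytest.mark.parametrize("mode", ["score", "edit"])
    def test_zero_error_reads_all_correctly_assigned(
        self, panel, panel_dicts, inserts, primers, mode
    ):
        """Error-free reads: 100% assignment accuracy, no cross-sample reads."""
        zero = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0)
        all_reads, labels = [], {}
        for k, p in enumerate(panel_dicts):
            template = AmpliconTemplate(
                f"t{k}", inserts[k % 2].bases, primers[0], primers[1],
                p["forward_index"], p["reverse_index"], p["sample_label"],
            )
            reads, _ = simulate_reads(
                template, 40, zero, 0.5, seed=100 + k, read_id_prefix=f"s{k}"
            )
            all_reads.extend(reads)
            labels.update({r.read_id: p["sample_label"] for r in reads})
        by_sample, log = demux_reads(
            all_reads, panel, mode=mode, primers=primers
        )
        assigned = [(lab, r.read_id) for lab, rs in by_sample.items() for r in rs]
        assert len(assigned) == len(all_reads)  # everyone assigned exactly once
        assert len({rid for _, rid in assigned}) == len(all_reads)
        assert all(labels[rid] == lab for lab, rid in assigned)
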