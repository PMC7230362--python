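"""Simulator calibration: error rates, homopolymer bias, strands, mixing."""

import edlib
import numpy as np
import pytest
from scipy import stats

from ampcon.seq_io import reverse_complement, write_fastq
from ampcon.simulate import (
    AmpliconTemplate,
    ErrorModel,
    homopolymer_mask,
    mix_contamination,
    simulate_reads,
)

ZERO = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0)


def test_zero_error_reads_equal_template_either_strand(template_a):
    reads, truth = simulate_reads(template_a, 50, ZERO, 0.5, seed=3)
    full = template_a.full_sequence
    for read, strand in zip(reads, truth["strand"]):
        expected = full if strand == "forward" else reverse_complement(full)
        assert read.bases == expected


def test_same_seed_is_byte_identical(template_a, tmp_path):
    a, _ = simulate_reads(template_a, 200, ErrorModel(), 0.5, seed=5)
    b, _ = simulate_reads(template_a, 200, ErrorModel(), 0.5, seed=5)
    pa, pb = tmp_path / "a.fastq", tmp_path / "b.fastq"
    write_fastq(a, pa)
    write_fastq(b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_realized_edit_rate_matches_configured_rates(template_a):
    """Mean edit distance to the template tracks sub+ins+del rates.

    The minimal edit distance undercuts the true event count slightly
    (an adjacent insertion+deletion collapses into one substitution), so
    the realized mean must fall between 90% of the event expectation and
    the expectation plus 3 standard errors.
    """
    model = ErrorModel(homopolymer_del_multiplier=1.0)
    n = 1000
    reads, _ = simulate_reads(template_a, n, model, 1.0, seed=13)
    full = template_a.full_sequence
    length = len(full)
    dists = np.array(
        [edlib.align(r.bases, full)["editDistance"] for r in reads], dtype=float
    )
    expected = length * (model.sub_rate + model.del_rate + model.ins_rate)
    se = np.sqrt(length * 0.09 * 0.91) / np.sqrt(n)
    assert 0.90 * expected < dists.mean() < expected + 3 * se


def test_error_class_counts_chi_square(template_a):
    """Per-class event counts over >=1e5 bases match configured rates.

    Each class is simulated in isolation so that cigar-based counting is
    unbiased (mixed classes let the aligner collapse adjacent indels into
    substitutions), then the three observed totals are tested against their
    common expectation by chi-square at alpha = 0.01.
    """
    import re

    full = template_a.full_sequence
    observed = []
    for seed, kwargs, op in [
        (17, dict(sub_rate=0.03, ins_rate=0, del_rate=0), "X"),
        (18, dict(sub_rate=0, ins_rate=0.03, del_rate=0), "I"),
        (19, dict(sub_rate=0, ins_rate=0, del_rate=0.03), "D"),
    ]:
        model = ErrorModel(homopolymer_del_multiplier=1.0, **kwargs)
        reads, _ = simulate_reads(template_a, 300, model, 1.0, seed=seed)
        assert 300 * len(full) >= 1e5
        count = 0
        for r in reads:
            cigar = edlib.align(r.bases, full, task="path")["cigar"]
            count += sum(
                int(m.group(1))
                for m in re.finditer(r"(\d+)([=XID])", cigar)
                if m.group(2) == op
            )
        observed.append(count)
    _, p = stats.chisquare(np.array(observed, dtype=float))
    assert p > 0.01


def test_homopolymer_deletions_scale_with_multiplier():
    """A half-homopolymer template loses bases at multiplier-weighted rate."""
    insert = "A" * 200 + "ACGT" * 50  # 50% one long homopolymer, 50% run-free
    template = AmpliconTemplate(
        "hp", insert, "ACGTACGTACGTACGTACGTACGTA", "TGCATGCATGCATGCATGCATGCAT",
        "A" * 12 + "C" * 12, "G" * 12 + "T" * 12,
    )
    model = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0.02,
                       homopolymer_del_multiplier=3.0)
    reads, _ = simulate_reads(template, 500, model, 1.0, seed=19)
    full = template.full_sequence
    hp = homopolymer_mask(full, 3)
    expected_loss = 0.02 * 3 * hp.sum() + 0.02 * (len(full) - hp.sum())
    losses = np.array([len(full) - len(r) for r in reads], dtype=float)
    se = losses.std(ddof=1) / np.sqrt(len(losses))
    assert abs(losses.mean() - expected_loss) < 4 * se


def test_strand_fraction_within_binomial_error(template_a):
    _, truth = simulate_reads(template_a, 2000, ZERO, 0.5, seed=23)
    n_fwd = (truth["strand"] == "forward").sum()
    assert abs(n_fwd - 1000) < 4 * np.sqrt(2000 * 0.25)


def test_chimera_rate_produces_double_length_reads(template_a):
    reads, truth = simulate_reads(template_a, 200, ZERO, 1.0, seed=29, chimera_rate=0.1)
    n_long = sum(len(r) > 1.5 * len(template_a.full_sequence) for r in reads)
    assert n_long == truth["chimeric"].sum() > 0


def test_degenerate_template_rejected(primers, panel_dicts):
    with pytest.raises(ValueError, match="empty insert"):
        AmpliconTemplate(
            "bad", "", primers[0], primers[1],
            panel_dicts[0]["forward_index"], panel_dicts[0]["reverse_index"],
        )


class TestMixContamination:
    def test_zero_fraction_returns_primary_unchanged(self, clean_reads_a):
        reads, truth = clean_reads_a
        mixed, _ = mix_contamination(reads, reads[:10], 0.0, seed=1)
        assert mixed == list(reads)

    @pytest.mark.parametrize("fraction,total,expected", [(0.22, 1000, 220), (0.039, 1000, 39)])
    def test_exact_contaminant_count(self, template_a, template_b, fraction, total, expected):
        ra, ta = simulate_reads(template_a, total, ZERO, 0.5, seed=31)
        rb, tb = simulate_reads(template_b, 300, ZERO, 0.5, seed=37)
        mixed, truth = mix_contamination(
            ra, rb, fraction, seed=41, primary_truth=ta, contaminant_truth=tb
        )
        assert len(mixed) == total
        assert (truth["template"] == "B").sum() == expected
        # truth rows stay aligned with the shuffled reads
        assert list(truth["read_id"]) == [r.read_id for r in mixed]

    def test_fraction_out_of_range_rejected(self, clean_reads_a):
        reads, _ = clean_reads_a
        with pytest.raises(ValueError, match="fraction"):
            mix_contamination(reads, reads, 1.0, seed=1)
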