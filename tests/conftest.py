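"""Shared fixtures: bundled synthetic references and simulated read sets."""

import pytest

from ampcon.demux import IndexPair
from ampcon.references import toy_index_panel, toy_inserts, toy_primers
from ampcon.simulate import AmpliconTemplate, ErrorModel, simulate_reads


@pytest.fixture(scope="session")
def inserts():
    return toy_inserts()


@pytest.fixture(scope="session")
def primers():
    fwd, rev = toy_primers()
    return fwd.bases, rev.bases


@pytest.fixture(scope="session")
def panel_dicts():
    return toy_index_panel(3)


@pytest.fixture(scope="session")
def panel(panel_dicts):
    return [
        IndexPair(p["sample_label"], p["forward_index"], p["reverse_index"])
        for p in panel_dicts
    ]


@pytest.fixture(scope="session")
def template_a(inserts, primers, panel_dicts):
    p = panel_dicts[0]
    return AmpliconTemplate(
        name="A",
        insert=inserts[0].bases,
        forward_primer=primers[0],
        reverse_primer=primers[1],
        forward_index=p["forward_index"],
        reverse_index=p["reverse_index"],
        sample_label=p["sample_label"],
    )


@pytest.fixture(scope="session")
def template_b(inserts, primers, panel_dicts):
    """Contaminant template: different insert, same index pair as A."""
    p = panel_dicts[0]
    return AmpliconTemplate(
        name="B",
        insert=inserts[1].bases,
        forward_primer=primers[0],
        reverse_primer=primers[1],
        forward_index=p["forward_index"],
        reverse_index=p["reverse_index"],
        sample_label=p["sample_label"],
    )


@pytest.fixture(scope="session")
def clean_reads_a(template_a):
    """120 error-free reads from template A, both strands."""
    reads, truth = simulate_reads(
        template_a,
        120,
        ErrorModel(sub_rate=0, ins_rate=0, del_rate=0),
        strand_fraction=0.5,
        seed=7,
    )
    return reads, truth


@pytest.fixture(scope="session")
def noisy_reads_a(template_a):
    """400 reads from template A at the default ~9% error rate."""
    reads, truth = simulate_reads(template_a, 400, ErrorModel(), 0.5, seed=11)
    return reads, truth
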