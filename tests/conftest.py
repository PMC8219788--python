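"""Shared fixtures: synthetic data sets reused across test modules."""

import pytest

import rhabdotools as rt
from rhabdotools.simulate import (
    SimConfig,
    simulate_annotated_genome,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def transcript_mixture():
    """2,000-transcript host/contaminant mixture with planted truth.

    1,800 host transcripts (exonic GC ~= 0.58, 15.3% SL-tagged) plus 200
    contaminants from an AT-rich codon model (GC ~= 0.35).
    """
    config = SimConfig(
        seed=11, n_genes=1800, introns_per_gene=0, contaminant_fraction=0.1
    )
    _, genome_truth = simulate_annotated_genome(config)
    transcripts, truth = simulate_transcriptome(genome_truth, config)
    return transcripts, truth["transcripts"]


@pytest.fixture(scope="session")
def host_reference_table():
    """Codon-usage table built from an independent host-model CDS sample."""
    config = SimConfig(seed=400, n_genes=300, introns_per_gene=0)
    _, truth = simulate_annotated_genome(config)
    reference = [
        rt.SeqRecord(id=row.gene_id, seq=row.mrna)
        for row in truth["genes"].itertuples()
    ]
    return rt.build_codon_usage(reference)


@pytest.fixture(scope="session")
def intron_simulation():
    """Small intron-rich genome plus spliced transcripts, with truth."""
    config = SimConfig(
        seed=21,
        n_genes=10,
        introns_per_gene=2,
        nonconventional_fraction=0.3,
        sl_fraction=0.2,
        contaminant_fraction=0.0,
    )
    contigs, genome_truth = simulate_annotated_genome(config)
    transcripts, tx_truth = simulate_transcriptome(genome_truth, config)
    return contigs, transcripts, genome_truth.merge(tx_truth)
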