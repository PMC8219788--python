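"""Codon-usage tables, CAI, ORF selection and contaminant screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhabdotools.decontam import (
    build_codon_usage,
    cai,
    classify_contaminants,
    find_orf,
)
from rhabdotools.records import SeqRecord, revcomp
from rhabdotools.simulate import SimConfig, simulate_annotated_genome


def _single_codon_reference():
    # every amino acid encoded by exactly one codon
    return [SeqRecord(id="ref", seq="ATGTTTAAACCCGGG")]


class TestCodonUsage:
    def test_single_codon_per_family_gives_w_one(self):
        table = build_codon_usage(_single_codon_reference(), pseudo=0.0)
        for codon in ("TTT", "AAA", "CCC", "GGG"):
            assert table.w[codon] == 1.0

    def test_relative_adaptiveness_ratio(self):
        # Leu observed as CTG:9, CTA:1 -> w(CTG)=1, w(CTA)=1/9
        reference = [SeqRecord(id="r", seq="CTG" * 9 + "CTA")]
        table = build_codon_usage(reference, pseudo=0.0)
        assert table.w["CTG"] == 1.0
        assert table.w["CTA"] == pytest.approx(1 / 9)

    def test_pseudo_count_keeps_w_positive(self):
        table = build_codon_usage(_single_codon_reference(), pseudo=0.5)
        assert all(w > 0 for w in table.w.values())

    def test_stop_codons_not_counted(self):
        table = build_codon_usage([SeqRecord(id="r", seq="TTTTAA")])
        assert "TAA" not in table.counts or table.counts.get("TAA", 0) == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_codon_usage([])


class TestCai:
    @pytest.fixture()
    def leu_table(self):
        return build_codon_usage(
            [SeqRecord(id="r", seq="CTG" * 9 + "CTA")], pseudo=0.0
        )

    def test_hand_computed_geometric_mean(self, leu_table):
        # sqrt(1 * 1/9) = 0.3333
        assert cai("CTGCTA", leu_table) == pytest.approx(1 / 3, abs=1e-4)

    def test_optimal_codons_give_one(self, leu_table):
        assert cai("CTGCTGCTG", leu_table) == pytest.approx(1.0)

    def test_single_codon_families_excluded(self, leu_table):
        # ATG and TGG carry no information and must not dilute the mean
        assert cai("ATGCTGCTATGG", leu_table) == pytest.approx(1 / 3, abs=1e-4)

    @given(st.permutations(["CTG", "CTA", "CTG", "CTT", "CTC"]))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_codon_order(self, codons):
        table = build_codon_usage(
            [SeqRecord(id="r", seq="CTG" * 9 + "CTA" * 3 + "CTT" * 2 + "CTC")],
            pseudo=0.5,
        )
        assert cai("".join(codons), table) == pytest.approx(
            cai("CTGCTACTGCTTCTC", table)
        )

    def test_no_informative_codons_is_an_error(self, leu_table):
        with pytest.raises(ValueError):
            cai("ATGTGG", leu_table)

    def test_bounded_in_unit_interval(self):
        table = build_codon_usage(
            [SeqRecord(id="r", seq="CTG" * 9 + "CTA" * 3 + "TTT" * 2)], pseudo=0.5
        )
        rng = np.random.default_rng(0)
        codons = ["CTG", "CTA", "CTT", "CTC", "TTT", "TTC"]
        for _ in range(20):
            seq = "".join(rng.choice(codons, size=30))
            assert 0 < cai(seq, table) <= 1


def _find_orf_oracle(seq, min_len):
    """Brute force: longest stop-free codon run over all six frames."""
    from rhabdotools.decontam import STOP_CODONS

    best = None  # (length, frame, start, end)
    for frame in range(6):
        oriented = seq if frame < 3 else revcomp(seq)
        offset = frame % 3
        start = offset
        pos = offset
        while pos + 3 <= len(oriented) + 3:
            codon = oriented[pos : pos + 3]
            if len(codon) < 3 or codon in STOP_CODONS:
                run = pos - start
                if run >= min_len and (best is None or run > best[0]):
                    best = (run, frame, start, pos)
                start = pos + 3
            pos += 3
    return best


class TestFindOrf:
    # "TTAA" repeats place a stop every four bases in all six frames
    STOP_DENSE = "TTAA" * 20

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
            orf = find_orf(seq, min_len=90)
            oracle = _find_orf_oracle(seq, min_len=90)
            if oracle is None:
                assert orf is None
            else:
                assert orf is not None
                assert (orf.end - orf.start, orf.frame, orf.start, orf.end) == oracle

    def test_reverse_strand_orf_found(self):
        # random CDS planted antisense: its own strand is the only one with
        # a long stop-free run (the forward strand hits stops quickly)
        from rhabdotools.decontam import STOP_CODONS

        sense = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in STOP_CODONS
        ]
        rng = np.random.default_rng(0)
        cds = "ATG" + "".join(rng.choice(sense, size=80)) + "TAA"
        seq = revcomp(self.STOP_DENSE + cds + self.STOP_DENSE)
        orf = find_orf(seq, min_len=150)
        assert orf is not None
        assert orf.frame >= 3
        assert cds[:-3] in orf.seq

    def test_stop_dense_sequence_has_no_orf(self):
        assert find_orf(self.STOP_DENSE * 4, min_len=150) is None


class TestClassifyContaminants:
    def test_conjunctive_rule_on_planted_mixture(
        self, transcript_mixture, host_reference_table
    ):
        transcripts, truth = transcript_mixture
        qc = classify_contaminants(transcripts, host_reference_table)
        truth_map = dict(zip(truth.transcript_id, truth.contaminant))
        tp = sum(1 for q in qc if q.contaminant and truth_map[q.id])
        fp = sum(1 for q in qc if q.contaminant and not truth_map[q.id])
        fn = sum(1 for q in qc if not q.contaminant and truth_map[q.id])
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.9
        assert recall >= 0.9

    def test_single_low_measure_is_kept(self, host_reference_table):
        # an AT-rich but well-adapted CDS must survive the conjunctive rule:
        # build it from the host table's per-family optimal codons with low GC
        optimal = [c for c, w in host_reference_table.w.items() if w == 1.0]
        at_rich = sorted(optimal, key=lambda c: c.count("G") + c.count("C"))[:4]
        seq = "".join(at_rich) * 30
        record = SeqRecord(id="t", seq=seq)
        (qc,) = classify_contaminants([record], host_reference_table)
        assert qc.cai > 0.45  # optimal codons only
        assert qc.contaminant is False

    def test_transcript_without_orf_is_unclassified(self, host_reference_table):
        record = SeqRecord(id="t", seq="TTAA" * 60)
        (qc,) = classify_contaminants([record], host_reference_table)
        assert qc.contaminant is None
        assert qc.reason == "no_orf"

    def test_raising_thresholds_grows_flagged_set(
        self, transcript_mixture, host_reference_table
    ):
        transcripts, _ = transcript_mixture
        subset = transcripts[::20]
        flagged = {}
        for thr in (0.35, 0.45, 0.55):
            qc = classify_contaminants(
                subset, host_reference_table, gc_threshold=thr, cai_threshold=thr
            )
            flagged[thr] = {q.id for q in qc if q.contaminant}
        assert flagged[0.35] <= flagged[0.45] <= flagged[0.55]

    def test_reference_separates_from_disjoint_codon_model(
        self, host_reference_table
    ):
        host_cfg = SimConfig(seed=91, n_genes=40, introns_per_gene=0)
        _, host_truth = simulate_annotated_genome(host_cfg)
        host_cai = [
            cai(row.mrna[3:-3], host_reference_table)
            for row in host_truth["genes"].itertuples()
        ]
        from rhabdotools.simulate import _sample_cds

        rng = np.random.default_rng(92)
        foreign_cai = [
            cai(_sample_cds(rng, 200, 0.35, "contaminant"), host_reference_table)
            for _ in range(40)
        ]
        assert np.mean(host_cai) > np.mean(foreign_cai)
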