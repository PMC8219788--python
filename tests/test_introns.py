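"""Spliced alignment, intron extraction, classification and stem scoring."""

import itertools

import numpy as np
import pytest

from rhabdotools.introns import (
    IntronCall,
    SplicedAlignment,
    boundary_pfm,
    call_introns,
    classify_intron,
    extract_introns,
    map_intron_positions,
    spliced_align,
    stem_loop_score,
)
from rhabdotools.records import SeqRecord, revcomp


def _bases(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestClassify:
    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [
            ("GT", "AG", "conventional"),
            ("GC", "AG", "conventional"),
            ("CT", "AC", "nonconventional"),
            ("GT", "AC", "nonconventional"),
            ("AA", "AG", "nonconventional"),
        ],
    )
    def test_rule(self, donor, acceptor, expected):
        assert classify_intron(donor, acceptor) == expected

    def test_exhaustive_partition_of_all_256_pairs(self):
        pairs = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        conventional = [
            (d, a)
            for d in pairs
            for a in pairs
            if classify_intron(d, a) == "conventional"
        ]
        # exactly GT/AG and GC/AG; the other 254 combinations are nonconventional
        assert sorted(conventional) == [("GC", "AG"), ("GT", "AG")]

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_intron("GN", "AG")


class TestSplicedAlign:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(42)
        exon1, exon2 = _bases(rng, 300), _bases(rng, 250)
        intron = "GT" + _bases(rng, 196) + "AG"
        # junction bases chosen so the gap placement is unambiguous
        if exon2[0] == intron[0]:
            exon2 = "C" + exon2[1:]
        if exon1[-1] == intron[-1]:
            exon1 = exon1[:-1] + "T"
        contig = SeqRecord(id="c", seq=exon1 + intron + exon2)
        tx = SeqRecord(id="t", seq=exon1 + exon2)
        return tx, contig, len(exon1), len(intron)

    def test_two_blocks_with_exact_coordinates(self, planted):
        tx, contig, exon1_len, intron_len = planted
        aln = spliced_align(tx, contig)
        assert aln is not None
        assert aln.blocks == [
            (0, exon1_len, 0, exon1_len),
            (exon1_len + intron_len, len(contig.seq), exon1_len, len(tx.seq)),
        ]
        assert not aln.query_revcomp

    def test_reverse_complemented_transcript_normalised(self, planted):
        tx, contig, exon1_len, intron_len = planted
        flipped = SeqRecord(id="t", seq=revcomp(tx.seq))
        aln = spliced_align(flipped, contig)
        assert aln is not None
        assert aln.query_revcomp
        assert aln.blocks == spliced_align(tx, contig).blocks

    def test_unrelated_sequences_return_none(self):
        rng = np.random.default_rng(0)
        tx = SeqRecord(id="t", seq=_bases(rng, 400))
        contig = SeqRecord(id="c", seq=_bases(rng, 800))
        assert spliced_align(tx, contig) is None


class TestExtractIntrons:
    def _alignment(self, blocks, tx_len, contig_len):
        return SplicedAlignment(
            transcript_id="t",
            contig_id="c",
            strand="+",
            blocks=blocks,
            transcript_len=tx_len,
            contig_len=contig_len,
        )

    def test_genomic_gap_becomes_intron(self, ):
        rng = np.random.default_rng(1)
        exon1, exon2 = _bases(rng, 100), _bases(rng, 100)
        intron = "GT" + _bases(rng, 196) + "AG"
        contig = SeqRecord(id="c", seq=exon1 + intron + exon2)
        aln = self._alignment(
            [(0, 100, 0, 100), (300, 400, 100, 200)], 200, 400
        )
        (call,) = extract_introns(aln, contig)
        assert (call.start, call.end) == (100, 300)
        assert call.completeness == "complete"
        assert call.type == "conventional"

    def test_small_gap_is_an_indel_not_an_intron(self):
        rng = np.random.default_rng(2)
        contig = SeqRecord(id="c", seq=_bases(rng, 210))
        aln = self._alignment([(0, 100, 0, 100), (110, 210, 100, 200)], 200, 210)
        assert extract_introns(aln, contig, min_intron=30) == []

    def test_truncated_contig_yields_incomplete_3p(self):
        rng = np.random.default_rng(3)
        exon1 = _bases(rng, 500)
        donor_side = "GT" + _bases(rng, 20)
        contig = SeqRecord(id="c", seq=exon1 + donor_side)
        aln = self._alignment([(0, 500, 0, 500)], 550, len(contig.seq))
        (call,) = extract_introns(aln, contig)
        assert call.completeness == "incomplete_3p"
        assert call.donor == "GT"
        assert call.acceptor is None
        assert call.type is None

    def test_truncated_contig_yields_incomplete_5p(self):
        rng = np.random.default_rng(4)
        exon2 = _bases(rng, 500)
        acceptor_side = _bases(rng, 20) + "AG"
        contig = SeqRecord(id="c", seq=acceptor_side + exon2)
        aln = self._alignment([(22, 522, 50, 550)], 550, len(contig.seq))
        (call,) = extract_introns(aln, contig)
        assert call.completeness == "incomplete_5p"
        assert call.acceptor == "AG"
        assert call.donor is None

    def test_out_of_order_blocks_rejected(self):
        with pytest.raises(ValueError):
            self._alignment([(200, 300, 0, 100), (0, 100, 100, 200)], 200, 400)

    def test_minus_strand_boundaries_read_reverse_complemented(self):
        rng = np.random.default_rng(5)
        exon1, exon2 = _bases(rng, 100), _bases(rng, 100)
        intron_plus = "CT" + _bases(rng, 96) + "AC"  # GT...AG on the minus strand
        contig = SeqRecord(id="c", seq=exon1 + intron_plus + exon2)
        aln = SplicedAlignment(
            transcript_id="t",
            contig_id="c",
            strand="-",
            blocks=[(200, 300, 0, 100), (0, 100, 100, 200)],
            transcript_len=200,
            contig_len=300,
        )
        (call,) = extract_introns(aln, contig)
        assert (call.start, call.end) == (100, 200)
        assert call.donor == "GT"
        assert call.acceptor == "AG"
        assert call.type == "conventional"


class TestAmbiguousJunctions:
    def test_repeat_junction_left_shift_then_gt_ag_recovery(self):
        rng = np.random.default_rng(6)
        # exon1 ends with G, intron ends ...AG: placements [s, e) and
        # [s-1, e-1) are equivalent; the GT..AG scan must restore the
        # canonical placement
        exon1 = _bases(rng, 120)[:-1] + "G"
        intron = "GT" + _bases(rng, 150) + "AG"
        exon2 = "A" + _bases(rng, 119)  # right shift invalid (A != G donor start)
        contig = SeqRecord(id="c", seq=exon1 + intron + exon2)
        tx = SeqRecord(id="t", seq=exon1 + exon2)
        aln = spliced_align(tx, contig)
        (call,) = extract_introns(aln, contig)
        assert (call.start, call.end) == (120, 120 + len(intron))
        assert (call.donor, call.acceptor) == ("GT", "AG")


class TestPlantedRecovery:
    def test_full_recovery_on_simulated_genes(self, intron_simulation):
        contigs, transcripts, truth = intron_simulation
        calls = call_introns(transcripts, contigs)
        called = {
            (c.contig, c.start, c.end, c.type)
            for c in calls
            if c.completeness == "complete"
        }
        planted = {
            (r.contig, r.start, r.end, r.type)
            for r in truth["introns"].itertuples()
        }
        assert called == planted

    def test_classifier_agrees_with_planted_types(self, intron_simulation):
        _, _, truth = intron_simulation
        for row in truth["introns"].itertuples():
            assert classify_intron(row.donor, row.acceptor) == row.type

    def test_stem_scores_separate_intron_types(self, intron_simulation):
        contigs, _, truth = intron_simulation
        by_id = {c.id: c for c in contigs}
        scores = {"conventional": [], "nonconventional": []}
        for row in truth["introns"].itertuples():
            seq = by_id[row.contig].seq[row.start : row.end]
            score, _pairs = stem_loop_score(seq, window=20)
            scores[row.type].append(score)
        assert all(s == 20 for s in scores["nonconventional"])
        assert np.mean(scores["conventional"]) < 8


class TestStemLoopScore:
    def test_direct_complement_run(self):
        rng = np.random.default_rng(7)
        seq = "AAGGGG" + _bases(rng, 50) + "CCCCTT"
        score, pairs = stem_loop_score(seq, window=6)
        assert score == 6
        assert pairs[0] == (0, len(seq) - 1)

    def test_poly_a_scores_zero(self):
        assert stem_loop_score("A" * 80, window=20)[0] == 0

    def test_gu_wobble_counts_when_allowed(self):
        seq = "GGGGGG" + "A" * 40 + "TTTTTT"
        assert stem_loop_score(seq, window=6, allow_gu=True)[0] == 6
        assert stem_loop_score(seq, window=6, allow_gu=False)[0] == 0

    def test_revcomp_invariance_watson_crick(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            seq = _bases(rng, 120)
            fwd, _ = stem_loop_score(seq, window=20, allow_gu=False)
            rev, _ = stem_loop_score(revcomp(seq), window=20, allow_gu=False)
            assert fwd == rev

    def test_window_shrinks_for_short_introns(self):
        seq = "GGGAAACCC"  # length 9 -> window 4
        score, _ = stem_loop_score(seq, window=20)
        assert score >= 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            stem_loop_score("")


class TestBoundaryPfm:
    def test_columns_sum_to_one_and_identical_boundaries_are_pure(
        self, intron_simulation
    ):
        contigs, transcripts, truth = intron_simulation
        calls = call_introns(transcripts, contigs)
        complete = [c for c in calls if c.completeness == "complete"]
        pfm = boundary_pfm(complete, contigs, flank=5)
        assert np.allclose(pfm.sum(axis=0), 1.0, atol=1e-12)
        # donor dinucleotide sits at offsets flank, flank+1; conventional
        # introns dominate, so G is the majority base at the donor position
        assert pfm.loc["G", 5] > 0.5

    def test_hand_counted_frequencies(self):
        seqs = {
            "c1": "A" * 10 + "GTAAACCAG" + "A" * 10,
            "c2": "A" * 10 + "GTCCCGGAG" + "A" * 10,
            "c3": "A" * 10 + "CTTTTTTAC" + "A" * 10,
        }
        contigs = {k: SeqRecord(id=k, seq=v) for k, v in seqs.items()}
        calls = [
            IntronCall(contig=k, start=10, end=19, donor=v[10:12], acceptor=v[17:19])
            for k, v in seqs.items()
        ]
        pfm = boundary_pfm(calls, contigs, flank=2)
        # donor position: G,G,C -> G 2/3, C 1/3
        assert pfm.loc["G", 2] == pytest.approx(2 / 3)
        assert pfm.loc["C", 2] == pytest.approx(1 / 3)

    def test_edge_introns_skipped_with_warning(self):
        contig = SeqRecord(id="c", seq="GTAAAAAAAG" + "A" * 30)
        call = IntronCall(contig="c", start=0, end=10, donor="GT", acceptor="AG")
        far = IntronCall(contig="c", start=12, end=30, donor="AA", acceptor="AA")
        with pytest.warns(UserWarning):
            pfm = boundary_pfm([call, far], {"c": contig}, flank=5)
        assert np.allclose(pfm.sum(axis=0), 1.0)


class TestMapIntronPositions:
    def test_shared_position_through_gapped_alignment(self):
        msa = [
            SeqRecord(id="g1", seq="MK--LVDE"),
            SeqRecord(id="g2", seq="MKAALVDE"),
        ]
        # g1 intron before residue 2 (L, column 4); g2 intron before its
        # residue 4 (L, column 4): same column, same phase -> shared
        table, matrix = map_intron_positions(
            [("g1", [(2, 0)]), ("g2", [(4, 0)])], msa
        )
        assert table["shared"].all()
        assert matrix.loc["g1", "g2"] == 1

    def test_different_phase_is_unique(self):
        msa = [
            SeqRecord(id="g1", seq="MKLV"),
            SeqRecord(id="g2", seq="MKLV"),
        ]
        table, matrix = map_intron_positions(
            [("g1", [(2, 0)]), ("g2", [(2, 1)])], msa
        )
        assert not table["shared"].any()
        assert matrix.loc["g1", "g2"] == 0

    def test_intron_in_region_absent_from_other_gene(self):
        msa = [
            SeqRecord(id="g1", seq="MKLVDE"),
            SeqRecord(id="g2", seq="MK--DE"),
        ]
        table, _ = map_intron_positions([("g1", [(3, 0)]), ("g2", [])], msa)
        assert list(table["shared"]) == [False]

    def test_gene_without_introns_has_empty_row(self):
        msa = [SeqRecord(id="g1", seq="MKLV")]
        table, matrix = map_intron_positions([("g1", [])], msa)
        assert table.empty
        assert matrix.loc["g1", "g1"] == 0

    def test_missing_msa_row_rejected(self):
        with pytest.raises(ValueError):
            map_intron_positions([("gX", [(0, 0)])], [SeqRecord(id="g1", seq="MK")])
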