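"""Intron discovery from spliced transcript-to-genome alignments.

Euglenid genes carry both conventional spliceosomal introns (GT or GC
donor, AG acceptor) and nonconventional introns whose boundaries follow no
dinucleotide rule but base-pair with each other, folding the intron ends
into a stem.  This module extracts introns from exon-block alignments,
classifies their boundaries, scores the stem-forming potential of intron
ends, builds boundary position-frequency matrices for logo rendering, and
maps intron positions between homologous genes through a protein MSA.

The built-in :func:`spliced_align` is an exact-match anchor chainer meant
for error-free synthetic data only; alignments of real reads come from an
external spliced aligner and enter as exon-block tables.

Coordinates are 0-based half-open on the contig's forward strand.  Blocks
are ordered along the mRNA; ``strand`` is the contig strand carrying the
mRNA sense, so for ``-`` alignments the genomic coordinates decrease along
the transcript and boundary dinucleotides are read reverse-complemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import SeqRecord, revcomp

MIN_INTRON_DEFAULT = 30
MIN_ANCHOR_DEFAULT = 20
STEM_WINDOW_DEFAULT = 20

CONVENTIONAL_DONORS = frozenset({"GT", "GC"})
CONVENTIONAL_ACCEPTOR = "AG"

_PAIRS_WC = frozenset({"AT", "TA", "GC", "CG"})
_PAIRS_GU = frozenset({"GT", "TG"})


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

Block = Tuple[int, int, int, int]  # genome start, genome end, tx start, tx end


@dataclass
class SplicedAlignment:
    """Gapped transcript-to-contig alignment as match-only exon blocks."""

    transcript_id: str
    contig_id: str
    strand: str  # contig strand carrying the mRNA sense
    blocks: List[Block]
    transcript_len: int
    contig_len: int
    query_revcomp: bool = False  # input record was antisense to the mRNA

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.validate()

    def validate(self) -> None:
        prev: Optional[Block] = None
        for blk in self.blocks:
            gs, ge, ts, te = blk
            if not (0 <= gs < ge <= self.contig_len and 0 <= ts < te <= self.transcript_len):
                raise ValueError(f"block {blk} out of bounds")
            if ge - gs != te - ts:
                raise ValueError(f"block {blk} has unequal genome/transcript spans")
            if prev is not None:
                if ts < prev[3]:
                    raise ValueError("blocks out of order on transcript")
                if self.strand == "+" and gs < prev[1]:
                    raise ValueError("blocks out of order on genome (+)")
                if self.strand == "-" and ge > prev[0]:
                    raise ValueError("blocks out of order on genome (-)")
            prev = blk

    @property
    def coverage(self) -> float:
        return sum(te - ts for _, _, ts, te in self.blocks) / self.transcript_len


@dataclass
class IntronCall:
    """One genomic intron interval with boundary evidence."""

    contig: str
    start: int  # 0-based, half-open, forward contig coordinates
    end: int
    strand: str = "+"
    donor: Optional[str] = None  # gene-sense dinucleotides
    acceptor: Optional[str] = None
    type: Optional[str] = None  # conventional | nonconventional | None (undetermined)
    completeness: str = "complete"  # complete | incomplete_5p | incomplete_3p
    support: Tuple[str, ...] = ()
    stem_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"invalid intron interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def intermediate(self) -> bool:
        """Exactly one boundary matches the conventional pattern."""
        has_donor = self.donor in CONVENTIONAL_DONORS if self.donor else False
        has_acceptor = self.acceptor == CONVENTIONAL_ACCEPTOR if self.acceptor else False
        return has_donor != has_acceptor


# ---------------------------------------------------------------------------
# Boundary classification
# ---------------------------------------------------------------------------

def classify_intron(donor: str, acceptor: str) -> str:
    """'conventional' iff donor is GT or GC and acceptor is AG."""
    donor = donor.upper()
    acceptor = acceptor.upper()
    for name, dinuc in (("donor", donor), ("acceptor", acceptor)):
        if len(dinuc) != 2 or set(dinuc) - set("ACGT"):
            raise ValueError(f"{name} must be a dinucleotide over ACGT, got {dinuc!r}")
    if donor in CONVENTIONAL_DONORS and acceptor == CONVENTIONAL_ACCEPTOR:
        return "conventional"
    return "nonconventional"


# ---------------------------------------------------------------------------
# Synthetic-data spliced aligner (exact anchors + collinear chaining)
# ---------------------------------------------------------------------------

def _maximal_matches(query: str, target: str, min_anchor: int) -> List[Block]:
    """Maximal exact matches >= min_anchor as (gs, ge, ts, te) blocks."""
    index: Dict[str, List[int]] = {}
    for g in range(len(target) - min_anchor + 1):
        index.setdefault(target[g : g + min_anchor], []).append(g)
    seen = set()
    blocks: List[Block] = []
    for t in range(len(query) - min_anchor + 1):
        kmer = query[t : t + min_anchor]
        for g in index.get(kmer, ()):
            # extend to the maximal match on this diagonal
            ts, gs = t, g
            while ts > 0 and gs > 0 and query[ts - 1] == target[gs - 1]:
                ts -= 1
                gs -= 1
            te, ge = t + min_anchor, g + min_anchor
            while te < len(query) and ge < len(target) and query[te] == target[ge]:
                te += 1
                ge += 1
            key = (gs, ts, te - ts)
            if key not in seen:
                seen.add(key)
                blocks.append((gs, ge, ts, te))
    return blocks


def _chain(blocks: List[Block], transcript_len: int) -> List[Block]:
    """Highest-coverage collinear chain; overlaps trimmed afterwards."""
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b[2], b[0]))
    n = len(blocks)
    score = [0] * n
    parent = [-1] * n
    for i, (gs, ge, ts, te) in enumerate(blocks):
        score[i] = te - ts
        for j in range(i):
            pgs, pge, pts, pte = blocks[j]
            # allow small overlap from junction micro-homology; both axes
            # must still advance after trimming
            overlap = max(0, pte - ts, pge - gs)
            if te - (ts + overlap) <= 0:
                continue
            gain = te - (ts + overlap)
            if score[j] + gain > score[i]:
                score[i] = score[j] + gain
                parent[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain: List[Block] = []
    i = best
    while i != -1:
        chain.append(blocks[i])
        i = parent[i]
    chain.reverse()
    # trim overlaps toward the later block
    trimmed: List[Block] = [chain[0]]
    for gs, ge, ts, te in chain[1:]:
        pgs, pge, pts, pte = trimmed[-1]
        cut = max(0, pte - ts, pge - gs)
        gs, ts = gs + cut, ts + cut
        if te > ts:
            trimmed.append((gs, ge, ts, te))
    return trimmed


def spliced_align(
    transcript: SeqRecord,
    contig: SeqRecord,
    min_anchor: int = MIN_ANCHOR_DEFAULT,
    min_coverage: float = 0.9,
) -> Optional[SplicedAlignment]:
    """Chain exact anchor matches of the transcript within one contig.

    Both transcript orientations are tried against the forward contig; the
    orientation covering more of the transcript wins.  Returns ``None``
    when less than ``min_coverage`` of the transcript is covered.  Intended
    for error-free synthetic data; real alignments enter as block tables.
    """
    best: Optional[SplicedAlignment] = None
    for is_rc in (False, True):
        oriented = revcomp(transcript.seq) if is_rc else transcript.seq
        chain = _chain(
            _maximal_matches(oriented, contig.seq, min_anchor), len(oriented)
        )
        if not chain:
            continue
        aln = SplicedAlignment(
            transcript_id=transcript.id,
            contig_id=contig.id,
            strand="+",
            blocks=chain,
            transcript_len=len(oriented),
            contig_len=len(contig.seq),
            query_revcomp=is_rc,
        )
        if best is None or aln.coverage > best.coverage:
            best = aln
    if best is None or best.coverage < min_coverage:
        return None
    return best


# ---------------------------------------------------------------------------
# Intron extraction
# ---------------------------------------------------------------------------

def _shift_gap(seq: str, start: int, end: int, max_right: int = 10) -> Tuple[int, int]:
    """Splice-aware placement of an ambiguous genomic gap.

    When a repeat at the junction makes several placements equivalent, the
    gap is first shifted maximally left, then moved right (bounded) to the
    first placement with GT/GC...AG boundaries, mimicking est2genome.
    """
    length = end - start
    while start > 0 and seq[start - 1] == seq[end - 1]:
        start -= 1
        end -= 1
    s = start
    for step in range(max_right + 1):
        t = start + step
        if step > 0 and seq[t - 1] != seq[t - 1 + length]:
            break  # placement no longer equivalent
        if seq[t : t + 2] in CONVENTIONAL_DONORS and seq[t + length - 2 : t + length] == CONVENTIONAL_ACCEPTOR:
            return t, t + length
    return s, s + length


def _boundaries(seq: str, start: int, end: int, strand: str) -> Tuple[str, str]:
    if strand == "+":
        return seq[start : start + 2], seq[end - 2 : end]
    return revcomp(seq[end - 2 : end]), revcomp(seq[start : start + 2])


def extract_introns(
    aln: SplicedAlignment,
    contig: SeqRecord,
    min_intron: int = MIN_INTRON_DEFAULT,
    min_tail: int = MIN_ANCHOR_DEFAULT,
) -> List[IntronCall]:
    """Turn genomic gaps between exon blocks into intron calls.

    A genomic gap >= ``min_intron`` with no transcript gap is a complete
    intron (smaller gaps are treated as indels and skipped).  A transcript
    overhang of at least ``min_tail`` that cannot fit on the contig
    (truncated contig) yields an incomplete call carrying only the observed
    boundary.
    """
    aln.validate()
    if aln.contig_id != contig.id:
        raise ValueError(
            f"alignment refers to {aln.contig_id!r}, got contig {contig.id!r}"
        )
    seq = contig.seq
    calls: List[IntronCall] = []
    for (pgs, pge, pts, pte), (gs, ge, ts, te) in zip(aln.blocks, aln.blocks[1:]):
        t_gap = ts - pte
        if aln.strand == "+":
            s, e = pge, gs
        else:
            s, e = ge, pgs
        g_gap = e - s
        if t_gap != 0 or g_gap < min_intron:
            continue  # indel or transcript insertion, not an intron
        if aln.strand == "+":
            s, e = _shift_gap(seq, s, e)
        donor, acceptor = _boundaries(seq, s, e, aln.strand)
        calls.append(
            IntronCall(
                contig=contig.id,
                start=s,
                end=e,
                strand=aln.strand,
                donor=donor,
                acceptor=acceptor,
                type=classify_intron(donor, acceptor),
                completeness="complete",
                support=(aln.transcript_id,),
            )
        )

    # truncation at the ends: one observed boundary only
    first = aln.blocks[0]
    last = aln.blocks[-1]
    if aln.strand == "+":
        head_unaligned = first[2]
        head_space = first[0]
        tail_unaligned = aln.transcript_len - last[3]
        tail_space = aln.contig_len - last[1]
        if head_unaligned >= min_tail and head_space < head_unaligned + min_intron and head_space >= 2:
            acceptor = seq[first[0] - 2 : first[0]]
            calls.insert(
                0,
                IntronCall(
                    contig=contig.id,
                    start=0,
                    end=first[0],
                    strand="+",
                    donor=None,
                    acceptor=acceptor,
                    type=None,
                    completeness="incomplete_5p",
                    support=(aln.transcript_id,),
                ),
            )
        if tail_unaligned >= min_tail and tail_space < tail_unaligned + min_intron and tail_space >= 2:
            donor = seq[last[1] : last[1] + 2]
            calls.append(
                IntronCall(
                    contig=contig.id,
                    start=last[1],
                    end=aln.contig_len,
                    strand="+",
                    donor=donor,
                    acceptor=None,
                    type=None,
                    completeness="incomplete_3p",
                    support=(aln.transcript_id,),
                )
            )
    return calls


def call_introns(
    transcripts: Sequence[SeqRecord],
    contigs: Sequence[SeqRecord],
    min_anchor: int = MIN_ANCHOR_DEFAULT,
    min_intron: int = MIN_INTRON_DEFAULT,
    min_coverage: float = 0.9,
    stem_window: int = STEM_WINDOW_DEFAULT,
) -> List[IntronCall]:
    """Align every transcript to every contig and merge the intron calls.

    Identical calls from different transcripts are merged with pooled
    support; complete calls get a stem pairing score.
    """
    merged: Dict[Tuple, IntronCall] = {}
    contig_by_id = {c.id: c for c in contigs}
    for transcript in transcripts:
        for contig in contigs:
            aln = spliced_align(
                transcript, contig, min_anchor=min_anchor, min_coverage=min_coverage
            )
            if aln is None:
                continue
            for call in extract_introns(aln, contig, min_intron=min_intron):
                key = (call.contig, call.start, call.end, call.strand, call.completeness)
                if key in merged:
                    prev = merged[key]
                    merged[key] = replace(
                        prev, support=tuple(sorted(set(prev.support + call.support)))
                    )
                else:
                    merged[key] = call
    calls = []
    for call in merged.values():
        if call.completeness == "complete":
            intron_seq = contig_by_id[call.contig].seq[call.start : call.end]
            if call.strand == "-":
                intron_seq = revcomp(intron_seq)
            score, _ = stem_loop_score(intron_seq, window=stem_window)
            call = replace(call, stem_score=score)
        calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.start, c.end))
    return calls


# ---------------------------------------------------------------------------
# Stem-loop evidence
# ---------------------------------------------------------------------------

def stem_loop_score(
    intron_seq: str,
    window: int = STEM_WINDOW_DEFAULT,
    allow_gu: bool = True,
) -> Tuple[int, List[Tuple[int, int]]]:
    """Longest contiguous base-paired stem between the two intron ends.

    The first ``window`` nt are slid gaplessly against the reversed last
    ``window`` nt; the score is the longest contiguous run of Watson-Crick
    (or, with ``allow_gu``, G.T wobble) pairs over all offsets, and the
    pairing map lists the paired (left, right) positions of the best run.
    The window shrinks to half the intron length when the intron is short.
    """
    seq = intron_seq.upper()
    if not seq:
        raise ValueError("empty intron sequence")
    w = min(window, len(seq) // 2)
    if w == 0:
        return 0, []
    pairs = _PAIRS_WC | _PAIRS_GU if allow_gu else _PAIRS_WC
    left = seq[:w]
    right_rev = seq[-w:][::-1]  # right_rev[j] is seq[len-1-j]
    best_score = 0
    best_map: List[Tuple[int, int]] = []
    for offset in range(-(w - 1), w):
        run: List[Tuple[int, int]] = []
        for i in range(w):
            j = i + offset
            if not 0 <= j < w:
                continue
            if left[i] + right_rev[j] in pairs:
                run.append((i, len(seq) - 1 - j))
                if len(run) > best_score:
                    best_score = len(run)
                    best_map = list(run)
            else:
                run = []
    return best_score, best_map


# ---------------------------------------------------------------------------
# Boundary position-frequency matrix
# ---------------------------------------------------------------------------

def boundary_pfm(
    introns: Sequence[IntronCall],
    contigs: Mapping[str, SeqRecord] | Sequence[SeqRecord],
    flank: int = 5,
) -> pd.DataFrame:
    """Base frequencies around donor and acceptor sites of complete introns.

    Windows of ``2*flank`` nt are cut around each boundary on the gene
    sense strand (donor dinucleotide at window offsets ``flank``/``flank+1``,
    acceptor at ``flank-2``/``flank-1``) and stacked into a matrix with rows
    A,C,G,T and one column per position; every column sums to 1.  Introns
    whose windows run off the contig are skipped with a warning.
    """
    if not isinstance(contigs, Mapping):
        contigs = {c.id: c for c in contigs}
    windows: List[str] = []
    for call in introns:
        if call.completeness != "complete":
            continue
        seq = contigs[call.contig].seq
        d0, d1 = call.start - flank, call.start + flank
        a0, a1 = call.end - flank, call.end + flank
        if d0 < 0 or a1 > len(seq):
            warnings.warn(
                f"intron {call.contig}:{call.start}-{call.end} too close to the "
                "contig edge; skipped from the PFM"
            )
            continue
        donor_win = seq[d0:d1]
        acceptor_win = seq[a0:a1]
        if call.strand == "-":
            donor_win, acceptor_win = revcomp(seq[a0:a1]), revcomp(seq[d0:d1])
        windows.append(donor_win + acceptor_win)
    if not windows:
        raise ValueError("no complete introns with full flanking windows")
    width = 4 * flank
    counts = np.zeros((4, width), dtype=float)
    base_index = {b: i for i, b in enumerate("ACGT")}
    n_valid = np.zeros(width)
    for win in windows:
        for pos, base in enumerate(win):
            if base in base_index:
                counts[base_index[base], pos] += 1
                n_valid[pos] += 1
    freqs = counts / np.where(n_valid == 0, 1, n_valid)
    return pd.DataFrame(freqs, index=list("ACGT"), columns=range(width))


# ---------------------------------------------------------------------------
# Intron position homology
# ---------------------------------------------------------------------------

def map_intron_positions(
    genes: Sequence[Tuple[str, Sequence[Tuple[int, int]]]],
    msa: Sequence[SeqRecord],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Project intron positions onto MSA columns and compare across genes.

    ``genes`` is a list of (gene id, [(codon index, phase)]) where phase 0
    means the intron precedes the codon's first base.  Every gene id must
    have a row in the protein MSA.  Two introns are *shared* when they map
    to the same column with the same phase.  Returns a long-form table
    (gene, codon_index, phase, column, shared) and the pairwise matrix of
    shared-position counts.
    """
    rows = {r.id: r.seq for r in msa}
    positions: Dict[str, set] = {}
    table = []
    for gene_id, intron_positions in genes:
        if gene_id not in rows:
            raise ValueError(f"gene {gene_id!r} has no row in the MSA")
        aligned = rows[gene_id]
        residue_cols = [c for c, ch in enumerate(aligned) if ch != "-"]
        keys = set()
        for codon_idx, phase in intron_positions:
            if phase not in (0, 1, 2):
                raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
            if not 0 <= codon_idx < len(residue_cols):
                raise ValueError(
                    f"codon index {codon_idx} outside protein of {gene_id!r}"
                )
            key = (residue_cols[codon_idx], phase)
            keys.add(key)
            table.append(
                {
                    "gene": gene_id,
                    "codon_index": codon_idx,
                    "phase": phase,
                    "column": key[0],
                }
            )
        positions[gene_id] = keys
    long = pd.DataFrame(table, columns=["gene", "codon_index", "phase", "column"])
    if not long.empty:
        counts = long.groupby(["column", "phase"])["gene"].nunique()
        long["shared"] = [
            counts[(c, p)] > 1 for c, p in zip(long["column"], long["phase"])
        ]
    else:
        long["shared"] = pd.Series(dtype=bool)
    gene_ids = [g for g, _ in genes]
    matrix = pd.DataFrame(
        [
            [len(positions[a] & positions[b]) for b in gene_ids]
            for a in gene_ids
        ],
        index=gene_ids,
        columns=gene_ids,
    )
    return long, matrix
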