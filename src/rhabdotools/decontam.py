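"""GC/CAI screening of assembled transcripts for contaminants.

Transcript decontamination works by comparing each transcript's coding
sequence against a benchmark set of transcripts of trusted (host)
affiliation: a reference codon-usage table is built from the benchmark set,
and each transcript is scored by the GC content of its best ORF and by the
codon adaptation index (CAI, Sharp & Li) against that table.  A transcript
is flagged as a probable contaminant only when *both* measures fall below
their thresholds (conservative conjunctive rule, 0.45/0.45 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Data import CodonTable as _BioCodonTable

from .records import SeqRecord, gc_fraction, revcomp

GC_THRESHOLD_DEFAULT = 0.45
CAI_THRESHOLD_DEFAULT = 0.45
MIN_ORF_NT_DEFAULT = 150

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: amino acid -> tuple of synonymous codons (standard nuclear code)
SYNONYMOUS_FAMILIES: Dict[str, Tuple[str, ...]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: codons excluded from the CAI geometric mean: stops plus the
#: single-codon families Met (ATG) and Trp (TGG), which carry no
#: codon-choice information.
CAI_EXCLUDED = STOP_CODONS | {"ATG", "TGG"}

_CODON_TO_AA = dict(_STANDARD.forward_table)


@dataclass
class CodonUsageTable:
    """Codon counts and relative adaptiveness w against a reference set.

    Within every synonymous family the most-used codon has w = 1; with a
    positive pseudo-count every sense codon has w > 0.
    """

    counts: Dict[str, float]
    w: Dict[str, float]
    pseudo: float


def _codons(seq: str) -> List[str]:
    n = len(seq) - len(seq) % 3
    return [seq[i : i + 3] for i in range(0, n, 3)]


def build_codon_usage(
    reference_cds: Sequence[SeqRecord], pseudo: float = 0.5
) -> CodonUsageTable:
    """Accumulate codon counts over in-frame reference CDS and derive w.

    Stop codons are excluded.  ``w(c) = (count(c)+pseudo) / max over the
    synonymous family of (count+pseudo)``.
    """
    if not reference_cds:
        raise ValueError("empty reference CDS set")
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    counts: Dict[str, float] = {c: 0.0 for c in _CODON_TO_AA}
    for rec in reference_cds:
        for codon in _codons(rec.seq.upper()):
            if codon in counts:
                counts[codon] += 1.0
    w: Dict[str, float] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        top = max(counts[c] + pseudo for c in family)
        for c in family:
            if top == 0:
                w[c] = 1.0  # family never observed and pseudo = 0
            else:
                w[c] = (counts[c] + pseudo) / top
    return CodonUsageTable(counts=counts, w=w, pseudo=pseudo)


def cai(cds: SeqRecord | str, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of w over informative codons.

    ATG, TGG and stop codons are excluded (single-codon families).  Raises
    ``ValueError`` when no informative codon remains.
    """
    seq = cds.seq if isinstance(cds, SeqRecord) else cds
    log_sum = 0.0
    n = 0
    for codon in _codons(seq.upper()):
        if codon in CAI_EXCLUDED or codon not in table.w:
            continue
        wc = table.w[codon]
        if wc <= 0:
            raise ValueError(
                f"codon {codon} has zero adaptiveness; build the table with a "
                "positive pseudo-count"
            )
        log_sum += math.log(wc)
        n += 1
    if n == 0:
        raise ValueError("no informative codons in CDS")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# ORF selection
# ---------------------------------------------------------------------------

@dataclass
class Orf:
    """Longest stop-free codon run: coordinates on the input transcript.

    ``frame`` numbers the six frames 0-2 (forward offsets) and 3-5 (reverse
    offsets); ``start``/``end`` are 0-based half-open on the *oriented*
    sequence (the reverse complement for frames 3-5).
    """

    start: int
    end: int
    frame: int
    seq: str


def find_orf(seq: str, min_len: int = MIN_ORF_NT_DEFAULT) -> Optional[Orf]:
    """Longest ORF >= ``min_len`` nt over six frames.

    An ORF is a maximal run of non-stop codons; ties are broken toward the
    lowest frame index, forward strand before reverse.
    """
    best: Optional[Orf] = None
    for frame in range(6):
        oriented = seq if frame < 3 else revcomp(seq)
        offset = frame % 3
        codons = _codons(oriented[offset:])
        run_start = 0
        i = 0
        n = len(codons)
        while i <= n:
            if i == n or codons[i] in STOP_CODONS:
                run_len = i - run_start
                if run_len * 3 >= min_len:
                    if best is None or run_len * 3 > best.end - best.start:
                        s = offset + 3 * run_start
                        e = offset + 3 * i
                        best = Orf(start=s, end=e, frame=frame, seq=oriented[s:e])
                run_start = i + 1
            i += 1
    return best


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class TranscriptQC:
    """Per-transcript decontamination verdict with provenance."""

    id: str
    cds_start: Optional[int]
    cds_end: Optional[int]
    frame: Optional[int]
    gc: Optional[float]
    cai: Optional[float]
    contaminant: Optional[bool]  # None = unclassified (no qualifying ORF)
    reason: str


def classify_contaminants(
    transcripts: Sequence[SeqRecord],
    table: CodonUsageTable,
    gc_threshold: float = GC_THRESHOLD_DEFAULT,
    cai_threshold: float = CAI_THRESHOLD_DEFAULT,
    min_orf: int = MIN_ORF_NT_DEFAULT,
) -> List[TranscriptQC]:
    """Flag transcripts whose CDS falls below *both* GC and CAI thresholds.

    GC and CAI are computed on the longest ORF of each transcript;
    transcripts without an ORF >= ``min_orf`` nt are reported as
    unclassified and never flagged.
    """
    if not (0 < gc_threshold < 1 and 0 < cai_threshold < 1):
        raise ValueError("thresholds must be in (0, 1)")
    results: List[TranscriptQC] = []
    for rec in transcripts:
        orf = find_orf(rec.seq, min_len=min_orf)
        if orf is None:
            results.append(
                TranscriptQC(rec.id, None, None, None, None, None, None, "no_orf")
            )
            continue
        gc = gc_fraction(orf.seq)
        cai_value = cai(orf.seq, table)
        flagged = gc < gc_threshold and cai_value < cai_threshold
        if flagged:
            reason = "gc_and_cai_below_threshold"
        elif gc < gc_threshold:
            reason = "kept_low_gc_only"
        elif cai_value < cai_threshold:
            reason = "kept_low_cai_only"
        else:
            reason = "kept"
        results.append(
            TranscriptQC(
                id=rec.id,
                cds_start=orf.start,
                cds_end=orf.end,
                frame=orf.frame,
                gc=gc,
                cai=cai_value,
                contaminant=flagged,
                reason=reason,
            )
        )
    return results
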