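"""Lightweight sequence records and nucleotide helpers.

All sequences are stored as plain upper-case Python strings.  Nucleotide
records use the {A,C,G,T,N} alphabet; RNA input (U) is normalised to T on
read so every downstream stage works on a single alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class SeqRecord:
    """A named sequence: genome contig, transcript, protein or ORF.

    ``id`` must be a non-empty token without whitespace; ``description`` is
    the free-text remainder of a FASTA header.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def is_nucleotide(self) -> bool:
        return set(self.seq) <= NUCLEOTIDE_ALPHABET


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T; N and other symbols are excluded from the denominator.

    Raises ``ValueError`` when the sequence contains no unambiguous base.
    """
    g = seq.count("G") + seq.count("g")
    c = seq.count("C") + seq.count("c")
    a = seq.count("A") + seq.count("a")
    t = seq.count("T") + seq.count("t")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (g + c) / denom
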