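"""Genetic codes, translation, and stop-codon reassignment inference.

Euglenozoan mitochondria translate with NCBI table 4 (UGA -> Trp); some
lineages additionally reassign UAG.  Such reassignments leave in-frame stop
codons inside otherwise intact ORFs, at alignment columns where homologues
show a consistent amino acid.  :func:`infer_reassignments` formalises that
observation: it maps every internal stop of a translated ORF to its column
in a protein multiple alignment and asks whether the homologues agree on a
residue there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

from .records import SeqRecord

_BASES = "TCAG"

# Standard nuclear code (NCBI table 1), written out in TCAG order.
_TABLE_1 = dict(
    zip(
        (a + b + c for a in _BASES for b in _BASES for c in _BASES),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
)
# Mold/protozoan/coelenterate mitochondrial code (NCBI table 4): TGA -> Trp.
_TABLE_4 = {**_TABLE_1, "TGA": "W"}

BASE_TABLES: Dict[int, Dict[str, str]] = {1: _TABLE_1, 4: _TABLE_4}


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with optional reassignment overrides.

    ``base`` selects the starting table (1 = standard, 4 = mold/protozoan
    mitochondrial); ``overrides`` maps codons to residues on top of it
    (e.g. ``{"TAG": "Y"}``).  Stops are whatever maps to '*' after the
    overrides; by default at least one stop must remain.
    """

    base: int = 1
    overrides: Mapping[str, str] = field(default_factory=dict)
    allow_no_stop: bool = False

    def __post_init__(self) -> None:
        if self.base not in BASE_TABLES:
            raise ValueError(f"unknown base table {self.base}; known: {sorted(BASE_TABLES)}")
        object.__setattr__(self, "overrides", dict(self.overrides))
        for codon, residue in self.overrides.items():
            if codon not in _TABLE_1:
                raise ValueError(f"override on invalid codon {codon!r}")
            if len(residue) != 1:
                raise ValueError(f"override residue must be one letter, got {residue!r}")
        if not self.allow_no_stop and not self.stops:
            raise ValueError("code has no stop codon left; pass allow_no_stop=True")

    @property
    def table(self) -> Dict[str, str]:
        merged = dict(BASE_TABLES[self.base])
        merged.update(self.overrides)
        return merged

    @property
    def stops(self) -> FrozenSet[str]:
        return frozenset(c for c, r in self.table.items() if r == "*")

    def with_override(self, codon: str, residue: str) -> "GeneticCode":
        return GeneticCode(
            base=self.base,
            overrides={**self.overrides, codon: residue},
            allow_no_stop=True,
        )


def translate(orf: SeqRecord | str, code: GeneticCode) -> str:
    """Translate an in-frame ORF; internal stops become '*'.

    The terminal stop codon, if present, is dropped.  Codons containing
    ambiguous bases translate to 'X'.  Length must be divisible by 3.
    """
    seq = (orf.seq if isinstance(orf, SeqRecord) else orf).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} is not divisible by 3")
    table = code.table
    residues = [table.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3)]
    if residues and residues[-1] == "*":
        residues.pop()
    return "".join(residues)


@dataclass
class ReassignmentEvidence:
    """Homologue-column evidence that one stop codon encodes a residue."""

    codon: str
    n_internal_sites: int
    majority_residue: Optional[str]
    agreement: float
    columns: List[int]
    verdict: str  # "inferred" | "insufficient" | "ambiguous"

    MIN_SITES_DEFAULT = 3
    MAJORITY_THR_DEFAULT = 0.5
    MIN_HOMOLOGUES_DEFAULT = 4


def _map_residues_to_columns(aligned_query: str) -> List[int]:
    """Column index of each ungapped query residue."""
    cols = []
    for col, ch in enumerate(aligned_query):
        if ch != "-":
            cols.append(col)
    return cols


def infer_reassignments(
    orf: SeqRecord,
    msa: Sequence[SeqRecord],
    base_code: GeneticCode = GeneticCode(base=4),
    min_sites: int = ReassignmentEvidence.MIN_SITES_DEFAULT,
    majority_thr: float = ReassignmentEvidence.MAJORITY_THR_DEFAULT,
    min_homologues: int = ReassignmentEvidence.MIN_HOMOLOGUES_DEFAULT,
) -> List[ReassignmentEvidence]:
    """Infer stop-codon reassignments from homologue alignment columns.

    The MSA must contain a row whose id matches ``orf.id`` and whose
    ungapped sequence equals the ORF's translation under ``base_code``
    (internal stops as '*').  For every stop codon with internal
    occurrences, each occurrence is mapped to its alignment column; residue
    counts of the non-gap homologues are pooled across the usable columns
    (those with >= ``min_homologues`` non-gap rows).  The pooled modal
    residue is called ``inferred`` when its pooled agreement reaches
    ``majority_thr``; otherwise the verdict is ``ambiguous`` when per-site
    modal residues disagree and ``insufficient`` when sites or agreement
    fall short.
    """
    query_rows = [r for r in msa if r.id == orf.id]
    if not query_rows:
        raise ValueError(f"MSA has no row matching ORF id {orf.id!r}")
    aligned_query = query_rows[0].seq
    translation = translate(orf, base_code)
    ungapped = aligned_query.replace("-", "")
    if ungapped not in (translation, translation + "*"):
        raise ValueError(
            "query MSA row does not match the ORF translation under the base code"
        )
    homologues = [r for r in msa if r.id != orf.id]
    residue_cols = _map_residues_to_columns(aligned_query)

    # internal stop positions per codon type
    seq = orf.seq.upper().replace("U", "T")
    stops_at: Dict[str, List[int]] = {}
    for idx, residue in enumerate(translation):
        if residue == "*":
            codon = seq[3 * idx : 3 * idx + 3]
            stops_at.setdefault(codon, []).append(idx)

    evidence: List[ReassignmentEvidence] = []
    for codon in sorted(stops_at):
        positions = stops_at[codon]
        columns = [residue_cols[p] for p in positions]
        pooled: Dict[str, int] = {}
        site_modals: List[str] = []
        usable_columns: List[int] = []
        for col in columns:
            col_counts: Dict[str, int] = {}
            for row in homologues:
                ch = row.seq[col]
                if ch in "-*":
                    continue
                col_counts[ch] = col_counts.get(ch, 0) + 1
            if sum(col_counts.values()) < min_homologues:
                continue
            usable_columns.append(col)
            for ch, cnt in col_counts.items():
                pooled[ch] = pooled.get(ch, 0) + cnt
            site_modals.append(max(sorted(col_counts), key=col_counts.get))
        total = sum(pooled.values())
        if len(positions) < min_sites or len(usable_columns) < min_sites or total == 0:
            evidence.append(
                ReassignmentEvidence(
                    codon=codon,
                    n_internal_sites=len(positions),
                    majority_residue=None,
                    agreement=0.0,
                    columns=columns,
                    verdict="insufficient",
                )
            )
            continue
        modal = max(sorted(pooled), key=pooled.get)
        agreement = pooled[modal] / total
        if agreement >= majority_thr:
            verdict = "inferred"
        elif len(set(site_modals)) > 1:
            verdict = "ambiguous"
        else:
            verdict = "insufficient"
        evidence.append(
            ReassignmentEvidence(
                codon=codon,
                n_internal_sites=len(positions),
                majority_residue=modal if verdict != "insufficient" else None,
                agreement=agreement,
                columns=columns,
                verdict=verdict,
            )
        )
    return evidence
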