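"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and tabular files are handled here; Newick trees live in
:mod:`rhabdotools.trees`.  Genomic coordinates are 0-based half-open
everywhere in memory and converted to 1-based inclusive only when GFF3 is
written.
"""

from __future__ import annotations

import io as _stdio
from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Union

import pandas as pd

from .records import NUCLEOTIDE_ALPHABET, SeqRecord

Source = Union[str, PathLike, IO[str]]


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _as_line_iterator(source: Source) -> Iterator[str]:
    if hasattr(source, "read"):
        return iter(source)  # type: ignore[arg-type]
    if isinstance(source, (str, Path)):
        text = str(source)
        # Raw FASTA text rather than a path.
        if isinstance(source, str) and (text.lstrip().startswith(">") or "\n" in text):
            return iter(_stdio.StringIO(text))
        return iter(open(source, "rt", encoding="ascii"))
    raise TypeError(f"cannot read FASTA from {type(source)!r}")


def read_fasta(source: Source, alphabet: str = "auto") -> List[SeqRecord]:
    """Parse FASTA into a list of :class:`SeqRecord`, order preserved.

    ``source`` may be a path, an open text handle, or raw FASTA text.
    Sequences are upper-cased; for nucleotide records U is mapped to T.
    ``alphabet`` is ``"nt"`` (validate against {A,C,G,T,N}), ``"aa"``
    (accept any residue letters), or ``"auto"`` (treat a record as
    nucleotide when its symbols allow it).
    """
    if alphabet not in ("auto", "nt", "aa"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: List[SeqRecord] = []
    header: tuple[str, str] | None = None
    chunks: List[str] = []
    lineno = 0

    def _flush(at_line: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(f"record {header[0]!r} has no sequence", at_line)
        if alphabet in ("nt", "auto") and set(seq) <= (NUCLEOTIDE_ALPHABET | {"U"}):
            seq = seq.replace("U", "T")
        elif alphabet == "nt":
            bad = sorted(set(seq) - NUCLEOTIDE_ALPHABET - {"U"})
            raise FastaParseError(
                f"record {header[0]!r} contains non-nucleotide symbols {bad}", at_line
            )
        records.append(SeqRecord(id=header[0], seq=seq, description=header[1]))
        header, chunks = None, []

    for lineno, raw in enumerate(_as_line_iterator(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            _flush(lineno)
            fields = line[1:].split(None, 1)
            if not fields:
                raise FastaParseError("empty FASTA header", lineno)
            header = (fields[0], fields[1].strip() if len(fields) > 1 else "")
        else:
            if header is None:
                raise FastaParseError("sequence data before first '>' header", lineno)
            chunks.append(line.strip())
    _flush(lineno + 1)
    return records


def write_fasta(records: Iterable[SeqRecord], dest: Source, width: int = 60) -> None:
    """Write records as wrapped FASTA (``width`` columns, 0 = single line)."""
    own = not hasattr(dest, "write")
    handle = open(dest, "wt", encoding="ascii") if own else dest  # type: ignore[arg-type]
    try:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            if width and width > 0:
                for i in range(0, len(rec.seq), width):
                    handle.write(rec.seq[i : i + width] + "\n")
            else:
                handle.write(rec.seq + "\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# GFF3 for intron calls
# ---------------------------------------------------------------------------

_GFF_HEADER = "##gff-version 3"


def write_gff3(calls, dest: Source | None = None) -> str:
    """Serialise intron calls as GFF3 (1-based inclusive on disk).

    Attributes carry donor/acceptor dinucleotides, type, completeness,
    supporting transcripts and the stem pairing score, so the file
    round-trips through :func:`read_gff3_introns`.  Returns the text; if
    ``dest`` is given the text is also written there.
    """
    lines = [_GFF_HEADER]
    for call in calls:
        if call.end <= call.start:
            raise ValueError(
                f"invalid interval [{call.start}, {call.end}) on {call.contig}"
            )
        attrs = [
            f"ID=intron_{call.contig}_{call.start}_{call.end}",
            f"donor={call.donor or '.'}",
            f"acceptor={call.acceptor or '.'}",
            f"intron_type={call.type or 'undetermined'}",
            f"completeness={call.completeness}",
        ]
        if call.support:
            attrs.append("support=" + ",".join(call.support))
        if call.stem_score is not None:
            attrs.append(f"stem_score={call.stem_score}")
        lines.append(
            "\t".join(
                [
                    call.contig,
                    "rhabdotools",
                    "intron",
                    str(call.start + 1),  # 0-based half-open -> 1-based inclusive
                    str(call.end),
                    ".",
                    call.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if dest is not None:
        own = not hasattr(dest, "write")
        handle = open(dest, "wt", encoding="ascii") if own else dest  # type: ignore[arg-type]
        try:
            handle.write(text)
        finally:
            if own:
                handle.close()
    return text


def read_gff3_introns(source: Source):
    """Read intron calls written by :func:`write_gff3` (paired reader)."""
    from .introns import IntronCall  # local import; introns.py does not import io

    calls = []
    for raw in _as_line_iterator(source):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"expected 9 GFF3 columns, got {len(cols)}: {line!r}")
        attrs = dict(
            item.split("=", 1) for item in cols[8].split(";") if "=" in item
        )
        itype = attrs.get("intron_type", "undetermined")
        calls.append(
            IntronCall(
                contig=cols[0],
                start=int(cols[3]) - 1,
                end=int(cols[4]),
                strand=cols[6],
                donor=None if attrs.get("donor", ".") == "." else attrs["donor"],
                acceptor=None if attrs.get("acceptor", ".") == "." else attrs["acceptor"],
                type=None if itype == "undetermined" else itype,
                completeness=attrs.get("completeness", "complete"),
                support=tuple(attrs["support"].split(",")) if "support" in attrs else (),
                stem_score=int(attrs["stem_score"]) if "stem_score" in attrs else None,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(source: Source) -> pd.DataFrame:
    """Read a TSV with a header row."""
    return pd.read_csv(source, sep="\t")


def write_table(df: pd.DataFrame, dest: Source) -> None:
    df.to_csv(dest, sep="\t", index=False)
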