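"""Assembly summary metrics and genome-size estimators.

Covers the descriptive statistics usually reported for draft genome and
transcriptome assemblies (contig counts above length thresholds, N50/L50,
GC, N-density) plus two coarse genome-size estimates: one from the fraction
of transcriptome reads that map to the assembly, and one from the canonical
k-mer multiplicity histogram of the reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, Sequence, Tuple

from .records import SeqRecord, revcomp

DEFAULT_THRESHOLDS = (500, 1000, 5000)


@dataclass
class AssemblyStats:
    """Summary of one assembly; lengths in bp, GC as a percentage."""

    n_contigs: int
    total_len: int
    median_len: float
    max_len: int
    n50: int
    l50: int
    gc_percent: float
    n_per_100kbp: float
    n_ge: Dict[int, int] = field(default_factory=dict)
    total_len_ge: Dict[int, int] = field(default_factory=dict)
    median_len_ge: Dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_contigs": self.n_contigs,
            "total_len": self.total_len,
            "median_len": self.median_len,
            "max_len": self.max_len,
            "n50": self.n50,
            "l50": self.l50,
            "gc_percent": self.gc_percent,
            "n_per_100kbp": self.n_per_100kbp,
        }
        for thr, n in sorted(self.n_ge.items()):
            out[f"n_contigs_ge_{thr}"] = n
        for thr, t in sorted(self.total_len_ge.items()):
            out[f"total_len_ge_{thr}"] = t
        for thr, m in sorted(self.median_len_ge.items()):
            out[f"median_len_ge_{thr}"] = m
        return out


def n50_l50(lengths: Sequence[int]) -> Tuple[int, int]:
    """(N50, L50): the length at which the descending cumulative sum first
    reaches half the total, and the 1-based rank of that contig."""
    if not lengths:
        raise ValueError("empty length list")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for rank, length in enumerate(ordered, start=1):
        acc += length
        if acc >= half:
            return length, rank
    raise AssertionError("unreachable")


def assembly_metrics(
    records: Sequence[SeqRecord],
    thresholds: Iterable[int] = DEFAULT_THRESHOLDS,
) -> AssemblyStats:
    """Compute assembly statistics over a set of contigs.

    GC counts G+C over unambiguous bases only; N-density is reported
    separately as Ns per 100 kbp of total assembly length.
    """
    if not records:
        raise ValueError("no contigs supplied")
    lengths = [len(r) for r in records]
    total = sum(lengths)
    n50, l50 = n50_l50(lengths)
    gc_num = 0
    gc_den = 0
    n_count = 0
    for rec in records:
        seq = rec.seq
        g = seq.count("G") + seq.count("C")
        a = seq.count("A") + seq.count("T")
        gc_num += g
        gc_den += g + a
        n_count += seq.count("N")
    if gc_den == 0:
        raise ValueError("assembly contains no unambiguous bases")
    stats = AssemblyStats(
        n_contigs=len(records),
        total_len=total,
        median_len=float(median(lengths)),
        max_len=max(lengths),
        n50=n50,
        l50=l50,
        gc_percent=100.0 * gc_num / gc_den,
        n_per_100kbp=1e5 * n_count / total,
    )
    for thr in thresholds:
        subset = [l for l in lengths if l >= thr]
        stats.n_ge[thr] = len(subset)
        stats.total_len_ge[thr] = sum(subset)
        stats.median_len_ge[thr] = float(median(subset)) if subset else 0.0
    return stats


def estimate_size_from_mapping(assembly_len: int, mapped_fraction: float) -> float:
    """Genome size implied by assembly completeness.

    If only ``mapped_fraction`` of transcriptome reads map to the assembly,
    the assembly is taken to represent that fraction of the genome, so the
    estimate is ``assembly_len / mapped_fraction`` (monotone decreasing in
    the fraction).
    """
    if not 0 < mapped_fraction <= 1:
        raise ValueError(f"mapped_fraction must be in (0, 1], got {mapped_fraction}")
    if assembly_len <= 0:
        raise ValueError("assembly_len must be positive")
    return assembly_len / mapped_fraction


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_histogram(reads: Iterable[SeqRecord], k: int) -> Counter:
    """Multiplicity -> number of distinct canonical k-mers at that multiplicity.

    K-mers containing ambiguous bases are skipped.
    """
    if k < 11 or k > 31 or k % 2 == 0:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    counts: Counter = Counter()
    for read in reads:
        seq = read.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[canonical_kmer(kmer)] += 1
    hist: Counter = Counter()
    for mult in counts.values():
        hist[mult] += 1
    return hist


def kmer_size_estimate(reads: Sequence[SeqRecord], k: int = 21) -> float:
    """Genome size from the canonical k-mer multiplicity histogram.

    Singleton k-mers (multiplicity 1) are treated as sequencing-error
    artefacts and excluded; the coverage peak is the modal multiplicity >= 2
    of the histogram, and the estimate is the total number of non-singleton
    k-mer occurrences divided by that peak.
    """
    hist = kmer_histogram(reads, k)
    usable = {m: c for m, c in hist.items() if m >= 2}
    if not usable:
        raise ValueError(
            "no k-mer observed more than once; coverage too low for an estimate"
        )
    # modal multiplicity (ties resolved toward lower coverage)
    peak = min(
        (m for m in usable), key=lambda m: (-usable[m], m)
    )
    total_occurrences = sum(m * c for m, c in usable.items())
    return total_occurrences / peak
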