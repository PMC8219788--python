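"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its configuration (the seed included):
running it twice with the same ``SimConfig`` yields byte-identical output.
The generated data mirror the statistical structure the analysis stages
assume: intron-bearing genes whose exonic sequence follows a GC-rich host
codon model, spliced-leader-tagged transcripts of unknown orientation,
AT-rich contaminant transcripts, mitochondrial ORFs with reassigned stop
codons aligned to homologues, bootstrap-annotated gene trees with known
clan memberships, and mitochondrial-proteome evidence tables.

Host exonic GC defaults to 0.58 and contaminant GC to 0.35, the
transcriptome-scale contrast the decontamination stage is designed to
separate; spliced leaders are planted on 15.3% of host transcripts by
default, matching the corpus-level rate the SL scan reports on real
euglenid data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mitocode import GeneticCode, translate
from .records import SeqRecord, revcomp
from .sl import SL_SEQUENCE
from .trees import Tree, parse_newick

QUERY_PREFIX_DEFAULT = "RCo"

_GENERATOR_KEYS = {
    "genome": 0,
    "transcriptome": 1,
    "mito_alignment": 2,
    "gene_trees": 3,
    "mito_features": 4,
    "reads": 5,
}

DEFAULT_BIN_SPEC: Tuple[Tuple[str, int, Tuple[int, int]], ...] = (
    ("Discoba", 53, (75, 100)),
    ("Prokaryota", 12, (75, 100)),
    ("Kinetoplastea", 10, (75, 100)),
    ("Viridiplantae", 5, (75, 100)),
)


@dataclass
class SimConfig:
    """Shared knobs of all generators; ``seed`` is mandatory.

    Probabilities are fractions in [0, 1]; GC targets are per-base
    fractions of the coding sequence the codon models aim at.
    """

    seed: int
    # genes / introns
    n_genes: int = 50
    introns_per_gene: int = 2
    nonconventional_fraction: float = 0.1
    gc_donor_fraction: float = 0.1  # GC...AG among conventional introns
    intron_len_range: Tuple[int, int] = (60, 300)
    gene_len_codons: Tuple[int, int] = (150, 300)
    min_exon_len: int = 40
    flank_len_range: Tuple[int, int] = (80, 150)
    host_gc_target: float = 0.58
    # transcripts
    sl_fraction: float = 0.153
    sl_sequence: str = SL_SEQUENCE
    sl_min_len: int = 10
    contaminant_fraction: float = 0.1
    contaminant_gc_target: float = 0.35
    # mitochondrial ORF / alignment
    reassignment_spec: Tuple[Tuple[str, str, int], ...] = (("TAG", "Y", 5),)
    orf_len_codons: int = 300
    n_homologues: int = 10
    agreement_rate: float = 0.8
    conservation_rate: float = 0.9
    # gene trees
    bin_spec: Tuple[Tuple[str, int, Tuple[int, int]], ...] = DEFAULT_BIN_SPEC
    taxa_per_bin: int = 10
    n_unassigned_low_support: int = 10
    n_unassigned_mixed: int = 10
    query_prefix: str = QUERY_PREFIX_DEFAULT
    # mitochondrial feature table
    n_feature_rows: int = 2000

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for name in (
            "nonconventional_fraction",
            "gc_donor_fraction",
            "sl_fraction",
            "contaminant_fraction",
            "agreement_rate",
            "conservation_rate",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "n_genes",
            "introns_per_gene",
            "orf_len_codons",
            "n_homologues",
            "n_feature_rows",
            "taxa_per_bin",
            "n_unassigned_low_support",
            "n_unassigned_mixed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sl_fraction > 0 and not self.sl_sequence:
            raise ValueError("sl_fraction > 0 requires a non-empty SL sequence")
        if not 0 < self.host_gc_target < 1 or not 0 < self.contaminant_gc_target < 1:
            raise ValueError("GC targets must be in (0, 1)")

    def rng(self, generator: str) -> np.random.Generator:
        """Child RNG for one generator, derived from the global seed."""
        key = _GENERATOR_KEYS[generator]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


class TruthTable:
    """Named tables of planted properties, keyed by entity kind."""

    def __init__(self, **tables: pd.DataFrame):
        self.tables: Dict[str, pd.DataFrame] = dict(tables)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.tables

    def merge(self, other: "TruthTable") -> "TruthTable":
        merged = dict(self.tables)
        merged.update(other.tables)
        return TruthTable(**merged)


# ---------------------------------------------------------------------------
# Codon model
# ---------------------------------------------------------------------------

_SENSE_CODONS: Tuple[str, ...] = tuple(
    sorted(c for c, aa in GeneticCode(base=1).table.items() if aa != "*")
)
_GC_COUNT = np.array([c.count("G") + c.count("C") for c in _SENSE_CODONS], dtype=float)

_FAMILIES: Dict[str, List[str]] = {}
for _c in _SENSE_CODONS:
    _FAMILIES.setdefault(GeneticCode(base=1).table[_c], []).append(_c)

#: per-family rank-bias decay: codon at preference rank r gets weight kappa**r
_KAPPA = 0.5


def _rank_bias(profile: str) -> np.ndarray:
    """Within-family codon preference weights for a codon-usage profile.

    The ``host`` profile prefers GC-rich codons within every synonymous
    family, the ``contaminant`` profile AT-rich ones; both decay
    geometrically with rank.  The two profiles therefore disagree on which
    synonymous codon is optimal, which is what the CAI screen keys on.
    """
    reverse = profile == "host"
    weight: Dict[str, float] = {}
    for family in _FAMILIES.values():
        ranked = sorted(
            family, key=lambda c: (c.count("G") + c.count("C"), c), reverse=reverse
        )
        for rank, codon in enumerate(ranked):
            weight[codon] = _KAPPA**rank
    return np.array([weight[c] for c in _SENSE_CODONS])


@lru_cache(maxsize=32)
def codon_distribution(
    gc_target: float, profile: str = "host"
) -> Tuple[Tuple[str, ...], Tuple[float, ...]]:
    """Sense-codon sampling distribution with a prescribed mean GC.

    Codon weights combine a within-family rank bias (see ``_rank_bias``)
    with exp(beta * GC-count); beta is solved so that the expected per-base
    GC of sampled codons equals ``gc_target``.
    """
    if profile not in ("host", "contaminant"):
        raise ValueError(f"unknown codon profile {profile!r}")
    bias = _rank_bias(profile)

    def mean_gc(beta: float) -> float:
        w = bias * np.exp(beta * _GC_COUNT)
        return float((w * _GC_COUNT).sum() / (3 * w.sum()))

    beta = brentq(lambda b: mean_gc(b) - gc_target, -30.0, 30.0, xtol=1e-12)
    w = bias * np.exp(beta * _GC_COUNT)
    p = w / w.sum()
    return _SENSE_CODONS, tuple(p)


def _sample_cds(
    rng: np.random.Generator, n_codons: int, gc_target: float, profile: str = "host"
) -> str:
    codons, p = codon_distribution(round(gc_target, 6), profile)
    idx = rng.choice(len(codons), size=n_codons, p=np.array(p))
    return "".join(codons[i] for i in idx)


def _random_bases(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join("ACGT"[i] for i in idx)


# ---------------------------------------------------------------------------
# Annotated genome
# ---------------------------------------------------------------------------

_NONCONV_DONORS: Tuple[str, ...] = tuple(
    sorted(
        a + b
        for a in "ACGT"
        for b in "ACGT"
        # donor must break the GT/GC rule; CT is excluded because the stem
        # construction mirrors the donor into the acceptor (revcomp), and
        # revcomp(CT) = AG would recreate a conventional acceptor
        if a + b not in ("GT", "GC", "CT")
    )
)


def _make_intron(rng: np.random.Generator, config: SimConfig, kind: str) -> str:
    lo, hi = config.intron_len_range
    length = int(rng.integers(lo, hi + 1))
    if kind == "conventional":
        donor = "GC" if rng.random() < config.gc_donor_fraction else "GT"
        return donor + _random_bases(rng, length - 4) + "AG"
    # nonconventional: terminal 20-mers are exact reverse complements,
    # giving the stem-pairing score a clean planted signal
    stem = 20
    first = _NONCONV_DONORS[rng.integers(len(_NONCONV_DONORS))] + _random_bases(
        rng, stem - 2
    )
    middle = _random_bases(rng, length - 2 * stem)
    return first + middle + revcomp(first)


def _place_cuts(
    rng: np.random.Generator,
    mrna: str,
    introns: Sequence[str],
    min_exon: int,
) -> List[int]:
    """Cut positions for introns, placed so that each genomic gap placement
    is unambiguous (the exon base entering the junction never equals the
    intron base leaving it, on either side)."""
    n = len(introns)
    span = len(mrna) - 2 * min_exon
    if span < (n - 1) * min_exon + 1:
        raise ValueError("gene too short for the requested exon structure")
    for _ in range(200):
        cuts = sorted(
            int(c) for c in rng.choice(span, size=n, replace=False) + min_exon
        )
        if any(b - a < min_exon for a, b in zip(cuts, cuts[1:])):
            continue
        ok = True
        adjusted: List[int] = []
        for cut, intron in zip(cuts, introns):
            placed = None
            for delta in (0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5):
                c = cut + delta
                if not min_exon <= c <= len(mrna) - min_exon:
                    continue
                if adjusted and c - adjusted[-1] < min_exon:
                    continue
                if mrna[c - 1] != intron[-1] and mrna[c] != intron[0]:
                    placed = c
                    break
            if placed is None:
                ok = False
                break
            adjusted.append(placed)
        if ok and all(b - a >= min_exon for a, b in zip(adjusted, adjusted[1:])):
            return adjusted
    raise RuntimeError("could not place unambiguous intron junctions")


def simulate_annotated_genome(
    config: SimConfig,
) -> Tuple[List[SeqRecord], TruthTable]:
    """One intron-bearing gene per contig, with exact planted coordinates.

    Exons follow the host codon model; conventional introns get GT (or,
    with a small probability, GC) donors and AG acceptors; nonconventional
    introns get stem-forming ends whose boundary dinucleotides break the
    GT(GC)/AG rule.  The truth table records every intron's contig
    coordinates, boundaries and type, plus each gene's spliced mRNA.
    """
    rng = config.rng("genome")
    contigs: List[SeqRecord] = []
    gene_rows = []
    intron_rows = []
    for i in range(config.n_genes):
        gene_id = f"g{i + 1}"
        contig_id = f"NODE_{i + 1}"
        lo, hi = config.gene_len_codons
        n_codons = int(rng.integers(lo, hi + 1))
        mrna = "ATG" + _sample_cds(rng, n_codons, config.host_gc_target) + "TAA"
        kinds = [
            "nonconventional"
            if rng.random() < config.nonconventional_fraction
            else "conventional"
            for _ in range(config.introns_per_gene)
        ]
        introns = [_make_intron(rng, config, kind) for kind in kinds]
        cuts = (
            _place_cuts(rng, mrna, introns, config.min_exon_len) if introns else []
        )
        flo, fhi = config.flank_len_range
        flank5 = _random_bases(rng, int(rng.integers(flo, fhi + 1)))
        flank3 = _random_bases(rng, int(rng.integers(flo, fhi + 1)))
        pieces = [flank5]
        genome_pos = len(flank5)
        prev_cut = 0
        for cut, intron, kind in zip(cuts, introns, kinds):
            exon = mrna[prev_cut:cut]
            pieces.append(exon)
            genome_pos += len(exon)
            pieces.append(intron)
            intron_rows.append(
                {
                    "contig": contig_id,
                    "gene_id": gene_id,
                    "start": genome_pos,
                    "end": genome_pos + len(intron),
                    "donor": intron[:2],
                    "acceptor": intron[-2:],
                    "type": kind,
                    "length": len(intron),
                    "mrna_cut": cut,
                }
            )
            genome_pos += len(intron)
            prev_cut = cut
        pieces.append(mrna[prev_cut:])
        pieces.append(flank3)
        contig_seq = "".join(pieces)
        contigs.append(SeqRecord(id=contig_id, seq=contig_seq))
        gene_rows.append(
            {
                "gene_id": gene_id,
                "contig": contig_id,
                "mrna": mrna,
                "n_introns": len(introns),
                "gene_start": len(flank5),
                "gene_end": len(contig_seq) - len(flank3),
            }
        )
    truth = TruthTable(
        genes=pd.DataFrame(
            gene_rows,
            columns=["gene_id", "contig", "mrna", "n_introns", "gene_start", "gene_end"],
        ),
        introns=pd.DataFrame(
            intron_rows,
            columns=[
                "contig",
                "gene_id",
                "start",
                "end",
                "donor",
                "acceptor",
                "type",
                "length",
                "mrna_cut",
            ],
        ),
    )
    return contigs, truth


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def simulate_transcriptome(
    genome_truth: TruthTable,
    config: SimConfig,
) -> Tuple[List[SeqRecord], TruthTable]:
    """Spliced transcripts with optional SL tags plus contaminants.

    Host transcripts are the planted mRNAs; with probability
    ``sl_fraction`` a suffix of the spliced leader (length uniform on
    [``sl_min_len``, full length]) is prepended, and with probability 0.5
    the whole transcript is reverse-complemented (assembly orientation is
    unknown).  Contaminant transcripts are drawn from an independent
    AT-rich codon model and carry no SL.
    """
    rng = config.rng("transcriptome")
    genes = genome_truth["genes"]
    transcripts: List[SeqRecord] = []
    rows = []
    for i, gene in enumerate(genes.itertuples(index=False)):
        tid = f"TR{i + 1}"
        seq = gene.mrna
        sl_len = 0
        if rng.random() < config.sl_fraction:
            sl_len = int(rng.integers(config.sl_min_len, len(config.sl_sequence) + 1))
            seq = config.sl_sequence[-sl_len:] + seq
        flipped = bool(rng.random() < 0.5)
        if flipped:
            seq = revcomp(seq)
        transcripts.append(SeqRecord(id=tid, seq=seq))
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": gene.gene_id,
                "contaminant": False,
                "sl_len": sl_len,
                "revcomp": flipped,
            }
        )
    n_host = len(genes)
    f = config.contaminant_fraction
    n_contaminants = int(round(n_host * f / (1 - f))) if f > 0 else 0
    lo, hi = config.gene_len_codons
    for j in range(n_contaminants):
        tid = f"TRC{j + 1}"
        n_codons = int(rng.integers(lo, hi + 1))
        seq = (
            "ATG"
            + _sample_cds(rng, n_codons, config.contaminant_gc_target, "contaminant")
            + "TAA"
        )
        flipped = bool(rng.random() < 0.5)
        if flipped:
            seq = revcomp(seq)
        transcripts.append(SeqRecord(id=tid, seq=seq))
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": "",
                "contaminant": True,
                "sl_len": 0,
                "revcomp": flipped,
            }
        )
    truth = TruthTable(
        transcripts=pd.DataFrame(
            rows, columns=["transcript_id", "gene_id", "contaminant", "sl_len", "revcomp"]
        )
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# Mitochondrial ORF + homologue alignment
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_mito_alignment(
    config: SimConfig,
    base_code: Optional[GeneticCode] = None,
) -> Tuple[SeqRecord, List[SeqRecord], TruthTable]:
    """A mitochondrial ORF with planted stop-codon reassignments.

    The ORF's translation under ``base_code`` (table 4 by default) carries
    internal stops exactly at the planted sites; homologue proteins show
    the planted residue at those columns at ``agreement_rate`` and match
    the query elsewhere at ``conservation_rate``.  The returned MSA is
    gap-free and includes the query's translation as its first row.
    """
    code = base_code if base_code is not None else GeneticCode(base=4)
    rng = config.rng("mito_alignment")
    L = config.orf_len_codons
    total_sites = sum(n for _, _, n in config.reassignment_spec)
    if total_sites > max(L - 2, 0):
        raise ValueError("more reassigned sites than internal codons")
    table = code.table
    stops = code.stops
    for codon, residue, _ in config.reassignment_spec:
        if codon not in stops:
            raise ValueError(f"{codon} is not a stop codon under the base code")
        if residue not in _AA20:
            raise ValueError(f"invalid residue {residue!r}")
    synonyms: Dict[str, List[str]] = {}
    for c in sorted(table):
        aa = table[c]
        if aa != "*":
            synonyms.setdefault(aa, []).append(c)

    protein = [_AA20[k] for k in rng.integers(0, len(_AA20), size=L)]
    internal = rng.permutation(np.arange(1, L - 1))
    planted: List[Tuple[int, str, str]] = []  # position, codon, residue
    cursor = 0
    for codon, residue, n_sites in config.reassignment_spec:
        for pos in sorted(int(p) for p in internal[cursor : cursor + n_sites]):
            protein[pos] = residue
            planted.append((pos, codon, residue))
        cursor += n_sites
    planted_at = {pos: codon for pos, codon, _ in planted}

    codons = []
    for pos, residue in enumerate(protein):
        if pos in planted_at:
            codons.append(planted_at[pos])
        else:
            options = synonyms[residue]
            codons.append(options[rng.integers(len(options))])
    orf = SeqRecord(id="mtORF1", seq="".join(codons) + "TAA")
    query_row = SeqRecord(id="mtORF1", seq=translate(orf, code))

    msa = [query_row]
    planted_positions = set(planted_at)
    for h in range(config.n_homologues):
        chars = []
        for pos, residue in enumerate(protein):
            if pos in planted_positions:
                keep = rng.random() < config.agreement_rate
            else:
                keep = rng.random() < config.conservation_rate
            if keep:
                chars.append(residue)
            else:
                alternatives = _AA20.replace(residue, "")
                chars.append(alternatives[rng.integers(len(alternatives))])
        msa.append(SeqRecord(id=f"H{h + 1}", seq="".join(chars)))

    truth = TruthTable(
        reassigned_sites=pd.DataFrame(
            [
                {"codon": codon, "residue": residue, "column": pos}
                for pos, codon, residue in sorted(planted)
            ],
            columns=["codon", "residue", "column"],
        )
    )
    return orf, msa, truth


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def _join(a: str, b: str, support: int) -> str:
    return f"({a},{b}){support}"


def _random_join(
    rng: np.random.Generator, parts: List[str], lo: int, hi: int
) -> str:
    parts = list(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(_join(a, b, int(rng.integers(lo, hi + 1))))
    return parts[0]


def simulate_gene_trees(
    config: SimConfig,
) -> Tuple[List[Tree], Dict[str, str], TruthTable]:
    """Bootstrap-annotated gene trees with known clan memberships.

    For each planted-assigned tree the query leaf forms a clan with 2-4
    leaves of its bin, supported within the bin's support range (>= 75);
    the rest of the tree mixes other bins.  Planted-unassigned trees either
    keep every support below 75 (``low_support``) or wrap the query in a
    taxonomically mixed neighbourhood (``mixed_clan``).
    """
    if not config.bin_spec:
        raise ValueError("bin_spec must be non-empty")
    if len(config.bin_spec) < 2 and (
        config.n_unassigned_mixed > 0 or any(n > 0 for _, n, _ in config.bin_spec)
    ):
        raise ValueError("need at least two bins to build mixed backgrounds")
    rng = config.rng("gene_trees")
    pools: Dict[str, List[str]] = {
        bin_name: [f"{bin_name}_{j + 1:02d}" for j in range(config.taxa_per_bin)]
        for bin_name, _, _ in config.bin_spec
    }
    if any(len(p) == 0 for p in pools.values()):
        raise ValueError("every bin needs at least one taxon")
    taxon_map = {leaf: b for b, leaves in pools.items() for leaf in leaves}
    bin_names = [b for b, _, _ in config.bin_spec]

    def outside_leaves(exclude: Optional[str], n: int, start: int = 0) -> List[str]:
        eligible = [b for b in bin_names if b != exclude]
        for _ in range(100):
            chosen_bins = [eligible[k] for k in rng.integers(0, len(eligible), size=n)]
            if len(set(chosen_bins)) >= min(2, len(eligible)):
                break
        leaves = []
        used: Dict[str, int] = {}
        for b in chosen_bins:
            pool = pools[b][start:]
            k = used.get(b, 0) % len(pool)
            leaves.append(pool[k])
            used[b] = used.get(b, 0) + 1
        return sorted(set(leaves))

    trees: List[Tree] = []
    rows = []
    counter = 0

    def emit(newick: str, true_bin: Optional[str], reason: str) -> None:
        nonlocal counter
        counter += 1
        tree_id = f"tree_{counter:04d}"
        trees.append(parse_newick(newick + ";", label=tree_id))
        rows.append({"tree_id": tree_id, "true_bin": true_bin or "", "reason": reason})

    for bin_name, n_trees, (lo, hi) in config.bin_spec:
        if lo < 75:
            raise ValueError("planted-assigned support range must start at >= 75")
        for t in range(n_trees):
            query = f"{config.query_prefix}_q{counter + 1}"
            m = int(rng.integers(2, min(5, config.taxa_per_bin) + 1))
            members = [pools[bin_name][k] for k in rng.choice(config.taxa_per_bin, size=m, replace=False)]
            clade_core = _random_join(rng, [query] + members, 20, 100)
            clade = clade_core.rsplit(")", 1)[0] + ")" + str(int(rng.integers(lo, hi + 1)))
            n_out = int(rng.integers(4, 9))
            others = outside_leaves(bin_name, n_out)
            top = _random_join(rng, [clade] + others, 20, 100)
            emit(top[: top.rfind(")") + 1], true_bin=bin_name, reason="assigned")

    for t in range(config.n_unassigned_low_support):
        query = f"{config.query_prefix}_q{counter + 1}"
        bin_name = bin_names[int(rng.integers(len(bin_names)))]
        m = int(rng.integers(2, 4))
        members = [pools[bin_name][k] for k in rng.choice(config.taxa_per_bin, size=m, replace=False)]
        clade = _random_join(rng, [query] + members, 20, 74)
        others = outside_leaves(bin_name, int(rng.integers(4, 9)))
        top = _random_join(rng, [clade] + others, 20, 74)
        emit(top[: top.rfind(")") + 1], true_bin=None, reason="low_support")

    for t in range(config.n_unassigned_mixed):
        query = f"{config.query_prefix}_q{counter + 1}"
        two = [bin_names[k] for k in rng.choice(len(bin_names), size=2, replace=False)]
        cherry = _join(pools[two[0]][0], pools[two[1]][0], int(rng.integers(75, 101)))
        anchored = _join(query, cherry, int(rng.integers(75, 101)))
        # background leaves drawn from pool indices >= 1 so they never
        # coincide with the cherry, keeping every query side mixed
        others = outside_leaves(None, int(rng.integers(4, 9)), start=1)
        if len({taxon_map[l] for l in others}) < 2:
            others = sorted({pools[two[0]][1], pools[two[1]][1]})
        top = _random_join(rng, [anchored] + others, 20, 100)
        emit(top[: top.rfind(")") + 1], true_bin=None, reason="mixed_clan")

    truth = TruthTable(
        trees=pd.DataFrame(rows, columns=["tree_id", "true_bin", "reason"])
    )
    return trees, taxon_map, truth


# ---------------------------------------------------------------------------
# Mitochondrial proteome feature table
# ---------------------------------------------------------------------------

def simulate_mito_feature_table(
    config: SimConfig,
    evalue_max: float = 1e-4,
    p_min: float = 0.5,
) -> Tuple[pd.DataFrame, TruthTable]:
    """Per-protein evidence rows with the planted inclusion label.

    Evidence fields are sampled independently; the truth label applies the
    published selection rule (three admission channels and the
    SL-or-eukaryote filter), so a correct selector recovers the labels
    exactly.
    """
    rng = config.rng("mito_features")
    n = config.n_feature_rows
    has_hit = rng.random(n) < 0.6
    evalue = np.where(has_hit, 10.0 ** rng.uniform(-30, 0, size=n), np.nan)
    p1 = np.where(rng.random(n) < 0.9, np.round(rng.random(n), 4), np.nan)
    p2 = np.where(rng.random(n) < 0.9, np.round(rng.random(n), 4), np.nan)
    ortholog = rng.random(n) < 0.25
    curated = rng.random(n) < 0.03
    sl = rng.random(n) < 0.5
    domain = rng.choice(
        np.array(["eukaryote", "prokaryote", "none"]), size=n, p=[0.6, 0.3, 0.1]
    )
    features = pd.DataFrame(
        {
            "protein_id": [f"{config.query_prefix}{i + 1:06d}" for i in range(n)],
            "mito_db_evalue": evalue,
            "mito_db_subject": np.where(
                has_hit, [f"MM{int(s):05d}" for s in rng.integers(0, 10 * n, size=n)], ""
            ),
            "p_target1": p1,
            "p_target2": p2,
            "ortholog_flag": ortholog,
            "curated_flag": curated,
            "sl_flag": sl,
            "best_hit_domain": domain,
        }
    )
    similarity = has_hit & (evalue < evalue_max)
    targeting = (np.nan_to_num(p1) >= p_min) | (np.nan_to_num(p2) >= p_min)
    channel1 = similarity & targeting
    preliminary = channel1 | ortholog | curated
    admitted = sl | (domain == "eukaryote")
    include = preliminary & admitted
    truth = TruthTable(
        mito_candidates=pd.DataFrame(
            {
                "protein_id": features["protein_id"],
                "include": include,
                "channel1": channel1,
                "channel2": ortholog,
                "channel3": curated,
                "admitted": admitted,
            }
        )
    )
    return features, truth


# ---------------------------------------------------------------------------
# Shotgun reads (for the k-mer genome-size estimator)
# ---------------------------------------------------------------------------

def simulate_reads(
    config: SimConfig,
    genome: Sequence[SeqRecord],
    coverage: float = 20.0,
    read_len: int = 100,
) -> List[SeqRecord]:
    """Error-free uniform shotgun reads at a target coverage.

    Reads are drawn uniformly from both strands of the supplied contigs;
    no sequencing error is simulated.
    """
    rng = config.rng("reads")
    reads: List[SeqRecord] = []
    counter = 0
    for contig in genome:
        n_reads = int(math.ceil(coverage * len(contig.seq) / read_len))
        if len(contig.seq) < read_len:
            raise ValueError(f"contig {contig.id} shorter than the read length")
        starts = rng.integers(0, len(contig.seq) - read_len + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        for s, flip in zip(starts, strands):
            counter += 1
            seq = contig.seq[int(s) : int(s) + read_len]
            if flip:
                seq = revcomp(seq)
            reads.append(SeqRecord(id=f"read{counter}", seq=seq))
    return reads
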