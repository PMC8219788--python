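# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generators emulate, and the
known limits of both.

## Coordinates, alphabets, formats

All genomic intervals are 0-based, half-open in memory; GFF3 output
converts to 1-based inclusive coordinates and round-trips through the
paired reader. Sequences are upper-cased on read and U is mapped to T for
nucleotide records, so every stage works on the {A,C,G,T,N} alphabet.
Newick internal-node labels are read as integer bootstrap supports
(RAxML/IQ-TREE convention); a missing label means support 0, and labels on
the two edges of a degree-2 root — the same unrooted edge — are merged,
keeping the larger value. Newick parsing is delegated to dendropy; the
tree is then re-expressed in a small node structure that exposes the
bipartition enumeration the clan stage needs.

## Assembly metrics and genome size

N50/L50 use the standard descending-sort definition: the first contig at
which the cumulative length reaches half the total, and its rank. GC is
counted over unambiguous bases only, with N-density reported separately as
Ns per 100 kbp of total length, so the two statistics do not interact.

The mapping-fraction size estimate is the identity `L / f`: if only a
fraction `f` of transcriptome reads map to an assembly of length `L`, the
assembly is taken to represent that fraction of the genome. It inherits
every bias of the mapping step and is reported to whole Mbp only.

The k-mer estimator counts canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement; default k = 21, odd k in [11, 31]
enforced), builds the multiplicity histogram, discards singletons as
sequencing-error artefacts, takes the modal multiplicity ≥ 2 as the
coverage peak (ties resolved toward lower coverage), and divides the total
non-singleton occurrence count by that peak. This is a documented standard
variant, not a reimplementation of any particular published tool; the
modal peak wobbles by ±1 on small simulated genomes, which is visible as a
few-percent scatter in the estimate. No heterozygosity- or bias-aware
model is fitted.

## Decontamination (GC + CAI)

The screen follows the conservative two-statistic design: a transcript is
a probable contaminant only when the GC content **and** the CAI of its
coding sequence both fall below the threshold (0.45/0.45 by default).
Single low measures are reported but never flagged.

Choices the published procedure leaves open, fixed here:

* **ORF selection.** The CDS of a transcript is the longest stop-free
  codon run of at least 150 nt over all six frames; ties go to the lowest
  frame index, forward strand before reverse. No ATG requirement is
  imposed — assembled transcripts are often 5'-truncated.
* **CAI.** Sharp & Li's geometric mean of relative adaptiveness, excluding
  stops and the single-codon families ATG and TGG. Relative adaptiveness
  uses a pseudo-count of 0.5 so that a codon never observed in the
  reference still has w > 0 and a single rare codon cannot zero out a
  transcript.
* **GC** is computed over the selected CDS, not the whole transcript.

On GC-rich transcripts the longest stop-free run occasionally lies in a
wrong frame (GC-rich sequence is stop-poor in every frame), which deflates
CAI for a minority of genuine transcripts. This is precisely why the
conjunctive rule is the right conservative choice: those transcripts keep
their high GC and are never flagged.

## Spliced-leader scan

Matching is exact and terminal by design: the longest k ≥ k_min (default
10) such that the length-k SL suffix is a transcript prefix, or — because
assembled transcripts are unoriented — its reverse complement is a
transcript suffix. Both orientations are searched by default
(`forward_only` restores a 5'-only rule); when both ends match, the longer
match wins, ties to the 5' end. Internal SL occurrences are deliberately
ignored. Corpus summaries report counts and percentages per minimum
length; the fraction is non-increasing in the minimum by construction.

## Introns

**Spliced aligner (synthetic data only).** The built-in aligner indexes
contig k-mers (default anchor 20 nt), extends exact matches maximally,
and chains the collinear subset maximising transcript coverage; an
alignment is accepted at ≥ 90% coverage. It is exact-match anchor
chaining for error-free simulated data; real alignments enter as
exon-block tables from an external spliced aligner.

**Extraction.** A genomic gap ≥ 30 nt (`min_intron`) with zero transcript
gap becomes an intron; smaller genomic gaps are indels and are skipped.
When a junction repeat makes several gap placements equivalent, the gap is
left-shifted maximally, then shifted right (up to 10 nt) to the first
placement with GT/GC…AG boundaries — the same normalisation spliced
aligners apply. A transcript overhang of at least one anchor length that
cannot fit on the remaining contig yields an incomplete call
(`incomplete_5p`/`incomplete_3p`) carrying only the observed boundary;
such calls get no type, since one boundary cannot decide it.

**Classification.** Conventional iff donor ∈ {GT, GC} and acceptor = AG;
every other pair of the 256 is nonconventional. Introns matching the
conventional pattern at exactly one end are flagged `intermediate` on the
call (a property, not a third class). Minus-strand alignments are
normalised before boundaries are read.

**Stem evidence.** The score is the longest gapless run of Watson–Crick
or G·U pairs between the first window (default 20 nt) and the reversed
last window, over all relative offsets; the pairing map lists the paired
positions. The window shrinks to half the intron length for short
introns. G·U pairing makes the score asymmetric under reverse complement
(G·U maps to C·A); with Watson–Crick pairs only it is strictly invariant,
and that is the mode the invariance test uses. This deliberately replaces
full secondary-structure prediction: the quantity of interest is boundary
complementarity, not the complete fold.

**Boundary PFMs** stack 2×flank windows around donor and acceptor on the
gene sense strand into a base-frequency matrix (columns sum to 1) for logo
rendering. **Intron-position homology** maps each intron to the MSA column
of its codon plus phase; two introns are shared iff column and phase
match.

## Clan binning

A clan is one side of a bipartition of the unrooted tree — a rooting-free
notion, since the input trees are unrooted. A tree is assigned to bin B
when all query leaves (label prefix, default `RCo`) lie in a side whose
non-query members are non-empty, all map to B, and whose support is ≥ 75
(inclusive). Among several qualifying clans the smallest wins (ties:
higher support, then lexicographic bin) — the closest relatives carry the
signal. Multiple query leaves are treated as query (ignored for
homogeneity) but must all sit inside the clan. Trees failing only on
support are tallied `low_support`; trees with no homogeneous
query-containing side at any support are `mixed_clan`. Correctness is
checked against an exhaustive edge-removal oracle on all trees up to 8
leaves.

## Mitochondrial genetic code

Translation tables 1 (standard) and 4 (mold/protozoan mitochondrial,
UGA → Trp) are built in and verified codon-by-codon against the NCBI
tables; overrides lay codon→residue reassignments over a base table, and
the stop set is derived after overrides.

Reassignment inference maps each internal stop of the base-code
translation to its MSA column through the gapped query row and pools
homologue residue counts across the usable columns (≥ 4 non-gap
homologues each). The pooled modal residue is called **inferred** at
pooled agreement ≥ 0.5 over ≥ 3 sites; pooling across sites (rather than
per-site voting) keeps the call robust to single divergent columns.
Below-threshold evidence is **insufficient**; disagreeing per-site modal
residues without a pooled majority are **ambiguous**. The thresholds are
explicit knobs, not reproductions of any published cutoff — the source
observation was qualitative. Query `*` characters never enter the tally.

## Mitochondrial proteome selection

The module implements decision logic only; BLAST e-values, targeting
probabilities, orthology and curation flags arrive as an input table.
Channel 1 requires database similarity (e-value < 1e-4, strict) **and** a
targeting probability ≥ 0.5 (inclusive) from at least one of the two
predictors, with a missing probability counting as 0. Channels 2
(orthology) and 3 (curated list) are flags. Best-hit deduplication keeps
one query per database subject (lowest e-value, then highest bitscore,
then lexicographic query id); a query may survive for several subjects.
The SL-or-eukaryote admission filter is applied uniformly to the union of
all channels as a final pass — the published account does not break the
removed set down by channel, so a uniform pass is the cleanest
formalisation. Stage counts expose every intermediate set size so the
inclusion–exclusion identities can be asserted exactly.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a `SimConfig`; child RNGs derive from
the single seed via fixed spawn keys, so identical configs give
byte-identical output, and every planted property is re-derivable from the
generated sequences themselves (the tests do exactly that).

* **Genes and introns.** One gene per contig: exons drawn from a GC-rich
  host codon model, introns of 60–300 nt inserted at junctions ≥ 40 nt
  apart. Conventional introns get GT (10% GC) donors and AG acceptors;
  nonconventional introns get terminal 20-mers that are exact reverse
  complements (a clean stem signal) with boundary dinucleotides outside
  GT/GC…AG. Junction bases are chosen so gap placement is unambiguous —
  real aligners face placement ambiguity that the splice-aware
  normalisation handles, and a dedicated test covers that case separately.
* **Codon models.** Host and contaminant models combine a per-family
  rank bias (geometric decay 0.5 per rank) with a GC tilt solved
  numerically so mean CDS GC hits the target: 0.58 for the host
  (transcriptome-like), 0.35 for contaminants. The two profiles prefer
  opposite codons within each synonymous family, which is what gives CAI
  its discriminating power — mirroring the real situation where
  contaminants follow a foreign codon-usage profile.
* **Transcripts.** Host transcripts are the spliced mRNAs; 15.3% (the
  corpus-level SL rate the scan reports on real euglenid data) receive an
  SL suffix of uniform length 10–27 nt, and each transcript is
  reverse-complemented with probability 0.5. Contaminants (10% of the
  corpus by default — large enough to measure precision and recall
  stably) carry no SL. No sequencing error, truncation, chimerism or
  coverage variation is simulated, so perfect recovery on synthetic data
  demonstrates the correctness of the decision rules, not robustness to
  assembly noise.
* **Mitochondrial ORFs.** A 300-codon protein with planted TAG sites
  (default 5) encoded under code 4; homologues show the planted residue at
  80% and match the query elsewhere at 90%, gap-free. Real alignments have
  gaps and truncated homologues; the inference handles gaps, but the
  default simulation does not stress them.
* **Gene trees.** Planted-assigned trees wrap the query in a pure clan of
  2–4 same-bin leaves with support drawn ≥ 75 against a mixed background;
  low-support trees keep every support below 75; mixed trees cherry the
  query with two different bins. Bin sizes default to the 53/12/10/5
  proportions of the four largest bins in the real affiliation profile,
  plus 20 unassigned trees.
* **Feature tables.** Evidence fields are sampled independently with
  rates that populate all decision branches; the truth label applies the
  selection rule at generation time, so selector recovery is an exact,
  not a statistical, check.

## Problem sizes

Defaults are sized for desk-scale runs: intron recovery uses 8 genes × 2
introns across 10–20 seeds, decontamination a 2,000-transcript mixture,
clan binning 100 trees, reassignment 100 null replicates, selection 5,000
rows. The full test suite and the acceptance script each complete in
seconds on one CPU.

## Known limitations

* The spliced aligner requires exact matches and is unsuitable for real
  reads; the funnel of nonconventional-intron candidates on real data
  additionally depends on external read mapping and similarity searches
  that are out of scope here.
* The k-mer size estimator assumes even coverage; amplified libraries
  violate that and bias the estimate in ways the module does not model.
* CAI frame misassignment on stop-poor GC-rich transcripts (above) makes
  the CAI axis conservative on its own; the conjunctive rule absorbs this.
* Clan binning treats every non-query leaf as correctly binned; taxonomy
  errors in the leaf map propagate directly.
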