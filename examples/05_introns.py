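"""Call introns from spliced alignments and classify their boundaries.

Transcripts are aligned back to genome contigs; genomic gaps of at least
30 nt become intron calls.  Introns with GT (or GC) donors and AG
acceptors are conventional spliceosomal introns; anything else is a
candidate nonconventional intron, for which base pairing between the two
intron ends (a stem) is the supporting evidence.
"""

from rhabdotools import boundary_pfm, call_introns, stem_loop_score
from rhabdotools.simulate import (
    SimConfig,
    simulate_annotated_genome,
    simulate_transcriptome,
)

config = SimConfig(
    seed=9, n_genes=12, introns_per_gene=2, nonconventional_fraction=0.4,
    contaminant_fraction=0.0,
)
contigs, truth = simulate_annotated_genome(config)
transcripts, _ = simulate_transcriptome(truth, config)

calls = call_introns(transcripts, contigs)
conventional = [c for c in calls if c.type == "conventional"]
nonconventional = [c for c in calls if c.type == "nonconventional"]
print(f"intron calls: {len(calls)} "
      f"({len(conventional)} conventional, {len(nonconventional)} nonconventional)")

example = nonconventional[0]
by_id = {c.id: c.seq for c in contigs}
seq = by_id[example.contig][example.start : example.end]
score, pairs = stem_loop_score(seq, window=20)
print(f"example nonconventional intron {example.contig}:{example.start}-{example.end}")
print(f"  boundaries {example.donor}..{example.acceptor}, stem score {score}/20")
print(f"  first pair {pairs[0]}, last pair {pairs[-1]} (positions in the intron)")

pfm = boundary_pfm(calls, contigs, flank=3)
print("\ndonor-side base frequencies (donor dinucleotide at columns 3-4):")
print(pfm.iloc[:, :6].round(2).to_string())
print("\nA stem score of 20 means the terminal 20-mers pair perfectly -")
print("the planted signature of nonconventional introns.")
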