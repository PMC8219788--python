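"""Two coarse genome-size estimates: mapping fraction and k-mer histogram.

The mapping estimate divides the assembly length by the fraction of
transcriptome reads that map to it (the unmapped remainder is assumed to
come from missing genome).  The k-mer estimate divides the total number of
non-singleton k-mer occurrences in the reads by the coverage peak of the
k-mer multiplicity histogram.
"""

import numpy as np

from rhabdotools import SeqRecord, estimate_size_from_mapping, kmer_size_estimate
from rhabdotools.simulate import SimConfig, simulate_reads

# Mapping-fraction estimate with the published inputs: a 106,888,161-bp
# assembly to which 43.5% of transcriptome reads map.
size = estimate_size_from_mapping(106_888_161, 0.435)
print(f"mapping-based estimate : {size / 1e6:.1f} Mbp (approx. 250 Mbp)")

# K-mer estimate on simulated error-free 20x reads from a 10-kb genome.
rng = np.random.default_rng(1)
genome = SeqRecord(id="G", seq="".join("ACGT"[i] for i in rng.integers(0, 4, 10_000)))
reads = simulate_reads(SimConfig(seed=2), [genome], coverage=20, read_len=100)
estimate = kmer_size_estimate(reads, k=21)
print(f"k-mer estimate         : {estimate:,.0f} bp (true genome 10,000 bp)")
print()
print("The k-mer route needs no assembly at all; its accuracy depends on")
print("even coverage, which whole-genome amplification can distort.")
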