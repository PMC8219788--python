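"""Infer a mitochondrial stop-codon reassignment from homologue columns.

Translating a mitochondrial ORF under NCBI code 4 (UGA -> Trp) can leave
in-frame TAG stops.  If homologues consistently show tyrosine at those
alignment columns, TAG has been reassigned to Tyr.  The inference maps
every internal stop to its column, pools homologue residues across sites,
and calls the reassignment when the pooled agreement clears a majority
threshold.
"""

from rhabdotools import GeneticCode, infer_reassignments, translate
from rhabdotools.simulate import SimConfig, simulate_mito_alignment

orf, msa, truth = simulate_mito_alignment(
    SimConfig(seed=15, reassignment_spec=(("TAG", "Y", 5),), agreement_rate=0.8)
)

code4 = GeneticCode(base=4)
translation = translate(orf, code4)
print(f"ORF {orf.id}: {len(orf.seq)} nt, "
      f"{translation.count('*')} internal stops under code 4")

(evidence,) = infer_reassignments(orf, msa, base_code=code4)
print(f"codon {evidence.codon}: {evidence.n_internal_sites} internal sites, "
      f"majority residue {evidence.majority_residue}, "
      f"agreement {evidence.agreement:.2f} -> {evidence.verdict}")

resolved = code4.with_override(evidence.codon, evidence.majority_residue)
print(f"after applying the override: "
      f"{translate(orf, resolved).count('*')} internal stops remain")
print("\nAgreement ~0.8 is the planted homologue conservation at the")
print("reassigned sites; 0 remaining stops confirms the override is right.")
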