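"""Substitution audit of a beta-type (delta) globin chain.

Lists differences of the shipped synthetic eastern-mole-like delta chain
against its reference scaffold and checks the four canonical DPG-binding
residues (1Val, 2His, 82Lys, 143His).
"""

from molehb import dpg_site_audit, list_substitutions, read_fasta
from molehb.io import data_path

reference, eastern = read_fasta(data_path("delta_globins_synthetic.fasta"))[:2]

print(f"substitutions in {eastern.id} vs {reference.id}:")
for rec in list_substitutions(eastern, reference):
    print(f"  {rec.position:>3} {rec.ref_aa}->{rec.query_aa}  ({rec.charge_change})")

audit = dpg_site_audit(eastern)
status = ", ".join(
    f"{pos}{s['observed']}{'' if s['conserved'] else '!'}"
    for pos, s in audit["sites"].items()
)
print(f"DPG-pocket residues: {status}  all_conserved={audit['all_conserved']}")
print("Every canonical phosphate-binding residue is intact, yet 136 Gly->Glu")
print("adds anionic charge to the central cavity - the combination that")
print("explains DPG insensitivity without loss of the binding-site residues.")
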