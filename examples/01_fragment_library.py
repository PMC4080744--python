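"""Fragment a small ester/amide library with the toy cleavage rules.

Builds a handful of molecules in memory, applies the three toy rules
(ester, amide, ether) with extensive fragmentation at a minimum fragment
size of 2 heavy atoms, and prints each molecule's fragment set.
"""

from rdkit import Chem

from molblocks import fragment_library
from molblocks.chem_io import MoleculeRecord
from molblocks.fixtures import toy_rules

MOLECULES = [
    ("CC(=O)OCC", "ethyl_acetate"),
    ("CCOC(=O)CCC(=O)OCC", "diethyl_succinate"),
    ("CC(=O)NC", "n_methylacetamide"),
    ("CCCC", "butane"),
]

records = [
    MoleculeRecord(id=mol_id, smiles=smi, mol=Chem.MolFromSmiles(smi))
    for smi, mol_id in MOLECULES
]
table = fragment_library(records, toy_rules(), min_size=2, extensive=True)

for row in table:
    frags = ", ".join(sorted(row.fragments)) or "(none)"
    print(f"{row.molecule_id:20s} {row.parent_smiles:22s} -> {frags}")

# Each line shows the canonical fragments released by cutting every
# maximal set of co-cleavable bonds; butane has no cleavable bond, so it
# yields no fragment (the intact parent is not a fragment).
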