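"""Similarity search: hashed-path fingerprint Tanimoto and exact MCS.

Scores a toluene query against a small library both ways and prints the
benzene/toluene MCS Tanimoto worked example (6 shared ring atoms out of a
7-atom union -> 6/7).
"""

from rdkit import Chem

from molscreen import (
    CompoundSet,
    mcs_tanimoto,
    parse_smiles,
    search_library,
)

library = CompoundSet(set_number=1, title="mini library")
for i, smi in enumerate(["c1ccccc1", "Cc1ccccc1O", "CCO", "c1ccncc1",
                         "CC(=O)Oc1ccccc1C(=O)O"], 1):
    library.add(parse_smiles(smi, auto_name=f"CMPD{i}"))

query = parse_smiles("Cc1ccccc1 toluene")
for metric in ("fingerprint", "mcs"):
    hits = search_library(query, library, metric=metric, threshold=0.2)
    print(f"{metric} hits:",
          [(h.compound_id, round(h.score, 3)) for h in hits])

score = mcs_tanimoto(Chem.MolFromSmiles("c1ccccc1"), Chem.MolFromSmiles("Cc1ccccc1"))
print(f"benzene vs toluene MCS Tanimoto = {score:.4f}  (= 6/7)")
# The MCS metric counts shared connected substructure atoms, so it rewards a
# common scaffold even when peripheral substituents differ.
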