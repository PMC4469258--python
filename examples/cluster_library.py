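"""Cluster a library: MaxMin diversity picks seed a Tanimoto k-means.

Two scaffold families (alkanes and phenols) with k=2 should split cleanly,
with one MaxMin representative per family.
"""

from molscreen import CompoundSet, cluster_set, parse_smiles

smiles = ["CCCC", "CCCCC", "CCCCCC", "Oc1ccccc1", "Oc1ccc(C)cc1", "Oc1ccc(CC)cc1"]
cset = CompoundSet(set_number=1, title="two families")
for i, smi in enumerate(smiles, 1):
    cset.add(parse_smiles(smi, auto_name=f"CMPD{i}"))

cset, result = cluster_set(cset, k=2, rng_seed=0)
print(f"objective={result.objective:.4f} after {result.iterations} iteration(s), "
      f"converged={result.converged}")
for rec in cset:
    rep = "*" if rec.annotations["is_representative"].value == "1" else " "
    print(f"  {rec.compound_id} {rec.smiles:16s} cluster={rec.annotations['cluster'].value} {rep}")
# '*' marks the MaxMin picks used as initial centroids; the objective is the
# summed (1 - Tanimoto) of each compound to its own cluster centroid.
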