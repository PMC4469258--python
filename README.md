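# molscreen

Small-molecule compound appraisal for screening laboratories: a Python
library (plus a thin `molscreen` command) that computes physico-chemical
descriptors, checks drug-/lead-/fragment-likeness rules, screens compounds
against the combined 480-pattern PAINS substructure catalogue, runs
fingerprint- and maximum-common-subgraph similarity searches, clusters
libraries by MaxMin + Tanimoto k-means, and writes tabular reports
(ASCII/CSV/HTML/PDF) with optional PubChem cross-linking.

It is aimed at groups running medium-sized compound screens who need to
answer, per molecule: *is it drug-like, is it a likely assay-interference
(PAINS) compound, what does it resemble, and how diverse is my library?*

## The core methods

**Likeness rules.** Each compound's descriptor block — average molecular
weight, Crippen atom-contribution logP, Lipinski H-bond donors (O–H/N–H
hydrogens) and acceptors (N+O atoms), Ertl TPSA, rotatable bonds, heavy
atoms, rings, formal charge, Hill formula — is checked against threshold
rule sets: Lipinski's rule of five (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10,
at most one violation), lead-likeness, and the rule of three for fragments.
Rule sets live in an editable YAML file.

**PAINS screening.** Pan-assay interference compounds carry substructures
(quinones, catechols, rhodanines, hydrazones, …) that produce promiscuous
apparent activity. The packaged catalogue is the public sln→SMARTS
translation of the interference filters, merged from its three source
families (A: 16, B: 55, C: 409 patterns). Each compound is matched against
all 480 compiled SMARTS queries; one hit flags the compound. A
`concordance_report` compares the flagged sets of two screening runs
(matching / only-in-A / only-in-B), since different SMARTS engines are known
to disagree slightly on these patterns.

**Similarity.** Hashed simple-path fingerprints (1024 bits, paths up to 7
bonds, CRC-32 bit assignment) give the Tanimoto coefficient
T = |A∩B|/|A∪B|. An exact branch-and-bound search finds the maximum
*connected* common subgraph (atoms match on element, bonds on
order/aromaticity) and scores it as the MCS Tanimoto
n_mcs / (n_a + n_b − n_mcs) over heavy-atom counts; for benzene vs toluene
this is 6/7 ≈ 0.857.

**Clustering.** MaxMin picks k maximally spread compounds under Tanimoto
distance (1 − T); those picks seed a k-means over real-valued centroids
with the continuous Tanimoto similarity Σxᵢcᵢ / (Σxᵢ² + Σcᵢ² − Σxᵢcᵢ).

## Worked example

```python
from molscreen import appraise_set, make_fixture_set

cset = make_fixture_set("mixed_bench", 10, rng_seed=7)  # exemplars + drugs
appraise_set(cset)
for rec in cset:
    d = rec.descriptors
    print(rec.name, round(d.mw, 2), rec.likeness["drug_like"].passed,
          rec.pains_flagged)
```

prints (abridged; see `examples/appraise_library.py` for the full script):

```
naproxen        230.26  True  False
rhodanine       133.2   True  True
p-benzoquinone  108.1   True  True
aspirin         180.16  True  False
```

Aspirin's block (MW 180.16, HBD 1, HBA 4, logP 1.31) passes the rule of
five with zero violations; rhodanine and p-benzoquinone are correctly
flagged as interference scaffolds while the approved drugs are not. The
same tasks are available from the shell:

```sh
molscreen appraise library.smi --out-dir out/   # set01.csv + set01.html
molscreen pains library.smi
molscreen search library.smi --query "Cc1ccccc1" --metric mcs --threshold 0.6
molscreen cluster library.smi --k 5 --seed 0
```

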