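"""Deterministic synthetic compound sets for testing and benchmarking.

Three families are generated:

``alkanes``
    the homologous linear series CH4, C2H6, ... — a clean, monotone ladder
    for descriptor and fingerprint properties;
``pains_exemplars``
    literature pan-assay-interference scaffolds (quinones, catechols,
    rhodanines, hydrazones, alkylidene barbiturates, azo dyes, Mannich
    phenols) that every engine screening the combined catalogue must flag;
``mixed_bench``
    exemplars interleaved with structurally clean approved-drug molecules at
    a recorded ratio — the in-repo analogue of screening a vendor library.

Every fixture is a pure function of ``(kind, n, rng_seed)``.
"""

from __future__ import annotations

import random

from .io import parse_smiles
from .model import AnnotationValue, CompoundSet

__all__ = ["PAINS_EXEMPLARS", "CLEAN_DRUGS", "make_fixture_set"]

#: Known interference scaffolds; each verified to match >= 1 filter of the
#: packaged catalogue.  (name, SMILES, expected filter family)
PAINS_EXEMPLARS: list[tuple[str, str]] = [
    ("p-benzoquinone", "O=C1C=CC(=O)C=C1"),
    ("naphthoquinone", "O=C1c2ccccc2C(=O)C=C1"),
    ("catechol", "Oc1ccccc1O"),
    ("rhodanine", "O=C1CSC(=S)N1"),
    ("ene-rhodanine", "O=C1N(CC(=O)O)C(=S)SC1=Cc1ccccc1"),
    ("hydroxyphenyl-hydrazone", "Oc1ccccc1/C=N/Nc1ccccc1"),
    ("alkylidene-barbiturate", "O=C1NC(=O)NC(=O)C1=Cc1ccccc1"),
    ("azo-aniline", "Nc1ccc(/N=N/c2ccccc2)cc1"),
    ("mannich-phenol", "CN(C)Cc1cc(O)ccc1O"),
    ("alizarin", "O=C1c2ccccc2C(=O)c2c1ccc(O)c2O"),
    ("isatin-hydrazone", "O=C1Nc2ccccc2C1=NNc1ccccc1"),
    ("thioxo-barbiturate", "S=C1NC(=O)C(=Cc2ccccc2)C(=O)N1"),
]

#: Approved-drug molecules verified to match no filter in the catalogue.
CLEAN_DRUGS: list[tuple[str, str]] = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("amoxicillin", "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O"),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"),
]

_CLASS_COLUMN = "fixture_class"


def _build(entries: list[tuple[str, str, str]], title: str,
           set_number: int) -> CompoundSet:
    cset = CompoundSet(set_number=set_number, title=title)
    cset.annotation_columns = [(_CLASS_COLUMN, "text")]
    for i, (name, smiles, cls) in enumerate(entries, start=1):
        rec = parse_smiles(f"{smiles} {name}", auto_name=f"CMPD{i}")
        rec.annotations[_CLASS_COLUMN] = AnnotationValue("text", cls)
        cset.add(rec)
    return cset


def make_fixture_set(kind: str, n: int, rng_seed: int = 0,
                     set_number: int = 1) -> CompoundSet:
    """Generate a deterministic fixture set of ``n`` compounds.

    ``mixed_bench`` interleaves interference exemplars and clean drugs in an
    order drawn from ``rng_seed``, aiming at a 1:1 ratio (recorded in the set
    title).  Raises ``ValueError`` when ``n`` exceeds the packaged material,
    stating the maximum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "alkanes":
        entries = [(f"alkane-C{i}", "C" * i, "clean") for i in range(1, n + 1)]
        return _build(entries, f"alkanes n={n}", set_number)
    if kind == "pains_exemplars":
        if n > len(PAINS_EXEMPLARS):
            raise ValueError(
                f"at most {len(PAINS_EXEMPLARS)} packaged interference exemplars")
        entries = [(name, smi, "pains_exemplar")
                   for name, smi in PAINS_EXEMPLARS[:n]]
        return _build(entries, f"pains_exemplars n={n}", set_number)
    if kind == "mixed_bench":
        n_max = len(PAINS_EXEMPLARS) + len(CLEAN_DRUGS)
        if n > n_max:
            raise ValueError(f"at most {n_max} packaged benchmark compounds")
        n_pains = min(len(PAINS_EXEMPLARS), (n + 1) // 2)
        n_clean = n - n_pains
        if n_clean > len(CLEAN_DRUGS):
            n_clean = len(CLEAN_DRUGS)
            n_pains = n - n_clean
        pool = ([(name, smi, "pains_exemplar") for name, smi in PAINS_EXEMPLARS[:n_pains]]
                + [(name, smi, "clean_drug") for name, smi in CLEAN_DRUGS[:n_clean]])
        random.Random(rng_seed).shuffle(pool)
        return _build(pool, f"mixed_bench n={n} ratio={n_pains}:{n_clean} seed={rng_seed}",
                      set_number)
    raise ValueError(f"unknown fixture kind {kind!r}")


def expected_flagged_ids(cset: CompoundSet) -> list[str]:
    """Ids of fixture records built from interference exemplars."""
    return [r.compound_id for r in cset
            if r.annotations.get(_CLASS_COLUMN)
            and r.annotations[_CLASS_COLUMN].value == "pains_exemplar"]
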