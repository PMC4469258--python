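"""Physico-chemical property calculation for the appraisal task.

The block computed here (MW, logP, HBD, HBA, TPSA, rotatable bonds, heavy
atoms, rings, formal charge, Hill formula) is the minimal set every
drug-/lead-/fragment-likeness rule needs, plus the standard spreadsheet
columns.  Conventions:

* MW uses average (not monoisotopic) atomic masses; reported to 2 decimals,
  full precision kept internally.
* logP is the Crippen atom-contribution estimate (typed-atom sum over the
  toolkit's versioned contribution table).  Agreement with other logP
  estimators is not promised.
* HBD = number of O-H and N-H hydrogens, HBA = number of N and O atoms
  (the Lipinski counting convention, not acceptor perception).
* TPSA is the Ertl fragment-contribution sum over polar N/O fragments.
* Rotatable bonds: acyclic single non-aromatic bonds whose endpoints both
  have >= 2 heavy-atom neighbours; amide C-N bonds excluded by default
  (``count_amide_bonds=True`` toggles the convention).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Union

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as _D, Lipinski, rdMolDescriptors

from .model import CompoundRecord, MolecularGraph

__all__ = [
    "DescriptorBlock",
    "CONTRIBUTION_TABLE_VERSION",
    "molecular_weight",
    "logp",
    "hbond_counts",
    "tpsa",
    "rotatable_bonds",
    "compute_all",
]

#: Version tag of the Crippen-logP and Ertl-TPSA contribution tables in use.
CONTRIBUTION_TABLE_VERSION = f"rdkit-{Chem.rdBase.rdkitVersion}"


@dataclass(frozen=True)
class DescriptorBlock:
    mw: float            # g/mol
    logp: float          # dimensionless
    hbd: int             # O-H + N-H hydrogen count
    hba: int             # N + O atom count
    tpsa: float          # Angstrom^2
    rotatable_bonds: int
    heavy_atoms: int
    ring_count: int
    formal_charge: int   # e
    formula: str         # Hill notation

    def __post_init__(self) -> None:
        for name in ("hbd", "hba", "rotatable_bonds", "heavy_atoms", "ring_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tpsa < 0:
            raise ValueError("tpsa must be non-negative")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _as_mol(graph: Union[Chem.Mol, CompoundRecord]) -> Chem.Mol:
    if isinstance(graph, CompoundRecord):
        return graph.mol
    if isinstance(graph, MolecularGraph):
        raise TypeError("descriptor operations take an RDKit Mol (or CompoundRecord); "
                        "MolecularGraph is a read-only view")
    return graph


def molecular_weight(graph: Union[Chem.Mol, CompoundRecord]) -> float:
    """Average molecular weight in g/mol (heavy atoms + all hydrogens)."""
    mol = _as_mol(graph)
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecular graph")
    return _D.MolWt(mol)


def logp(graph: Union[Chem.Mol, CompoundRecord]) -> float:
    """Crippen atom-contribution octanol/water partition estimate."""
    mol = _as_mol(graph)
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecular graph")
    return Crippen.MolLogP(mol)


def hbond_counts(graph: Union[Chem.Mol, CompoundRecord]) -> tuple[int, int]:
    """(HBD, HBA) under the Lipinski counting convention."""
    mol = _as_mol(graph)
    return Lipinski.NHOHCount(mol), Lipinski.NOCount(mol)


def tpsa(graph: Union[Chem.Mol, CompoundRecord]) -> float:
    """Topological polar surface area (Ertl fragment sum) in Angstrom^2."""
    return _D.TPSA(_as_mol(graph))


def _is_amide_cn(bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a, b), (b, a)):
        if c.GetSymbol() == "C" and n.GetSymbol() == "N":
            for nb in c.GetBonds():
                other = nb.GetOtherAtom(c)
                if (other.GetSymbol() == "O"
                        and nb.GetBondType() == Chem.BondType.DOUBLE):
                    return True
    return False


def rotatable_bonds(graph: Union[Chem.Mol, CompoundRecord],
                    count_amide_bonds: bool = False) -> int:
    """Count acyclic single bonds with both endpoints attached to >= 2 heavy
    atoms; amide C-N bonds excluded unless ``count_amide_bonds``."""
    mol = _as_mol(graph)
    n = 0
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if bond.GetBeginAtom().GetDegree() < 2 or bond.GetEndAtom().GetDegree() < 2:
            continue
        if not count_amide_bonds and _is_amide_cn(bond):
            continue
        n += 1
    return n


def compute_all(record: CompoundRecord) -> CompoundRecord:
    """Populate ``record.descriptors`` in place (idempotent) and return it.

    Element/typing errors are re-raised with the compound id for context.
    """
    if record.mol is None or record.mol.GetNumAtoms() == 0:
        raise ValueError(f"{record.compound_id}: empty molecular graph")
    try:
        hbd, hba = hbond_counts(record.mol)
        record.descriptors = DescriptorBlock(
            mw=molecular_weight(record.mol),
            logp=logp(record.mol),
            hbd=hbd,
            hba=hba,
            tpsa=tpsa(record.mol),
            rotatable_bonds=rotatable_bonds(record.mol),
            heavy_atoms=record.mol.GetNumHeavyAtoms(),
            ring_count=rdMolDescriptors.CalcNumRings(record.mol),
            formal_charge=Chem.GetFormalCharge(record.mol),
            formula=rdMolDescriptors.CalcMolFormula(record.mol),
        )
    except Exception as exc:  # pragma: no cover - defensive context wrapping
        raise type(exc)(f"{record.compound_id}: {exc}") from exc
    return record
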