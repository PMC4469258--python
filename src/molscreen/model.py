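"""Core data model: molecular graphs, compound records, sets and projects.

Molecules are carried as RDKit ``Mol`` objects (the field-standard in-memory
container); :class:`MolecularGraph` is a plain-data, hashable view of the
perceived graph used for isomorphism checks and by the pure-Python graph
oracles in the test-suite.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterator, Optional

from rdkit import Chem

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "AnnotationValue",
    "CompoundRecord",
    "CompoundSet",
    "Project",
    "AROMATICITY_MODEL",
]

#: Aromaticity perception model applied uniformly at parse time.  Recorded in
#: project metadata so that results are reproducible across versions.
AROMATICITY_MODEL = "rdkit-default"


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, formal charge (e), total attached
    hydrogens (implicit + explicit) and aromatic flag."""

    symbol: str
    charge: int = 0
    n_h: int = 0
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    """A bond between two heavy atoms; ``order`` is 1, 2 or 3 (aromatic bonds
    carry ``aromatic=True`` and order as kekulized where available)."""

    a: int
    b: int
    order: int
    aromatic: bool = False


@dataclass(frozen=True)
class MolecularGraph:
    """Immutable heavy-atom graph view of a molecule."""

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "MolecularGraph":
        atoms = tuple(
            Atom(
                symbol=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                n_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
            )
            for a in mol.GetAtoms()
        )
        bonds = []
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            aromatic = b.GetIsAromatic()
            order = {
                Chem.BondType.SINGLE: 1,
                Chem.BondType.DOUBLE: 2,
                Chem.BondType.TRIPLE: 3,
                Chem.BondType.AROMATIC: 1,
            }.get(b.GetBondType(), 1)
            bonds.append(Bond(i, j, order, aromatic))
        return cls(atoms=atoms, bonds=tuple(bonds))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbours(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a == idx:
                out.append(b.b)
            elif b.b == idx:
                out.append(b.a)
        return sorted(out)


def canonical_form(mol: Chem.Mol) -> str:
    """Canonical SMILES used as the graph-isomorphism certificate."""
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class AnnotationValue:
    """A user annotation: free text, a file link or a URL."""

    kind: str  # "text" | "file" | "url"
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("text", "file", "url"):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.kind == "url" and "://" not in self.value:
            raise ValueError(f"annotation of kind 'url' must be an absolute URL: {self.value!r}")


@dataclass
class CompoundRecord:
    """One molecule plus everything computed or recorded about it."""

    compound_id: str
    name: str
    mol: Chem.Mol
    source_format: str  # "smiles" | "sdf" | "inchi"
    source_string: str
    descriptors: Optional["DescriptorBlock"] = None  # noqa: F821 - populated lazily
    likeness: dict = field(default_factory=dict)  # ruleset name -> LikenessVerdict
    pains_hits: Optional[list] = None  # list[PainsHit]; None = not screened yet
    annotations: dict = field(default_factory=dict)  # column name -> AnnotationValue

    @property
    def graph(self) -> MolecularGraph:
        return MolecularGraph.from_mol(self.mol)

    @property
    def smiles(self) -> str:
        return canonical_form(self.mol)

    @property
    def pains_flagged(self) -> Optional[bool]:
        if self.pains_hits is None:
            return None
        return len(self.pains_hits) > 0


@dataclass
class CompoundSet:
    """An ordered, numbered list of compound records (one spreadsheet tab)."""

    set_number: int = 1
    title: str = ""
    records: list[CompoundRecord] = field(default_factory=list)
    annotation_columns: list[tuple[str, str]] = field(default_factory=list)  # (name, kind)

    def __post_init__(self) -> None:
        if self.set_number < 1:
            raise ValueError("set_number must be a positive integer")
        self._check_unique_ids()

    def _check_unique_ids(self) -> None:
        seen = set()
        for r in self.records:
            if r.compound_id in seen:
                raise ValueError(f"duplicate compound_id {r.compound_id!r} in set {self.set_number}")
            seen.add(r.compound_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CompoundRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def add(self, record: CompoundRecord) -> None:
        if record.compound_id in set(self.ids()):
            raise ValueError(f"duplicate compound_id {record.compound_id!r}")
        for key in record.annotations:
            if key not in {n for n, _ in self.annotation_columns}:
                raise ValueError(f"annotation {key!r} has no registered column")
        self.records.append(record)

    def column_names(self) -> list[str]:
        return [n for n, _ in self.annotation_columns]


@dataclass
class Project:
    """All compound sets of one session, with creation metadata."""

    sets: list[CompoundSet] = field(default_factory=list)
    created: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())
    metadata: dict = field(default_factory=lambda: {"aromaticity_model": AROMATICITY_MODEL})

    def add_set(self, cset: CompoundSet) -> None:
        numbers = [s.set_number for s in self.sets]
        if cset.set_number in numbers:
            raise ValueError(f"set number {cset.set_number} already used")
        if numbers and cset.set_number <= max(numbers):
            raise ValueError("set numbers must be strictly increasing in creation order")
        self.sets.append(cset)

    def next_set_number(self) -> int:
        return max((s.set_number for s in self.sets), default=0) + 1
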