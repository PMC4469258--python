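"""Readers and writers for the three supported formats: SMILES line files,
SDF (V2000 connection tables) and standard InChI strings.

All parsing goes through RDKit; aromaticity perception is therefore the
single model recorded in :data:`molscreen.model.AROMATICITY_MODEL`.  Parsing
is pure — identical inputs give identical records.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional, Union

from rdkit import Chem, rdBase
from rdkit.Chem import inchi as _inchi

from .model import AnnotationValue, CompoundRecord, CompoundSet

log = logging.getLogger("molscreen.io")

__all__ = [
    "ParseError",
    "parse_smiles",
    "read_smiles_file",
    "read_sdf",
    "parse_inchi",
    "write_set",
]


class ParseError(ValueError):
    """Raised for malformed chemical input.

    ``position`` is the offending token position within the string when the
    underlying parser reports one; ``line_number`` the 1-based source line
    for file input.
    """

    def __init__(self, message: str, position: Optional[int] = None,
                 line_number: Optional[int] = None):
        self.position = position
        self.line_number = line_number
        where = []
        if line_number is not None:
            where.append(f"line {line_number}")
        if position is not None:
            where.append(f"position {position}")
        suffix = f" ({', '.join(where)})" if where else ""
        super().__init__(message + suffix)


def _mol_from_smiles_checked(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising ParseError with the token position on failure."""
    with rdBase.BlockLogs():
        mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        return mol
    # recover the failing position by probing prefixes: the shortest prefix
    # that can no longer be extended to a valid SMILES marks the bad token
    position = None
    for i in range(1, len(smiles) + 1):
        with rdBase.BlockLogs():
            ok = Chem.MolFromSmiles(smiles[:i], sanitize=False)
        if ok is None:
            position = i
            break
    if position is None:
        position = len(smiles)  # structurally incomplete (e.g. unclosed branch)
    raise ParseError(f"malformed SMILES {smiles!r}", position=position)


def parse_smiles(line: str, auto_name: str = "CMPD1") -> CompoundRecord:
    """Parse one ``SMILES [name]`` line into a compound record.

    The name is everything after the first run of whitespace, verbatim;
    unnamed molecules get ``auto_name``.
    """
    if not line or not line.strip():
        raise ParseError("empty SMILES line")
    parts = line.strip().split(None, 1)
    smiles = parts[0]
    name = parts[1].strip() if len(parts) > 1 else auto_name
    mol = _mol_from_smiles_checked(smiles)
    return CompoundRecord(
        compound_id=auto_name,
        name=name,
        mol=mol,
        source_format="smiles",
        source_string=line.strip(),
    )


def read_smiles_file(path: Union[str, Path], strict: bool = False,
                     set_number: int = 1, title: str = "") -> CompoundSet:
    """Read a SMILES line file (one molecule per line; blank lines and lines
    starting with ``#`` are skipped).

    In lenient mode (default) malformed lines are logged with their line
    number and skipped; ``strict=True`` aborts on the first failure.
    """
    path = Path(path)
    cset = CompoundSet(set_number=set_number, title=title or path.name)
    n_errors = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rec = parse_smiles(line, auto_name=f"CMPD{len(cset) + 1}")
            except ParseError as exc:
                if strict:
                    raise ParseError(str(exc), position=exc.position,
                                     line_number=lineno) from exc
                n_errors += 1
                log.warning("%s: skipped line %d: %s", path.name, lineno, exc)
                continue
            cset.add(rec)
    if len(cset) == 0:
        log.warning("%s: no molecules read", path.name)
    if n_errors:
        log.warning("%s: %d line(s) failed to parse", path.name, n_errors)
    return cset


_SD_TAG_RE = re.compile(r"^>\s+<([^>]+)>")


def read_sdf(path: Union[str, Path], strict: bool = False,
             set_number: int = 1, title: str = "") -> CompoundSet:
    """Read an SDF of V2000 connection tables delimited by ``$$$$``.

    SD data fields (``> <TAG>`` blocks) become text annotation columns; the
    molecule title line supplies the name.  V3000 records are rejected.
    """
    path = Path(path)
    text = Path(path).read_text()
    if text.strip() == "":
        log.warning("%s: empty SDF", path.name)
        return CompoundSet(set_number=set_number, title=title or path.name)

    blocks = re.split(r"^\$\$\$\$\s*$", text, flags=re.M)
    trailing = blocks[-1]
    if trailing.strip():
        log.warning("%s: final record not terminated by $$$$; accepted", path.name)
    else:
        blocks = blocks[:-1]
    blocks = [b for b in blocks if b.strip()]

    cset = CompoundSet(set_number=set_number, title=title or path.name)
    columns: list[str] = []
    for ordinal, block in enumerate(blocks, start=1):
        lines = block.lstrip("\n").split("\n")
        if "V3000" in "".join(lines[:4]):
            raise ParseError(
                f"record {ordinal}: V3000 connection tables are not supported "
                "(V2000 only)")
        try:
            end = next(i for i, ln in enumerate(lines) if ln.startswith("M  END"))
        except StopIteration:
            raise ParseError(f"truncated SDF record {ordinal}: missing 'M  END'")
        molblock = "\n".join(lines[: end + 1]) + "\n"
        with rdBase.BlockLogs():
            mol = Chem.MolFromMolBlock(molblock)
        if mol is None:
            if strict:
                raise ParseError(f"unparsable SDF record {ordinal}")
            log.warning("%s: skipped unparsable record %d", path.name, ordinal)
            continue
        name = lines[0].strip() or f"CMPD{len(cset) + 1}"
        rec = CompoundRecord(
            compound_id=f"CMPD{len(cset) + 1}",
            name=name,
            mol=mol,
            source_format="sdf",
            source_string=molblock,
        )
        # SD data fields after M END
        i = end + 1
        while i < len(lines):
            m = _SD_TAG_RE.match(lines[i])
            if m:
                tag = m.group(1)
                vals = []
                i += 1
                while i < len(lines) and lines[i].strip() != "":
                    vals.append(lines[i])
                    i += 1
                if tag not in columns:
                    columns.append(tag)
                rec.annotations[tag] = AnnotationValue("text", "\n".join(vals))
            i += 1
        cset.annotation_columns = [(c, "text") for c in columns]
        cset.records.append(rec)
    cset._check_unique_ids()
    return cset


def parse_inchi(string: str, auto_name: str = "CMPD1") -> CompoundRecord:
    """Parse a standard InChI string (must begin ``InChI=1S/``)."""
    if not string.startswith("InChI=1S/"):
        raise ParseError(f"not a standard InChI (must start 'InChI=1S/'): {string[:30]!r}")
    with rdBase.BlockLogs():
        mol = _inchi.MolFromInchi(string)
    if mol is None:
        raise ParseError(f"unparsable InChI {string!r}")
    return CompoundRecord(
        compound_id=auto_name,
        name=auto_name,
        mol=mol,
        source_format="inchi",
        source_string=string,
    )


def write_set(cset: CompoundSet, fmt: str, path: Union[str, Path]) -> Path:
    """Write a compound set as a SMILES line file or an SDF.

    SDF output carries annotation values as SD tags.  Round trip guarantee:
    re-parsing the output reproduces isomorphic graphs.
    """
    path = Path(path)
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unsupported output format {fmt!r} (smiles or sdf)")
    if len(cset) == 0:
        log.warning("writing empty set %d to %s", cset.set_number, path)
        path.write_text("")
        return path
    if fmt == "smiles":
        with open(path, "w") as fh:
            for rec in cset:
                fh.write(f"{rec.smiles} {rec.name}\n")
    else:
        writer = Chem.SDWriter(str(path))
        try:
            for rec in cset:
                mol = Chem.Mol(rec.mol)
                mol.SetProp("_Name", rec.name)
                for key, val in rec.annotations.items():
                    mol.SetProp(key, val.value)
                writer.write(mol)
        finally:
            writer.close()
    return path
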