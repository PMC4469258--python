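"""Tabular presentation of compound sets (ASCII, CSV, HTML, minimal PDF)
plus versioned JSON project persistence.

Column order is fixed and documented: id, name, SMILES, the ten descriptor
fields, one pass/violations column per likeness rule set, the interference
flag, then user annotation columns in registration order.  Output filenames
embed the two-digit set number (``set<NN>.<ext>``).  Rendering never
mutates the set.

The PDF writer is a deliberately minimal, dependency-free table renderer
(monospaced text, no structure depictions).
"""

from __future__ import annotations

import csv
import html as _html
import json
import logging
from pathlib import Path
from typing import Union

from rdkit import Chem

from .descriptors import DescriptorBlock
from .likeness import LikenessVerdict, Rule, RuleSet
from .model import AnnotationValue, CompoundRecord, CompoundSet, Project
from .pains import PainsHit

log = logging.getLogger("molscreen.report")

__all__ = [
    "add_annotation_column",
    "render",
    "save_project",
    "load_project",
    "PROJECT_FORMAT_VERSION",
]

PROJECT_FORMAT_VERSION = 1

_RESERVED = {"id", "name", "smiles", "pains"} | set(DescriptorBlock.field_names())


def add_annotation_column(cset: CompoundSet, name: str, kind: str) -> CompoundSet:
    """Register a new annotation column of kind text, file or url."""
    if kind not in ("text", "file", "url"):
        raise ValueError(f"unknown annotation kind {kind!r}")
    if name in _RESERVED:
        raise ValueError(f"column name {name!r} is reserved")
    if name in cset.column_names():
        raise ValueError(f"column {name!r} already exists")
    cset.annotation_columns.append((name, kind))
    return cset


# ---------------------------------------------------------------------------
# rendering

def _table(cset: CompoundSet) -> tuple[list[str], list[list[str]]]:
    ruleset_names: list[str] = []
    for rec in cset:
        for rs in rec.likeness:
            if rs not in ruleset_names:
                ruleset_names.append(rs)
    header = (["id", "name", "smiles"] + DescriptorBlock.field_names()
              + ruleset_names + ["pains"] + cset.column_names())
    rows = []
    for rec in cset:
        row = [rec.compound_id, rec.name, rec.smiles]
        if rec.descriptors:
            d = rec.descriptors
            for fname in DescriptorBlock.field_names():
                v = getattr(d, fname)
                row.append(f"{v:.2f}" if isinstance(v, float) else str(v))
        else:
            row.extend([""] * len(DescriptorBlock.field_names()))
        for rs in ruleset_names:
            verdict = rec.likeness.get(rs)
            row.append("" if verdict is None else
                       f"{'pass' if verdict.passed else 'FAIL'}({verdict.violations})")
        flag = rec.pains_flagged
        row.append("" if flag is None else ("yes" if flag else "no"))
        for col in cset.column_names():
            ann = rec.annotations.get(col)
            row.append("" if ann is None else ann.value)
        rows.append(row)
    return header, rows


def _render_ascii(header, rows) -> str:
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines = [fmt.format(*header)]
    lines.append("  ".join("-" * w for w in widths))
    lines.extend(fmt.format(*r) for r in rows)
    return "\n".join(lines) + "\n"


def _render_csv(header, rows, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)  # RFC 4180 quoting
        writer.writerow(header)
        writer.writerows(rows)


def _render_html(cset: CompoundSet, header, rows) -> str:
    kinds = dict(cset.annotation_columns)
    out = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
           f"<title>Compound set {cset.set_number}: {_html.escape(cset.title)}</title>",
           "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
           "padding:2px 6px;font:12px monospace}</style></head><body>",
           f"<h1>Set {cset.set_number}: {_html.escape(cset.title)}</h1>",
           "<table><tr>" + "".join(f"<th>{_html.escape(h)}</th>" for h in header) + "</tr>"]
    for row in rows:
        cells = []
        for name, cell in zip(header, row):
            kind = kinds.get(name, "text")
            if cell and kind in ("url", "file"):
                href = cell if kind == "url" else f"file://{cell}"
                cells.append(f"<td><a href='{_html.escape(href, quote=True)}'>"
                             f"{_html.escape(cell)}</a></td>")
            else:
                cells.append(f"<td>{_html.escape(cell)}</td>")
        out.append("<tr>" + "".join(cells) + "</tr>")
    out.append("</table></body></html>")
    return "\n".join(out)


def _pdf_escape(s: str) -> str:
    return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


def _render_pdf(header, rows) -> bytes:
    """A minimal multi-page PDF: the ASCII table in 8-pt Courier."""
    text_lines = _render_ascii(header, rows).rstrip("\n").split("\n")
    lines_per_page = 66
    pages_text = [text_lines[i:i + lines_per_page]
                  for i in range(0, len(text_lines), lines_per_page)] or [[]]

    objects: list[bytes] = []

    def add(obj: bytes) -> int:
        objects.append(obj)
        return len(objects)

    font = add(b"<< /Type /Font /Subtype /Type1 /BaseFont /Courier >>")
    page_ids = []
    content_ids = []
    pages_id_placeholder = len(objects) + 2 * len(pages_text) + 1
    for pg in pages_text:
        stream = ["BT /F1 8 Tf 24 816 Td 12 TL"]
        for ln in pg:
            stream.append(f"({_pdf_escape(ln)}) Tj T*")
        stream.append("ET")
        data = "\n".join(stream).encode("latin-1", errors="replace")
        cid = add(b"<< /Length " + str(len(data)).encode() + b" >>\nstream\n"
                  + data + b"\nendstream")
        pid = add(f"<< /Type /Page /Parent {pages_id_placeholder} 0 R "
                  f"/MediaBox [0 0 595 842] /Contents {cid} 0 R "
                  f"/Resources << /Font << /F1 {font} 0 R >> >> >>".encode())
        content_ids.append(cid)
        page_ids.append(pid)
    kids = " ".join(f"{p} 0 R" for p in page_ids)
    pages = add(f"<< /Type /Pages /Kids [{kids}] /Count {len(page_ids)} >>".encode())
    assert pages == pages_id_placeholder
    catalog = add(f"<< /Type /Catalog /Pages {pages} 0 R >>".encode())

    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, obj in enumerate(objects, start=1):
        offsets.append(len(out))
        out += f"{i} 0 obj\n".encode() + obj + b"\nendobj\n"
    xref_at = len(out)
    out += f"xref\n0 {len(objects) + 1}\n".encode()
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += f"{off:010d} 00000 n \n".encode()
    out += (f"trailer\n<< /Size {len(objects) + 1} /Root {catalog} 0 R >>\n"
            f"startxref\n{xref_at}\n%%EOF\n").encode()
    return bytes(out)


def render(cset: CompoundSet, fmt: str, out_dir: Union[str, Path]) -> Path:
    """Write the set as ``set<NN>.<ext>`` into ``out_dir`` and return the path."""
    if fmt not in ("ascii", "csv", "html", "pdf"):
        raise ValueError(f"unknown render format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"ascii": "txt", "csv": "csv", "html": "html", "pdf": "pdf"}[fmt]
    path = out_dir / f"set{cset.set_number:02d}.{ext}"
    for name, kind in cset.annotation_columns:
        if kind == "file":
            for rec in cset:
                ann = rec.annotations.get(name)
                if ann and ann.value and not Path(ann.value).exists():
                    log.warning("%s: file annotation %r does not exist",
                                rec.compound_id, ann.value)
    header, rows = _table(cset)
    if fmt == "csv":
        _render_csv(header, rows, path)
    elif fmt == "ascii":
        path.write_text(_render_ascii(header, rows))
    elif fmt == "html":
        path.write_text(_render_html(cset, header, rows))
    else:
        path.write_bytes(_render_pdf(header, rows))
    return path


# ---------------------------------------------------------------------------
# project persistence

def _verdict_to_json(v: LikenessVerdict) -> dict:
    return {
        "ruleset_name": v.ruleset_name,
        "violations": v.violations,
        "passed": v.passed,
        "per_rule": [
            {"descriptor": r.descriptor, "comparator": r.comparator,
             "bound": r.bound, "observed": obs, "passed": ok}
            for r, obs, ok in v.per_rule
        ],
    }


def _verdict_from_json(doc: dict) -> LikenessVerdict:
    per_rule = tuple(
        (Rule(e["descriptor"], e["comparator"], e["bound"]), e["observed"], e["passed"])
        for e in doc["per_rule"])
    return LikenessVerdict(ruleset_name=doc["ruleset_name"], per_rule=per_rule,
                           violations=doc["violations"], passed=doc["passed"])


def save_project(project: Project, path: Union[str, Path]) -> Path:
    path = Path(path)
    doc = {
        "format_version": PROJECT_FORMAT_VERSION,
        "created": project.created,
        "metadata": project.metadata,
        "sets": [],
    }
    for cset in project.sets:
        sdoc = {
            "set_number": cset.set_number,
            "title": cset.title,
            "annotation_columns": [list(c) for c in cset.annotation_columns],
            "records": [],
        }
        for rec in cset:
            rdoc = {
                "compound_id": rec.compound_id,
                "name": rec.name,
                "smiles": rec.smiles,
                "source_format": rec.source_format,
                "source_string": rec.source_string,
                "annotations": {k: {"kind": v.kind, "value": v.value}
                                for k, v in rec.annotations.items()},
                "descriptors": rec.descriptors.as_dict() if rec.descriptors else None,
                "likeness": {k: _verdict_to_json(v) for k, v in rec.likeness.items()},
                "pains_hits": None if rec.pains_hits is None else [
                    {"filter_id": h.filter_id, "matched_atoms": list(h.matched_atoms)}
                    for h in rec.pains_hits],
            }
            sdoc["records"].append(rdoc)
        doc["sets"].append(sdoc)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_project(path: Union[str, Path]) -> Project:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path.name}: not a valid project file: {exc}")
    version = doc.get("format_version")
    if version != PROJECT_FORMAT_VERSION:
        raise ValueError(f"project format version {version} not supported "
                         f"(this build reads version {PROJECT_FORMAT_VERSION})")
    project = Project(created=doc["created"], metadata=doc["metadata"], sets=[])
    for sdoc in doc["sets"]:
        cset = CompoundSet(set_number=sdoc["set_number"], title=sdoc["title"])
        cset.annotation_columns = [tuple(c) for c in sdoc["annotation_columns"]]
        for rdoc in sdoc["records"]:
            mol = Chem.MolFromSmiles(rdoc["smiles"])
            if mol is None:
                raise ValueError(f"{path.name}: record {rdoc['compound_id']} "
                                 "has an unparsable structure")
            rec = CompoundRecord(
                compound_id=rdoc["compound_id"],
                name=rdoc["name"],
                mol=mol,
                source_format=rdoc["source_format"],
                source_string=rdoc["source_string"],
            )
            rec.annotations = {k: AnnotationValue(v["kind"], v["value"])
                               for k, v in rdoc["annotations"].items()}
            if rdoc["descriptors"]:
                rec.descriptors = DescriptorBlock(**rdoc["descriptors"])
            rec.likeness = {k: _verdict_from_json(v)
                            for k, v in rdoc.get("likeness", {}).items()}
            if rdoc["pains_hits"] is not None:
                rec.pains_hits = [PainsHit(rec.compound_id, h["filter_id"],
                                           tuple(h["matched_atoms"]))
                                  for h in rdoc["pains_hits"]]
            cset.records.append(rec)
        cset._check_unique_ids()
        project.sets.append(cset)
    return project
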