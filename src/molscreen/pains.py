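"""Pan-assay interference (PAINS) substructure screening.

The packaged default catalogue is the public sln-to-SMARTS translation of
the original PAINS interference filters, merged from its three source
families (A/B/C) into one 480-pattern set.  The translation is known not to
reproduce the original sln rules perfectly; small cross-engine variations
are expected, which is why :func:`concordance_report` exists — it compares
the flagged sets of any two screening runs by set algebra, so users can
benchmark this engine against another one on the same library.

A compound is *flagged* when at least one filter matches; summary counts are
over flagged compounds, not matches.  Only the first embedding per filter is
reported by default (``all_embeddings=True`` enumerates them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from rdkit import Chem

from .model import CompoundSet

log = logging.getLogger("molscreen.pains")

__all__ = [
    "SmartsFilter",
    "FilterCatalogue",
    "PainsHit",
    "ScreenSummary",
    "load_catalogue",
    "default_catalogue",
    "match_compound",
    "screen_set",
    "concordance_report",
    "mcs_similarity_flag",
]


@dataclass(frozen=True)
class SmartsFilter:
    """One named substructure filter with its source-family provenance."""

    filter_id: str
    smarts: str
    family: str  # "A" | "B" | "C" (or "?" for user catalogues without provenance)

    def compile(self) -> Chem.Mol:
        # mergeHs folds the explicit [#1] atoms these patterns carry into
        # H-count constraints on the heavy atoms, as substructure engines do
        query = Chem.MolFromSmarts(self.smarts, mergeHs=True)
        if query is None:
            raise ValueError(f"filter {self.filter_id!r}: uncompilable SMARTS")
        return query


@dataclass
class FilterCatalogue:
    filters: list[SmartsFilter]
    source_label: str = ""
    version: str = ""
    _compiled: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        ids = [f.filter_id for f in self.filters]
        if len(set(ids)) != len(ids):
            raise ValueError("filter_ids must be unique")
        if not self._compiled:
            self._compiled = [f.compile() for f in self.filters]

    def __len__(self) -> int:
        return len(self.filters)

    def families(self) -> set[str]:
        return {f.family for f in self.filters}

    def compiled(self) -> list[tuple[SmartsFilter, Chem.Mol]]:
        return list(zip(self.filters, self._compiled))


@dataclass(frozen=True)
class PainsHit:
    compound_id: str
    filter_id: str
    matched_atoms: tuple[int, ...]


@dataclass
class ScreenSummary:
    n_compounds: int
    n_flagged: int
    hits_per_filter: dict[str, int]
    flagged_ids: list[str]

    def __post_init__(self) -> None:
        assert self.n_flagged == len(self.flagged_ids) <= self.n_compounds


def load_catalogue(path: Union[str, Path], strict: bool = True,
                   source_label: str = "", version: str = "") -> FilterCatalogue:
    """Read a ``pains.smt``-dialect file: one ``SMARTS filter_id [family]``
    per line, ``#`` comments allowed.

    Uncompilable patterns abort with the offending line numbers in strict
    mode; lenient mode drops them with a warning recording the count.
    """
    path = Path(path)
    filters: list[SmartsFilter] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                bad.append(lineno)
                continue
            smarts, filter_id = parts[0], parts[1]
            family = parts[2] if len(parts) > 2 else "?"
            filt = SmartsFilter(filter_id=filter_id, smarts=smarts, family=family)
            try:
                filt.compile()
            except ValueError:
                bad.append(lineno)
                continue
            filters.append(filt)
    if bad and strict:
        raise ValueError(f"{path.name}: uncompilable/malformed filter line(s): {bad}")
    if bad:
        log.warning("%s: dropped %d uncompilable filter line(s): %s",
                    path.name, len(bad), bad)
    if not filters:
        raise ValueError(f"{path.name}: no filters loaded")
    return FilterCatalogue(filters=filters,
                           source_label=source_label or path.name,
                           version=version)


@lru_cache(maxsize=1)
def default_catalogue() -> FilterCatalogue:
    """The packaged combined 480-filter catalogue (families A+B+C)."""
    ref = resources.files("molscreen.data") / "pains.smt"
    with resources.as_file(ref) as path:
        return load_catalogue(path, strict=True,
                              source_label="combined PAINS A+B+C (sln->SMARTS)",
                              version="1")


def match_compound(mol: Chem.Mol, catalogue: FilterCatalogue,
                   compound_id: str = "", all_embeddings: bool = False
                   ) -> list[PainsHit]:
    """Run every filter against one molecule.

    Returns one hit per (filter, first embedding) — or per embedding with
    ``all_embeddings`` — with matched atom indices in deterministic order.
    """
    hits: list[PainsHit] = []
    for filt, query in catalogue.compiled():
        if all_embeddings:
            for match in mol.GetSubstructMatches(query):
                hits.append(PainsHit(compound_id, filt.filter_id, tuple(match)))
        else:
            match = mol.GetSubstructMatch(query)
            if match:
                hits.append(PainsHit(compound_id, filt.filter_id, tuple(match)))
    return hits


def screen_set(cset: CompoundSet, catalogue: Optional[FilterCatalogue] = None
               ) -> ScreenSummary:
    """Screen every record (annotating it with its hits) and summarise.

    A compound counts once toward ``n_flagged`` no matter how many filters
    it matches; ``hits_per_filter`` counts compounds per filter.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    flagged: list[str] = []
    per_filter: dict[str, int] = {}
    n_ok = 0
    for rec in cset:
        try:
            rec.pains_hits = match_compound(rec.mol, catalogue,
                                            compound_id=rec.compound_id)
        except Exception as exc:
            log.warning("%s: screening failed, excluded: %s", rec.compound_id, exc)
            continue
        n_ok += 1
        if rec.pains_hits:
            flagged.append(rec.compound_id)
            for hit in {h.filter_id for h in rec.pains_hits}:
                per_filter[hit] = per_filter.get(hit, 0) + 1
    return ScreenSummary(n_compounds=n_ok, n_flagged=len(flagged),
                         hits_per_filter=per_filter, flagged_ids=flagged)


def concordance_report(a: ScreenSummary, b: ScreenSummary,
                       universe_a: Optional[set] = None,
                       universe_b: Optional[set] = None
                       ) -> tuple[int, int, int]:
    """Set algebra over two flagged sets: (matching, only_a, only_b).

    Identities: matching + only_a = a.n_flagged and matching + only_b =
    b.n_flagged.  When the compound universes of the two runs are supplied
    they must agree, since a cross-engine comparison is only meaningful over
    the same library.
    """
    if universe_a is not None and universe_b is not None and universe_a != universe_b:
        raise ValueError("screening summaries cover different compound universes")
    sa, sb = set(a.flagged_ids), set(b.flagged_ids)
    matching = len(sa & sb)
    return matching, len(sa - sb), len(sb - sa)


def mcs_similarity_flag(mol: Chem.Mol, reference: Chem.Mol,
                        threshold: float, timeout: float = 10.0
                        ) -> Optional[bool]:
    """Alternative interference criterion: flag when the maximum-common-
    subgraph Tanimoto to a known interference scaffold reaches ``threshold``.

    Returns True/False, or ``None`` when the MCS search timed out before the
    answer was certain (undetermined, deliberately distinct from False).
    """
    from .similarity import mcs_tanimoto

    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    score, exhausted = mcs_tanimoto(mol, reference, timeout=timeout,
                                    with_status=True)
    if score >= threshold:
        return True
    return False if exhausted else None
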