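"""Fingerprint and maximum-common-subgraph similarity.

Fingerprints are hashed-path bit vectors: every simple path of up to
``depth`` bonds is written as a canonical atom/bond string and hashed to a
single bit with CRC-32 (a named, stable, non-cryptographic hash), so the
fingerprint of a graph is identical across runs and platforms.  Bit-exact
compatibility with any other toolkit's path fingerprint is not a goal; only
the metric behaviour is contracted.

The MCS search finds the maximum *connected* common subgraph by atom count
(atoms match on element; aromatic bonds match aromatic bonds, non-aromatic
bonds match on order, aromatic never matches single/double).  The search is
an exhaustive branch-and-bound over connected partial atom mappings with a
wall-clock timeout; results carry an ``exhausted`` flag that is False when
the timeout truncated the search.  Ties between equal-size subgraphs are
broken deterministically (first found in index order).
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass
from typing import Optional, Union

from rdkit import Chem

from .model import CompoundRecord, CompoundSet

log = logging.getLogger("molscreen.similarity")

__all__ = [
    "Fingerprint",
    "MCSResult",
    "SimilarityHit",
    "path_fingerprint",
    "tanimoto",
    "find_mcs",
    "mcs_tanimoto",
    "search_library",
]

ALGORITHM_TAG = "simple-path/crc32/v1"

_BOND_LABEL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length hashed-path bit vector (bits held as a Python int mask)."""

    bits: int
    nbits: int = 1024
    depth: int = 7
    algorithm_tag: str = ALGORITHM_TAG

    @property
    def popcount(self) -> int:
        return self.bits.bit_count()

    def on_bits(self) -> list[int]:
        return [i for i in range(self.nbits) if self.bits >> i & 1]

    def to_hex(self) -> str:
        return format(self.bits, f"0{self.nbits // 4}x")

    def to_vector(self):
        import numpy as np
        return np.array([(self.bits >> i) & 1 for i in range(self.nbits)],
                        dtype=float)


def _atom_label(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def _bond_label(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic():
        return ":"
    return _BOND_LABEL.get(bond.GetBondType(), "-")


def path_fingerprint(mol: Union[Chem.Mol, CompoundRecord], nbits: int = 1024,
                     depth: int = 7) -> Fingerprint:
    """Hash every simple path of 0..depth bonds into an ``nbits`` vector.

    ``nbits`` must be a power of two >= 64.  Each distinct canonical path
    string sets exactly one bit; an empty graph gives the all-zero vector.
    """
    if isinstance(mol, CompoundRecord):
        mol = mol.mol
    if nbits < 64 or nbits & (nbits - 1):
        raise ValueError("nbits must be a power of two >= 64")
    if depth < 0:
        raise ValueError("depth must be >= 0")

    atom_labels = [_atom_label(a) for a in mol.GetAtoms()]
    adj: list[list[tuple[int, str]]] = [[] for _ in range(mol.GetNumAtoms())]
    for b in mol.GetBonds():
        i, j, lab = b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_label(b)
        adj[i].append((j, lab))
        adj[j].append((i, lab))

    paths: set[str] = set()

    def walk(tokens: list[str], visited: set[int], last: int, nbonds: int) -> None:
        forward = "".join(tokens)
        backward = "".join(reversed(tokens))
        paths.add(min(forward, backward))
        if nbonds == depth:
            return
        for nxt, lab in adj[last]:
            if nxt not in visited:
                visited.add(nxt)
                tokens.extend((lab, atom_labels[nxt]))
                walk(tokens, visited, nxt, nbonds + 1)
                tokens.pop(); tokens.pop()
                visited.remove(nxt)

    for start in range(mol.GetNumAtoms()):
        walk([atom_labels[start]], {start}, start, 0)

    mask = 0
    for p in paths:
        mask |= 1 << (zlib.crc32(p.encode()) % nbits)
    return Fingerprint(bits=mask, nbits=nbits, depth=depth)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints count as identical
    (similarity 1.0, logged as degenerate)."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    union = (a.bits | b.bits).bit_count()
    if union == 0:
        log.debug("tanimoto of two empty fingerprints: defined as 1.0")
        return 1.0
    return (a.bits & b.bits).bit_count() / union


@dataclass(frozen=True)
class MCSResult:
    mapping: tuple[tuple[int, int], ...]  # (atom in A, atom in B)
    n_mcs: int
    exhausted: bool

    def __post_init__(self) -> None:
        assert self.n_mcs == len(self.mapping)


def _mol_tables(mol: Chem.Mol):
    elems = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds: dict[tuple[int, int], str] = {}
    adj: list[list[int]] = [[] for _ in elems]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        lab = _bond_label(b)
        bonds[(i, j)] = bonds[(j, i)] = lab
        adj[i].append(j)
        adj[j].append(i)
    return elems, bonds, adj


def find_mcs(mol_a: Union[Chem.Mol, CompoundRecord],
             mol_b: Union[Chem.Mol, CompoundRecord],
             timeout: float = 10.0) -> MCSResult:
    """Maximum connected common subgraph of two molecules by atom count.

    Exhaustive within ``timeout`` seconds of wall clock; on timeout the best
    mapping found so far is returned with ``exhausted=False``.
    """
    if isinstance(mol_a, CompoundRecord):
        mol_a = mol_a.mol
    if isinstance(mol_b, CompoundRecord):
        mol_b = mol_b.mol
    if mol_a.GetNumAtoms() == 0 or mol_b.GetNumAtoms() == 0:
        raise ValueError("MCS of an empty molecular graph is undefined")

    elems_a, bonds_a, adj_a = _mol_tables(mol_a)
    elems_b, bonds_b, adj_b = _mol_tables(mol_b)
    n_a, n_b = len(elems_a), len(elems_b)

    # element multiset overlap is a global upper bound
    from collections import Counter
    overlap = Counter(elems_a) & Counter(elems_b)
    global_bound = sum(overlap.values())

    best: dict = {"n": 0, "mapping": ()}
    deadline = time.monotonic() + timeout
    timed_out = False
    seen_states: set[frozenset] = set()

    def extend(fwd: dict[int, int], rev: dict[int, int], seed: int) -> None:
        nonlocal timed_out
        if timed_out or time.monotonic() > deadline:
            timed_out = True
            return
        state = frozenset(fwd.items())
        if state in seen_states:
            return
        seen_states.add(state)
        if len(fwd) > best["n"]:
            best["n"] = len(fwd)
            best["mapping"] = tuple(sorted(fwd.items()))
        bound = len(fwd) + min(n_a - len(fwd), n_b - len(fwd))
        if bound <= best["n"]:
            return
        # candidate atoms of A adjacent to the mapped core (seed-index
        # restriction removes symmetric duplicates: the seed is the lowest
        # A-index of the subgraph)
        seen_pairs = set()
        for a_mapped in fwd:
            for a_next in adj_a[a_mapped]:
                if a_next in fwd or a_next < seed:
                    continue
                for b_next in adj_b[fwd[a_mapped]]:
                    if b_next in rev or elems_b[b_next] != elems_a[a_next]:
                        continue
                    if bonds_a[(a_mapped, a_next)] != bonds_b[(fwd[a_mapped], b_next)]:
                        continue
                    if (a_next, b_next) in seen_pairs:
                        continue
                    seen_pairs.add((a_next, b_next))
                    fwd[a_next] = b_next
                    rev[b_next] = a_next
                    extend(fwd, rev, seed)
                    del fwd[a_next]
                    del rev[b_next]

    for a0 in range(n_a):
        if best["n"] >= global_bound or timed_out:
            break
        for b0 in range(n_b):
            if elems_a[a0] != elems_b[b0]:
                continue
            extend({a0: b0}, {b0: a0}, a0)
            if best["n"] >= global_bound or timed_out:
                break

    return MCSResult(mapping=best["mapping"], n_mcs=best["n"],
                     exhausted=not timed_out)


def mcs_tanimoto(mol_a, mol_b, timeout: float = 10.0,
                 with_status: bool = False):
    """MCS Tanimoto over heavy-atom counts: n_mcs / (n_a + n_b - n_mcs)."""
    if isinstance(mol_a, CompoundRecord):
        mol_a = mol_a.mol
    if isinstance(mol_b, CompoundRecord):
        mol_b = mol_b.mol
    res = find_mcs(mol_a, mol_b, timeout=timeout)
    n_a, n_b = mol_a.GetNumAtoms(), mol_b.GetNumAtoms()
    score = res.n_mcs / (n_a + n_b - res.n_mcs)
    return (score, res.exhausted) if with_status else score


@dataclass(frozen=True)
class SimilarityHit:
    compound_id: str
    score: float
    metric: str  # "fingerprint" | "mcs"


def search_library(query: CompoundRecord, library: CompoundSet,
                   metric: str = "fingerprint", threshold: float = 0.0,
                   top_k: Optional[int] = None, nbits: int = 1024,
                   depth: int = 7, prescreen_margin: float = 0.2,
                   mcs_timeout: float = 10.0) -> list[SimilarityHit]:
    """Rank library members by similarity to the query.

    With ``metric="mcs"`` the fingerprint Tanimoto is used as a pre-screen
    at ``threshold - prescreen_margin`` before the (much costlier) MCS score
    — the fingerprint bound is heuristic, so the margin is configurable.
    Hits are sorted by descending score, ties broken by library order.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if metric not in ("fingerprint", "mcs"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(library) == 0:
        log.warning("similarity search against an empty library")
        return []
    qfp = path_fingerprint(query.mol, nbits=nbits, depth=depth)
    hits: list[SimilarityHit] = []
    for rec in library:
        fp_score = tanimoto(qfp, path_fingerprint(rec.mol, nbits=nbits, depth=depth))
        if metric == "fingerprint":
            score = fp_score
        else:
            if fp_score < threshold - prescreen_margin:
                continue
            score = mcs_tanimoto(query.mol, rec.mol, timeout=mcs_timeout)
        if score >= threshold:
            hits.append(SimilarityHit(rec.compound_id, score, metric))
    hits.sort(key=lambda h: -h.score)  # stable: ties keep library order
    return hits[:top_k] if top_k is not None else hits
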