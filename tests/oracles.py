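"""Independent oracles used by the test-suite.

These deliberately avoid the code paths they check: structural counts are
recomputed by walking the plain-data MolecularGraph view, the MCS oracle is
RDKit's exhaustive FMCS implementation, and the clustering oracles are
brute-force enumerations.
"""

from __future__ import annotations

import itertools

from rdkit import Chem
from rdkit.Chem import rdFMCS

from molscreen.model import MolecularGraph

# IUPAC 2021 standard atomic weights (abridged) for the hand MW oracle
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


def mw_oracle(graph: MolecularGraph) -> float:
    total = 0.0
    for atom in graph.atoms:
        total += ATOMIC_MASS[atom.symbol] + atom.n_h * ATOMIC_MASS["H"]
    return total


def hbd_oracle(graph: MolecularGraph) -> int:
    return sum(a.n_h for a in graph.atoms if a.symbol in ("N", "O"))


def hba_oracle(graph: MolecularGraph) -> int:
    return sum(1 for a in graph.atoms if a.symbol in ("N", "O"))


def ring_count_oracle(graph: MolecularGraph) -> int:
    # cyclomatic number: bonds - atoms + connected components
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from((b.a, b.b) for b in graph.bonds)
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def rotatable_oracle(graph: MolecularGraph) -> int:
    """Acyclic single non-aromatic bonds, both endpoints degree >= 2,
    excluding amide C-N bonds."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from((b.a, b.b) for b in graph.bonds)
    # an edge lies on a ring iff it is not a bridge
    bridges = set(tuple(sorted(e)) for e in nx.bridges(g))
    degree = {i: g.degree(i) for i in g.nodes}

    def is_amide(b):
        for c_idx, n_idx in ((b.a, b.b), (b.b, b.a)):
            if graph.atoms[c_idx].symbol == "C" and graph.atoms[n_idx].symbol == "N":
                for other in graph.bonds:
                    if other.order == 2 and not other.aromatic:
                        pair = {other.a, other.b}
                        if c_idx in pair:
                            o_idx = (pair - {c_idx}).pop()
                            if graph.atoms[o_idx].symbol == "O":
                                return True
        return False

    count = 0
    for b in graph.bonds:
        edge = tuple(sorted((b.a, b.b)))
        if edge not in bridges:  # in a ring
            continue
        if b.order != 1 or b.aromatic:
            continue
        if degree[b.a] < 2 or degree[b.b] < 2:
            continue
        if is_amide(b):
            continue
        count += 1
    return count


def mcs_size_oracle(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Exhaustive connected MCS size by atom count via RDKit FMCS
    (atoms match on element, bonds on exact order / aromaticity)."""
    res = rdFMCS.FindMCS(
        [mol_a, mol_b],
        maximizeBonds=False,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        timeout=60,
    )
    if res.numAtoms <= 0:
        # FMCS is bond-seeded: recover the single-atom MCS by element overlap
        elems_a = {a.GetSymbol() for a in mol_a.GetAtoms()}
        elems_b = {b.GetSymbol() for b in mol_b.GetAtoms()}
        return 1 if elems_a & elems_b else 0
    return res.numAtoms


def maxmin_bruteforce(dist, n: int, k: int, seed: int) -> list[int]:
    """Greedy MaxMin recomputed naively: at each step scan all candidates,
    ties to the lowest index."""
    picked = [seed]
    while len(picked) < k:
        best, best_d = None, -1.0
        for i in range(n):
            if i in picked:
                continue
            d = min(dist(i, j) for j in picked)
            if d > best_d:
                best, best_d = i, d
        picked.append(best)
    return picked


def best_partition_objective(vecs, k: int) -> float:
    """Exhaustive minimum of the continuous-Tanimoto k-means objective over
    all assignments of n points to k clusters (n small)."""
    import numpy as np

    def cont_tani(x, c):
        num = float(x @ c)
        den = float(x @ x) + float(c @ c) - num
        return num / den if den > 0 else 1.0

    n = len(vecs)
    best = float("inf")
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        obj = 0.0
        for j in range(k):
            members = [i for i in range(n) if assign[i] == j]
            centroid = np.mean([vecs[i] for i in members], axis=0)
            obj += sum(1.0 - cont_tani(vecs[i], centroid) for i in members)
        best = min(best, obj)
    return best
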