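"""Structural descriptors computed from the heavy-atom molecular graph.

Implements the topological diameter (TD) and the count-based subset of the
drug-like descriptor panel used for binding-score modelling.  Descriptors
that require fragment-contribution or surface models (TotalSurfaceArea, PSA,
RelativePSA, cLogP, cLogS, drug-likeness, QPpolrz, StereoCenters,
SymmetricAtoms) are *consumed as input columns*, never computed here.

Counting rule table (frozen; all tests are relative to these rules):

==================== =======================================================
Descriptor           Rule
==================== =======================================================
TD                   longest shortest path between heavy atoms, in bond
                     steps; maximum over dot-separated components
NonHAtoms            number of heavy atoms
NonCHAtoms           heavy atoms that are not carbon
ElectronegativeAtoms N, O, F, P, S, Cl, Br, I
HAcceptors           all N and O atoms (simple Lipinski-style rule)
HDonors              N or O bearing at least one hydrogen
RotatableBonds       non-ring single bonds between two non-terminal heavy
                     atoms, excluding amide C–N
RingClosures         cyclomatic ring count (SSSR size)
SmallRings           SSSR rings with ≤ 7 atoms
AromaticRings        SSSR rings whose atoms are all aromatic
AromaticAtoms        atoms flagged aromatic
Sp3Atoms             non-aromatic C/N/O/S atoms with only single bonds
Amines               N with only single bonds to C/H, not amide N
Amides               C(=O)N motifs (counted per carbonyl–N pair)
AromaticNitrogens    aromatic-flagged N
BasicNitrogens       non-amide, non-aromatic N, single bonds only, with
                     ≥ 1 H or only-carbon heavy neighbours
AcidicOxygens        O–H where the O is bonded to a C, S or P that carries
                     a double-bonded O
MolWeight            sum of standard atomic masses incl. implicit H (g/mol)
==================== =======================================================
"""

from __future__ import annotations

from collections import deque

import networkx as nx

from .smiles_graph import AROMATIC, MolecularGraph

# Standard atomic masses (g/mol), CIAAW conventional values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.086,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.453,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.904,
}

ELECTRONEGATIVE = {"N", "O", "F", "P", "S", "Cl", "Br", "I"}

#: names of the count descriptors produced by :func:`count_descriptors`
COUNT_DESCRIPTOR_NAMES = (
    "NonHAtoms",
    "NonCHAtoms",
    "ElectronegativeAtoms",
    "HAcceptors",
    "HDonors",
    "RotatableBonds",
    "RingClosures",
    "SmallRings",
    "AromaticRings",
    "AromaticAtoms",
    "Sp3Atoms",
    "Amines",
    "Amides",
    "AromaticNitrogens",
    "BasicNitrogens",
    "AcidicOxygens",
)


def _to_networkx(g: MolecularGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_atoms))
    G.add_edges_from((a, b) for a, b, _ in g.bonds)
    return G


def topological_diameter(g: MolecularGraph) -> int:
    """Longest shortest path between heavy atoms, in bond steps.

    For multi-component inputs the maximum over components is returned.
    """
    if g.n_atoms == 0:
        raise ValueError("topological diameter of an empty graph is undefined")
    adj = g.adjacency()
    best = 0
    for start in range(g.n_atoms):
        dist = {start: 0}
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        best = max(best, max(dist.values()))
    return best


def molecular_weight(g: MolecularGraph) -> float:
    """Molecular weight (g/mol) including implicit/explicit hydrogens."""
    total = 0.0
    for atom in g.atoms:
        mass = ATOMIC_MASSES.get(atom.element)
        if mass is None:
            raise ValueError(f"no atomic mass for element {atom.element!r}")
        total += mass + atom.h_count * ATOMIC_MASSES["H"]
    return total


def _ring_info(g: MolecularGraph):
    """SSSR-style rings (minimum cycle basis) and the set of ring bonds."""
    G = _to_networkx(g)
    rings = nx.minimum_cycle_basis(G) if g.n_bonds else []
    bridges = set()
    for a, b in nx.bridges(G):
        bridges.add((min(a, b), max(a, b)))
    ring_bonds = {
        (min(a, b), max(a, b))
        for a, b, _ in g.bonds
        if (min(a, b), max(a, b)) not in bridges
    }
    return rings, ring_bonds


def _amide_pairs(g: MolecularGraph) -> set[tuple[int, int]]:
    """(carbonyl C, N) pairs of C(=O)N motifs."""
    pairs = set()
    for c in range(g.n_atoms):
        if g.atoms[c].element != "C" or g.atoms[c].aromatic:
            continue
        nbrs = g.neighbors(c)
        has_carbonyl_o = any(
            g.atoms[j].element == "O" and order == 2.0 for j, order in nbrs
        )
        if not has_carbonyl_o:
            continue
        for j, order in nbrs:
            if g.atoms[j].element == "N" and order == 1.0:
                pairs.add((c, j))
    return pairs


def count_descriptors(g: MolecularGraph) -> dict[str, int]:
    """Count-based drug-like descriptors under the frozen rule table."""
    atoms = g.atoms
    degree = [0] * g.n_atoms
    for a, b, _ in g.bonds:
        degree[a] += 1
        degree[b] += 1

    rings, ring_bonds = _ring_info(g)
    amides = _amide_pairs(g)
    amide_nitrogens = {n for _, n in amides}

    def only_single_bonds(i: int) -> bool:
        return all(order == 1.0 for _, order in g.neighbors(i))

    non_h = g.n_atoms
    non_ch = sum(1 for a in atoms if a.element != "C")
    electroneg = sum(1 for a in atoms if a.element in ELECTRONEGATIVE)
    h_acc = sum(1 for a in atoms if a.element in ("N", "O"))
    h_don = sum(1 for a in atoms if a.element in ("N", "O") and a.h_count >= 1)
    arom_atoms = sum(1 for a in atoms if a.aromatic)
    arom_n = sum(1 for a in atoms if a.aromatic and a.element == "N")

    rotatable = 0
    for a, b, order in g.bonds:
        key = (min(a, b), max(a, b))
        if order != 1.0 or key in ring_bonds:
            continue
        if degree[a] <= 1 or degree[b] <= 1:
            continue
        if (a, b) in amides or (b, a) in amides:
            continue
        rotatable += 1

    sp3 = sum(
        1
        for i, a in enumerate(atoms)
        if a.element in ("C", "N", "O", "S")
        and not a.aromatic
        and only_single_bonds(i)
    )

    amines = 0
    basic_n = 0
    for i, a in enumerate(atoms):
        if a.element != "N" or a.aromatic or i in amide_nitrogens:
            continue
        if not only_single_bonds(i):
            continue
        heavy_nbrs = [j for j, _ in g.neighbors(i)]
        if all(atoms[j].element == "C" for j in heavy_nbrs):
            amines += 1
            if a.h_count >= 1 or heavy_nbrs:
                basic_n += 1
        elif a.h_count >= 1:
            basic_n += 1

    acidic_o = 0
    for i, a in enumerate(atoms):
        if a.element != "O" or a.h_count < 1:
            continue
        for j, order in g.neighbors(i):
            if order != 1.0 or atoms[j].element not in ("C", "S", "P"):
                continue
            if any(
                atoms[k].element == "O" and o2 == 2.0 for k, o2 in g.neighbors(j)
            ):
                acidic_o += 1
                break

    small_rings = sum(1 for r in rings if len(r) <= 7)
    aromatic_rings = sum(
        1 for r in rings if r and all(atoms[i].aromatic for i in r)
    )

    return {
        "NonHAtoms": non_h,
        "NonCHAtoms": non_ch,
        "ElectronegativeAtoms": electroneg,
        "HAcceptors": h_acc,
        "HDonors": h_don,
        "RotatableBonds": rotatable,
        "RingClosures": len(rings),
        "SmallRings": small_rings,
        "AromaticRings": aromatic_rings,
        "AromaticAtoms": arom_atoms,
        "Sp3Atoms": sp3,
        "Amines": amines,
        "Amides": len(amides),
        "AromaticNitrogens": arom_n,
        "BasicNitrogens": basic_n,
        "AcidicOxygens": acidic_o,
    }


def descriptor_vector(g: MolecularGraph) -> dict[str, float]:
    """All computed descriptors: counts plus TD and MolWeight."""
    out: dict[str, float] = dict(count_descriptors(g))
    out["TD"] = topological_diameter(g)
    out["MolWeight"] = molecular_weight(g)
    return out
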