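"""SMILES tokenizer and heavy-atom molecular graph parser.

The tokenizer is lossless and maximal-munch (``Cl``/``Br`` before ``C``/``B``,
``%nn`` before a single ring digit); bracket-atom blocks ``[...]`` are kept as
single tokens.  Tokens feed two consumers: the correlation-weight optimal
descriptor (which treats tokens and adjacent-token pairs as attributes) and
the graph parser below.

Grammar scope: organic-subset atoms, aromatic lower-case atoms, bracket atoms
with charge and explicit hydrogens, branches, ring closures (including
``%nn``), bond orders, and dot-separated fragments.  Stereo marks (``/``,
``\\``, ``@``) are accepted and recorded as flags but carry no structural
meaning here; aromaticity is taken as written (no perception/kekulization).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class SmilesError(ValueError):
    """Raised for malformed SMILES, with a character position where known."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)
        self.position = position


#: aromatic bond order sentinel (between single and double)
AROMATIC = 1.5

ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
AROMATIC_SYMBOLS = {"b", "c", "n", "o", "p", "s"}

# Daylight default valences used to fill implicit hydrogens.
_DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

_BOND_ORDERS = {"-": 1.0, "=": 2.0, "#": 3.0, ":": AROMATIC, "/": 1.0, "\\": 1.0}

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<symbol>[A-Z][a-z]?|[a-z]|\*)(?P<stereo>@{1,2}(?:TH\d|AL\d|SP\d|TB\d\d?|OH\d\d?)?)?"
    r"(?P<hcount>H\d*)?(?P<charge>\+\d+|-\d+|\++|-+)?(?::(?P<map>\d+))?\]$"
)


@dataclass(frozen=True)
class Atom:
    element: str  # capitalized element symbol
    aromatic: bool = False
    charge: int = 0
    h_count: int = 0
    stereo: bool = False  # @/@@ seen (structurally ignored)


@dataclass
class MolecularGraph:
    """Heavy-atom graph: element/aromatic/charge/H per atom, order per bond."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for a, b, _ in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def components(self) -> list[list[int]]:
        adj = self.adjacency()
        seen = [False] * self.n_atoms
        comps = []
        for start in range(self.n_atoms):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(v)
                for w in adj[v]:
                    if not seen[w]:
                        seen[w] = True
                        stack.append(w)
            comps.append(sorted(comp))
        return comps


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into lossless, left-to-right tokens.

    Concatenating the returned tokens reproduces the input exactly.
    """
    if not smiles:
        raise SmilesError("empty SMILES string")
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise SmilesError("unclosed bracket '['", i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesError("'%' must be followed by two digits", i)
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in ("Cl", "Br"):
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch in "BCNOPSFI" or ch in AROMATIC_SYMBOLS:
            tokens.append(ch)
            i += 1
        elif ch.isdigit() or ch in "()=#-:./\\":
            tokens.append(ch)
            i += 1
        else:
            raise SmilesError(f"illegal character {ch!r}", i)
    return tokens


def _parse_bracket(token: str, position: int) -> Atom:
    m = _BRACKET_RE.match(token)
    if m is None:
        raise SmilesError(f"malformed bracket atom {token!r}", position)
    raw = m.group("symbol")
    aromatic = raw.islower() and raw != "*"
    element = raw.capitalize() if raw != "*" else "*"
    hgroup = m.group("hcount")
    if hgroup is None:
        h = 0
    elif hgroup == "H":
        h = 1
    else:
        h = int(hgroup[1:])
    cgroup = m.group("charge")
    if cgroup is None:
        charge = 0
    elif cgroup[0] in "+-" and len(cgroup) > 1 and cgroup[1:].isdigit():
        charge = int(cgroup) if cgroup[0] == "-" else int(cgroup[1:])
        if cgroup[0] == "-":
            charge = -int(cgroup[1:])
    else:
        charge = cgroup.count("+") - cgroup.count("-")
    return Atom(
        element=element,
        aromatic=aromatic,
        charge=charge,
        h_count=h,
        stereo=m.group("stereo") is not None,
    )


def _implicit_h(element: str, aromatic: bool, bond_order_sum: float) -> int:
    """Implicit hydrogen count for an organic-subset atom.

    Aromatic atoms reserve one valence unit for the delocalized system and
    count each aromatic bond as one.
    """
    valences = _DEFAULT_VALENCES.get(element)
    if valences is None:
        raise SmilesError(f"element {element!r} not in the organic subset")
    # bond_order_sum already counts aromatic bonds as 1 each
    for v in valences:
        target = v - 1 if aromatic else v
        if bond_order_sum <= target:
            return int(target - bond_order_sum)
    raise SmilesError(
        f"valence {bond_order_sum:g} impossible for organic-subset atom {element}"
    )


def parse(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Implicit hydrogens are filled by standard organic-subset valence rules;
    bracket atoms carry only their explicit hydrogens.
    """
    tokens = tokenize(smiles)
    graph = MolecularGraph()
    is_bracket: list[bool] = []

    prev: int | None = None
    pending_bond: float | None = None
    branch_stack: list[int | None] = []
    ring_open: dict[str, tuple[int, float | None, int]] = {}
    pos = 0  # character position for error reporting

    def add_atom(atom: Atom, bracket: bool) -> None:
        nonlocal prev, pending_bond
        idx = graph.n_atoms
        graph.atoms.append(atom)
        is_bracket.append(bracket)
        if prev is not None:
            order = pending_bond
            if order is None:
                order = (
                    AROMATIC
                    if graph.atoms[prev].aromatic and atom.aromatic
                    else 1.0
                )
            graph.bonds.append((prev, idx, order))
        prev = idx
        pending_bond = None

    for tok in tokens:
        if tok.startswith("["):
            add_atom(_parse_bracket(tok, pos), bracket=True)
        elif tok in ORGANIC_SUBSET:
            add_atom(Atom(element=tok), bracket=False)
        elif tok in AROMATIC_SYMBOLS:
            add_atom(Atom(element=tok.upper(), aromatic=True), bracket=False)
        elif tok in _BOND_ORDERS:
            if pending_bond is not None:
                raise SmilesError("two consecutive bond symbols", pos)
            pending_bond = _BOND_ORDERS[tok]
        elif tok == "(":
            if prev is None:
                raise SmilesError("branch before any atom", pos)
            branch_stack.append(prev)
        elif tok == ")":
            if not branch_stack:
                raise SmilesError("unmatched ')'", pos)
            prev = branch_stack.pop()
        elif tok == ".":
            prev = None
            pending_bond = None
        elif tok.isdigit() or tok.startswith("%"):
            if prev is None:
                raise SmilesError("ring closure before any atom", pos)
            key = tok.lstrip("%")
            if key in ring_open:
                other, open_order, _ = ring_open.pop(key)
                if other == prev:
                    raise SmilesError(f"ring closure {key} bonds atom to itself", pos)
                order = pending_bond if pending_bond is not None else open_order
                if order is None:
                    order = (
                        AROMATIC
                        if graph.atoms[other].aromatic and graph.atoms[prev].aromatic
                        else 1.0
                    )
                graph.bonds.append((other, prev, order))
                pending_bond = None
            else:
                ring_open[key] = (prev, pending_bond, pos)
                pending_bond = None
        else:  # pragma: no cover - tokenizer guarantees coverage
            raise SmilesError(f"unexpected token {tok!r}", pos)
        pos += len(tok)

    if branch_stack:
        raise SmilesError("unmatched '('")
    if ring_open:
        key, (_, _, where) = next(iter(ring_open.items()))
        raise SmilesError(f"unmatched ring-closure digit {key}", where)
    if pending_bond is not None:
        raise SmilesError("dangling bond symbol at end of SMILES")

    # fill implicit hydrogens on non-bracket atoms
    order_sum = [0.0] * graph.n_atoms
    for a, b, order in graph.bonds:
        contrib = 1.0 if order == AROMATIC else order
        order_sum[a] += contrib
        order_sum[b] += contrib
    for i, atom in enumerate(graph.atoms):
        if is_bracket[i]:
            continue
        h = _implicit_h(atom.element, atom.aromatic, order_sum[i])
        graph.atoms[i] = Atom(
            element=atom.element,
            aromatic=atom.aromatic,
            charge=atom.charge,
            h_count=h,
            stereo=atom.stereo,
        )
    return graph
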