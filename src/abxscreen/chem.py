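"""Molecular graphs from a SMILES subset.

The pipeline operates at the constitutional level: atoms of the organic
subset (B, C, N, O, P, S and the halogens), aromatic lowercase atoms,
bracket atoms with explicit charge and hydrogen counts, branches, ring
closures and dot-separated fragments.  Stereochemistry markers are accepted
and discarded, isotopes are rejected.  Implicit hydrogens are assigned from
default valences (B 3; C 4; N 3; O 2; P 3/5; S 2/4/6; halogens 1); bracket
atoms carry only the hydrogen count written in the bracket.

Multi-fragment inputs (salts) are reduced to the largest fragment by heavy
atom count, ties broken by molecular weight and then canonical key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Atom",
    "Molecule",
    "ParseError",
    "parse_smiles",
    "molecular_weight",
    "canonical_key",
    "read_smi",
    "read_sdf",
    "AROMATIC_BOND",
]

#: Bond-order sentinel for aromatic bonds (numeric so orders sort cleanly).
AROMATIC_BOND = 1.5

ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
AROMATIC_ELEMENTS = {"b", "c", "n", "o", "p", "s"}
#: Monatomic counter-ions accepted in brackets (desalted away as smaller
#: fragments); anything else outside the organic subset is a parse error.
COUNTERIONS = {"Na", "K", "Li", "Mg", "Ca", "Zn"}

# Smallest-first default valences used for implicit-hydrogen assignment.
DEFAULT_VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

# Conventional (abridged IUPAC) atomic weights, Da.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.453,
    "Br": 79.904,
    "I": 126.904,
    "Na": 22.990,
    "K": 39.098,
    "Li": 6.94,
    "Mg": 24.305,
    "Ca": 40.078,
    "Zn": 65.38,
}


class ParseError(ValueError):
    """Raised for strings outside the supported SMILES subset."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Atom:
    element: str
    aromatic: bool = False
    formal_charge: int = 0
    implicit_h: int = 0


@dataclass
class Molecule:
    """A labelled molecular graph.

    ``bonds`` holds ``(i, j, order)`` with ``i < j`` and order in
    ``{1, 2, 3, AROMATIC_BOND}``.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    source_smiles: str = ""
    _key: str | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def adjacency(self) -> list[list[tuple[float, int]]]:
        adj: list[list[tuple[float, int]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((order, j))
            adj[j].append((order, i))
        return adj

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))


# ---------------------------------------------------------------------------
# parsing


class _PendingAtom:
    __slots__ = ("element", "aromatic", "charge", "explicit_h", "bracket")

    def __init__(self, element, aromatic, charge=0, explicit_h=None, bracket=False):
        self.element = element
        self.aromatic = aromatic
        self.charge = charge
        self.explicit_h = explicit_h
        self.bracket = bracket


_BOND_ORDERS = {"-": 1.0, "=": 2.0, "#": 3.0, ":": AROMATIC_BOND, "/": 1.0, "\\": 1.0}


def _parse_bracket(s: str, start: int) -> tuple[_PendingAtom, int]:
    """Parse a bracket atom beginning at ``s[start] == '['``."""
    end = s.find("]", start)
    if end < 0:
        raise ParseError("unterminated bracket atom", start)
    body = s[start + 1 : end]
    pos = 0
    if pos < len(body) and body[pos].isdigit():
        raise ParseError(f"isotopes are not supported: '[{body}]'", start)
    # element symbol
    aromatic = False
    if pos < len(body) and body[pos] in AROMATIC_ELEMENTS and (
        pos + 1 >= len(body) or not body[pos + 1].islower()
    ):
        element = body[pos].upper()
        aromatic = True
        pos += 1
    else:
        sym2 = body[pos : pos + 2]
        if sym2 in ("Cl", "Br") or sym2 in COUNTERIONS:
            element, pos = sym2, pos + 2
        elif pos < len(body) and (body[pos] in ORGANIC_SUBSET or body[pos] in COUNTERIONS):
            element, pos = body[pos], pos + 1
        else:
            raise ParseError(f"unsupported element in bracket: '[{body}]'", start)
    # chirality markers: discarded
    while pos < len(body) and body[pos] == "@":
        pos += 1
    # explicit hydrogen count
    explicit_h = 0
    if pos < len(body) and body[pos] == "H":
        pos += 1
        num = ""
        while pos < len(body) and body[pos].isdigit():
            num += body[pos]
            pos += 1
        explicit_h = int(num) if num else 1
    # charge
    charge = 0
    if pos < len(body) and body[pos] in "+-":
        sign = 1 if body[pos] == "+" else -1
        count = 0
        while pos < len(body) and body[pos] in "+-":
            if (body[pos] == "+") != (sign > 0):
                raise ParseError(f"mixed charge signs in '[{body}]'", start)
            count += 1
            pos += 1
        num = ""
        while pos < len(body) and body[pos].isdigit():
            num += body[pos]
            pos += 1
        charge = sign * (int(num) if num else count)
    if pos != len(body):
        raise ParseError(f"unsupported token '{body[pos:]}' in bracket '[{body}]'", start)
    return _PendingAtom(element, aromatic, charge, explicit_h, bracket=True), end + 1


def _implicit_h(atom: _PendingAtom, bond_orders: list[float]) -> int:
    if atom.bracket:
        return atom.explicit_h or 0
    # aromatic bonds to O/S count as single (formally single in 5-rings)
    weight = 1.0 if atom.element in ("O", "S") else None
    total = 0.0
    for o in bond_orders:
        if o == AROMATIC_BOND:
            total += weight if weight is not None else 1.5
        else:
            total += o
    used = math.ceil(total - 1e-9)
    for v in DEFAULT_VALENCES[atom.element]:
        if v >= used:
            return v - used
    return 0


def parse_smiles(smiles: str) -> Molecule:
    """Parse ``smiles`` and return its largest connected fragment.

    Raises :class:`ParseError` for empty input, unsupported elements or
    isotopes, and unmatched ring closures or parentheses.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    s = smiles.strip()

    atoms: list[_PendingAtom] = []
    bonds: list[tuple[int, int, float]] = []
    prev: int | None = None
    pending_bond: float | None = None
    stack: list[int | None] = []
    ring: dict[int, tuple[int, float | None, int]] = {}

    def add_atom(atom: _PendingAtom, pos: int) -> None:
        nonlocal prev, pending_bond
        idx = len(atoms)
        atoms.append(atom)
        if prev is not None:
            order = pending_bond
            if order is None:
                order = AROMATIC_BOND if (atoms[prev].aromatic and atom.aromatic) else 1.0
            bonds.append((min(prev, idx), max(prev, idx), order))
        prev = idx
        pending_bond = None

    i = 0
    while i < len(s):
        c = s[i]
        if c == "[":
            atom, i2 = _parse_bracket(s, i)
            add_atom(atom, i)
            i = i2
        elif s[i : i + 2] in ("Cl", "Br"):
            add_atom(_PendingAtom(s[i : i + 2], False), i)
            i += 2
        elif c in ORGANIC_SUBSET:
            add_atom(_PendingAtom(c, False), i)
            i += 1
        elif c in AROMATIC_ELEMENTS:
            add_atom(_PendingAtom(c.upper(), True), i)
            i += 1
        elif c in _BOND_ORDERS:
            if pending_bond is not None:
                raise ParseError("consecutive bond symbols", i)
            pending_bond = _BOND_ORDERS[c]
            i += 1
        elif c == "(":
            if prev is None:
                raise ParseError("branch with no preceding atom", i)
            stack.append(prev)
            i += 1
        elif c == ")":
            if not stack:
                raise ParseError("unmatched closing parenthesis", i)
            prev = stack.pop()
            i += 1
        elif c == ".":
            prev = None
            pending_bond = None
            i += 1
        elif c.isdigit() or c == "%":
            if c == "%":
                if i + 2 >= len(s) or not s[i + 1 : i + 3].isdigit():
                    raise ParseError("malformed %nn ring closure", i)
                num, i2 = int(s[i + 1 : i + 3]), i + 3
            else:
                num, i2 = int(c), i + 1
            if prev is None:
                raise ParseError("ring closure with no preceding atom", i)
            if num in ring:
                other, other_bond, _ = ring.pop(num)
                order = pending_bond if pending_bond is not None else other_bond
                if (
                    pending_bond is not None
                    and other_bond is not None
                    and pending_bond != other_bond
                ):
                    raise ParseError(f"conflicting bond orders for ring closure {num}", i)
                if order is None:
                    order = (
                        AROMATIC_BOND
                        if (atoms[prev].aromatic and atoms[other].aromatic)
                        else 1.0
                    )
                if other == prev:
                    raise ParseError(f"ring closure {num} bonds an atom to itself", i)
                bonds.append((min(prev, other), max(prev, other), order))
            else:
                ring[num] = (prev, pending_bond, i)
            pending_bond = None
            i = i2
        elif c.isspace():
            i += 1
        else:
            raise ParseError(f"unsupported token '{c}'", i)

    if pending_bond is not None:
        raise ParseError("dangling bond symbol at end of string")
    if stack:
        raise ParseError("unmatched opening parenthesis")
    if ring:
        num, (_, _, pos) = next(iter(ring.items()))
        raise ParseError(f"unmatched ring closure {num}", pos)
    if not atoms:
        raise ParseError("no atoms in SMILES string")

    # drop duplicate bonds (e.g. c1ccccc1 closing a bond written twice)
    seen: set[tuple[int, int]] = set()
    uniq: list[tuple[int, int, float]] = []
    for i_, j_, o_ in bonds:
        if (i_, j_) not in seen:
            seen.add((i_, j_))
            uniq.append((i_, j_, o_))
    bonds = uniq

    adj_orders: list[list[float]] = [[] for _ in atoms]
    for i_, j_, o_ in bonds:
        adj_orders[i_].append(o_)
        adj_orders[j_].append(o_)

    built = [
        Atom(a.element, a.aromatic, a.charge, _implicit_h(a, adj_orders[k]))
        for k, a in enumerate(atoms)
    ]
    mol = Molecule(built, bonds, source_smiles=smiles)
    return _largest_fragment(mol)


def _components(mol: Molecule) -> list[list[int]]:
    adj = mol.adjacency()
    seen = [False] * mol.n_atoms
    comps = []
    for start in range(mol.n_atoms):
        if seen[start]:
            continue
        comp, stack = [], [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for _, v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _subgraph(mol: Molecule, keep: list[int]) -> Molecule:
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [mol.atoms[i] for i in keep]
    bonds = [
        (remap[i], remap[j], o)
        for i, j, o in mol.bonds
        if i in remap and j in remap
    ]
    return Molecule(atoms, bonds, source_smiles=mol.source_smiles)


def _largest_fragment(mol: Molecule) -> Molecule:
    comps = _components(mol)
    if len(comps) == 1:
        return mol
    frags = [_subgraph(mol, c) for c in comps]
    return max(
        frags,
        key=lambda f: (f.n_atoms, molecular_weight(f), _neg_lex(canonical_key(f))),
    )


class _neg_lex(str):
    """Wrapper inverting string comparison, so max() picks the lexicographically
    smallest canonical key among weight ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# molecular weight


def molecular_weight(mol: Molecule) -> float:
    """Sum of conventional atomic weights over heavy atoms plus implicit H, Da."""
    if mol.n_atoms == 0:
        raise ValueError("cannot compute molecular weight of an empty molecule")
    total = 0.0
    for a in mol.atoms:
        total += ATOMIC_WEIGHTS[a.element] + a.implicit_h * ATOMIC_WEIGHTS["H"]
    return round(total, 3)


# ---------------------------------------------------------------------------
# canonical key


def _atom_invariant(a: Atom, degree: int) -> tuple:
    return (a.element, a.aromatic, a.formal_charge, a.implicit_h, degree)


def _refine(labels: list[int], adj) -> list[int]:
    """Iterative neighbourhood refinement to a stable partition."""
    n = len(labels)
    while True:
        sig = [
            (labels[i], tuple(sorted((o, labels[j]) for o, j in adj[i])))
            for i in range(n)
        ]
        ranks = {v: r for r, v in enumerate(sorted(set(sig)))}
        new = [ranks[sig[i]] for i in range(n)]
        if new == labels:
            return labels
        labels = new


def _canon_string(order_of: list[int], mol: Molecule) -> str:
    by_rank = sorted(range(mol.n_atoms), key=lambda i: order_of[i])
    pos = {atom: rank for rank, atom in enumerate(by_rank)}
    atom_part = ";".join(
        f"{a.element}{'a' if a.aromatic else ''}{a.formal_charge:+d}H{a.implicit_h}"
        for a in (mol.atoms[i] for i in by_rank)
    )
    bond_part = ",".join(
        f"{i}-{j}:{o:g}"
        for i, j, o in sorted(
            (min(pos[x], pos[y]), max(pos[x], pos[y]), o) for x, y, o in mol.bonds
        )
    )
    return atom_part + "|" + bond_part


def _canonicalize(labels: list[int], mol: Molecule, adj) -> str:
    labels = _refine(labels, adj)
    cells: dict[int, list[int]] = {}
    for i, l in enumerate(labels):
        cells.setdefault(l, []).append(i)
    target = None
    for l in sorted(cells):
        if len(cells[l]) > 1:
            target = cells[l]
            break
    if target is None:
        return _canon_string(labels, mol)
    best: str | None = None
    for atom in target:
        sig = [(labels[i], 0 if i == atom else 1) for i in range(len(labels))]
        ranks = {v: r for r, v in enumerate(sorted(set(sig)))}
        cand = _canonicalize([ranks[x] for x in sig], mol, adj)
        if best is None or cand < best:
            best = cand
    return best


def canonical_key(mol: Molecule) -> str:
    """A string invariant under atom reordering; equal keys mean identical
    labelled graphs.  Used as the structural deduplication criterion."""
    if mol._key is not None:
        return mol._key
    if mol.n_atoms == 0:
        return "|"
    adj = mol.adjacency()
    init = [_atom_invariant(a, len(adj[i])) for i, a in enumerate(mol.atoms)]
    ranks = {v: r for r, v in enumerate(sorted(set(init)))}
    key = _canonicalize([ranks[x] for x in init], mol, adj)
    mol._key = key
    return key


# ---------------------------------------------------------------------------
# readers


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file: one ``SMILES [id]`` per line.  Returns (id, smiles)
    pairs; missing ids become ``line<k>``."""
    out = []
    with open(path) as fh:
        for k, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"line{k}"
            out.append((ident, smiles))
    return out


_SDF_BOND_ORDERS = {1: 1.0, 2: 2.0, 3: 3.0, 4: AROMATIC_BOND}


def read_sdf(path) -> list[tuple[str, Molecule]]:
    """Minimal V2000 SDF reader mapped onto :class:`Molecule`.

    Reads element symbols, bond block orders (4 = aromatic) and ``M  CHG``
    lines; implicit hydrogens are assigned with the same valence model as the
    SMILES parser.  Aromatic flags follow bond order 4.
    """
    mols: list[tuple[str, Molecule]] = []
    with open(path) as fh:
        blocks = fh.read().split("$$$$")
    for block in blocks:
        lines = block.strip("\n").splitlines()
        if len(lines) < 4:
            continue
        name = lines[0].strip() or f"mol{len(mols) + 1}"
        counts = lines[3]
        try:
            n_atoms, n_bonds = int(counts[0:3]), int(counts[3:6])
        except ValueError as e:
            raise ParseError(f"bad V2000 counts line: {counts!r}") from e
        raw_atoms = []
        for ln in lines[4 : 4 + n_atoms]:
            element = ln[31:34].strip()
            if element not in ORGANIC_SUBSET:
                raise ParseError(f"unsupported element '{element}' in SDF block")
            raw_atoms.append(element)
        bonds: list[tuple[int, int, float]] = []
        for ln in lines[4 + n_atoms : 4 + n_atoms + n_bonds]:
            i, j, bo = int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])
            bonds.append((min(i, j), max(i, j), _SDF_BOND_ORDERS[bo]))
        charges = {}
        for ln in lines[4 + n_atoms + n_bonds :]:
            if ln.startswith("M  CHG"):
                fields = ln.split()
                n = int(fields[2])
                for k in range(n):
                    charges[int(fields[3 + 2 * k]) - 1] = int(fields[4 + 2 * k])
        aromatic = [False] * n_atoms
        for i, j, o in bonds:
            if o == AROMATIC_BOND:
                aromatic[i] = aromatic[j] = True
        adj_orders: list[list[float]] = [[] for _ in range(n_atoms)]
        for i, j, o in bonds:
            adj_orders[i].append(o)
            adj_orders[j].append(o)
        atoms = []
        for k, el in enumerate(raw_atoms):
            pend = _PendingAtom(el, aromatic[k], charges.get(k, 0), bracket=k in charges)
            atoms.append(
                Atom(el, aromatic[k], charges.get(k, 0), _implicit_h(pend, adj_orders[k]))
            )
        mols.append((name, _largest_fragment(Molecule(atoms, bonds, source_smiles=""))))
    return mols
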