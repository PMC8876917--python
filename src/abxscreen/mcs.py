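"""Exact maximum common substructure (MCS) search.

Finds the largest *connected* common subgraph of two molecular graphs under
strict label compatibility: atoms match when element and aromatic flag agree,
bonds when their orders agree (aromatic only matches aromatic).  Common
subgraphs are not required to be induced — a ring may map onto an open chain
of the same labels, with the ring-closing bond simply absent from the common
subgraph — which matches the usual MCS convention of cheminformatics
toolkits.  The search maximises mapped atom count, breaking ties by mapped
bond count and then by the lexicographically smallest sorted atom-pair list,
so the result is deterministic.

The overlap coefficient — MCS heavy-atom count divided by the smaller
molecule's heavy-atom count — is the scaffold-possession statistic; an
overlap strictly greater than 0.9 marks high substructure similarity.

A mismatch budget is accepted as a configuration hook but only the exact
(zero-mismatch) search is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import Molecule

__all__ = [
    "MCSResult",
    "ScaffoldMatch",
    "MCSSizeError",
    "maximum_common_substructure",
    "overlap_coefficient",
    "scaffold_screen",
]

#: Combined heavy-atom guard for the exact search.
MAX_COMBINED_ATOMS = 80

OVERLAP_THRESHOLD = 0.9


class MCSSizeError(ValueError):
    """Raised when the combined molecule size exceeds the exact-search guard."""


@dataclass(frozen=True)
class MCSResult:
    atom_pairs: tuple[tuple[int, int], ...]
    n_atoms: int
    n_bonds: int


@dataclass(frozen=True)
class ScaffoldMatch:
    scaffold_id: str
    mcs_atoms: int
    overlap_coefficient: float
    is_high_similarity: bool


def _atom_label(mol: Molecule, i: int) -> tuple[str, bool]:
    a = mol.atoms[i]
    return (a.element, a.aromatic)


def _bond_maps(mol: Molecule) -> dict[tuple[int, int], float]:
    return {(i, j): o for i, j, o in mol.bonds} | {(j, i): o for i, j, o in mol.bonds}


def maximum_common_substructure(
    a: Molecule, b: Molecule, mismatch_budget: int = 0
) -> MCSResult:
    """Exact connected MCS of ``a`` and ``b``.

    Raises :class:`MCSSizeError` when ``a.n_atoms + b.n_atoms`` exceeds the
    guard; pre-filter candidates by fingerprint similarity before calling.
    """
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("MCS requires two non-empty molecules")
    if a.n_atoms + b.n_atoms > MAX_COMBINED_ATOMS:
        raise MCSSizeError(
            f"combined size {a.n_atoms + b.n_atoms} exceeds {MAX_COMBINED_ATOMS} "
            "heavy atoms for exact MCS; pre-filter with fingerprint similarity"
        )
    if mismatch_budget != 0:
        raise NotImplementedError("only exact (zero-mismatch) MCS is implemented")

    bonds_a, bonds_b = _bond_maps(a), _bond_maps(b)
    adj_a: list[list[int]] = [[] for _ in range(a.n_atoms)]
    for i, j, _ in a.bonds:
        adj_a[i].append(j)
        adj_a[j].append(i)

    # candidate pair list, ordered rarest atom label first for fast seeding
    label_count: dict[tuple[str, bool], int] = {}
    for mol in (a, b):
        for k in range(mol.n_atoms):
            lab = _atom_label(mol, k)
            label_count[lab] = label_count.get(lab, 0) + 1
    pairs = [
        (i, j)
        for i in range(a.n_atoms)
        for j in range(b.n_atoms)
        if _atom_label(a, i) == _atom_label(b, j)
    ]
    pairs.sort(key=lambda p: (label_count[_atom_label(a, p[0])], p))
    pair_index = {p: k for k, p in enumerate(pairs)}

    # upper bound on attainable atoms from label multiset intersection
    count_a: dict[tuple[str, bool], int] = {}
    count_b: dict[tuple[str, bool], int] = {}
    for k in range(a.n_atoms):
        lab = _atom_label(a, k)
        count_a[lab] = count_a.get(lab, 0) + 1
    for k in range(b.n_atoms):
        lab = _atom_label(b, k)
        count_b[lab] = count_b.get(lab, 0) + 1
    global_bound = sum(min(v, count_b.get(k, 0)) for k, v in count_a.items())

    best: list = [(), 0, 0]  # atom_pairs sorted, n_atoms, n_bonds

    def better(n_atoms: int, n_bonds: int, mapping_sorted) -> bool:
        if n_atoms != best[1]:
            return n_atoms > best[1]
        if n_bonds != best[2]:
            return n_bonds > best[2]
        return mapping_sorted < best[0]

    def count_bonds(mapping: dict[int, int]) -> int:
        n = 0
        for i, j, o in a.bonds:
            if i in mapping and j in mapping:
                ob = bonds_b.get((mapping[i], mapping[j]))
                if ob is not None and ob == o:
                    n += 1
        return n

    def extend(mapping: dict[int, int], used_b: set[int], min_seed: int):
        mapping_sorted = tuple(sorted(mapping.items()))
        n_bonds = count_bonds(mapping)
        if better(len(mapping), n_bonds, mapping_sorted):
            best[0], best[1], best[2] = mapping_sorted, len(mapping), n_bonds
        if len(mapping) >= global_bound:
            return
        # frontier: compatible pairs adjacent (via a compatible bond) to the mapping
        frontier = []
        for i in mapping:
            for i2 in adj_a[i]:
                if i2 in mapping:
                    continue
                o = bonds_a[(i, i2)]
                lab = _atom_label(a, i2)
                for j2 in range(b.n_atoms):
                    if j2 in used_b:
                        continue
                    if _atom_label(b, j2) != lab:
                        continue
                    ob = bonds_b.get((mapping[i], j2))
                    if ob is None or ob != o:
                        continue
                    p = (i2, j2)
                    if pair_index[p] >= min_seed:
                        frontier.append(p)
        if not frontier:
            return
        frontier = sorted(set(frontier), key=lambda p: pair_index[p])
        # optimistic bound: distinct A-atoms on the frontier can all be added
        if len(mapping) + len({p[0] for p in frontier}) < best[1]:
            return
        for i2, j2 in frontier:
            mapping[i2] = j2
            used_b.add(j2)
            extend(mapping, used_b, min_seed)
            del mapping[i2]
            used_b.discard(j2)

    for k, (i, j) in enumerate(pairs):
        if best[1] >= global_bound:
            break
        extend({i: j}, {j}, k)

    return MCSResult(atom_pairs=best[0], n_atoms=best[1], n_bonds=best[2])


def overlap_coefficient(res: MCSResult, a: Molecule, b: Molecule) -> float:
    """MCS atom count over the smaller molecule's heavy-atom count."""
    return res.n_atoms / min(a.n_atoms, b.n_atoms)


def scaffold_screen(
    drug: Molecule,
    scaffolds: list[tuple[str, Molecule]],
    threshold: float = OVERLAP_THRESHOLD,
) -> list[ScaffoldMatch]:
    """One :class:`ScaffoldMatch` per core scaffold.

    A drug "contains no core scaffold" iff no match is high-similarity
    (overlap coefficient strictly above ``threshold``).
    """
    if not scaffolds:
        raise ValueError("scaffold list is empty")
    out = []
    for sid, scaffold in scaffolds:
        res = maximum_common_substructure(drug, scaffold)
        oc = overlap_coefficient(res, drug, scaffold)
        out.append(
            ScaffoldMatch(
                scaffold_id=sid,
                mcs_atoms=res.n_atoms,
                overlap_coefficient=oc,
                is_high_similarity=oc > threshold,
            )
        )
    return out
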