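"""Hashed substructure fingerprints and Tanimoto similarity.

Two families are provided:

* **path** — linear-fragment fingerprints in the FP2 tradition: every simple
  path of 1..``max_path_len`` atoms is encoded as a canonical token string and
  hashed with FNV-1a-32 into an ``n_bits`` vector.  The hashing is defined
  here bit-exactly so fingerprints are reproducible run-to-run and
  platform-to-platform.
* **circular** — Morgan/ECFP-style iterative neighbourhood hashing; radius
  ``r`` corresponds to ECFP(2r).

Tanimoto similarity on two fingerprints is ``|A and B| / |A or B|`` over the
set bits; two all-zero fingerprints compare as 1.0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import AROMATIC_BOND, Molecule

__all__ = [
    "Fingerprint",
    "SimilarityProfile",
    "fnv1a_32",
    "enumerate_paths",
    "path_fingerprint",
    "circular_fingerprint",
    "tanimoto",
    "similarity_profile",
]

_FNV_OFFSET = 0x811C9DC5
_FNV_PRIME = 0x01000193


def fnv1a_32(data: str | bytes) -> int:
    """32-bit FNV-1a hash (the fingerprint's bit-assignment primitive)."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFF
    return h


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    n_bits: int
    family: str  # "path" | "circular"
    params: tuple

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        if self.bits:
            arr[sorted(self.bits)] = 1
        return arr

    def to_hex(self) -> str:
        arr = np.packbits(self.to_array())
        return arr.tobytes().hex()

    @classmethod
    def from_hex(cls, s: str, family: str, params: tuple) -> "Fingerprint":
        raw = np.frombuffer(bytes.fromhex(s), dtype=np.uint8)
        arr = np.unpackbits(raw)
        bits = frozenset(int(i) for i in np.nonzero(arr)[0])
        return cls(bits, len(arr), family, params)

    def compatible_with(self, other: "Fingerprint") -> bool:
        return (
            self.n_bits == other.n_bits
            and self.family == other.family
            and self.params == other.params
        )


@dataclass(frozen=True)
class SimilarityProfile:
    """Mean / min / max Tanimoto of a query against a reference panel."""

    mean_tc: float
    min_tc: float
    max_tc: float
    n_reference: int


# ---------------------------------------------------------------------------
# path (linear fragment) fingerprints


def _atom_token(mol: Molecule, i: int) -> str:
    a = mol.atoms[i]
    tok = a.element
    if a.aromatic:
        tok += "a"
    if a.formal_charge:
        tok += f"{a.formal_charge:+d}"
    return tok


def _bond_token(order: float) -> str:
    return "a" if order == AROMATIC_BOND else f"{int(order)}"


def enumerate_paths(mol: Molecule, max_path_len: int = 7) -> list[str]:
    """Canonical encodings of every simple path of 1..max_path_len atoms.

    Each undirected path appears exactly once, encoded as the lexicographic
    minimum of its forward and reverse token strings.  Distinct paths with
    identical encodings (e.g. in a homogeneous chain) are all listed; the
    fingerprint reduces them to a set.
    """
    if max_path_len < 1:
        raise ValueError("max_path_len must be >= 1")
    adj = mol.adjacency()
    out: list[str] = []

    def encode(path_atoms: list[int], path_bonds: list[float]) -> str:
        fwd_toks = []
        for k, atom in enumerate(path_atoms):
            if k:
                fwd_toks.append(_bond_token(path_bonds[k - 1]))
            fwd_toks.append(_atom_token(mol, atom))
        fwd = "|".join(fwd_toks)
        rev = "|".join(reversed(fwd_toks))
        return min(fwd, rev)

    def dfs(path_atoms: list[int], path_bonds: list[float], visited: set[int]):
        if len(path_atoms) >= 2:
            # emit once per undirected path: only when start < end index
            if path_atoms[0] < path_atoms[-1]:
                out.append(encode(path_atoms, path_bonds))
        if len(path_atoms) == max_path_len:
            return
        last = path_atoms[-1]
        for order, nxt in adj[last]:
            if nxt not in visited:
                visited.add(nxt)
                path_atoms.append(nxt)
                path_bonds.append(order)
                dfs(path_atoms, path_bonds, visited)
                path_atoms.pop()
                path_bonds.pop()
                visited.remove(nxt)

    for start in range(mol.n_atoms):
        out.append(_atom_token(mol, start))
        dfs([start], [], {start})
    return out


def path_fingerprint(
    mol: Molecule, max_path_len: int = 7, n_bits: int = 1024
) -> Fingerprint:
    """Linear-fragment fingerprint: FNV-1a-32 of each canonical simple-path
    encoding, folded modulo ``n_bits``."""
    if n_bits < 64 or n_bits & (n_bits - 1):
        raise ValueError("n_bits must be a power of two >= 64")
    tokens = set(enumerate_paths(mol, max_path_len))
    bits = frozenset(fnv1a_32(t) % n_bits for t in tokens)
    return Fingerprint(bits, n_bits, "path", (max_path_len,))


# ---------------------------------------------------------------------------
# circular (Morgan-style) fingerprints


def circular_fingerprint(mol: Molecule, radius: int = 2, n_bits: int = 1024) -> Fingerprint:
    """Iterative neighbourhood-hashing fingerprint.

    The initial atom identifier hashes (element, aromatic, charge, degree,
    implicit H); each iteration rehashes the atom identifier together with
    the sorted multiset of (bond order, neighbour identifier).  Identifiers
    from all iterations 0..radius are folded into ``n_bits``.  Isolated atoms
    keep their radius-0 identifier (their environment cannot grow).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 64 or n_bits & (n_bits - 1):
        raise ValueError("n_bits must be a power of two >= 64")
    adj = mol.adjacency()
    ids = [
        fnv1a_32(
            f"{a.element}|{int(a.aromatic)}|{a.formal_charge}|{len(adj[i])}|{a.implicit_h}"
        )
        for i, a in enumerate(mol.atoms)
    ]
    features = set(ids)
    for _ in range(radius):
        new_ids = []
        for i in range(mol.n_atoms):
            if not adj[i]:
                new_ids.append(ids[i])
                continue
            env = sorted((_bond_token(o), ids[j]) for o, j in adj[i])
            payload = f"{ids[i]}" + "".join(f"|{b}:{nid}" for b, nid in env)
            new_ids.append(fnv1a_32(payload))
        ids = new_ids
        features.update(ids)
    bits = frozenset(f % n_bits for f in features)
    return Fingerprint(bits, n_bits, "circular", (radius,))


# ---------------------------------------------------------------------------
# similarity


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient over set bits; both-empty => 1.0."""
    if not a.compatible_with(b):
        raise ValueError(
            f"incompatible fingerprints: {a.family}/{a.n_bits}/{a.params} vs "
            f"{b.family}/{b.n_bits}/{b.params}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def similarity_profile(query: Fingerprint, reference: list[Fingerprint]) -> SimilarityProfile:
    """Mean/min/max Tanimoto of ``query`` against a non-empty reference panel."""
    if not reference:
        raise ValueError("reference fingerprint list is empty")
    tcs = [tanimoto(query, r) for r in reference]
    return SimilarityProfile(
        mean_tc=float(np.mean(tcs)),
        min_tc=float(min(tcs)),
        max_tc=float(max(tcs)),
        n_reference=len(reference),
    )
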