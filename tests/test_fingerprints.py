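"""Fingerprint hashing, Tanimoto similarity and similarity profiles."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abxscreen.chem import AROMATIC_BOND, parse_smiles
from abxscreen.fingerprints import (
    Fingerprint,
    circular_fingerprint,
    enumerate_paths,
    fnv1a_32,
    path_fingerprint,
    similarity_profile,
    tanimoto,
)

# ---------------------------------------------------------------------------
# independent oracle: path enumeration via networkx + a fresh FNV-1a


def oracle_fnv(data: str) -> int:
    h = 2166136261
    for b in data.encode():
        h = ((h ^ b) * 16777619) % 2**32
    return h


def oracle_path_bits(mol, max_len=7, n_bits=1024) -> set[int]:
    """Brute-force simple-path enumeration through networkx."""
    g = nx.Graph()
    for i, a in enumerate(mol.atoms):
        tok = a.element + ("a" if a.aromatic else "")
        if a.formal_charge:
            tok += f"{a.formal_charge:+d}"
        g.add_node(i, tok=tok)
    for i, j, o in mol.bonds:
        g.add_edge(i, j, tok="a" if o == AROMATIC_BOND else str(int(o)))
    tokens = {g.nodes[i]["tok"] for i in g}
    for u in g:
        for v in g:
            if u >= v:
                continue
            for path in nx.all_simple_paths(g, u, v, cutoff=max_len - 1):
                toks = []
                for k, node in enumerate(path):
                    if k:
                        toks.append(g.edges[path[k - 1], node]["tok"])
                    toks.append(g.nodes[node]["tok"])
                fwd = "|".join(toks)
                rev = "|".join(reversed(toks))
                tokens.add(min(fwd, rev))
    return {oracle_fnv(t) % n_bits for t in tokens}


class TestPathFingerprint:
    def test_propane_has_three_distinct_paths(self):
        fp = path_fingerprint(parse_smiles("CCC"))
        assert fp.popcount == 3

    def test_single_atom(self):
        assert path_fingerprint(parse_smiles("C")).popcount == 1

    def test_benzene_differs_from_cyclohexane(self):
        benzene = set(enumerate_paths(parse_smiles("c1ccccc1")))
        cyclohexane = set(enumerate_paths(parse_smiles("C1CCCCC1")))
        assert benzene.isdisjoint(cyclohexane)
        assert tanimoto(
            path_fingerprint(parse_smiles("c1ccccc1")),
            path_fingerprint(parse_smiles("C1CCCCC1")),
        ) == 0.0

    @pytest.mark.parametrize("n", range(1, 11))
    def test_chain_path_count_closed_form(self, n):
        mol = parse_smiles("C" * n)
        expected = sum(n - k + 1 for k in range(1, min(7, n) + 1))
        assert len(enumerate_paths(mol, max_path_len=7)) == expected

    def test_bits_match_bruteforce_oracle(self, random_molecules):
        for mol in random_molecules[:60]:
            fp = path_fingerprint(mol)
            assert fp.bits == frozenset(oracle_path_bits(mol))

    def test_deterministic_across_recomputation(self, random_molecules):
        for mol in random_molecules[:20]:
            a = path_fingerprint(mol)
            b = path_fingerprint(parse_smiles(mol.source_smiles))
            assert a.bits == b.bits
            assert a.to_hex() == b.to_hex()

    def test_bit_exact_across_processes(self):
        """Hashing must be platform- and process-independent: the fingerprint
        of a fixed molecule equals a frozen hex constant."""
        fp = path_fingerprint(parse_smiles("c1cc(CCO)ncc1N"))
        assert fp.to_hex() == (
            "000080002080008200080100000000000100000000100000000008000002"
            "020002000010000040000000200000028000000000000004400200004000"
            "015820004008000008001061000000000050000020000000044100000000"
            "040040000000100804000000000080000000000100001004000020051000"
            "080e030080080000"
        )
        cfp = circular_fingerprint(parse_smiles("c1cc(CCO)ncc1N"))
        assert cfp.to_hex() == (
            "040000800000000000000000000000000000000000800000000008008000"
            "000080200100000000000000000000000088000000000000000a00000000"
            "000100000000000000008000000000000001000240000000000000020000"
            "000000000000002020000000000008000000000000000400000800400000"
            "0000000000020000"
        )

    def test_invalid_nbits(self):
        with pytest.raises(ValueError):
            path_fingerprint(parse_smiles("C"), n_bits=100)

    def test_hex_roundtrip(self):
        fp = path_fingerprint(parse_smiles("CCOc1ccccc1"))
        back = Fingerprint.from_hex(fp.to_hex(), fp.family, fp.params)
        assert back.bits == fp.bits


class TestFNV:
    def test_known_vectors(self):
        # published FNV-1a 32-bit test vectors
        assert fnv1a_32(b"") == 0x811C9DC5
        assert fnv1a_32(b"a") == 0xE40C292C
        assert fnv1a_32(b"foobar") == 0xBF9CF968


class TestCircularFingerprint:
    def test_methane_single_environment(self):
        for radius in (0, 1, 2, 3):
            assert circular_fingerprint(parse_smiles("C"), radius=radius).popcount == 1

    def test_ethanol_radius0_three_invariants(self):
        assert circular_fingerprint(parse_smiles("CCO"), radius=0).popcount == 3

    def test_connectivity_isomers_differ(self):
        a = circular_fingerprint(parse_smiles("CCCO"), radius=2)
        b = circular_fingerprint(parse_smiles("CC(C)O"), radius=2)
        assert a.bits != b.bits

    def test_radius_monotone_feature_growth(self):
        mol = parse_smiles("CCOc1ccncc1")
        fp1 = circular_fingerprint(mol, radius=1)
        fp2 = circular_fingerprint(mol, radius=2)
        assert fp1.bits <= fp2.bits


class TestTanimoto:
    def make(self, bits, n_bits=64):
        return Fingerprint(frozenset(bits), n_bits, "path", (7,))

    def test_identity(self):
        fp = self.make({1, 5, 9})
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(self.make({1, 2}), self.make({3, 4})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(self.make({1, 2}), self.make({1, 3})) == pytest.approx(1 / 3)

    def test_empty_convention(self):
        assert tanimoto(self.make(set()), self.make(set())) == 1.0
        assert tanimoto(self.make(set()), self.make({1})) == 0.0

    def test_incompatible_raises(self):
        a = self.make({1})
        b = Fingerprint(frozenset({1}), 64, "circular", (2,))
        with pytest.raises(ValueError):
            tanimoto(a, b)
        with pytest.raises(ValueError):
            tanimoto(a, Fingerprint(frozenset({1}), 128, "path", (7,)))

    def test_symmetry_and_self_similarity_random_pairs(self):
        rng = np.random.default_rng(23)
        fps = [
            self.make(set(rng.choice(64, size=rng.integers(1, 20), replace=False)))
            for _ in range(60)
        ]
        for _ in range(300):
            a, b = rng.choice(len(fps), 2)
            fa, fb = fps[a], fps[b]
            assert tanimoto(fa, fb) == tanimoto(fb, fa)
            assert tanimoto(fa, fa) == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(
        sa=st.frozensets(st.integers(0, 63)),
        sb=st.frozensets(st.integers(0, 63)),
    )
    def test_properties_hold_for_arbitrary_bit_sets(self, sa, sb):
        a, b = self.make(sa), self.make(sb)
        tc = tanimoto(a, b)
        assert 0.0 <= tc <= 1.0
        assert tc == tanimoto(b, a)
        assert tanimoto(a, a) == 1.0
        if sa and sa == sb:
            assert tc == 1.0

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            sa = set(map(int, rng.choice(256, size=rng.integers(0, 40))))
            sb = set(map(int, rng.choice(256, size=rng.integers(0, 40))))
            a = Fingerprint(frozenset(sa), 256, "path", (7,))
            b = Fingerprint(frozenset(sb), 256, "path", (7,))
            expected = (
                1.0 if not (sa | sb) else len(sa & sb) / len(sa | sb)
            )
            assert tanimoto(a, b) == pytest.approx(expected, abs=1e-12)


class TestSimilarityProfile:
    def make(self, bits):
        return Fingerprint(frozenset(bits), 64, "path", (7,))

    def test_query_matches_one_of_three(self):
        q = self.make({1, 2})
        refs = [self.make({1, 2}), self.make({5}), self.make({6})]
        prof = similarity_profile(q, refs)
        assert prof.max_tc == 1.0
        assert prof.min_tc == 0.0
        assert prof.mean_tc == pytest.approx(1 / 3)
        assert prof.n_reference == 3

    def test_reference_is_query(self):
        q = self.make({3, 4})
        prof = similarity_profile(q, [q])
        assert (prof.mean_tc, prof.min_tc, prof.max_tc) == (1.0, 1.0, 1.0)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            similarity_profile(self.make({1}), [])

    def test_matches_direct_loop_oracle(self):
        rng = np.random.default_rng(31)
        fps = [
            self.make(set(map(int, rng.choice(64, size=rng.integers(1, 30)))))
            for _ in range(21)
        ]
        q, refs = fps[0], fps[1:]
        tcs = [tanimoto(q, r) for r in refs]
        prof = similarity_profile(q, refs)
        assert prof.mean_tc == pytest.approx(sum(tcs) / len(tcs), abs=1e-12)
        assert prof.min_tc == min(tcs)
        assert prof.max_tc == max(tcs)
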