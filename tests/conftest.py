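import numpy as np
import pytest

from abxscreen.chem import Molecule, parse_smiles
from abxscreen.synthetic import GeneratorConfig, generate_bundle


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """Desk-scale corpus for fast pipeline/unit tests."""
    return GeneratorConfig(
        n_active=40,
        n_inactive_ic50=25,
        n_inactive_label_only=90,
        n_library=30,
        n_reference=10,
        planted={
            "n_duplicates": 2,
            "n_heavy": 1,
            "n_cross_similar": 1,
            "n_label_conflicts": 1,
            "n_novel_actives_in_library": 5,
            "n_scaffold_actives_in_library": 6,
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_bundle(small_cfg)


def permute_molecule(mol: Molecule, rng: np.random.Generator) -> Molecule:
    """Reorder atoms with a random permutation (test utility)."""
    perm = rng.permutation(mol.n_atoms)
    inv = {int(old): new for new, old in enumerate(perm)}
    atoms = [mol.atoms[int(i)] for i in perm]
    bonds = [
        (min(inv[i], inv[j]), max(inv[i], inv[j]), o) for i, j, o in mol.bonds
    ]
    return Molecule(atoms, bonds, source_smiles=mol.source_smiles)


@pytest.fixture(scope="session")
def random_molecules(small_bundle):
    """A pool of parsed synthetic molecules for property tests."""
    mols = [parse_smiles(r.smiles) for r in small_bundle.records[:120]]
    return mols
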