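"""Synthetic activity corpora and drug libraries with planted ground truth.

Molecules are built by decorating class-specific scaffold templates with
random substituents, which guarantees every emitted SMILES parses under the
package grammar, gives the classifiers a controllable scaffold signal, and
makes scaffold containment verifiable by exact MCS.

Three *active* scaffold families are used: two aromatic N-heterocycles
(pyridine- and pyrimidine-based, families A1/A2) and one halogenated-ether
family (A3).  The approved-antibacterial reference panel and the core
scaffold list are drawn from A1/A2 only, so A3-decorated library entries are
the planted "novel structure" candidates: the classifiers have seen their
family among the training actives, but the reference panel has not.
Inactives come from two aliphatic families (cyclohexane- and chain-based).

Active IC50s are log-normal with median 1 umol/L, inactive IC50s log-normal
with median 100 umol/L (sigma_log 0.5 on the natural-log scale for both), so
the two distributions straddle the 10 umol/L cutoff with ~4.6 sigma to
spare on each side.

Planted violations (exact counts, recorded in the truth table):

* duplicates — re-emitted records under fresh ids (same structure, same IC50);
* heavy compounds — long alkanes above 1000 Da;
* cross-class near-duplicates — an active with a long-chain decoration paired
  with an inactive differing by one chain atom (path-Tanimoto > 0.9);
* label conflicts — the same structure emitted once with an active IC50 and
  once with a bare inactive flag.

Output is byte-identical for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import ActivityRecord
from .chem import canonical_key, parse_smiles

__all__ = [
    "GeneratorConfig",
    "SyntheticBundle",
    "generate_activity_corpus",
    "generate_drug_library",
    "generate_reference",
    "core_scaffolds",
    "generate_bundle",
]


# Scaffold templates.  "<k>" marks an optional substitution slot; a chosen
# substituent S is inserted as the branch "(S)", an empty slot as "".
ACTIVE_TEMPLATES = {
    "A1": "c1cc<0>nc<1>c1<2>",          # pyridine family
    "A2": "c1nc<0>ncc1<1>",             # pyrimidine family
    "A3": "C(F)(F)<0>OC<1>(F)F",        # halogenated-ether family
}
INACTIVE_TEMPLATES = {
    "I1": "C1CC<0>CC<1>C1<2>",          # cyclohexane family
    "I2": "CC<0>CC<1>CC<2>O",           # aliphatic-chain family
}
# Undecorated cores of the reference-covered families: the core scaffolds.
CORE_SCAFFOLDS = {"A1": "c1ccncc1", "A2": "c1ncncc1"}

SUBSTITUENT_TERMINALS = {
    "A1": ["O", "N", "OC", "C"],
    "A2": ["O", "N", "OC", "C"],
    "A3": ["F", "Cl", "C(F)F", "C"],
    "I1": ["O", "C", "CC", "N", "OC"],
    "I2": ["O", "C", "CC", "N", "OC"],
}

_EMPTY_SLOT_PROB = 0.35
_MAX_CHAIN = 3
_MAX_TRIES = 200


@dataclass
class GeneratorConfig:
    """Corpus dimensions and planted-violation counts."""

    n_active: int = 250
    n_inactive_ic50: int = 150
    n_inactive_label_only: int = 700
    n_library: int = 100
    n_reference: int = 20
    n_scaffolds_active: int = 2
    n_scaffolds_inactive: int = 2
    planted: dict = field(
        default_factory=lambda: {
            "n_duplicates": 3,
            "n_heavy": 2,
            "n_cross_similar": 2,
            "n_label_conflicts": 2,
            "n_novel_actives_in_library": 10,
            "n_scaffold_actives_in_library": 15,
        }
    )
    ic50_active_median: float = 1.0       # umol/L
    ic50_inactive_median: float = 100.0   # umol/L
    sigma_log: float = 0.5                # natural-log scale
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_active",
            "n_inactive_ic50",
            "n_inactive_label_only",
            "n_library",
            "n_reference",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.ic50_active_median < 10.0 < self.ic50_inactive_median:
            raise ValueError("IC50 medians must straddle the 10 umol/L cutoff")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        planted = d.pop("planted", None)
        cfg = cls(**d)
        if planted:
            cfg.planted.update(planted)
        return cfg


class _Decorator:
    """Rejection-sampling molecule builder over one scaffold template set."""

    def __init__(self, rng: np.random.Generator, seen_keys: set[str]):
        self.rng = rng
        self.seen = seen_keys

    def substituent(self, family: str) -> str:
        chain = "C" * int(self.rng.integers(0, _MAX_CHAIN + 1))
        terminal = str(self.rng.choice(SUBSTITUENT_TERMINALS[family]))
        sub = chain + terminal
        return sub if sub else "C"

    def fill(self, template: str, family: str, n_slots: int) -> str:
        out = template
        any_filled = False
        for k in range(n_slots):
            if self.rng.random() < _EMPTY_SLOT_PROB and (any_filled or k < n_slots - 1):
                out = out.replace(f"<{k}>", "")
            else:
                out = out.replace(f"<{k}>", f"({self.substituent(family)})")
                any_filled = True
        return out

    def emit(self, family: str, template: str) -> str:
        n_slots = template.count("<")
        for _ in range(_MAX_TRIES):
            smi = self.fill(template, family, n_slots)
            key = canonical_key(parse_smiles(smi))
            if key not in self.seen:
                self.seen.add(key)
                return smi
        raise ValueError(
            f"scaffold family {family!r} cannot supply more distinct decorations; "
            "reduce the requested corpus size"
        )


def _active_families(cfg: GeneratorConfig) -> list[str]:
    fams = list(ACTIVE_TEMPLATES)
    return fams[: max(1, min(cfg.n_scaffolds_active + 1, len(fams)))]


def _inactive_families(cfg: GeneratorConfig) -> list[str]:
    fams = list(INACTIVE_TEMPLATES)
    return fams[: max(1, min(cfg.n_scaffolds_inactive, len(fams)))]


def _cross_pair_smiles(k: int) -> tuple[str, str]:
    """An active/inactive near-duplicate pair differing by one chain atom."""
    terminals = ["OC", "N", "O", "C"]
    t = terminals[k % len(terminals)]
    chain = "C" * 8
    active = f"c1cc({chain})nc({t})c1"
    inactive = f"c1cc({chain}C)nc({t})c1"
    return active, inactive


def generate_activity_corpus(cfg: GeneratorConfig):
    """Return (records, truth frame).  Byte-identical for identical seeds."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[0])
    seen: set[str] = set()
    deco = _Decorator(rng, seen)
    act_fams = _active_families(cfg)
    inact_fams = _inactive_families(cfg)

    records: list[ActivityRecord] = []
    truth_rows: list[dict] = []
    counter = [0]

    def next_id(prefix="CMP"):
        counter[0] += 1
        return f"{prefix}{counter[0]:05d}"

    def draw_ic50(median: float) -> float:
        return float(rng.lognormal(mean=np.log(median), sigma=cfg.sigma_log))

    def add(smiles, ic50, inactive_label, role, scaffold, cls):
        cid = next_id()
        records.append(
            ActivityRecord(cid, smiles, ic50=ic50, inactive_label=inactive_label)
        )
        truth_rows.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "class": cls,
                "has_ic50": ic50 is not None,
                "scaffold_id": scaffold,
                "role": role,
            }
        )
        return cid

    for k in range(cfg.n_active):
        fam = act_fams[k % len(act_fams)]
        smi = deco.emit(fam, ACTIVE_TEMPLATES[fam])
        ic50 = draw_ic50(cfg.ic50_active_median)
        cls = "active" if ic50 < 10.0 else "inactive"
        add(smi, ic50, False, "base_active", fam, cls)

    for k in range(cfg.n_inactive_ic50):
        fam = inact_fams[k % len(inact_fams)]
        smi = deco.emit(fam, INACTIVE_TEMPLATES[fam])
        ic50 = draw_ic50(cfg.ic50_inactive_median)
        cls = "inactive" if ic50 >= 10.0 else "active"
        add(smi, ic50, False, "base_inactive_ic50", fam, cls)

    for k in range(cfg.n_inactive_label_only):
        fam = inact_fams[k % len(inact_fams)]
        smi = deco.emit(fam, INACTIVE_TEMPLATES[fam])
        add(smi, None, True, "base_inactive_label", fam, "inactive")

    p = cfg.planted
    # duplicates: re-emit existing records (same structure and IC50, new id)
    n_dup = p.get("n_duplicates", 0)
    if n_dup:
        if n_dup > len(records):
            raise ValueError("more planted duplicates than base records")
        idx = rng.choice(len(records), size=n_dup, replace=False)
        for i in sorted(idx):
            src = records[i]
            row = truth_rows[i]
            add(
                src.smiles,
                src.ic50,
                src.inactive_label,
                "duplicate",
                row["scaffold_id"],
                row["class"],
            )

    # heavy compounds: long alkanes above 1000 Da
    for k in range(p.get("n_heavy", 0)):
        smi = "C" * (75 + k)
        add(smi, None, True, "heavy", "chain", "inactive")

    # cross-class near-duplicates
    for k in range(p.get("n_cross_similar", 0)):
        a_smi, i_smi = _cross_pair_smiles(k)
        add(a_smi, draw_ic50(cfg.ic50_active_median), False, "cross_active_partner", "A1", "active")
        add(i_smi, draw_ic50(cfg.ic50_inactive_median), False, "cross_similar", "A1", "inactive")

    # label conflicts: the same structure with contradictory evidence
    for k in range(p.get("n_label_conflicts", 0)):
        fam = act_fams[k % len(act_fams)]
        smi = deco.emit(fam, ACTIVE_TEMPLATES[fam])
        add(smi, draw_ic50(cfg.ic50_active_median), False, "conflict", fam, "active")
        add(smi, None, True, "conflict", fam, "inactive")

    return records, pd.DataFrame(truth_rows)


def generate_reference(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    """Approved-antibacterial reference panel: A1/A2-decorated molecules."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[1])
    deco = _Decorator(rng, set())
    fams = [f for f in _active_families(cfg) if f in CORE_SCAFFOLDS]
    out = []
    for k in range(cfg.n_reference):
        fam = fams[k % len(fams)]
        out.append((f"ABX{k + 1:03d}", deco.emit(fam, ACTIVE_TEMPLATES[fam])))
    return out


def core_scaffolds(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    fams = [f for f in _active_families(cfg) if f in CORE_SCAFFOLDS]
    return [(fam, CORE_SCAFFOLDS[fam]) for fam in fams]


def generate_drug_library(cfg: GeneratorConfig):
    """Return (library records, truth frame).

    Mixes scaffold-bearing actives (A1/A2: consensus-active, core-scaffold
    matched), planted novel actives (A3: consensus-active, reference-
    dissimilar) and inert decoys from the inactive families.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[2])
    deco = _Decorator(rng, set())
    p = cfg.planted
    n_novel = p.get("n_novel_actives_in_library", 0)
    n_scaff = p.get("n_scaffold_actives_in_library", 0)
    n_decoy = cfg.n_library - n_novel - n_scaff
    if n_decoy < 0:
        raise ValueError("planted library actives exceed n_library")
    fams_scaff = [f for f in _active_families(cfg) if f in CORE_SCAFFOLDS]
    inact_fams = _inactive_families(cfg)

    rows = []
    entries = []
    k_id = 0

    def add(smi, role, scaffold):
        nonlocal k_id
        k_id += 1
        did = f"DRG{k_id:04d}"
        entries.append((did, smi))
        rows.append({"drug_id": did, "smiles": smi, "role": role, "scaffold_id": scaffold})

    for k in range(n_scaff):
        fam = fams_scaff[k % len(fams_scaff)]
        add(deco.emit(fam, ACTIVE_TEMPLATES[fam]), "scaffold_active", fam)
    for k in range(n_novel):
        add(deco.emit("A3", ACTIVE_TEMPLATES["A3"]), "novel_active", "A3")
    for k in range(n_decoy):
        fam = inact_fams[k % len(inact_fams)]
        add(deco.emit(fam, INACTIVE_TEMPLATES[fam]), "decoy", fam)

    return entries, pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    records: list[ActivityRecord]
    activity_truth: pd.DataFrame
    library: list[tuple[str, str]]
    library_truth: pd.DataFrame
    reference: list[tuple[str, str]]
    scaffolds: list[tuple[str, str]]


def generate_bundle(cfg: GeneratorConfig) -> SyntheticBundle:
    records, truth = generate_activity_corpus(cfg)
    library, lib_truth = generate_drug_library(cfg)
    return SyntheticBundle(
        records=records,
        activity_truth=truth,
        library=library,
        library_truth=lib_truth,
        reference=generate_reference(cfg),
        scaffolds=core_scaffolds(cfg),
    )
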