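"""Benchmark construction: labelling, cleaning, and balanced negative sets.

Raw activity records (compound id, SMILES, optional IC50 in umol/L, optional
inactive flag) become a curated benchmark in four steps:

1. label by the IC50 cutoff (default 10 umol/L; active strictly below it,
   an IC50 exactly at the cutoff counts as inactive);
2. deduplicate by canonical structural key — duplicate groups with
   conflicting labels are removed entirely;
3. drop compounds with molecular weight above 1000 Da (strict '>');
4. drop inactives whose path-fingerprint Tanimoto against any active
   exceeds 0.9 (the actives, being the scarce class, are preserved).

Because label-only inactives vastly outnumber actives, each of ``n_repeats``
(default 10) negative sets is built as: every IC50-bearing inactive, plus a
without-replacement sample of label-only inactives up to the positive-set
size.  All sampling is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .fingerprints import Fingerprint, path_fingerprint, tanimoto

__all__ = [
    "ActivityRecord",
    "CleanCompound",
    "BenchmarkDataset",
    "label_activity",
    "records_from_frame",
    "clean_compounds",
    "sample_negatives",
    "build_benchmark",
]

IC50_CUTOFF_UMOL = 10.0
MAX_MW_BENCHMARK = 1000.0
CROSS_CLASS_TC = 0.9


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    smiles: str
    ic50: float | None = None
    inactive_label: bool = False

    def __post_init__(self):
        if self.ic50 is None and not self.inactive_label:
            raise ValueError(
                f"record {self.compound_id!r} carries neither an IC50 value "
                "nor an inactive label"
            )
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValueError(f"record {self.compound_id!r} has non-positive IC50")


@dataclass
class CleanCompound:
    """A surviving record with parsed structure and fingerprint."""

    compound_id: str
    smiles: str
    label: str  # "active" | "inactive"
    has_ic50: bool
    mol: chem.Molecule
    key: str
    fp: Fingerprint


@dataclass
class BenchmarkDataset:
    positives: list[CleanCompound]
    negative_sets: list[list[CleanCompound]]
    feature_params: dict
    provenance_log: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return len(self.negative_sets)

    def features(self, set_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and 1/0 label vector for positives + negative set k."""
        compounds = self.positives + self.negative_sets[set_index]
        X = np.stack([c.fp.to_array() for c in compounds]).astype(np.float64)
        y = np.array([1] * len(self.positives) + [0] * len(self.negative_sets[set_index]))
        return X, y


def label_activity(rec: ActivityRecord, cutoff: float = IC50_CUTOFF_UMOL) -> str:
    """'active' iff IC50 strictly below the cutoff; the cutoff itself and
    anything above it — or a bare inactive flag — is 'inactive'."""
    if rec.ic50 is not None:
        return "active" if rec.ic50 < cutoff else "inactive"
    if rec.inactive_label:
        return "inactive"
    raise ValueError(f"record {rec.compound_id!r} cannot be labelled")


def records_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    """Build records from a CSV-style frame with columns compound_id, smiles,
    ic50_umol (blank allowed), inactive (0/1)."""
    records = []
    for row in df.itertuples(index=False):
        ic50 = getattr(row, "ic50_umol", None)
        if ic50 is not None and (ic50 == "" or (isinstance(ic50, float) and math.isnan(ic50))):
            ic50 = None
        records.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                ic50=float(ic50) if ic50 is not None else None,
                inactive_label=bool(int(getattr(row, "inactive", 0))),
            )
        )
    return records


def clean_compounds(
    records: list[ActivityRecord],
    max_mw: float = MAX_MW_BENCHMARK,
    cross_sim: float = CROSS_CLASS_TC,
    cutoff: float = IC50_CUTOFF_UMOL,
    fp_params: dict | None = None,
) -> tuple[list[CleanCompound], list[CleanCompound], dict]:
    """Apply the three cleaning steps in order; returns (actives, inactives,
    provenance log).  Unparseable SMILES are skipped and logged."""
    fp_params = fp_params or {}
    max_path_len = fp_params.get("max_path_len", 7)
    n_bits = fp_params.get("n_bits", 1024)

    log = {
        "input": len(records),
        "parse_skipped": 0,
        "dedup_removed": 0,
        "conflict_removed": 0,
        "mw_removed": 0,
        "cross_removed": 0,
        "skipped_ids": [],
        "cross_removed_pairs": [],
    }

    parsed: list[CleanCompound] = []
    for rec in records:
        try:
            mol = chem.parse_smiles(rec.smiles)
        except chem.ParseError:
            log["parse_skipped"] += 1
            log["skipped_ids"].append(rec.compound_id)
            continue
        parsed.append(
            CleanCompound(
                compound_id=rec.compound_id,
                smiles=rec.smiles,
                label=label_activity(rec, cutoff),
                has_ic50=rec.ic50 is not None,
                mol=mol,
                key=chem.canonical_key(mol),
                fp=path_fingerprint(mol, max_path_len=max_path_len, n_bits=n_bits),
            )
        )

    # step 1: structural deduplication; conflicting labels remove the group
    groups: dict[str, list[CleanCompound]] = {}
    for c in parsed:
        groups.setdefault(c.key, []).append(c)
    deduped: list[CleanCompound] = []
    for key, group in groups.items():
        labels = {c.label for c in group}
        if len(labels) > 1:
            log["conflict_removed"] += len(group)
            continue
        deduped.append(group[0])
        log["dedup_removed"] += len(group) - 1
    # preserve input order
    order = {id(c): k for k, c in enumerate(parsed)}
    deduped.sort(key=lambda c: order[id(c)])

    # step 2: molecular weight strictly above the limit
    kept: list[CleanCompound] = []
    for c in deduped:
        if chem.molecular_weight(c.mol) > max_mw:
            log["mw_removed"] += 1
        else:
            kept.append(c)

    # step 3: cross-class similarity; remove the inactive member of each
    # offending pair (actives are the scarce class)
    actives = [c for c in kept if c.label == "active"]
    inactives = [c for c in kept if c.label == "inactive"]
    drop: set[str] = set()
    for inact in inactives:
        for act in actives:
            tc = tanimoto(inact.fp, act.fp)
            if tc > cross_sim:
                drop.add(inact.compound_id)
                log["cross_removed_pairs"].append(
                    (inact.compound_id, act.compound_id, round(tc, 4))
                )
                break
    log["cross_removed"] = len(drop)
    inactives = [c for c in inactives if c.compound_id not in drop]

    log["survivors_active"] = len(actives)
    log["survivors_inactive"] = len(inactives)
    log["survivors"] = len(actives) + len(inactives)
    return actives, inactives, log


def sample_negatives(
    negatives: list[CleanCompound],
    n_target: int,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[list[CleanCompound]]:
    """Build ``n_repeats`` negative sets of exactly ``n_target`` members.

    Every IC50-bearing inactive belongs to every set; the shortfall is drawn
    without replacement from the label-only inactives, with per-set RNG
    streams spawned deterministically from ``seed``.
    """
    fixed = [c for c in negatives if c.has_ic50]
    pool = [c for c in negatives if not c.has_ic50]
    if len(fixed) > n_target:
        raise ValueError(
            f"{len(fixed)} IC50-bearing inactives exceed the target set size {n_target}"
        )
    n_sample = n_target - len(fixed)
    if n_sample > len(pool):
        raise ValueError(
            f"need {n_sample} label-only inactives but only {len(pool)} available "
            f"(shortfall {n_sample - len(pool)})"
        )
    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    sets = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.choice(len(pool), size=n_sample, replace=False)
        sets.append(fixed + [pool[i] for i in sorted(idx)])
    return sets


def build_benchmark(
    records: list[ActivityRecord],
    n_repeats: int = 10,
    seed: int = 0,
    max_mw: float = MAX_MW_BENCHMARK,
    cross_sim: float = CROSS_CLASS_TC,
    cutoff: float = IC50_CUTOFF_UMOL,
    fp_params: dict | None = None,
) -> BenchmarkDataset:
    """Full benchmark assembly: clean, then resample balanced negative sets."""
    actives, inactives, log = clean_compounds(
        records, max_mw=max_mw, cross_sim=cross_sim, cutoff=cutoff, fp_params=fp_params
    )
    if not actives:
        raise ValueError("no active compounds survive cleaning")
    negative_sets = sample_negatives(
        inactives, n_target=len(actives), n_repeats=n_repeats, seed=seed
    )
    fp_params = fp_params or {}
    return BenchmarkDataset(
        positives=actives,
        negative_sets=negative_sets,
        feature_params={
            "family": "path",
            "max_path_len": fp_params.get("max_path_len", 7),
            "n_bits": fp_params.get("n_bits", 1024),
        },
        provenance_log=log,
    )
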