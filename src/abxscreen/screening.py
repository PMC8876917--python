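"""Library screening: consensus prediction, novelty and scaffold analysis.

A drug-library entry is called active by one classifier when its predicted
probability is strictly greater than 0.5, and consensus-active when all
three classifiers agree.  Consensus-active drugs whose structure (canonical
key) is not in the approved-antibacterial reference panel are the novel
predicted antibacterial drugs; among those, a drug is *structurally novel*
when its mean path-fingerprint Tanimoto against the whole reference panel is
below 0.1 and its maximum below 0.2 (both strict).  A coarser bucket flags
mean similarity <= 0.2.  Scaffold possession is judged by the exact-MCS
overlap coefficient against each core scaffold (> 0.9 = high similarity).

Molecular-weight boundaries are kept exactly as the two stages define them:
benchmark cleaning removes weights strictly above 1000 Da, while library
preparation removes weights at or above 1000 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import chem
from .fingerprints import Fingerprint, SimilarityProfile, path_fingerprint, similarity_profile
from .mcs import ScaffoldMatch, scaffold_screen

__all__ = [
    "LibraryEntry",
    "PredictionResult",
    "NoveltyVerdict",
    "ScreenReport",
    "prepare_library",
    "predict_library",
    "apply_novelty_rule",
    "novelty_screen",
    "full_screen",
]

MAX_MW_LIBRARY = 1000.0
CONSENSUS_PROB = 0.5
NOVELTY_MEAN = 0.1
NOVELTY_MAX = 0.2
LOW_SIM_BUCKET = 0.2


@dataclass
class LibraryEntry:
    drug_id: str
    smiles: str
    mol: chem.Molecule
    key: str
    fp: Fingerprint


@dataclass(frozen=True)
class PredictionResult:
    drug_id: str
    prob_svm: float
    prob_rf: float
    prob_mlp: float
    active_per_model: tuple[bool, bool, bool]
    consensus_active: bool

    @classmethod
    def from_probs(
        cls, drug_id: str, probs: dict[str, float], threshold: float = CONSENSUS_PROB
    ) -> "PredictionResult":
        per_model = tuple(probs[m] > threshold for m in ("svm", "rf", "mlp"))
        return cls(
            drug_id=drug_id,
            prob_svm=probs["svm"],
            prob_rf=probs["rf"],
            prob_mlp=probs["mlp"],
            active_per_model=per_model,
            consensus_active=all(per_model),
        )


@dataclass
class NoveltyVerdict:
    drug_id: str
    profile: SimilarityProfile
    low_similarity_bucket: bool
    novel_structure: bool
    scaffold_matches: list[ScaffoldMatch] = field(default_factory=list)
    scaffold_free: bool = True


@dataclass
class ScreenReport:
    predictions: list[PredictionResult]
    verdicts: list[NoveltyVerdict]
    counts: dict
    library: list[LibraryEntry]

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": p.drug_id,
                "prob_svm": p.prob_svm,
                "prob_rf": p.prob_rf,
                "prob_mlp": p.prob_mlp,
                "consensus_active": p.consensus_active,
            }
            for p in self.predictions
        )

    def novelty_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": v.drug_id,
                "mean_tc": v.profile.mean_tc,
                "min_tc": v.profile.min_tc,
                "max_tc": v.profile.max_tc,
                "low_similarity_bucket": v.low_similarity_bucket,
                "novel_structure": v.novel_structure,
                "scaffold_free": v.scaffold_free,
            }
            for v in self.verdicts
        )

    def scaffolds_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            for m in v.scaffold_matches:
                rows.append(
                    {
                        "drug_id": v.drug_id,
                        "scaffold_id": m.scaffold_id,
                        "mcs_atoms": m.mcs_atoms,
                        "overlap_coefficient": m.overlap_coefficient,
                        "is_high_similarity": m.is_high_similarity,
                    }
                )
        return pd.DataFrame(rows)


def prepare_library(
    drugs: list[tuple[str, str]],
    max_mw: float = MAX_MW_LIBRARY,
    fp_params: dict | None = None,
    status: dict[str, str] | None = None,
) -> tuple[list[LibraryEntry], dict]:
    """Parse, status-filter, weight-filter and fingerprint a drug library.

    ``status``, when given, maps drug id -> status string; only 'approved'
    entries are kept.  Weight filtering removes entries at or *above*
    ``max_mw``.  Returns (entries, log).
    """
    fp_params = fp_params or {}
    log = {"input": len(drugs), "parse_skipped": 0, "status_removed": 0, "mw_removed": 0}
    skipped = []
    entries: list[LibraryEntry] = []
    for drug_id, smiles in drugs:
        if status is not None and status.get(drug_id, "approved") != "approved":
            log["status_removed"] += 1
            continue
        try:
            mol = chem.parse_smiles(smiles)
        except chem.ParseError:
            log["parse_skipped"] += 1
            skipped.append(drug_id)
            continue
        if chem.molecular_weight(mol) >= max_mw:
            log["mw_removed"] += 1
            continue
        entries.append(
            LibraryEntry(
                drug_id=drug_id,
                smiles=smiles,
                mol=mol,
                key=chem.canonical_key(mol),
                fp=path_fingerprint(
                    mol,
                    max_path_len=fp_params.get("max_path_len", 7),
                    n_bits=fp_params.get("n_bits", 1024),
                ),
            )
        )
    log["skipped_ids"] = skipped
    log["survivors"] = len(entries)
    if not entries:
        raise ValueError("no library entries survive preparation")
    return entries, log


def predict_library(
    results, library: list[LibraryEntry], threshold: float = CONSENSUS_PROB
) -> list[PredictionResult]:
    """Per-drug probabilities from each method plus the consensus flag.

    ``results`` is a fitted :class:`~abxscreen.models.ConsensusResults`; a
    fingerprint-configuration mismatch raises a usage error.
    """
    frame = results.predict_proba([e.fp for e in library])
    out = []
    for entry, row in zip(library, frame.itertuples(index=False)):
        probs = {m: float(getattr(row, f"prob_{m}")) for m in ("svm", "rf", "mlp")}
        out.append(PredictionResult.from_probs(entry.drug_id, probs, threshold))
    return out


def apply_novelty_rule(
    mean_tc: float,
    max_tc: float,
    mean_cut: float = NOVELTY_MEAN,
    max_cut: float = NOVELTY_MAX,
    bucket_cut: float = LOW_SIM_BUCKET,
) -> tuple[bool, bool]:
    """(low_similarity_bucket, novel_structure) for one similarity profile.

    Structural novelty requires mean < ``mean_cut`` AND max < ``max_cut``,
    both strict; the bucket is the coarser mean <= ``bucket_cut``.
    """
    return mean_tc <= bucket_cut, (mean_tc < mean_cut and max_tc < max_cut)


def novelty_screen(
    candidates: list[LibraryEntry],
    reference_fps: list[Fingerprint],
    mean_cut: float = NOVELTY_MEAN,
    max_cut: float = NOVELTY_MAX,
    bucket_cut: float = LOW_SIM_BUCKET,
) -> list[NoveltyVerdict]:
    """Similarity-profile each candidate against the reference panel.

    ``novel_structure`` requires mean < ``mean_cut`` AND max < ``max_cut``
    (strict); ``low_similarity_bucket`` is mean <= ``bucket_cut``.
    """
    if not reference_fps:
        raise ValueError("approved-antibacterial reference set is empty")
    out = []
    for entry in candidates:
        prof = similarity_profile(entry.fp, reference_fps)
        bucket, novel = apply_novelty_rule(
            prof.mean_tc, prof.max_tc, mean_cut, max_cut, bucket_cut
        )
        out.append(
            NoveltyVerdict(
                drug_id=entry.drug_id,
                profile=prof,
                low_similarity_bucket=bucket,
                novel_structure=novel,
            )
        )
    return out


def full_screen(
    results,
    library: list[LibraryEntry],
    reference: list[tuple[str, str]],
    scaffolds: list[tuple[str, str]] | None = None,
    thresholds: dict | None = None,
) -> ScreenReport:
    """Predict the whole library, then novelty- and scaffold-screen the
    consensus-active drugs that are not themselves reference structures."""
    th = {
        "consensus": CONSENSUS_PROB,
        "novelty_mean": NOVELTY_MEAN,
        "novelty_max": NOVELTY_MAX,
        "overlap": 0.9,
        **(thresholds or {}),
    }
    fp_params = results.feature_params
    ref_entries = []
    ref_keys = set()
    for rid, smi in reference:
        mol = chem.parse_smiles(smi)
        ref_keys.add(chem.canonical_key(mol))
        ref_entries.append(
            path_fingerprint(
                mol,
                max_path_len=fp_params["max_path_len"],
                n_bits=fp_params["n_bits"],
            )
        )
    if not ref_entries:
        raise ValueError("approved-antibacterial reference set is empty")

    predictions = predict_library(results, library, threshold=th["consensus"])
    by_id = {e.drug_id: e for e in library}
    consensus = [p.drug_id for p in predictions if p.consensus_active]
    known = [d for d in consensus if by_id[d].key in ref_keys]
    candidates = [by_id[d] for d in consensus if by_id[d].key not in ref_keys]

    verdicts = novelty_screen(
        candidates, ref_entries, mean_cut=th["novelty_mean"], max_cut=th["novelty_max"]
    )
    parsed_scaffolds = None
    if scaffolds:
        parsed_scaffolds = [(sid, chem.parse_smiles(smi)) for sid, smi in scaffolds]
        for v in verdicts:
            v.scaffold_matches = scaffold_screen(
                by_id[v.drug_id].mol, parsed_scaffolds, threshold=th["overlap"]
            )
            v.scaffold_free = not any(m.is_high_similarity for m in v.scaffold_matches)

    counts = {
        "library": len(library),
        "active_svm": sum(p.active_per_model[0] for p in predictions),
        "active_rf": sum(p.active_per_model[1] for p in predictions),
        "active_mlp": sum(p.active_per_model[2] for p in predictions),
        "consensus_active": len(consensus),
        "known_antibacterial": len(known),
        "novel_candidates": len(candidates),
        "structurally_novel": sum(v.novel_structure for v in verdicts),
        "low_similarity_bucket": sum(v.low_similarity_bucket for v in verdicts),
        "scaffold_free": sum(v.scaffold_free for v in verdicts) if scaffolds else None,
    }
    return ScreenReport(predictions, verdicts, counts, library)
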