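"""End-to-end workflow: build benchmark -> train -> screen -> novelty.

Each stage writes its artifact under the output directory and appends one
structured log line with input/output counts, mirroring the provenance a
curation report states as prose.  Reruns with an identical configuration and
seed reproduce every CSV/JSON output byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import chem
from .benchmark import build_benchmark, records_from_frame
from .config import PipelineConfig
from .models import ConsensusActivityModel
from .screening import full_screen, prepare_library
from .synthetic import GeneratorConfig, generate_bundle

logger = logging.getLogger("abxscreen")

__all__ = ["run_pipeline", "write_bundle", "load_activity_csv", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _log(stage: str, **counts):
    logger.info("%s %s", stage, json.dumps(counts, sort_keys=True, default=str))


def write_bundle(bundle, out_dir: Path) -> None:
    """Write a synthetic bundle as the pipeline's file inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "compound_id": r.compound_id,
            "smiles": r.smiles,
            "ic50_umol": "" if r.ic50 is None else r.ic50,
            "inactive": int(r.inactive_label),
        }
        for r in bundle.records
    ]
    pd.DataFrame(rows).to_csv(out_dir / "activity.csv", index=False)
    pd.DataFrame(
        [{"drug_id": d, "smiles": s} for d, s in bundle.library]
    ).to_csv(out_dir / "library.csv", index=False)
    with open(out_dir / "reference_abx.smi", "w") as fh:
        for rid, smi in bundle.reference:
            fh.write(f"{smi} {rid}\n")
    with open(out_dir / "scaffolds.smi", "w") as fh:
        for sid, smi in bundle.scaffolds:
            fh.write(f"{smi} {sid}\n")
    truth = bundle.activity_truth.copy()
    truth["table"] = "activity"
    lib_truth = bundle.library_truth.copy()
    lib_truth["table"] = "library"
    pd.concat([truth, lib_truth], ignore_index=True).to_csv(
        out_dir / "truth.csv", index=False
    )


def load_activity_csv(path):
    df = pd.read_csv(path)
    required = {"compound_id", "smiles"}
    if not required <= set(df.columns):
        raise ValueError(f"activity CSV must have columns {sorted(required)}")
    return records_from_frame(df)


def _require(path, name):
    if path is None:
        raise FileNotFoundError(f"config paths.{name} is not set")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{name} file not found: {p}")
    return p


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns the report dictionary.

    When ``cfg.paths.activity`` is unset, a synthetic bundle is generated
    from ``cfg.generator`` (seeded by ``cfg.seed``) and written under the
    output directory, then consumed through the same file loaders as user
    data.  Any stage failure raises :class:`StageError` naming the stage.
    """
    cfg.validate()
    out = Path(cfg.paths.get("output") or "abxscreen_out")
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": []}

    stage = "inputs"
    try:
        if cfg.paths.get("activity") is None:
            gcfg = GeneratorConfig.from_dict({**cfg.generator, "seed": cfg.seed})
            bundle = generate_bundle(gcfg)
            write_bundle(bundle, out / "inputs")
            for key, fname in (
                ("activity", "activity.csv"),
                ("library", "library.csv"),
                ("reference", "reference_abx.smi"),
                ("scaffolds", "scaffolds.smi"),
            ):
                cfg.paths[key] = str(out / "inputs" / fname)
            _log(stage, generated=len(bundle.records), library=len(bundle.library))
        records = load_activity_csv(_require(cfg.paths["activity"], "activity"))
        report["stages"].append(stage)

        stage = "build-benchmark"
        benchmark = build_benchmark(
            records,
            n_repeats=cfg.n_negative_sets,
            seed=cfg.seed,
            max_mw=cfg.filters["max_mw_benchmark"],
            cross_sim=cfg.filters["cross_sim"],
            cutoff=cfg.cutoff_umol,
            fp_params=cfg.fingerprint,
        )
        prov = {k: v for k, v in benchmark.provenance_log.items() if not isinstance(v, list)}
        report["benchmark"] = prov
        with open(out / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
        with open(out / "positives.smi", "w") as fh:
            for c in benchmark.positives:
                fh.write(f"{c.smiles} {c.compound_id}\n")
        for k, negs in enumerate(benchmark.negative_sets, 1):
            with open(out / f"negatives_{k}.smi", "w") as fh:
                for c in negs:
                    fh.write(f"{c.smiles} {c.compound_id}\n")
        import numpy as np

        feats = {}
        for k in range(benchmark.n_repeats):
            X, y = benchmark.features(k)
            feats[f"X_{k}"] = X.astype(np.uint8)
            feats[f"y_{k}"] = y.astype(np.uint8)
        np.savez_compressed(out / "features.npz", **feats)
        _log(stage, **prov)
        report["stages"].append(stage)

        stage = "train"
        model = ConsensusActivityModel(benchmark, grids=cfg.grids)
        results = model.fit(
            seed=cfg.seed,
            test_frac=cfg.cv["test_frac"],
            k=cfg.cv["k"],
            do_grid_search=cfg.cv.get("grid_search", False),
            grid_search_repeats=cfg.cv.get("repeats", 10),
        )
        metrics = results.metrics_frame()
        metrics.to_csv(out / "metrics.csv")
        results.save(out / "bundle")
        report["metrics"] = {
            m: {
                "accuracy": results.reports[m].means["accuracy"],
                "auc": results.reports[m].means["auc"],
                "mse": results.reports[m].means["mse"],
                "chosen": results.specs[m].chosen,
            }
            for m in results.methods
        }
        _log(stage, **{m: round(results.reports[m].means["accuracy"], 4) for m in results.methods})
        report["stages"].append(stage)

        stage = "screen"
        library, lib_log = prepare_library(
            [
                (str(r.drug_id), str(r.smiles))
                for r in pd.read_csv(_require(cfg.paths["library"], "library")).itertuples()
            ],
            max_mw=cfg.filters["max_mw_library"],
            fp_params=cfg.fingerprint,
        )
        reference = chem.read_smi(_require(cfg.paths["reference"], "reference"))
        scaffolds = None
        if cfg.paths.get("scaffolds"):
            scaffolds = chem.read_smi(_require(cfg.paths["scaffolds"], "scaffolds"))
        screen = full_screen(
            results, library, reference, scaffolds, thresholds=cfg.thresholds
        )
        screen.predictions_frame().to_csv(out / "predictions.csv", index=False)
        screen.novelty_frame().to_csv(out / "novelty.csv", index=False)
        sf = screen.scaffolds_frame()
        if len(sf):
            sf.to_csv(out / "scaffolds.csv", index=False)
        report["library"] = {k: v for k, v in lib_log.items() if not isinstance(v, list)}
        report["screen"] = screen.counts
        _log(stage, **screen.counts)
        report["stages"].append(stage)
    except Exception as e:  # noqa: BLE001 - stage attribution
        (out / "report.json").write_text(
            json.dumps({"incomplete": True, "failed_stage": stage}, indent=2) + "\n"
        )
        raise StageError(stage, e) from e

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
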