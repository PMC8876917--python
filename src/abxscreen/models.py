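"""Consensus activity model: SVM + random forest + multi-layer perceptron.

The three classifiers are fitted on path-fingerprint features of the
benchmark (one positive set against each of the balanced negative sets).
This module owns everything around the learners — the stratified 80/20
split, grid search with repeated k-fold cross-validation, the rank-based
AUC, the confusion-derived metric panel, and the aggregation of metrics as
mean +/- sd over the negative sets.  The learners themselves come from
scikit-learn with all parameters at library defaults except those searched.

Metric conventions
------------------
All seven indices are computed from the confusion counts at probability
threshold 0.5:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

MSE is computed on *hard* 0/1 predictions, so it equals the
misclassification rate and ``accuracy + MSE = 1`` holds exactly on every
run.  This is deliberate and nonstandard: it is the only reading under which
an accuracy/MSE pair like 0.852/0.148 is self-consistent, and it is the
convention this package reports.

AUC is the Mann-Whitney rank statistic with midrank tie handling, which
equals trapezoidal integration of the ROC curve.

Usage
-----
    model = ConsensusActivityModel(benchmark)
    res = model.fit(seed=1)
    print(res.summary())
    probs = res.predict_proba(fingerprints)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .benchmark import BenchmarkDataset
from .fingerprints import Fingerprint

__all__ = [
    "ModelSpec",
    "MetricsReport",
    "ConsensusActivityModel",
    "ConsensusResults",
    "DEFAULT_GRIDS",
    "split_dataset",
    "grid_search_cv",
    "roc_auc",
    "confusion_metrics",
    "evaluate",
]

METHODS = ("svm", "rf", "mlp")

#: Search grids; each contains the reference optimum of its method
#: (svm: gamma 0.01, C 10; rf: n_estimators 750; mlp: hidden 512, alpha 1e-4).
DEFAULT_GRIDS = {
    "svm": {"gamma": [0.001, 0.01, 0.1], "C": [1.0, 10.0, 100.0]},
    "rf": {"n_estimators": [250, 500, 750, 1000]},
    "mlp": {"hidden_layer_sizes": [128, 256, 512], "alpha": [1e-4, 1e-3]},
}

DEFAULT_CHOSEN = {
    "svm": {"gamma": 0.01, "C": 10.0},
    "rf": {"n_estimators": 750},
    "mlp": {"hidden_layer_sizes": 512, "alpha": 1e-4},
}

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1", "auc", "mse")


@dataclass
class ModelSpec:
    method: str
    grid: dict = field(default_factory=dict)
    chosen: dict | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.method].items()}

    def grid_points(self) -> list[dict]:
        keys = sorted(self.grid)
        if not keys:
            raise ValueError("empty hyperparameter grid")
        points = [{}]
        for k in keys:
            points = [{**p, k: v} for p in points for v in self.grid[k]]
        return points


def make_estimator(method: str, params: dict, seed: int):
    """Instantiate the underlying scikit-learn learner; parameters not in
    ``params`` stay at library defaults."""
    if method == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if method == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if method == "mlp":
        p = dict(params)
        hidden = p.pop("hidden_layer_sizes", 512)
        if isinstance(hidden, int):
            hidden = (hidden,)
        return MLPClassifier(hidden_layer_sizes=hidden, random_state=seed, **p)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# splitting, CV, metrics


def split_dataset(
    X: np.ndarray, y: np.ndarray, test_frac: float = 0.2, seed: int = 0
):
    """Stratified random split into (train_val, test) at the given fraction."""
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must lie strictly between 0 and 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 members for a stratified split")
    X_tv, X_te, y_tv, y_te = train_test_split(
        X, y, test_size=test_frac, stratify=y, random_state=seed
    )
    return (X_tv, y_tv), (X_te, y_te)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank ties; equals trapezoidal ROC area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in the labels")
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """The seven-index panel from confusion counts (MSE = error rate on hard
    predictions; AUC is not derivable from counts and is filled by callers)."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": (tp + tn) / total,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
        "mse": (fp + fn) / total,
        "confusion": (tp, tn, fp, fn),
    }


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> dict:
    """Single-run metric panel on a labelled test set (threshold 0.5)."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(X_test)[:, 1]
    pred = (probs > 0.5).astype(int)
    tp = int(((pred == 1) & (y_test == 1)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    panel = confusion_metrics(tp, tn, fp, fn)
    panel["auc"] = roc_auc(probs, y_test)
    return panel


def _cv_accuracy(method, params, X, y, k, seed):
    accs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, va in skf.split(X, y):
        est = make_estimator(method, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        accs.append(float((est.predict(X[va]) == y[va]).mean()))
    return float(np.mean(accs))


def grid_search_cv(
    train_val,
    test,
    spec: ModelSpec,
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> ModelSpec:
    """Choose hyperparameters by repeated k-fold CV accuracy.

    For each grid point the mean CV accuracy over ``k`` folds x ``n_repeats``
    repeats is computed on the train/validation portion.  The winner is the
    maximum mean accuracy; exact ties are broken by the AUC of a temporary
    model (fitted on the whole train/validation set) on the held-out test
    set.  Deterministic given ``seed``.
    """
    X_tv, y_tv = train_val
    X_te, y_te = test
    points = spec.grid_points()
    mean_accs = []
    for params in points:
        accs = [
            _cv_accuracy(spec.method, params, X_tv, y_tv, k, seed + rep)
            for rep in range(n_repeats)
        ]
        mean_accs.append(float(np.mean(accs)))
    best_acc = max(mean_accs)
    contenders = [p for p, acc in zip(points, mean_accs) if acc == best_acc]
    if len(contenders) == 1:
        chosen = contenders[0]
    else:
        aucs = []
        for params in contenders:
            est = make_estimator(spec.method, params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X_tv, y_tv)
            aucs.append(roc_auc(est.predict_proba(X_te)[:, 1], y_te))
        chosen = contenders[int(np.argmax(aucs))]
    return ModelSpec(method=spec.method, grid=spec.grid, chosen=chosen)


# ---------------------------------------------------------------------------
# results container


@dataclass
class MetricsReport:
    """Per-method metric panel aggregated over the negative sets."""

    method: str
    means: dict
    sds: dict
    per_run: list[dict]

    def as_series(self) -> pd.Series:
        data = {}
        for m in METRIC_NAMES:
            data[f"{m}_mean"] = self.means[m]
            data[f"{m}_sd"] = self.sds[m]
        return pd.Series(data, name=self.method)


class ConsensusResults:
    """Fit results: chosen hyperparameters, metric panels, fitted bundles.

    ``predict_proba`` averages the predicted probability over the fits to
    the individual negative sets, per method.
    """

    def __init__(self, model, specs, reports, bundles, seed, feature_params=None):
        self.model = model
        self.specs: dict[str, ModelSpec] = specs
        self.reports: dict[str, MetricsReport] = reports
        self._bundles: dict[str, list] = bundles
        self.seed = seed
        self._feature_params = feature_params or (
            model.benchmark.feature_params if model is not None else None
        )

    @property
    def feature_params(self) -> dict:
        return self._feature_params

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.reports[m].as_series() for m in self.methods])

    @property
    def methods(self):
        return list(self.specs)

    def n_member_fits(self, method: str) -> int:
        return len(self._bundles[method])

    def predict_proba(self, fps: list[Fingerprint]) -> pd.DataFrame:
        """Per-method mean probability (over negative-set fits) for each query."""
        for fp in fps:
            if (
                fp.family != self.feature_params["family"]
                or fp.n_bits != self.feature_params["n_bits"]
            ):
                raise ValueError(
                    "query fingerprint configuration does not match the "
                    f"training features {self.feature_params}"
                )
        X = np.stack([fp.to_array() for fp in fps]).astype(np.float64)
        out = {}
        for method, members in self._bundles.items():
            probs = np.mean([m.predict_proba(X)[:, 1] for m in members], axis=0)
            out[f"prob_{method}"] = probs
        return pd.DataFrame(out)

    def save(self, out_dir) -> None:
        """Persist member models (joblib) with a manifest for exact reload."""
        import joblib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "feature_params": self.feature_params,
            "methods": {
                m: {"chosen": self.specs[m].chosen, "n_members": len(self._bundles[m])}
                for m in self.methods
            },
            "metrics": {
                m: {k: self.reports[m].means[k] for k in METRIC_NAMES}
                for m in self.methods
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        for method, members in self._bundles.items():
            joblib.dump(members, out / f"{method}.joblib")

    @classmethod
    def load(cls, bundle_dir) -> "ConsensusResults":
        """Reload a persisted bundle; metric panels carry the saved means
        (per-run detail is not persisted)."""
        import joblib

        path = Path(bundle_dir)
        manifest = json.loads((path / "manifest.json").read_text())
        specs, reports, bundles = {}, {}, {}
        ordered = sorted(
            manifest["methods"],
            key=lambda m: METHODS.index(m) if m in METHODS else len(METHODS),
        )
        for method in ordered:
            info = manifest["methods"][method]
            specs[method] = ModelSpec(method=method, chosen=info["chosen"])
            means = manifest["metrics"][method]
            reports[method] = MetricsReport(method, means, {m: float("nan") for m in means}, [])
            bundles[method] = joblib.load(path / f"{method}.joblib")
        return cls(
            None,
            specs,
            reports,
            bundles,
            manifest["seed"],
            feature_params=manifest["feature_params"],
        )

    def summary(self) -> str:
        lines = ["Consensus antibacterial activity model", "=" * 54]
        if self.model is not None:
            lines.append(
                f"negative sets: {self.model.benchmark.n_repeats}   "
                f"positives: {len(self.model.benchmark.positives)}   seed: {self.seed}"
            )
        for method in self.methods:
            spec = self.specs[method]
            lines.append("")
            lines.append(f"[{method}]  chosen: {spec.chosen}")
            rep = self.reports[method]
            for m in METRIC_NAMES:
                lines.append(f"  {m:<12s} {rep.means[m]:.3f} +/- {rep.sds[m]:.3f}")
        return "\n".join(lines)

    def plot_metric_panel(self, ax=None):
        """Bar panel of metric means with sd whiskers, one group per method."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        width = 0.8 / len(self.methods)
        x = np.arange(len(METRIC_NAMES))
        for k, method in enumerate(self.methods):
            rep = self.reports[method]
            means = [rep.means[m] for m in METRIC_NAMES]
            sds = [rep.sds[m] for m in METRIC_NAMES]
            ax.bar(x + k * width, means, width, yerr=sds, label=method, capsize=2)
        ax.set_xticks(x + width)
        ax.set_xticklabels(METRIC_NAMES, rotation=30)
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax


class ConsensusActivityModel:
    """The three-classifier consensus model over a benchmark dataset.

    Parameters
    ----------
    benchmark : BenchmarkDataset
        Positives plus balanced negative sets with path-fingerprint features.
    methods : sequence of str
        Subset of ("svm", "rf", "mlp").
    grids : dict, optional
        Per-method hyperparameter grids; defaults include each method's
        reference optimum.
    """

    def __init__(self, benchmark: BenchmarkDataset, methods=METHODS, grids=None):
        if benchmark.n_repeats == 0:
            raise ValueError("benchmark has no negative sets")
        self.benchmark = benchmark
        self.methods = tuple(methods)
        self.grids = grids or {}

    @classmethod
    def from_records(cls, records, n_repeats: int = 10, seed: int = 0, **kwargs):
        from .benchmark import build_benchmark

        return cls(build_benchmark(records, n_repeats=n_repeats, seed=seed), **kwargs)

    def fit(
        self,
        seed: int = 0,
        test_frac: float = 0.2,
        k: int = 5,
        do_grid_search: bool = False,
        grid_search_repeats: int = 10,
        chosen: dict | None = None,
    ) -> ConsensusResults:
        """Fit all methods across all negative sets.

        When ``do_grid_search`` is true, hyperparameters are searched once per
        method on the first negative-set composite (repeated k-fold CV with
        AUC tie-break); otherwise ``chosen`` (default: the reference optima)
        is used directly.  Each negative set then contributes one evaluation
        run — k-fold CV accuracy on the train/validation portion plus a full
        metric panel on its 20% test split — and one final member model fitted
        on the complete composite.  Metrics are aggregated as mean +/- sd.
        """
        chosen = dict(DEFAULT_CHOSEN, **(chosen or {}))
        specs: dict[str, ModelSpec] = {}
        reports: dict[str, MetricsReport] = {}
        bundles: dict[str, list] = {}

        for method in self.methods:
            spec = ModelSpec(method=method, grid=self.grids.get(method, {}))
            if do_grid_search:
                X, y = self.benchmark.features(0)
                train_val, test = split_dataset(X, y, test_frac=test_frac, seed=seed)
                spec = grid_search_cv(
                    train_val, test, spec, k=k,
                    n_repeats=grid_search_repeats, seed=seed,
                )
            else:
                spec.chosen = dict(chosen[method])

            runs = []
            members = []
            for set_idx in range(self.benchmark.n_repeats):
                X, y = self.benchmark.features(set_idx)
                run_seed = seed + 1000 * set_idx
                (X_tv, y_tv), (X_te, y_te) = split_dataset(
                    X, y, test_frac=test_frac, seed=run_seed
                )
                est = make_estimator(method, spec.chosen, run_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X_tv, y_tv)
                panel = evaluate(est, X_te, y_te)
                panel["cv_accuracy"] = _cv_accuracy(
                    method, spec.chosen, X_tv, y_tv, k, run_seed
                )
                runs.append(panel)
                final = make_estimator(method, spec.chosen, run_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    final.fit(X, y)
                members.append(final)

            means = {m: float(np.mean([r[m] for r in runs])) for m in METRIC_NAMES}
            sds = {m: float(np.std([r[m] for r in runs])) for m in METRIC_NAMES}
            means["cv_accuracy"] = float(np.mean([r["cv_accuracy"] for r in runs]))
            sds["cv_accuracy"] = float(np.std([r["cv_accuracy"] for r in runs]))
            specs[method] = spec
            reports[method] = MetricsReport(method, means, sds, runs)
            bundles[method] = members

        return ConsensusResults(self, specs, reports, bundles, seed)
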