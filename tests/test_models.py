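"""Splitting, grid search, AUC, metric panel and the consensus fit."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import abxscreen.models as models
from abxscreen.benchmark import build_benchmark
from abxscreen.models import (
    DEFAULT_GRIDS,
    ConsensusActivityModel,
    ModelSpec,
    confusion_metrics,
    evaluate,
    grid_search_cv,
    roc_auc,
    split_dataset,
)


class TestSplitDataset:
    def test_stratification_arithmetic(self):
        X = np.arange(200).reshape(-1, 1).astype(float)
        y = np.array([1] * 100 + [0] * 100)
        (X_tv, y_tv), (X_te, y_te) = split_dataset(X, y, test_frac=0.2, seed=0)
        assert len(y_tv) == 160 and len(y_te) == 40
        assert y_te.sum() == 20

    def test_seed_replay(self):
        X = np.arange(60).reshape(-1, 1).astype(float)
        y = np.array([1, 0] * 30)
        a = split_dataset(X, y, seed=4)
        b = split_dataset(X, y, seed=4)
        assert np.array_equal(a[1][0], b[1][0])

    def test_degenerate_fractions_and_classes(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValueError):
            split_dataset(X, np.array([1] * 5 + [0] * 5), test_frac=0.0)
        with pytest.raises(ValueError):
            split_dataset(X, np.ones(10, dtype=int))


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_partial_concordance(self):
        assert roc_auc([0.9, 0.3, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 8, [1, 0] * 4) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_trapezoidal_integration(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(10, 80))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            # ties included on purpose
            scores = np.round(rng.random(n), 1)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = np.array([1] * 15 + [0] * 25)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(
            1.0, abs=1e-12
        )


class TestMetricPanel:
    def test_reference_confusion_matrix(self):
        m = confusion_metrics(tp=850, tn=854, fp=146, fn=150)
        assert m["accuracy"] == pytest.approx(0.852, abs=5e-4)
        assert m["sensitivity"] == pytest.approx(0.850, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.854, abs=5e-4)
        assert m["precision"] == pytest.approx(850 / 996, abs=1e-12)
        assert m["f1"] == pytest.approx(1700 / 1996, abs=1e-12)
        assert m["mse"] == pytest.approx(0.148, abs=5e-4)
        assert m["accuracy"] + m["mse"] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_and_degenerate_predictors(self):
        perfect = confusion_metrics(tp=10, tn=10, fp=0, fn=0)
        assert all(perfect[k] == 1.0 for k in ("accuracy", "precision", "sensitivity", "specificity", "f1"))
        assert perfect["mse"] == 0.0
        allpos = confusion_metrics(tp=10, tn=0, fp=10, fn=0)
        assert allpos["sensitivity"] == 1.0
        assert allpos["specificity"] == 0.0
        assert allpos["accuracy"] == 0.5

    def test_f1_consistent_with_defining_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 500, size=4))
            m = confusion_metrics(tp, tn, fp, fn)
            prec, sens = m["precision"], m["sensitivity"]
            assert m["f1"] == pytest.approx(2 * prec * sens / (prec + sens), abs=1e-12)
            assert m["accuracy"] + m["mse"] == pytest.approx(1.0, abs=1e-12)


class _StubEstimator:
    def __init__(self, probs):
        self.probs = np.asarray(probs)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = self.probs[: len(X)]
        return np.column_stack([1 - p, p])


class TestGridSearch:
    def test_higher_accuracy_wins(self, monkeypatch):
        accs = {(("C", 1.0),): 0.84, (("C", 10.0),): 0.86}
        monkeypatch.setattr(
            models,
            "_cv_accuracy",
            lambda method, params, X, y, k, seed: accs[tuple(sorted(params.items()))],
        )
        spec = ModelSpec("svm", grid={"C": [1.0, 10.0]})
        dummy = (np.zeros((4, 2)), np.array([0, 0, 1, 1]))
        out = grid_search_cv(dummy, dummy, spec, k=2, n_repeats=3, seed=0)
        assert out.chosen == {"C": 10.0}

    def test_accuracy_tie_broken_by_test_auc(self, monkeypatch):
        monkeypatch.setattr(
            models, "_cv_accuracy", lambda *a, **k: 0.85
        )
        aucs = {1.0: [0.1, 0.9, 0.2, 0.8], 10.0: [0.9, 0.1, 0.8, 0.2]}

        def fake_estimator(method, params, seed):
            return _StubEstimator(aucs[params["C"]])

        monkeypatch.setattr(models, "make_estimator", fake_estimator)
        spec = ModelSpec("svm", grid={"C": [1.0, 10.0]})
        X = np.zeros((4, 2))
        y = np.array([1, 0, 1, 0])  # C=10 scores concordant with labels
        out = grid_search_cv((X, y), (X, y), spec, k=2, n_repeats=2, seed=0)
        assert out.chosen == {"C": 10.0}

    def test_empty_grid_rejected(self):
        spec = ModelSpec("svm", grid={"C": []})
        with pytest.raises(ValueError):
            grid_search_cv(
                (np.zeros((4, 1)), np.array([0, 1, 0, 1])),
                (np.zeros((4, 1)), np.array([0, 1, 0, 1])),
                spec,
            )

    def test_default_grids_contain_reference_optima(self):
        assert 0.01 in DEFAULT_GRIDS["svm"]["gamma"] and 10.0 in DEFAULT_GRIDS["svm"]["C"]
        assert 750 in DEFAULT_GRIDS["rf"]["n_estimators"]
        assert 512 in DEFAULT_GRIDS["mlp"]["hidden_layer_sizes"]
        assert 1e-4 in DEFAULT_GRIDS["mlp"]["alpha"]

    def test_search_on_separable_data_returns_grid_member(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(3, 0.3, (30, 4))])
        y = np.array([0] * 30 + [1] * 30)
        spec = ModelSpec("svm", grid={"C": [1.0, 10.0], "gamma": [0.01]})
        out = grid_search_cv((X, y), (X, y), spec, k=3, n_repeats=1, seed=1)
        assert out.chosen["C"] in (1.0, 10.0)
        assert out.chosen["gamma"] == 0.01


@pytest.fixture(scope="module")
def fitted(small_bundle):
    bm = build_benchmark(small_bundle.records, n_repeats=4, seed=3)
    model = ConsensusActivityModel(bm)
    chosen = {
        "svm": {"gamma": 0.01, "C": 10.0},
        "rf": {"n_estimators": 60},
        "mlp": {"hidden_layer_sizes": 32, "alpha": 1e-4},
    }
    return bm, model.fit(seed=3, chosen=chosen)


class TestConsensusFit:
    def test_one_member_model_per_negative_set(self, fitted):
        bm, res = fitted
        for method in ("svm", "rf", "mlp"):
            assert res.n_member_fits(method) == bm.n_repeats

    def test_metric_identities_every_run(self, fitted):
        _, res = fitted
        for method, report in res.reports.items():
            for run in report.per_run:
                assert run["accuracy"] + run["mse"] == pytest.approx(1.0, abs=1e-12)
                tp, tn, fp, fn = run["confusion"]
                P, N = tp + fn, tn + fp
                assert run["sensitivity"] * P + run["specificity"] * N == pytest.approx(
                    tp + tn, abs=1e-9
                )

    def test_summary_and_frame(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "svm" in text and "accuracy" in text
        frame = res.metrics_frame()
        assert "auc_mean" in frame.columns
        assert set(frame.index) == {"svm", "rf", "mlp"}

    def test_predict_proba_shape_and_config_guard(self, fitted):
        from abxscreen.chem import parse_smiles
        from abxscreen.fingerprints import circular_fingerprint, path_fingerprint

        _, res = fitted
        fps = [path_fingerprint(parse_smiles(s)) for s in ("c1ccncc1C", "CCCCO")]
        frame = res.predict_proba(fps)
        assert frame.shape == (2, 3)
        assert ((frame >= 0) & (frame <= 1)).all().all()
        with pytest.raises(ValueError):
            res.predict_proba([circular_fingerprint(parse_smiles("CC"))])

    def test_evaluate_guards(self, fitted):
        _, res = fitted
        member = res._bundles["rf"][0]
        with pytest.raises(ValueError):
            evaluate(member, np.zeros((0, 1024)), np.array([]))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("gbrt")

    def test_bundle_save_and_reload_predicts_identically(self, fitted, tmp_path):
        from abxscreen.chem import parse_smiles
        from abxscreen.fingerprints import path_fingerprint
        from abxscreen.models import ConsensusResults

        _, res = fitted
        res.save(tmp_path / "bundle")
        back = ConsensusResults.load(tmp_path / "bundle")
        assert back.feature_params == res.feature_params
        assert {m: s.chosen for m, s in back.specs.items()} == {
            m: s.chosen for m, s in res.specs.items()
        }
        fps = [path_fingerprint(parse_smiles(s)) for s in ("c1ccncc1C", "CCCCO")]
        assert back.predict_proba(fps).equals(res.predict_proba(fps))
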