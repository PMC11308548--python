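"""MCC, splitting, scaling, nested CV, model selection, persistence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from traitpred import synth
from traitpred.learn import (
    DEFAULT_GRIDS,
    ClassifierBundle,
    FunctionClassifier,
    RegistryError,
    TrainConfig,
    UnstratifiableClassError,
    apply_scaler,
    choose_final_hp,
    compute_mcc,
    fit_scaler,
    load_registry,
    mcc_score,
    nested_cv_grid_search,
    persist_registry,
    select_best,
    stratified_split,
    train_class_model,
    train_registry,
)

counts = st.integers(min_value=0, max_value=500)


class TestMCC:
    def test_perfect_prediction(self):
        assert compute_mcc(5, 0, 0, 5) == 1.0

    def test_zero_denominator_convention(self):
        assert compute_mcc(5, 5, 0, 0) == 0.0

    def test_hydrogenotrophic_validation_case(self):
        # 1 true positive, 9 false positives among 4,146 genomes
        expected = 4136 / math.sqrt(10 * 1 * 4145 * 4136)
        assert compute_mcc(1, 9, 0, 4136) == pytest.approx(expected)
        assert compute_mcc(1, 9, 0, 4136) == pytest.approx(0.316, abs=5e-4)

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            compute_mcc(-1, 0, 0, 5)

    @given(tp=counts, fp=counts, fn=counts, tn=counts)
    @settings(derandomize=True, max_examples=200)
    def test_swap_symmetry_and_inversion_antisymmetry(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = compute_mcc(tp, fp, fn, tn)
        assert compute_mcc(tn, fn, fp, tp) == pytest.approx(m)
        assert compute_mcc(fn, tn, tp, fp) == pytest.approx(-m)

    def test_agrees_with_pearson_of_binary_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            y_true = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
            y_pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp),
                           np.zeros(tn)]
            pearson = np.corrcoef(y_true, y_pred)[0, 1]
            assert compute_mcc(tp, fp, fn, tn) == pytest.approx(
                pearson, abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, size=300)
        y_pred = rng.integers(0, 2, size=300)
        assert mcc_score(y_true, y_pred) == pytest.approx(
            matthews_corrcoef(y_true, y_pred)
        )


class TestSplit:
    def test_proportions_preserved(self):
        y = np.r_[np.ones(10), np.zeros(90)]
        X = np.zeros((100, 2))
        train, test = stratified_split(X, y, seed=4)
        assert y[train].sum() == 8 and len(train) == 80
        assert y[test].sum() == 2 and len(test) == 20
        assert sorted(np.r_[train, test].tolist()) == list(range(100))

    def test_all_negative_class_errors(self):
        with pytest.raises(UnstratifiableClassError):
            stratified_split(np.zeros((20, 2)), np.zeros(20))

    def test_deterministic_per_seed(self):
        y = np.r_[np.ones(6), np.zeros(30)]
        X = np.zeros((36, 1))
        a = stratified_split(X, y, seed=9)
        b = stratified_split(X, y, seed=9)
        c = stratified_split(X, y, seed=10)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()
        assert not (a[0] == c[0]).all()


class TestScaler:
    def test_closed_form_zscore(self):
        params = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
        out = apply_scaler(params, np.array([[2.0], [4.0], [6.0]]))
        assert out.ravel() == pytest.approx(
            [-1.224744871, 0.0, 1.224744871]
        )

    def test_constant_column_maps_to_zero(self):
        params = fit_scaler(np.full((5, 1), 7.0))
        assert params.sd[0] == 1.0
        assert apply_scaler(params, np.full((3, 1), 7.0)).ravel().tolist() \
            == [0.0, 0.0, 0.0]

    def test_train_columns_centered_unit_variance(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(3.0, size=(50, 8)).astype(float)
        params = fit_scaler(X)
        Z = apply_scaler(params, X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-9)

    def test_feature_count_mismatch_errors(self):
        params = fit_scaler(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            apply_scaler(params, np.zeros((2, 5)))


def _separable(n=60, seed=0, weak=False):
    """Linearly separable two-feature fixture."""
    rng = np.random.default_rng(seed)
    n_pos = n // 3
    X = rng.normal(0, 1, size=(n, 2))
    y = np.r_[np.ones(n_pos), np.zeros(n - n_pos)].astype(int)
    shift = 1.5 if weak else 6.0
    X[y == 1] += shift
    return X, y


class TestNestedCV:
    def test_single_combination_returned_k_times(self):
        X, y = _separable()
        grid = [{"C": 1.0, "penalty": "l2"}]
        results = nested_cv_grid_search(X, y, "LR", grid, k=3, seed=0)
        assert len(results) == 3
        assert all(r.hp == grid[0] for r in results)

    def test_dominant_hyperparameter_wins_all_folds(self):
        # l1 at C=0.001 zeroes every coefficient -> majority-class model;
        # C=1 separates: it must win every outer fold
        X, y = _separable(n=90, seed=1)
        grid = [{"C": 0.001, "penalty": "l1"}, {"C": 1.0, "penalty": "l1"}]
        results = nested_cv_grid_search(X, y, "LR", grid, k=3, seed=2)
        assert all(r.hp["C"] == 1.0 for r in results)
        assert all(r.outer_mcc == 1.0 for r in results)

    def test_stratification_of_positives_across_folds(self):
        X = np.random.default_rng(0).normal(size=(45, 2))
        y = np.r_[np.ones(9), np.zeros(36)].astype(int)
        from sklearn.model_selection import StratifiedKFold

        outer = StratifiedKFold(n_splits=3, shuffle=True, random_state=7)
        for _, te in outer.split(X, y):
            assert y[te].sum() == 3

    def test_too_few_positives_for_folds_errors(self):
        X = np.zeros((20, 2))
        y = np.r_[np.ones(2), np.zeros(18)].astype(int)
        with pytest.raises(UnstratifiableClassError, match="smaller"):
            nested_cv_grid_search(X, y, "LR",
                                  [{"C": 1.0, "penalty": "l2"}], k=3)

    def test_final_hp_rule_prefers_outer_then_inner_then_order(self):
        from traitpred.learn import CVResult

        results = [
            CVResult({"C": 1}, inner_mean_mcc=0.5, outer_mcc=0.7,
                     grid_index=0),
            CVResult({"C": 2}, inner_mean_mcc=0.9, outer_mcc=0.8,
                     grid_index=1),
            CVResult({"C": 3}, inner_mean_mcc=0.95, outer_mcc=0.8,
                     grid_index=2),
        ]
        assert choose_final_hp(results) == {"C": 3}
        results[2] = CVResult({"C": 3}, 0.9, 0.8, 2)
        assert choose_final_hp(results) == {"C": 2}


class TestTrainAndSelect:
    def test_separable_fixture_training_mcc_one(self):
        X, y = _separable()
        model = train_class_model(X, y, "LR", {"C": 1.0, "penalty": "l2"})
        assert mcc_score(y, model.predict(X)) == 1.0

    def test_label_shuffle_gives_null_mcc(self):
        rng = np.random.default_rng(21)
        mccs = []
        for rep in range(20):
            X = rng.normal(size=(80, 5))
            y = np.r_[np.ones(20), np.zeros(60)].astype(int)
            rng.shuffle(y)
            tr, te = stratified_split(X, y, seed=rep)
            model = train_class_model(X[tr], y[tr], "LR",
                                      {"C": 1.0, "penalty": "l2"})
            mccs.append(mcc_score(y[te], model.predict(X[te])))
        assert -0.3 <= float(np.mean(mccs)) <= 0.3

    def test_unknown_algorithm_errors(self):
        with pytest.raises(ValueError):
            train_class_model(np.zeros((4, 2)), np.array([0, 1, 0, 1]),
                              "XGB", {})

    def test_nn_without_backend_raises_backend_missing(self):
        try:
            import tensorflow  # noqa: F401
            pytest.skip("keras backend present; error path not reachable")
        except ImportError:
            pass
        with pytest.raises(RuntimeError, match="backend missing"):
            train_class_model(np.zeros((8, 2)),
                              np.array([0, 1] * 4), "NN",
                              {"dense_units": 8, "dropout_rate": 0.1})

    def test_select_best_argmax_and_tie_preference(self):
        class Stub:
            def __init__(self, pred):
                self._pred = np.asarray(pred)

            def predict(self, X):
                return self._pred

        y = np.array([1, 1, 0, 0])
        perfect = Stub([1, 1, 0, 0])
        wrong = Stub([0, 0, 1, 1])
        # argmax
        alg, _, _, mcc, scores = select_best(
            [("RF", wrong, {}), ("SVM", perfect, {}), ("LR", wrong, {})],
            np.zeros((4, 1)), y,
        )
        assert alg == "SVM" and mcc == 1.0
        # exact tie LR vs SVM -> LR preferred
        alg, *_ = select_best(
            [("SVM", perfect, {}), ("LR", perfect, {})],
            np.zeros((4, 1)), y,
        )
        assert alg == "LR"


class TestFunctionClassifier:
    def test_sklearn_params_protocol(self):
        clf = FunctionClassifier(seed=3)
        params = clf.get_params()
        assert params["seed"] == 3
        clf.set_params(cv_folds=3)
        assert clf.cv_folds == 3

    def test_fit_on_separable_data(self, fast_config):
        X, y = _separable(n=90, seed=5)
        clf = FunctionClassifier(grids=fast_config.grids, seed=5).fit(X, y)
        assert clf.test_mcc_ == 1.0
        assert set(clf.candidate_scores_) == {"LR", "SVM", "RF"}
        assert (clf.predict(X) == y).all()

    def test_no_test_set_leakage(self, fast_config):
        """Scaler and model are exactly reproducible from the training
        partition alone — the test split contributes nothing to the fit."""
        X, y = _separable(n=90, seed=6)
        clf = FunctionClassifier(grids=fast_config.grids, seed=6).fit(X, y)
        tr = clf.train_indices_
        scaler = fit_scaler(X[tr])
        assert np.allclose(scaler.mean, clf.scaler_.mean)
        assert np.allclose(scaler.sd, clf.scaler_.sd)
        refit = train_class_model(scaler.apply(X[tr]), y[tr],
                                  clf.algorithm_, clf.hyperparameters_,
                                  seed=6)
        assert np.allclose(refit.coef_, clf.model_.coef_)


@pytest.fixture(scope="module")
def small_world(fast_config):
    truth = synth.make_default_truth(n_classes=3, seed=17)
    _, _, ds = synth.synth_dataset(truth, n_genomes=120,
                                   n_background_kos=60)
    registry = train_registry(ds, fast_config)
    return truth, ds, registry


class TestRegistry:
    def test_one_bundle_per_class(self, small_world):
        _, ds, registry = small_world
        assert set(registry.bundles) == set(ds.class_names)
        assert all(b.feature_order == ds.feature_order
                   for b in registry.bundles.values())

    def test_unstratifiable_class_skipped_not_fatal(self, fast_config):
        truth = synth.make_default_truth(n_classes=2, seed=18)
        _, _, ds = synth.synth_dataset(truth, n_genomes=80,
                                       n_background_kos=40)
        ds.labels["impossible"] = 0
        ds.labels.loc[ds.labels.index[0], "impossible"] = 1
        registry = train_registry(ds, fast_config)
        assert "impossible" not in registry.bundles
        assert "impossible" in registry.manifest["skipped_classes"]

    def test_persistence_round_trip_bit_identical_calls(self, small_world,
                                                        tmp_path):
        _, ds, registry = small_world
        persist_registry(registry, tmp_path / "reg")
        loaded = load_registry(tmp_path / "reg")
        X = ds.features.values[:50].astype(float)
        for name, bundle in registry.bundles.items():
            assert (bundle.predict(X) == loaded.bundles[name].predict(X)
                    ).all()
        assert loaded.manifest["dataset_sha256"] == \
            registry.manifest["dataset_sha256"]
        assert loaded.manifest["seed"] == registry.manifest["seed"]

    def test_corrupted_artifact_errors(self, small_world, tmp_path):
        _, _, registry = small_world
        persist_registry(registry, tmp_path / "reg")
        victim = next((tmp_path / "reg").glob("*.joblib"))
        victim.write_bytes(b"not a joblib payload")
        with pytest.raises(RegistryError):
            load_registry(tmp_path / "reg")

    def test_version_mismatch_errors(self, small_world, tmp_path):
        import json

        _, _, registry = small_world
        persist_registry(registry, tmp_path / "reg")
        manifest = json.loads((tmp_path / "reg" / "manifest.json").read_text())
        manifest["format_version"] = 999
        (tmp_path / "reg" / "manifest.json").write_text(
            json.dumps(manifest)
        )
        with pytest.raises(RegistryError, match="version"):
            load_registry(tmp_path / "reg")


class TestConfig:
    def test_from_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "config.yaml"
        p.write_text("seed: 42\ncv_folds: 3\nalgorithms: [LR, SVM]\n"
                     "mcc_success_threshold: 0.7\n")
        cfg = TrainConfig.from_yaml(p)
        assert cfg.seed == 42 and cfg.algorithms == ("LR", "SVM")

    def test_default_grids_cover_tuned_dimensions(self):
        assert {"C", "penalty"} == set(DEFAULT_GRIDS["LR"][0])
        assert {"n_trees", "max_features_rule"} == set(DEFAULT_GRIDS["RF"][0])
        assert {"kernel", "C"} == set(DEFAULT_GRIDS["SVM"][0])
        assert {"dense_units", "dropout_rate"} == set(DEFAULT_GRIDS["NN"][0])
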