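import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import regenne as rg
from regenne.containers import PathwayCollection
from regenne.estimator import PathwayCNNClassifier
from regenne.training import load_model, save_model, screen_pathways


def _toy_data(seed=0, n=60, separable=True):
    rng = np.random.default_rng(seed)
    coll = PathwayCollection.from_mapping(
        {"PA": [f"A{i}" for i in range(6)], "PB": [f"B{i}" for i in range(6)]}
    )
    latent = rng.standard_normal(n)
    a = latent[:, None] + 0.5 * rng.standard_normal((n, 6))
    b = rng.standard_normal((n, 6))
    X = pd.DataFrame(
        np.hstack([a, b]),
        columns=[f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)],
    )
    y = (
        (latent > 0).astype(int)
        if separable
        else rng.integers(0, 2, n)
    )
    return X, y, coll


class TestFit:
    def test_learning_reduces_training_cross_entropy(self):
        X, y, coll = _toy_data()
        clf = PathwayCNNClassifier(pathways=coll, epochs=30, random_state=0)
        clf.fit(X, y)
        assert clf.training_log_[-1]["cross_entropy"] < clf.training_log_[0]["cross_entropy"]

    def test_zero_epochs_keeps_initialization(self):
        X, y, coll = _toy_data()
        clf0 = PathwayCNNClassifier(pathways=coll, epochs=0, random_state=1)
        clf0.fit(X, y)
        clf1 = PathwayCNNClassifier(pathways=coll, epochs=0, random_state=1)
        clf1.fit(X, y)
        for w0, w1 in zip(clf0.net_.get_weights(), clf1.net_.get_weights()):
            np.testing.assert_array_equal(w0, w1)
        assert clf0.training_log_ == []

    def test_same_seed_reproduces_training_log(self):
        X, y, coll = _toy_data()
        logs = []
        for _ in range(2):
            clf = PathwayCNNClassifier(pathways=coll, epochs=8, random_state=5)
            clf.fit(X, y)
            logs.append(clf.training_log_)
        assert logs[0] == logs[1]

    def test_training_log_length_and_identity(self):
        X, y, coll = _toy_data()
        clf = PathwayCNNClassifier(
            pathways=coll, epochs=6, lambda_cca=0.3, cca_dim=2, random_state=2
        )
        clf.fit(X, y)
        assert len(clf.training_log_) == 6
        for entry in clf.training_log_:
            assert entry["total"] == pytest.approx(
                entry["cross_entropy"] - 0.3 * entry["cca_penalty"], abs=1e-12
            )

    def test_lambda_zero_log_is_pure_cross_entropy(self):
        X, y, coll = _toy_data()
        clf = PathwayCNNClassifier(pathways=coll, epochs=4, lambda_cca=0.0, random_state=0)
        clf.fit(X, y)
        for entry in clf.training_log_:
            assert entry["cca_penalty"] == 0.0
            assert entry["total"] == entry["cross_entropy"]

    def test_single_pathway_with_cca_warns(self):
        X, y, coll = _toy_data()
        single = PathwayCollection.from_mapping({"PA": list(coll.genes("PA"))})
        clf = PathwayCNNClassifier(pathways=single, epochs=1, lambda_cca=0.5, random_state=0)
        with pytest.warns(RuntimeWarning, match="single pathway"):
            clf.fit(X, y)
        assert all(e["cca_penalty"] == 0.0 for e in clf.training_log_)

    def test_non_binary_labels_rejected(self):
        X, y, coll = _toy_data()
        with pytest.raises(ValueError, match="binary"):
            PathwayCNNClassifier(pathways=coll, epochs=1).fit(X, np.zeros(len(y)))

    def test_cca_dim_capped_at_branch_dimension(self):
        X, y, coll = _toy_data()
        clf = PathwayCNNClassifier(
            pathways=coll, epochs=1, cca_dim=999, n_filters=4, random_state=0
        )
        clf.fit(X, y)
        assert clf.cca_dim_ == min(clf.net_.feature_dims)


class TestPredict:
    def test_probabilities_complementary_and_in_range(self, tiny_fitted):
        clf, X, y = tiny_fitted
        p = clf.predict_proba(X)
        assert np.all(p > 0) and np.all(p < 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_duplicated_sample_duplicated_probability(self, tiny_fitted):
        clf, X, y = tiny_fitted
        X2 = pd.concat([X.iloc[[0]], X.iloc[[0]]])
        p = clf.predict_proba(X2)
        assert p[0, 1] == p[1, 1]

    def test_column_order_irrelevant_for_dataframe_input(self, tiny_fitted):
        clf, X, y = tiny_fitted
        shuffled = X[list(X.columns[::-1])]
        np.testing.assert_allclose(
            clf.predict_proba(X), clf.predict_proba(shuffled), atol=1e-12
        )

    def test_missing_gene_rejected(self, tiny_fitted):
        clf, X, y = tiny_fitted
        with pytest.raises(ValueError, match="lacks"):
            clf.predict_proba(X.drop(columns=["A0"]))

    def test_predict_returns_original_labels(self):
        X, y, coll = _toy_data()
        ylab = np.where(y == 1, "late", "early")
        clf = PathwayCNNClassifier(pathways=coll, epochs=10, random_state=0)
        clf.fit(X, ylab)
        assert set(clf.predict(X)) <= {"early", "late"}
        assert list(clf.classes_) == ["early", "late"]


class TestSklearnProtocol:
    def test_get_set_params_and_clone(self):
        clf = PathwayCNNClassifier(pathways={"P": ["G1"]}, epochs=3, lambda_cca=0.2)
        cloned = clone(clf)
        assert cloned.get_params()["epochs"] == 3
        cloned.set_params(lambda_cca=0.0)
        assert cloned.lambda_cca == 0.0 and clf.lambda_cca == 0.2

    def test_works_inside_cross_val_score(self):
        from sklearn.model_selection import cross_val_score

        X, y, coll = _toy_data(n=80)
        clf = PathwayCNNClassifier(pathways=coll, epochs=10, random_state=0)
        scores = cross_val_score(clf, X, y, cv=2, scoring="roc_auc")
        assert scores.shape == (2,) and np.all(scores >= 0) and np.all(scores <= 1)


class TestScreening:
    def test_causal_pathway_ranks_first(self):
        cfg = rg.SimConfig(
            n_samples=300,
            n_pathways=10,
            genes_per_pathway=8,
            overlap_frac=0.0,
            within_corr=0.6,
            causal_pathways=(0,),
            effect_size=3.0,
            seed=21,
        )
        bundle = rg.simulate_bundle(cfg)
        X = bundle.expression.to_dataframe()
        y = bundle.phenotype.to_array(bundle.expression.sample_ids)
        mc = rg.ModelConfig(epochs=30, seed=0)
        res = screen_pathways(X, y, bundle.pathways, config=mc, top_k=3)
        assert res.ranked[0][0] == bundle.causal_names[0]
        assert res.ranked[0][1] > 0.8
        assert res.selected[0] == bundle.causal_names[0]

    def test_ordering_matches_bruteforce_and_topk_cardinality(self, small_bundle):
        X = small_bundle.expression.to_dataframe()
        y = small_bundle.phenotype.to_array(small_bundle.expression.sample_ids)
        mc = rg.ModelConfig(epochs=3, seed=1)
        res = screen_pathways(X, y, small_bundle.pathways, config=mc, top_k=100)
        # all pathways selected when K exceeds the pathway count
        assert len(res.selected) == len(small_bundle.pathways)
        aucs = [a for _, a in res.ranked]
        assert aucs == sorted(aucs, reverse=True)
        # brute-force re-evaluation of each single pathway gives the same order
        redo = screen_pathways(X, y, small_bundle.pathways, config=mc, top_k=100)
        assert redo.ranked == res.ranked

    def test_duplicated_pathways_tie_broken_by_name(self):
        X, y, coll = _toy_data(n=80)
        dup = PathwayCollection.from_mapping(
            {
                "Z_COPY": list(coll.genes("PA")),
                "A_COPY": list(coll.genes("PA")),
            }
        )
        mc = rg.ModelConfig(epochs=5, seed=0)
        res = screen_pathways(X, y, dup, config=mc, top_k=2)
        names = [n for n, _ in res.ranked]
        aucs = [a for _, a in res.ranked]
        assert aucs[0] == aucs[1]  # identical blocks, identical AUC
        assert names == ["A_COPY", "Z_COPY"]  # name tie-break


class TestScreenedComposite:
    def test_screens_then_fits_on_selected_pathways(self):
        from regenne.training import ScreenedPathwayCNNClassifier

        X, y, coll = _toy_data(n=100)
        mc = rg.ModelConfig(epochs=5, seed=0)
        clf = ScreenedPathwayCNNClassifier(pathways=coll, top_k=1, config=mc, random_state=0)
        clf.fit(X, y)
        assert len(clf.screening_.selected) == 1
        assert [p.name for p in clf.estimator_.pathways_] == clf.screening_.selected
        p = clf.predict_proba(X)
        assert p.shape == (100, 2)

    def test_composes_with_cross_validation(self):
        from sklearn.model_selection import cross_val_score

        from regenne.training import ScreenedPathwayCNNClassifier

        X, y, coll = _toy_data(n=80)
        mc = rg.ModelConfig(epochs=3, seed=0)
        clf = ScreenedPathwayCNNClassifier(pathways=coll, top_k=1, config=mc, random_state=0)
        scores = cross_val_score(clf, X, y, cv=2, scoring="roc_auc")
        assert scores.shape == (2,)


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tiny_fitted, tmp_path):
        clf, X, y = tiny_fitted
        path = tmp_path / "model.npz"
        save_model(clf, path)
        back = load_model(path)
        np.testing.assert_allclose(
            back.predict_proba(X), clf.predict_proba(X), atol=1e-12
        )
        assert [p.name for p in back.pathways_] == [p.name for p in clf.pathways_]


class TestLossComponents:
    def test_identity_and_ablation(self, tiny_fitted):
        clf, X, y = tiny_fitted
        comp = clf.loss_components(X, y)
        assert comp["total"] == pytest.approx(
            comp["cross_entropy"] - clf.lambda_cca * comp["cca_penalty"], abs=1e-12
        )
        clf0 = clone(clf).set_params(lambda_cca=0.0, epochs=0)
        clf0.fit(X, y)
        comp0 = clf0.loss_components(X, y)
        assert comp0["total"] == comp0["cross_entropy"]
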