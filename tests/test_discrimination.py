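"""Model grid, cross-validation design, frequency ranking, Isomap."""

import numpy as np
import pandas as pd
import pytest

import rectodose as rd
from rectodose.discrimination import ModelResult, make_folds


def toy_features(n_patients=30, n_features=20, informative=False, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for cond in ("pre", "post"):
            base = rng.normal(0, 1, n_features)
            if informative and cond == "post":
                base[:3] += 3.0
            rows.append({"patient_id": f"P{p:03d}", "condition": cond,
                         **{f"f{j}": base[j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestFolds:
    def test_patient_grouping_keeps_pairs_together(self):
        df = toy_features()
        folds, _ = make_folds(df.patient_id, (df.condition == "post").astype(int),
                              seed=3)
        for _, te in folds:
            pids = df.patient_id.iloc[te]
            for pid in pids.unique():
                assert (df.patient_id == pid).sum() == (pids == pid).sum()

    def test_balanced_classes_in_every_fold(self):
        df = toy_features()
        y = (df.condition == "post").astype(int).to_numpy()
        folds, _ = make_folds(df.patient_id, y, seed=1)
        for _, te in folds:
            assert y[te].mean() == pytest.approx(0.5)


class TestFitEval:
    def test_separable_toy_perfect_auc(self):
        df = toy_features(informative=True, seed=2)
        res = rd.fit_eval("MIM", "logistic_regression", df, df.condition,
                          df.patient_id, seed=0)
        assert res.mean_auc == pytest.approx(1.0)

    def test_permuted_labels_near_chance(self):
        df = toy_features(seed=4)
        rng = np.random.default_rng(9)
        aucs = []
        for rep in range(50):
            labels = rng.permutation((df.condition == "post").astype(int).to_numpy())
            res = rd.fit_eval("MIM", "logistic_regression", df, labels,
                              df.patient_id, seed=rep)
            aucs.append(res.mean_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_same_seed_identical_result(self):
        df = toy_features(informative=True, seed=5)
        a = rd.fit_eval("MRMR", "random_forest", df, df.condition,
                        df.patient_id, seed=11)
        b = rd.fit_eval("MRMR", "random_forest", df, df.condition,
                        df.patient_id, seed=11)
        assert a.fold_aucs == b.fold_aucs
        assert a.fold_features == b.fold_features


class TestGrid:
    def test_reduced_registry_product(self):
        df = toy_features(informative=True, seed=6)
        res = rd.run_model_grid(df, df.condition, df.patient_id, seed=0,
                                selectors=["MIM", "fisher_score"],
                                classifiers=["logistic_regression", "naive_bayes",
                                             "knn"])
        assert len(res) == 6
        assert len({r.fold_hash for r in res}) == 1     # shared folds
        for r in res:
            assert len(r.fold_aucs) == 5
            assert all(0 <= a <= 1 for a in r.fold_aucs)
            assert all(len(f) == 20 for f in r.fold_features)


class TestDiscriminationGridEstimator:
    def test_fit_exposes_results_and_frequency(self):
        df = toy_features(informative=True, seed=8)
        grid = rd.DiscriminationGrid(selectors=["MIM", "t_score"],
                                     classifiers=["logistic_regression",
                                                  "naive_bayes"], seed=0)
        grid.fit(df, df.condition)
        assert len(grid.results_) == 4
        assert grid.best_model_.mean_auc == max(r.mean_auc for r in grid.results_)
        assert grid.best_model_.mean_auc > 0.9      # separable construction
        assert not grid.frequency_.empty

    def test_groups_required_without_patient_column(self):
        import numpy as np
        X = np.random.default_rng(0).normal(size=(20, 5))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError):
            rd.DiscriminationGrid().fit(X, y)


def _fake_result(selector, auc, fold_features):
    return ModelResult(selector=selector, classifier="clf",
                       fold_aucs=[auc] * 5, mean_auc=auc, pooled_auc=auc,
                       fold_features=fold_features, fold_hash="x")


class TestFrequency:
    def test_single_passing_model_full_frequency(self):
        res = [_fake_result("s1", 0.9, [["A", "B"]] * 5)]
        rep = rd.rank_feature_frequency(res, auc_min=0.8)
        assert rep.n_passing_models == 1
        assert rep.percentages["A"] == 100.0

    def test_counting_across_two_passing_models(self):
        res = [
            _fake_result("s1", 0.9, [["A"]] * 5),
            _fake_result("s2", 0.85, [["B"], ["B"], ["B"], ["B"], ["B"]]),
            _fake_result("s3", 0.5, [["C"]] * 5),       # below gate: ignored
        ]
        rep = rd.rank_feature_frequency(res, auc_min=0.8)
        assert rep.percentages["A"] == 50.0
        assert rep.percentages["B"] == 50.0
        assert "C" not in rep.counts.index

    def test_no_passing_models_flagged_empty(self):
        res = [_fake_result("s1", 0.6, [["A"]] * 5)]
        rep = rd.rank_feature_frequency(res, auc_min=0.8)
        assert rep.empty and rep.n_passing_models == 0
        assert rep.top10 == []

    def test_tie_break_alphabetical(self):
        res = [_fake_result("s1", 0.9, [["B", "A"]] * 5)]
        rep = rd.rank_feature_frequency(res, auc_min=0.8)
        assert list(rep.counts.index[:2]) == ["A", "B"]


class TestIsomap:
    def test_output_is_two_dimensional(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 10))
        emb = rd.isomap_embed(X, n_neighbors=5)
        assert emb.shape == (40, 2)

    def test_planar_points_recovered(self):
        # dense sampling so graph geodesics approximate straight lines
        rng = np.random.default_rng(1)
        plane = rng.uniform(-1, 1, (300, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        X = plane @ basis.T                       # isometric embedding in 10D
        emb = rd.isomap_embed(X, n_neighbors=15)
        d0 = np.linalg.norm(plane[:, None] - plane[None, :], axis=2)
        d1 = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        m = d0 > 0.3
        rel = np.abs(d1[m] - d0[m]) / d0[m]
        assert np.median(rel) < 0.05

    def test_duplicated_rows_coincide(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        X[10] = X[0]
        emb = rd.isomap_embed(X, n_neighbors=5)
        assert np.linalg.norm(emb[10] - emb[0]) < 1e-6

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            rd.isomap_embed(np.zeros((4, 3)), n_neighbors=5)
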