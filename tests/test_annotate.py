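"""The annotation framework against brute-force and rank-statistic oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import oracles
from atlasmap import (CellTypeAnnotator, ModelBundle, TrainingConfig,
                      annotation_auc, fit_celltype_model, label_clusters,
                      project, rank_genes_by_auc, select_gene_count,
                      stratified_split, train_bundle)
from atlasmap.annotate import (CellTypeModel, RankedGeneList, _effective_grid,
                               fit_single_gene_lr, rank_auc)
from atlasmap.qc import normalize


def _labels(counts: dict[str, int]) -> pd.Series:
    vals = sum(([t] * n for t, n in counts.items()), [])
    return pd.Series(vals, index=[f"c{i}" for i in range(len(vals))])


class TestStratifiedSplit:
    def test_seventy_thirty_per_type(self):
        train, test = stratified_split(_labels({"A": 10, "B": 20}), 0.7, seed=0)
        labels = _labels({"A": 10, "B": 20})
        assert (labels[train] == "A").sum() == 7 and (labels[test] == "A").sum() == 3
        assert (labels[train] == "B").sum() == 14 and (labels[test] == "B").sum() == 6
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(labels.index)

    def test_same_seed_reproduces_partition(self):
        labels = _labels({"A": 13, "B": 9, "C": 31})
        a = stratified_split(labels, 0.7, seed=5)
        b = stratified_split(labels, 0.7, seed=5)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])

    def test_per_type_proportion_within_one_cell(self):
        labels = _labels({"A": 7, "B": 11, "C": 15, "D": 28, "E": 100})
        train, _ = stratified_split(labels, 0.7, seed=1)
        for t, n in labels.value_counts().items():
            got = (labels[train] == t).sum()
            assert abs(got - 0.7 * n) <= 1

    def test_singleton_type_is_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            stratified_split(_labels({"A": 5, "B": 1}), 0.7, seed=0)


class TestGeneRanking:
    def test_perfectly_separating_gene_scores_auc_one(self):
        x = np.zeros((12, 2))
        x[:4, 0] = [3.0, 2.5, 4.0, 3.5]  # expressed only in the positive class
        labels = _labels({"pos": 4, "neg": 8})
        ranked = rank_genes_by_auc(x, labels, "pos", genes=["marker", "flat"],
                                   config=TrainingConfig(gene_auc_mode="resubstitution"))
        assert ranked.table.iloc[0]["gene"] == "marker"
        assert ranked.table.iloc[0]["auc"] == pytest.approx(1.0)

    def test_constant_gene_scores_half(self):
        x = np.full((10, 1), 2.5)
        labels = _labels({"pos": 3, "neg": 7})
        ranked = rank_genes_by_auc(x, labels, "pos", genes=["flat"],
                                   config=TrainingConfig(gene_auc_mode="resubstitution"))
        assert ranked.table.iloc[0]["auc"] == pytest.approx(0.5, abs=1e-12)

    def test_tied_values_match_brute_force_pair_counting(self):
        # positives {2, 3}, negatives {1, 2}: 3.5 of 4 pairs win -> 0.875
        assert oracles.brute_force_auc([2, 3], [1, 2]) == 0.875
        x = np.array([[2.0], [3.0], [1.0], [2.0]])
        labels = _labels({"pos": 2, "neg": 2})
        ranked = rank_genes_by_auc(x, labels, "pos", genes=["g"],
                                   config=TrainingConfig(gene_auc_mode="resubstitution"))
        assert ranked.table.iloc[0]["auc"] == pytest.approx(0.875, abs=1e-12)

    def test_resubstitution_auc_equals_sign_corrected_mann_whitney(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 50
            y = np.zeros(n, dtype=bool)
            y[: rng.integers(5, 45)] = True
            x = np.round(rng.normal(size=n) + y * rng.normal(), 1)  # rounding forces ties
            b0, b1 = fit_single_gene_lr(x, y)
            lr_auc = rank_auc(y, b0 + b1 * x)
            mw = oracles.mann_whitney_auc(y, x)
            expected = 0.5 if b1 == 0 else (mw if b1 > 0 else 1.0 - mw)
            assert abs(lr_auc - expected) < 1e-9

    def test_ranking_is_a_sorted_permutation_of_the_gene_universe(self, small_pair):
        adata = normalize(small_pair.reference)
        ranked = rank_genes_by_auc(adata, adata.obs["cell_type"], "T00",
                                   TrainingConfig(cv_folds=5, seed=4))
        assert sorted(ranked.table["gene"]) == sorted(adata.var_names)
        aucs = ranked.table["auc"].to_numpy()
        assert np.all(np.diff(aucs) <= 0)
        assert np.all((aucs >= 0) & (aucs <= 1))

    def test_cv_ranking_puts_true_markers_on_top(self, small_pair):
        adata = normalize(small_pair.reference)
        ranked = rank_genes_by_auc(adata, adata.obs["cell_type"], "T02",
                                   TrainingConfig(seed=4))
        top5 = set(ranked.top(5))
        assert len(top5 & set(small_pair.truth_reference.marker_sets["T02"])) >= 4

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            rank_genes_by_auc(np.ones((4, 1)), _labels({"A": 2, "B": 2}),
                              "C", genes=["g"])


class TestGeneCountSelection:
    def test_grid_truncated_and_deduplicated(self):
        assert _effective_grid((5, 10, 20, 50), 12) == [5, 10, 12]

    def test_selected_count_attains_trace_maximum_with_smallest_k(self, small_pair):
        adata = normalize(small_pair.reference)
        labels = adata.obs["cell_type"]
        config = TrainingConfig(gene_count_grid=(2, 5, 10, 30), cv_folds=5, seed=8)
        train, test = stratified_split(labels, 0.7, config.seed)
        ranked = rank_genes_by_auc(adata[train], labels[train], "T01", config)
        k, trace = select_gene_count(adata[train], adata[test],
                                     labels[train], labels[test], ranked, config)
        best = max(trace.values())
        assert trace[k] == best
        assert all(kk >= k for kk, v in trace.items() if v == best)

    def test_informative_marker_recovery(self):
        # one type with exactly 10 informative genes among 500
        from atlasmap import SimulationConfig, generate_atlas_pair
        pair = generate_atlas_pair(SimulationConfig(
            n_types=4, cells_per_type=150, n_genes=500, markers_per_type=10,
            batch_log_fc_sd=0.0, seed=77))
        adata = normalize(pair.reference)
        labels = adata.obs["cell_type"]
        config = TrainingConfig(cv_folds=5, seed=77)
        train, test = stratified_split(labels, 0.7, config.seed)
        ranked = rank_genes_by_auc(adata[train], labels[train], "T03", config)
        assert len(set(ranked.top(10)) & set(pair.truth_reference.marker_sets["T03"])) >= 8
        k, trace = select_gene_count(adata[train], adata[test],
                                     labels[train], labels[test], ranked, config)
        assert trace[k] >= max(trace.values()) - 0.02

    def test_single_class_test_set_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        ranked = RankedGeneList("A", pd.DataFrame({"gene": ["g0", "g1", "g2"],
                                                   "auc": [0.9, 0.8, 0.7]}))
        with pytest.raises(ValueError, match="single-class"):
            select_gene_count(x[:6], x[6:], _labels({"A": 3, "B": 3}),
                              pd.Series(["A"] * 4), ranked, genes=["g0", "g1", "g2"])


class TestFinalModel:
    def _fixture(self, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3))
        y = rng.random(20) < 0.5
        X[:, 0] += 0.8 * y  # informative but not separable
        return X, y

    def test_coefficients_match_independent_irls(self):
        X, y = self._fixture()
        labels = pd.Series(np.where(y, "A", "B"))
        ranked = RankedGeneList("A", pd.DataFrame({"gene": ["g0", "g1", "g2"],
                                                   "auc": [0.8, 0.6, 0.5]}))
        config = TrainingConfig(ridge_penalty=1e-4)
        model = fit_celltype_model(X, labels, ranked, 3, config,
                                   genes=["g0", "g1", "g2"])
        coef, intercept = oracles.irls_logistic(X, y, ridge=config.ridge_penalty)
        assert np.max(np.abs(model.coef - coef)) < 1e-6
        assert abs(model.intercept - intercept) < 1e-6

    def test_separable_marker_stays_finite_with_auc_one(self):
        X = np.zeros((12, 1))
        X[:5, 0] = 1.0
        labels = pd.Series(["A"] * 5 + ["B"] * 7)
        ranked = RankedGeneList("A", pd.DataFrame({"gene": ["g"], "auc": [1.0]}))
        model = fit_celltype_model(X, labels, ranked, 1, genes=["g"])
        assert np.isfinite(model.coef).all() and np.isfinite(model.intercept)
        probs = 1 / (1 + np.exp(-(model.intercept + X[:, 0] * model.coef[0])))
        assert np.all((probs >= 0) & (probs <= 1))
        assert rank_auc(labels.to_numpy() == "A", probs) == 1.0


class TestProjection:
    def _bundle(self):
        models = {
            "A": CellTypeModel("A", ["g1"], np.array([2.0]), -1.0, 1, 0.9, {1: 0.9}),
            "B": CellTypeModel("B", ["g1", "g2"], np.array([1.0, 1.0]), 0.0, 2, 0.8, {2: 0.8}),
        }
        return ModelBundle(models, ["g1", "g2"], TrainingConfig())

    def test_closed_form_probability(self):
        probs = project(self._bundle(), np.array([[0.5, 0.0]]), genes=["g1", "g2"])
        assert probs.loc[0, "A"] == pytest.approx(0.5)  # logistic(-1 + 2*0.5)

    def test_missing_gene_scored_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing genes scored as 0"):
            probs = project(self._bundle(), np.array([[0.5]]), genes=["g1"])
        assert probs.loc[0, "B"] == pytest.approx(1 / (1 + np.exp(-0.5)))

    def test_no_shared_genes_is_an_error(self):
        with pytest.raises(ValueError, match="no genes"):
            project(self._bundle(), np.array([[1.0]]), genes=["other"])

    def test_bundle_roundtrips_and_is_deterministic(self, small_pair, tmp_path):
        adata = normalize(small_pair.reference)
        config = TrainingConfig(gene_count_grid=(3, 8), cv_folds=4, seed=12)
        b1 = train_bundle(adata, adata.obs["cell_type"], config)
        b2 = train_bundle(adata, adata.obs["cell_type"], config)
        assert b1.to_json() == b2.to_json()
        path = tmp_path / "bundle.json"
        b1.save(path)
        loaded = ModelBundle.load(path)
        assert loaded.to_json() == b1.to_json()
        probs = project(loaded, adata)
        assert ((probs.to_numpy() >= 0) & (probs.to_numpy() <= 1)).all()

    def test_self_projection_auc_not_below_selection_auc(self, small_pair):
        adata = normalize(small_pair.reference)
        labels = adata.obs["cell_type"].astype(str)
        result = CellTypeAnnotator(adata, config=TrainingConfig(
            gene_count_grid=(3, 8, 15), cv_folds=5, seed=6)).fit()
        projection = result.annotate(adata, labels)
        for t, model in result.bundle.models.items():
            assert projection.label_auc[projection.labels[t]] >= model.test_auc - 0.05


class TestClusterLabeling:
    def test_mean_probability_arithmetic(self):
        probs = pd.DataFrame({"A": [0.2, 0.8], "B": [0.6, 0.6]}, index=["c1", "c2"])
        res = label_clusters(probs, pd.Series(["k", "k"], index=["c1", "c2"]))
        assert res.labels["k"] == "B"
        assert res.cluster_means.loc["k", "A"] == pytest.approx(0.5)

    def test_dominant_type_wins(self):
        probs = pd.DataFrame({"A": [0.9] * 4, "B": [0.1] * 4})
        res = label_clusters(probs, pd.Series(["k"] * 4))
        assert res.labels["k"] == "A" and not res.ambiguous["k"]

    def test_tie_breaks_by_type_id_and_flags_ambiguity(self):
        probs = pd.DataFrame({"B": [0.5], "A": [0.5]})
        res = label_clusters(probs, pd.Series(["k"]))
        assert res.labels["k"] == "A" and bool(res.ambiguous["k"])

    def test_cell_without_cluster_is_an_error(self):
        probs = pd.DataFrame({"A": [0.5, 0.5]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="without a cluster"):
            label_clusters(probs, pd.Series(["k"], index=["c1"]))

    def test_synthetic_clusters_recover_truth(self, small_pair):
        from atlasmap import annotate_query
        from atlasmap.qc import QCThresholds
        out = annotate_query(small_pair.reference, small_pair.query,
                             thresholds=QCThresholds(min_genes=30),
                             config=TrainingConfig(gene_count_grid=(5, 10, 30),
                                                   cv_folds=5, seed=2))
        labels = out.projection.labels
        assert (labels.index == labels.to_numpy()).mean() >= 0.95


class TestAnnotationAuc:
    def test_perfect_separation_gives_one(self):
        probs = pd.DataFrame({"A": [0.9, 0.8, 0.1, 0.2]})
        clusters = pd.Series(["k1", "k1", "k2", "k2"])
        labels = pd.Series({"k1": "A", "k2": "A"})
        # both clusters labelled A covers all cells -> undefined
        assert np.isnan(annotation_auc(probs, labels, clusters)["A"])
        labels = pd.Series({"k1": "A", "k2": "other"})
        probs["other"] = 1 - probs["A"]
        auc = annotation_auc(probs, labels, clusters)
        assert auc["A"] == 1.0 and auc["other"] == 1.0

    def test_shuffled_probabilities_average_half(self):
        rng = np.random.default_rng(2)
        clusters = pd.Series(["k1"] * 25 + ["k2"] * 25)
        labels = pd.Series({"k1": "A", "k2": "B"})
        base = rng.random(50)
        aucs = []
        for _ in range(100):
            probs = pd.DataFrame({"A": rng.permutation(base),
                                  "B": rng.permutation(base)})
            aucs.append(annotation_auc(probs, labels, clusters)["A"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_agrees_with_mann_whitney_oracle_on_fixture(self):
        rng = np.random.default_rng(3)
        probs = pd.DataFrame({"A": np.round(rng.random(50), 2),
                              "B": np.round(rng.random(50), 2)})
        clusters = pd.Series(["k1"] * 20 + ["k2"] * 30)
        labels = pd.Series({"k1": "A", "k2": "B"})
        auc = annotation_auc(probs, labels, clusters)
        y = clusters.map(labels) == "A"
        assert abs(auc["A"] - oracles.mann_whitney_auc(y, probs["A"])) < 1e-9
        assert abs(auc["A"] - roc_auc_score(y, probs["A"])) < 1e-9


class TestModelResultsInterface:
    def test_summary_lists_every_type(self, small_pair):
        adata = normalize(small_pair.reference)
        result = CellTypeAnnotator(adata, config=TrainingConfig(
            gene_count_grid=(3, 8), cv_folds=4, seed=1)).fit()
        summary = result.summary()
        assert sorted(summary.index) == sorted(set(adata.obs["cell_type"].astype(str)))
        assert (summary["test_auc"] > 0.5).all()

    def test_bidirectional_projection_recovers_types(self, small_pair):
        config = TrainingConfig(gene_count_grid=(5, 10, 30), cv_folds=5, seed=9)
        ref = normalize(small_pair.reference)
        qry = normalize(small_pair.query)
        forward = CellTypeAnnotator(ref, config=config).fit().annotate(
            qry, qry.obs["cell_type"].astype(str))
        reverse = CellTypeAnnotator(qry, config=config).fit().annotate(
            ref, ref.obs["cell_type"].astype(str))
        for res in (forward, reverse):
            assert (res.labels.index == res.labels.to_numpy()).all()
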