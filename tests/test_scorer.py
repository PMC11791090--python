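import numpy as np
import pandas as pd
import pytest

from manascore.datamodel import GeneSet, ValidationError
from manascore.normalize import lognormalize, quantile_normalize_bundle, impute
from manascore.scorer import (
    ScorerBundle,
    SinglePatientModel,
    build_ensemble,
    make_training_split,
    module_score,
    roc_auc,
    score_cells,
    ssgsea_score,
    train_scorer,
    train_single_patient,
)
from conftest import make_bundle


def _annotations(patients, labels):
    return pd.DataFrame(
        {
            "barcode": [f"bc{i}" for i in range(len(patients))],
            "patient_id": patients,
            "sample_id": "S",
            "tissue": "tumor",
            "clonotype_id": None,
            "antigen_label": labels,
            "response_label": "not_applicable",
        }
    )


def _separable_xy(n_per_class=50, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal([5, 5, 0], 0.2, size=(n_per_class, 3))
    neg = rng.normal([0, 0, 5], 0.2, size=(n_per_class, 3))
    X = np.vstack([pos, neg])
    y = np.array([1] * n_per_class + [0] * n_per_class)
    return X, y


class TestTrainingSplit:
    def test_eighty_twenty_arithmetic(self):
        ann = _annotations(["P1"] * 10, ["tumor_reactive"] * 10)
        train, test = make_training_split(ann, 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2
        assert sorted(set(train) | set(test)) == list(range(10))
        assert not set(train) & set(test)

    def test_stratum_of_five(self):
        labels = ["tumor_reactive"] * 5 + ["bystander"] * 10
        ann = _annotations(["P1"] * 15, labels)
        train, test = make_training_split(ann, 0.8, seed=2)
        pos_train = [i for i in train if i < 5]
        assert len(pos_train) == 4 and len(train) == 12

    def test_same_seed_same_split(self):
        labels = (["tumor_reactive"] * 20 + ["bystander"] * 30) * 2
        ann = _annotations(["P1"] * 50 + ["P2"] * 50, labels)
        a = make_training_split(ann, seed=3)
        b = make_training_split(ann, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_stratum_goes_to_training(self):
        ann = _annotations(["P1"] * 6, ["tumor_reactive"] + ["bystander"] * 5)
        with pytest.warns(UserWarning, match="wholly to training"):
            train, test = make_training_split(ann, seed=4)
        assert 0 in train and 0 not in test

    def test_unknown_labels_excluded(self):
        ann = _annotations(
            ["P1"] * 6, ["tumor_reactive", "bystander"] * 2 + ["unknown"] * 2
        )
        train, test = make_training_split(ann, seed=5)
        assert not {4, 5} & (set(train) | set(test))


class TestSinglePatientModel:
    @pytest.mark.parametrize("algorithm", ["random_forest", "logistic", "linear_clipped"])
    def test_separable_training_auc_is_one(self, algorithm):
        X, y = _separable_xy()
        model = train_single_patient(X, y, algorithm=algorithm, seed=0)
        auc, _ = roc_auc(model.predict_proba(X)[:, 1], y)
        assert auc == 1.0

    def test_permuted_labels_give_chance_auc(self):
        X, _ = _separable_xy(seed=1)
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(20):
            y = rng.permutation([1] * 50 + [0] * 50)
            model = train_single_patient(X, y, algorithm="logistic")
            auc, _ = roc_auc(model.predict_proba(X)[:, 1], y)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_deterministic_given_seed(self):
        X, y = _separable_xy(seed=2)
        p1 = train_single_patient(X, y, "random_forest", seed=7).predict_proba(X)
        p2 = train_single_patient(X, y, "random_forest", seed=7).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X, _ = _separable_xy()
        with pytest.raises(ValidationError, match="single class"):
            train_single_patient(X, np.ones(len(X)))

    def test_probabilities_in_unit_interval(self):
        X, y = _separable_xy(seed=3)
        for algorithm in ("random_forest", "logistic", "linear_clipped"):
            p = train_single_patient(X, y, algorithm).predict_proba(X * 10)
            assert ((p >= 0) & (p <= 1)).all()
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class _FixedModel(SinglePatientModel):
    """Member stub emitting a constant class-1 probability."""

    def __init__(self, p, patient_id, algorithm="random_forest", layer="norm"):
        super().__init__(algorithm=algorithm, patient_id=patient_id, layer=layer)
        self._p = p
        self.estimator_ = "stub"
        self.classes_ = np.array([0, 1])

    def predict_proba(self, X):
        p = np.full(len(np.asarray(X)), self._p)
        return np.column_stack([1 - p, p])


class TestVotingEnsemble:
    def test_mean_of_member_probabilities(self):
        probs = [0.2, 0.4, 0.9, 0.1, 0.5, 0.3]
        members = [
            _FixedModel(p, patient_id=f"P{i // 2}",
                        algorithm=["random_forest", "logistic"][i % 2])
            for i, p in enumerate(probs)
        ]
        ens = build_ensemble(members)
        out = ens.predict_proba(np.zeros((4, 3)))[:, 1]
        np.testing.assert_allclose(out, 0.4, atol=1e-12)

    def test_all_ones_and_identical_members(self):
        members = [
            _FixedModel(1.0, f"P{i // 2}", ["random_forest", "logistic"][i % 2])
            for i in range(6)
        ]
        assert build_ensemble(members).predict_proba(np.zeros((2, 3)))[0, 1] == 1.0

    def test_matches_explicit_member_average(self):
        # oracle: per-member predict then average, against the ensemble path
        X, y = _separable_xy(seed=4)
        rng = np.random.default_rng(4)
        members = []
        for pid in ("A", "B", "C"):
            rows = rng.choice(len(X), 60, replace=False)
            for alg in ("random_forest", "logistic"):
                m = SinglePatientModel(algorithm=alg, patient_id=pid, layer="norm")
                m.fit(X[rows], y[rows])
                members.append(m)
        ens = build_ensemble(members)
        expected = np.mean([m.predict_proba(X)[:, 1] for m in members], axis=0)
        np.testing.assert_allclose(ens.predict_proba(X)[:, 1], expected, atol=1e-12)

    def test_invalid_compositions_rejected(self):
        mk = lambda pid, alg, layer="norm": _FixedModel(0.5, pid, alg, layer)
        with pytest.raises(ValidationError, match="distinct patients"):
            build_ensemble([mk("A", "random_forest"), mk("A", "logistic")])
        with pytest.raises(ValidationError, match="layers"):
            build_ensemble(
                [mk("A", "random_forest"), mk("B", "random_forest", "imputed_qn")]
            )
        with pytest.raises(ValidationError, match="unbalanced"):
            build_ensemble(
                [mk("A", "random_forest"), mk("A", "logistic"), mk("B", "logistic")]
            )
        with pytest.raises(ValidationError, match="at least one"):
            build_ensemble([])


@pytest.fixture(scope="module")
def trained(small_cohort):
    bundle = small_cohort["bundle"]
    if bundle.layer_imputed_qn is None:
        lognormalize(bundle)
        impute(bundle, method="identity")
        quantile_normalize_bundle(bundle)
    scorer, split = train_scorer(bundle, small_cohort["annotations"], seed=7)
    return bundle, small_cohort["annotations"], scorer


class TestScoreCells:
    def test_overall_is_euclidean_combination(self, trained):
        bundle, ann, scorer = trained
        table = score_cells(bundle, scorer, ann)
        np.testing.assert_allclose(
            table["overall"],
            np.sqrt(table["score_i"] ** 2 + table["score_ni"] ** 2),
            atol=1e-12,
        )
        assert table["high_flag"].isna().all()

    def test_three_four_five_identity(self):
        assert np.sqrt(0.6**2 + 0.8**2) == pytest.approx(1.0, abs=1e-12)

    def test_scoring_is_deterministic(self, trained):
        bundle, ann, scorer = trained
        t1 = score_cells(bundle, scorer, ann)
        t2 = score_cells(bundle, scorer, ann)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_signature_gene_named(self, trained):
        bundle, ann, scorer = trained
        sub = bundle.subset_genes(bundle.gene_ids != "ENTPD1")
        with pytest.raises(ValidationError, match="ENTPD1"):
            score_cells(sub, scorer, ann)

    def test_scores_bounded(self, trained):
        bundle, ann, scorer = trained
        t = score_cells(bundle, scorer, ann)
        assert t["score_i"].between(0, 1).all()
        assert t["score_ni"].between(0, 1).all()
        assert t["overall"].between(0, np.sqrt(2)).all()


class TestSingleGeneScorer:
    def test_single_informative_gene_matches_three_gene_model(self, small_cohort):
        # CXCL13 carries most of the signal in the simulated cohort
        bundle = small_cohort["bundle"]
        ann = small_cohort["annotations"]
        if bundle.layer_imputed_qn is None:
            lognormalize(bundle)
            impute(bundle, method="identity")
            quantile_normalize_bundle(bundle)
        labels = (ann["antigen_label"] == "tumor_reactive").to_numpy().astype(int)
        labeled = ann["antigen_label"].isin(["tumor_reactive", "bystander"]).to_numpy()
        three, split = train_scorer(bundle, ann, seed=7)
        one, _ = train_scorer(bundle, ann, genes=("IL7R",), seed=7)
        test = split["test_idx"]
        t3 = score_cells(bundle, three, ann)["score_ni"].to_numpy()
        t1 = score_cells(bundle, one, ann)["score_ni"].to_numpy()
        auc1, _ = roc_auc(t1[test], labels[test])
        # anti-correlated marker: the model learns the sign
        assert auc1 > 0.5

    def test_absent_gene_rejected(self, small_cohort):
        bundle = small_cohort["bundle"]
        with pytest.raises(ValidationError, match="NOPE"):
            train_scorer(bundle, small_cohort["annotations"], genes=("NOPE",), seed=1)


class TestModuleScore:
    def _layer(self, n_genes=60, n_cells=20, seed=0):
        rng = np.random.default_rng(seed)
        layer = rng.gamma(2.0, 1.0, size=(n_genes, n_cells))
        genes = [f"G{i}" for i in range(n_genes)]
        return layer, genes

    def test_whole_matrix_set_scores_zero(self):
        layer, genes = self._layer()
        gs = GeneSet("all", list(genes))
        out = module_score(layer, genes, gs, n_bins=1, ctrl="bin")
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_bin_deterministic_controls(self):
        layer, genes = self._layer(seed=1)
        gs = GeneSet("s", genes[:10])
        out = module_score(layer, genes, gs, n_bins=1, ctrl="bin")
        expected = layer[:10].mean(axis=0) - layer.mean(axis=0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_random_sets_center_on_zero(self):
        layer, genes = self._layer(n_genes=200, n_cells=30, seed=2)
        rng = np.random.default_rng(2)
        means = []
        for i in range(50):
            gs = GeneSet(f"r{i}", list(rng.choice(genes, 15, replace=False)))
            means.append(module_score(layer, genes, gs, seed=i, n_bins=10).mean())
        assert np.mean(means) == pytest.approx(0.0, abs=0.05)

    def test_per_cell_constant_shift_invariance(self):
        layer, genes = self._layer(seed=3)
        gs = GeneSet("s", genes[5:15])
        base = module_score(layer, genes, gs, seed=1)
        shifted = layer.copy()
        shifted[:, 3] += 7.0
        out = module_score(shifted, genes, gs, seed=1)
        np.testing.assert_allclose(np.delete(out, 3), np.delete(base, 3), atol=1e-9)
        assert out[3] == pytest.approx(base[3], abs=1e-9)

    def test_absent_set_rejected_partial_warned(self):
        layer, genes = self._layer()
        with pytest.raises(ValidationError):
            module_score(layer, genes, GeneSet("none", ["X1", "X2"]), n_bins=5)
        with pytest.warns(UserWarning, match="missing"):
            module_score(layer, genes, GeneSet("part", [genes[0], "X1"]), n_bins=5)


class TestSsgsea:
    def test_top_ranked_set_is_maximal(self):
        n_genes, n_cells = 50, 10
        rng = np.random.default_rng(0)
        layer = rng.random((n_genes, n_cells))
        genes = [f"G{i}" for i in range(n_genes)]
        gs = GeneSet("s", genes[:5])
        layer[:, 0] = rng.random(n_genes)
        layer[:5, 0] += 10  # set genes occupy the top ranks in cell 0
        out = ssgsea_score(layer, genes, gs)
        assert np.argmax(out) == 0

    def test_bottom_ranked_set_is_minimal(self):
        n_genes, n_cells = 50, 10
        rng = np.random.default_rng(1)
        layer = rng.random((n_genes, n_cells))
        genes = [f"G{i}" for i in range(n_genes)]
        gs = GeneSet("s", genes[:5])
        layer[:5, 3] -= 10  # set genes at the bottom in cell 3
        out = ssgsea_score(layer, genes, gs)
        assert np.argmin(out) == 3

    def test_identical_cells_identical_scores(self):
        layer = np.tile(np.arange(30, dtype=float)[:, None], (1, 4))
        genes = [f"G{i}" for i in range(30)]
        out = ssgsea_score(layer, genes, GeneSet("s", genes[10:15]))
        assert np.ptp(out) == pytest.approx(0.0, abs=1e-12)

    def test_empty_overlap_rejected(self):
        layer = np.ones((5, 2))
        with pytest.raises(ValidationError):
            ssgsea_score(layer, [f"G{i}" for i in range(5)], GeneSet("s", ["X"]))


class TestRocAuc:
    def test_worked_example(self):
        auc, points = roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)
        assert {"fpr", "tpr", "threshold"} <= set(points.columns)

    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestScorerBundleIO:
    def test_save_load_round_trip(self, tmp_path):
        members = [
            _FixedModel(0.3, f"P{i // 2}", ["random_forest", "logistic"][i % 2])
            for i in range(6)
        ]
        sb = ScorerBundle(
            ensemble_i=build_ensemble(members), ensemble_ni=build_ensemble(members)
        )
        sb.save(tmp_path / "model.pkl")
        back = ScorerBundle.load(tmp_path / "model.pkl")
        assert back.genes == sb.genes
        np.testing.assert_allclose(
            back.ensemble_i.predict_proba(np.zeros((2, 3))),
            sb.ensemble_i.predict_proba(np.zeros((2, 3))),
        )
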