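"""The 3-gene ensemble voting scorer and its comparison baselines.

Two soft-voting ensembles are trained over the signature genes CXCL13,
ENTPD1 and IL7R: one on the quantile-normalized imputed layer (score_i)
and one on the log-normalized layer (score_ni).  Each ensemble combines
one random-forest and one logistic model per training patient by
averaging their class-1 probabilities.  The two per-cell scores are
combined into an overall score sqrt(score_i^2 + score_ni^2).

Estimators follow the scikit-learn protocol (``fit``/``predict_proba``,
``get_params``, fitted attributes with a trailing underscore) and compose
with sklearn model selection.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.utils.validation import check_is_fitted

from .datamodel import ExpressionBundle, GeneSet, ValidationError, SIGNATURE_GENES

ALGORITHMS = ("random_forest", "logistic", "linear_clipped")

#: Hyperparameter grid originally searched for the random forest; the
#: selected values (100 trees, all features per split) are the defaults.
RF_SEARCH_GRID = {"n_estimators": [100, 500, 1000, 2000, 2500],
                  "max_features": [1, 2, 3]}


class SinglePatientModel(ClassifierMixin, BaseEstimator):
    """One patient's tumor-reactive-vs-bystander classifier.

    Parameters
    ----------
    algorithm : {"random_forest", "logistic", "linear_clipped"}
        ``random_forest`` uses 100 trees with all features considered at
        each split; ``logistic`` is an unpenalized maximum-likelihood fit
        (the probabilistic reading of a linear model, required for soft
        voting); ``linear_clipped`` is the literal least-squares variant
        with predictions clipped to [0, 1], kept for sensitivity analysis.
    patient_id, layer : provenance carried along for ensemble validation.
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        patient_id: str | None = None,
        layer: str = "imputed_qn",
        n_estimators: int = 100,
        max_features: int | str | None = 3,
        seed: int = 0,
    ):
        self.algorithm = algorithm
        self.patient_id = patient_id
        self.layer = layer
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (cells x genes)")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValidationError(
                f"training data for patient {self.patient_id!r} has a single class"
            )
        if self.algorithm == "random_forest":
            max_features = self.max_features
            if isinstance(max_features, int):
                max_features = min(max_features, X.shape[1])
            est = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=max_features,
                random_state=self.seed,
            )
            est.fit(X, y)
        elif self.algorithm == "logistic":
            # unpenalized maximum likelihood (C -> inf disables shrinkage)
            est = LogisticRegression(C=np.inf, max_iter=1000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(X, y)
        elif self.algorithm == "linear_clipped":
            est = LinearRegression()
            est.fit(X, y.astype(float))
        else:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        self.estimator_ = est
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        if self.algorithm == "linear_clipped":
            p1 = np.clip(self.estimator_.predict(X), 0.0, 1.0)
            return np.column_stack([1.0 - p1, p1])
        return self.estimator_.predict_proba(X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


class SoftVotingEnsemble(ClassifierMixin, BaseEstimator):
    """Unweighted soft vote over pre-fitted single-patient members.

    The ensemble class-1 probability is the arithmetic mean of the member
    class-1 probabilities; the canonical composition is 3 training
    patients x 2 algorithms = 6 members sharing one input layer.
    """

    def __init__(self, members: list | None = None):
        self.members = members

    def fit(self, X=None, y=None):
        members = self.members or []
        if not members:
            raise ValidationError("ensemble requires at least one fitted member")
        layers = {m.layer for m in members}
        if len(layers) != 1:
            raise ValidationError(f"members span multiple layers: {sorted(layers)}")
        patients = [m.patient_id for m in members]
        by_patient: dict[str, set] = {}
        for m in members:
            by_patient.setdefault(m.patient_id, set()).add(m.algorithm)
        if len(by_patient) < 2:
            raise ValidationError("ensemble needs members from >= 2 distinct patients")
        algsets = set(map(frozenset, by_patient.values()))
        if len(algsets) != 1 or len(next(iter(algsets))) != len(members) // len(by_patient):
            raise ValidationError(
                f"unbalanced ensemble composition: {dict((k, sorted(v)) for k, v in by_patient.items())}"
            )
        if len(members) != len(by_patient) * len(next(iter(algsets))):
            raise ValidationError("duplicate (patient, algorithm) members")
        for m in members:
            check_is_fitted(m, "estimator_")
        self.members_ = list(members)
        self.layer_ = next(iter(layers))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "members_")
        probas = np.stack([m.predict_proba(np.asarray(X))[:, 1] for m in self.members_])
        p1 = probas.mean(axis=0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


@dataclass
class ScorerBundle:
    """The trained scorer: one ensemble per input layer plus its genes."""

    ensemble_i: SoftVotingEnsemble
    ensemble_ni: SoftVotingEnsemble
    genes: tuple = SIGNATURE_GENES
    version: str = "1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ensemble_i is None or self.ensemble_ni is None:
            raise ValidationError("both ensembles (imputed, non-imputed) are required")

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ScorerBundle":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, ScorerBundle):
            raise ValidationError(f"{path} does not contain a scorer bundle")
        return obj


def make_training_split(
    annotations: pd.DataFrame,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 80/20 split of ground-truth cells.

    Cells with ``antigen_label`` of ``tumor_reactive`` (class 1) or
    ``bystander`` (class 0) are split within each (patient, class)
    stratum; strata with fewer than 2 cells go wholly to training.
    Returns positional index arrays into ``annotations``.
    """
    labeled = annotations["antigen_label"].isin(["tumor_reactive", "bystander"])
    if not labeled.any():
        raise ValidationError("no ground-truth labeled cells to split")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    pos = np.flatnonzero(labeled.to_numpy())
    strata = pd.DataFrame(
        {
            "row": pos,
            "patient_id": annotations["patient_id"].to_numpy()[pos],
            "antigen_label": annotations["antigen_label"].to_numpy()[pos],
        }
    )
    for _, grp in strata.groupby(["patient_id", "antigen_label"], sort=True):
        members = grp["row"].to_numpy()
        if len(members) < 2:
            warnings.warn(
                f"stratum with {len(members)} cell(s) assigned wholly to training",
                stacklevel=2,
            )
            train_idx.extend(members.tolist())
            continue
        perm = rng.permutation(len(members))
        n_train = int(np.floor(train_frac * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train_idx.extend(members[perm[:n_train]].tolist())
        test_idx.extend(members[perm[n_train:]].tolist())
    return np.sort(train_idx), np.sort(test_idx)


def extract_features(
    bundle: ExpressionBundle, genes, layer: str
) -> np.ndarray:
    """Cells x genes feature matrix from the named layer."""
    rows = []
    for g in genes:
        try:
            rows.append(bundle.gene_values(g, layer=layer))
        except KeyError as exc:
            raise ValidationError(f"signature gene {g!r} missing: {exc}") from exc
    return np.column_stack(rows)


def train_single_patient(
    X, y, algorithm: str = "random_forest", seed: int = 0, **kwargs
) -> SinglePatientModel:
    """Fit one single-patient member model on a cells x genes matrix."""
    model = SinglePatientModel(algorithm=algorithm, seed=seed, **kwargs)
    return model.fit(X, y)


def build_ensemble(members) -> SoftVotingEnsemble:
    """Validate member composition and return the fitted soft-voting ensemble."""
    return SoftVotingEnsemble(members=list(members)).fit()


def train_scorer(
    bundle: ExpressionBundle,
    annotations: pd.DataFrame,
    genes=SIGNATURE_GENES,
    train_frac: float = 0.8,
    seed: int = 0,
    algorithms: tuple = ("random_forest", "logistic"),
) -> tuple[ScorerBundle, dict]:
    """Train both ensembles on the ground-truth cells of a bundle.

    For every patient contributing ground truth, one member per algorithm
    is fitted per layer on the 80% training portion of that patient's
    labeled cells.  Returns the scorer and the split (positional indices
    into ``annotations``) for held-out evaluation.
    """
    if len(annotations) != bundle.n_cells:
        raise ValidationError("annotations and bundle disagree on cell count")
    train_idx, test_idx = make_training_split(annotations, train_frac, seed)
    labels = (annotations["antigen_label"] == "tumor_reactive").to_numpy().astype(int)
    patients = annotations["patient_id"].to_numpy()

    ensembles = {}
    for layer, key in (("imputed_qn", "i"), ("norm", "ni")):
        X_all = extract_features(bundle, genes, layer)
        members = []
        for patient in sorted(set(patients[train_idx])):
            rows = train_idx[patients[train_idx] == patient]
            for alg in algorithms:
                m = SinglePatientModel(
                    algorithm=alg, patient_id=patient, layer=layer, seed=seed
                )
                m.fit(X_all[rows], labels[rows])
                members.append(m)
        ensembles[key] = build_ensemble(members)
    scorer = ScorerBundle(
        ensemble_i=ensembles["i"], ensemble_ni=ensembles["ni"],
        genes=tuple(genes), seed=seed,
    )
    return scorer, {"train_idx": train_idx, "test_idx": test_idx}


def single_gene_scorer(
    bundle: ExpressionBundle,
    annotations: pd.DataFrame,
    gene: str,
    train_frac: float = 0.8,
    seed: int = 0,
) -> ScorerBundle:
    """Same voting framework restricted to a single input gene."""
    scorer, _ = train_scorer(
        bundle, annotations, genes=(gene,), train_frac=train_frac, seed=seed
    )
    return scorer


def score_cells(bundle: ExpressionBundle, scorer: ScorerBundle,
                annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score every cell of a bundle with a trained scorer.

    Returns the score table with columns barcode, patient_id, score_i,
    score_ni, overall (= sqrt(score_i^2 + score_ni^2)) and an
    undetermined ``high_flag`` (filled in by the thresholding step).
    """
    X_i = extract_features(bundle, scorer.genes, "imputed_qn")
    X_ni = extract_features(bundle, scorer.genes, "norm")
    score_i = scorer.ensemble_i.predict_proba(X_i)[:, 1]
    score_ni = scorer.ensemble_ni.predict_proba(X_ni)[:, 1]
    patient = (
        annotations["patient_id"].to_numpy()
        if annotations is not None
        else np.full(bundle.n_cells, "NA", dtype=object)
    )
    return pd.DataFrame(
        {
            "barcode": bundle.cell_barcodes,
            "patient_id": patient,
            "score_i": score_i,
            "score_ni": score_ni,
            "overall": np.sqrt(score_i**2 + score_ni**2),
            "high_flag": pd.array([pd.NA] * bundle.n_cells, dtype="boolean"),
        }
    )


def module_score(
    layer: np.ndarray,
    gene_ids,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    ctrl: str = "sample",
) -> np.ndarray:
    """Binned-control gene-set score per cell.

    Genes are binned into ``n_bins`` equal-size bins by average expression
    across cells; for every gene of the set, ``n_ctrl`` control genes are
    drawn from its bin (with replacement when the bin is small).  The
    score is mean(set genes) - mean(pooled control genes) per cell.
    With ``ctrl="bin"`` the whole bin of each set gene is used as its
    control, deterministically (useful for exact checks).
    """
    layer = np.asarray(layer, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    if layer.shape[0] < n_bins:
        raise ValidationError(f"need >= {n_bins} genes for {n_bins} bins")
    present = [g for g in gene_set.genes if g in set(gene_ids)]
    if not present:
        raise ValidationError(f"gene set {gene_set.name!r} absent from matrix")
    if len(present) < len(gene_set.genes):
        warnings.warn(
            f"gene set {gene_set.name!r}: dropping "
            f"{len(gene_set.genes) - len(present)} missing gene(s)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    avg = layer.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(gene_ids), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    set_idx = np.array([idx_of[g] for g in present])
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        if ctrl == "bin":
            ctrl_idx.extend(pool.tolist())
        else:
            replace = len(pool) < n_ctrl
            ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=replace).tolist())
    ctrl_idx = np.asarray(ctrl_idx)
    return layer[set_idx].mean(axis=0) - layer[ctrl_idx].mean(axis=0)


def ssgsea_score(
    layer: np.ndarray,
    gene_ids,
    gene_set: GeneSet,
    alpha: float = 0.25,
) -> np.ndarray:
    """Single-sample GSEA enrichment per cell (comparison baseline).

    Per cell, genes are ranked by expression (ties averaged); a weighted
    Kolmogorov-Smirnov running sum with in-set weight rank^alpha is
    accumulated and the score is the sum of running-sum differences,
    normalized by the score range across cells.
    """
    layer = np.asarray(layer, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    in_set = np.isin(gene_ids, gene_set.genes)
    if not in_set.any():
        raise ValidationError(f"gene set {gene_set.name!r} has no overlap with matrix")
    n_genes, n_cells = layer.shape
    scores = np.empty(n_cells)
    for j in range(n_cells):
        ranks = rankdata(layer[:, j], method="average")
        order = np.argsort(-ranks, kind="stable")  # descending expression
        set_sorted = in_set[order]
        w = np.where(set_sorted, ranks[order] ** alpha, 0.0)
        p_hit = np.cumsum(w) / w.sum()
        n_miss = max(n_genes - in_set.sum(), 1)
        p_miss = np.cumsum(~set_sorted) / n_miss
        scores[j] = np.sum(p_hit - p_miss)
    rng_span = scores.max() - scores.min()
    if rng_span > 0:
        scores = scores / rng_span
    return scores


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Mann-Whitney AUC with ROC points from all distinct thresholds.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie), computed from average
    ranks; ties therefore contribute half a concordance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = rankdata(scores, method="average")
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresh = roc_curve(labels, scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return float(auc), points
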