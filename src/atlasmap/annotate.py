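"""AUC-ranked one-vs-rest logistic-regression cell-type annotation.

The framework trains, per reference cell type, a binary logistic-regression
classifier against all other cells. Genes are first ranked by the ROC AUC of
single-gene classifiers fitted on a stratified 70% training partition (with
tenfold cross-validation by default); the number of top-ranked genes kept for
the final classifier is the one whose multivariate model, fitted on the
training partition, scores the highest AUC on the held-out 30%. The final
model is refitted on the full reference and its per-cell prediction
probabilities are projected onto any query dataset sharing the gene
namespace. Query clusters are labelled by the model with the highest mean
probability, and a per-label AUC quantifies how sharply each annotation
separates its cluster from the rest of the query.

Probabilities from the independent one-vs-rest models are deliberately not
renormalized across types.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.special import expit, logit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "TrainingConfig",
    "RankedGeneList",
    "CellTypeModel",
    "ModelBundle",
    "ProjectionResult",
    "stratified_split",
    "fit_single_gene_lr",
    "rank_genes_by_auc",
    "select_gene_count",
    "fit_celltype_model",
    "train_bundle",
    "project",
    "label_clusters",
    "annotation_auc",
    "rank_auc",
    "CellTypeAnnotator",
    "AnnotationResult",
]

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the annotation framework.

    ``gene_auc_mode`` controls how per-gene AUCs are obtained on the training
    partition: ``"cv"`` pools out-of-fold predictions from a stratified
    ``cv_folds``-fold split (less optimistic), ``"resubstitution"`` scores the
    single fit on its own training cells. ``ridge_penalty`` is the L2 weight
    added to every slope coefficient (intercepts are unpenalized); a small
    positive value keeps coefficients finite when good markers separate the
    classes perfectly.
    """

    train_fraction: float = 0.7
    cv_folds: int = 10
    gene_count_grid: tuple[int, ...] = (5, 10, 20, 50, 100, 200, 500)
    ridge_penalty: float = 1e-4
    gene_auc_mode: str = "cv"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        grid = tuple(self.gene_count_grid)
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])) or grid[0] <= 0:
            raise ValueError("gene_count_grid must be a strictly increasing positive sequence")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be non-negative")
        if self.gene_auc_mode not in ("cv", "resubstitution"):
            raise ValueError("gene_auc_mode must be 'cv' or 'resubstitution'")


@dataclass
class RankedGeneList:
    """Genes ordered by single-gene classification AUC for one cell type."""

    cell_type: str
    table: pd.DataFrame  # columns: gene, auc; sorted by auc desc, gene asc

    def top(self, k: int) -> list[str]:
        return self.table["gene"].head(k).tolist()


@dataclass
class CellTypeModel:
    cell_type: str
    genes: list[str]
    coef: np.ndarray
    intercept: float
    selected_count: int
    test_auc: float
    auc_trace: dict[int, float]  # gene count -> held-out AUC


@dataclass
class ModelBundle:
    """The trained annotation artifact: one classifier per reference type."""

    models: dict[str, CellTypeModel]
    gene_universe: list[str]
    config: TrainingConfig

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.models)

    def to_json(self) -> str:
        doc = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "config": {**asdict(self.config),
                       "gene_count_grid": list(self.config.gene_count_grid)},
            "gene_universe": list(self.gene_universe),
            "models": {
                t: {
                    "genes": m.genes,
                    "coef": [float(c) for c in m.coef],
                    "intercept": float(m.intercept),
                    "selected_count": int(m.selected_count),
                    "test_auc": float(m.test_auc),
                    "auc_trace": {str(k): float(v) for k, v in m.auc_trace.items()},
                }
                for t, m in self.models.items()
            },
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelBundle":
        doc = json.loads(text)
        if doc.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(f"unsupported bundle format: {doc.get('format_version')!r}")
        cfg = dict(doc["config"])
        cfg["gene_count_grid"] = tuple(cfg["gene_count_grid"])
        config = TrainingConfig(**cfg)
        models = {
            t: CellTypeModel(
                cell_type=t,
                genes=list(d["genes"]),
                coef=np.asarray(d["coef"], dtype=float),
                intercept=float(d["intercept"]),
                selected_count=int(d["selected_count"]),
                test_auc=float(d["test_auc"]),
                auc_trace={int(k): float(v) for k, v in d["auc_trace"].items()},
            )
            for t, d in doc["models"].items()
        }
        return cls(models=models, gene_universe=list(doc["gene_universe"]), config=config)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class ProjectionResult:
    """Cluster-level outcome of projecting a bundle onto a query."""

    cell_probabilities: pd.DataFrame  # cells x types
    cluster_means: pd.DataFrame  # clusters x types
    labels: pd.Series  # cluster -> assigned type
    ambiguous: pd.Series  # cluster -> top-two margin < threshold
    label_auc: pd.Series | None = None  # assigned type -> AUC


# ---------------------------------------------------------------------------
# low-level numerics


def rank_auc(y: np.ndarray, scores: np.ndarray) -> np.ndarray | float:
    """ROC AUC via midranks (the Mann-Whitney normalization); tied scores
    contribute 1/2. ``scores`` may be 1-D or (n, G) for G score columns."""
    y = np.asarray(y, dtype=bool)
    scalar = np.ndim(scores) == 1
    s = np.asarray(scores, dtype=float)
    if scalar:
        s = s[:, None]
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both positive and negative cells")
    ranks = rankdata(s, axis=0, method="average")
    auc = (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc[0]) if scalar else auc


def _fit_single_gene_batch(X: np.ndarray, y: np.ndarray, ridge: float,
                           max_iter: int = 60, tol: float = 1e-10
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Damped Newton fit of G independent single-covariate logistic models.

    Each gene g gets its own (intercept, slope); the ridge penalty applies to
    the slope only. Under perfect separation the slope grows until the
    penalty balances it, so the fit stays finite.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    yf = np.asarray(y, dtype=np.float64)
    n, G = X.shape
    base = yf.mean()
    if base <= 0.0 or base >= 1.0:
        raise ValueError("both classes must be present")
    b0 = np.full(G, float(logit(base)))
    b1 = np.zeros(G)
    for _ in range(max_iter):
        eta = b0[None, :] + X * b1[None, :]
        p = expit(eta)
        r = p - yf[:, None]
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", X, r) + ridge * b1
        w = p * (1.0 - p)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", w, X)
        h11 = np.einsum("ij,ij,ij->j", w, X, X) + ridge
        det = np.maximum(h00 * h11 - h01 * h01, 1e-300)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        # cap the Newton step: separation makes early steps overshoot
        scale = np.maximum(1.0, np.maximum(np.abs(d0), np.abs(d1)) / 10.0)
        b0 -= d0 / scale
        b1 -= d1 / scale
        if max(np.abs(g0).max(initial=0.0), np.abs(g1).max(initial=0.0)) < tol:
            break
    return b0, b1


def fit_single_gene_lr(x: np.ndarray, y: np.ndarray, ridge: float = 1e-4
                       ) -> tuple[float, float]:
    """Single-covariate logistic regression; returns (intercept, slope)."""
    b0, b1 = _fit_single_gene_batch(np.asarray(x, float)[:, None], y, ridge)
    return float(b0[0]), float(b1[0])


def _sklearn_lr(ridge: float, tol: float, max_iter: int) -> LogisticRegression:
    if ridge > 0:
        return LogisticRegression(penalty="l2", C=1.0 / ridge, solver="lbfgs",
                                  tol=tol, max_iter=max_iter)
    return LogisticRegression(penalty=None, solver="lbfgs", tol=tol, max_iter=max_iter)


def _type_seed(seed: int, cell_type: str) -> int:
    return int((seed * 1_000_003 + zlib.crc32(str(cell_type).encode())) % (2**31 - 1))


# ---------------------------------------------------------------------------
# operations


def stratified_split(labels: pd.Series, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[pd.Index, pd.Index]:
    """Per-type train/test partition of cell ids.

    For each type, the training share is ``round(train_fraction * n)``
    (half-up), clamped so both partitions keep at least one cell of every
    type. The partition is disjoint, exhaustive and reproducible.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labels = pd.Series(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    train_ids: list = []
    test_ids: list = []
    for cell_type in sorted(labels.astype(str).unique()):
        ids = labels.index[labels.astype(str) == cell_type].to_numpy()
        n = ids.size
        if n < 2:
            raise ValueError(
                f"cell type {cell_type!r} has {n} cell(s); at least 2 are needed to split"
            )
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return pd.Index(train_ids), pd.Index(test_ids)


def _as_dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def _matrix_and_genes(data, genes=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, AnnData):
        return _as_dense(data.X), list(data.var_names)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    if genes is None:
        raise ValueError("gene names are required with a bare matrix")
    return _as_dense(data), list(genes)


def rank_genes_by_auc(train, labels: pd.Series, cell_type: str,
                      config: TrainingConfig | None = None,
                      genes=None) -> RankedGeneList:
    """Rank every gene by the AUC of its single-gene one-vs-rest classifier.

    With ``gene_auc_mode="cv"`` the AUC is computed on pooled out-of-fold
    linear predictors from a stratified K-fold split of the training cells;
    with ``"resubstitution"`` a single fit is scored on its own cells. AUC is
    evaluated on the linear predictor, which is monotone in the predicted
    probability and therefore yields the same AUC without saturation ties.
    Constant genes get slope 0 and hence AUC 0.5. Ties rank by gene id.
    """
    config = config or TrainingConfig()
    X, gene_names = _matrix_and_genes(train, genes)
    labels = pd.Series(labels).astype(str)
    if cell_type not in set(labels):
        raise ValueError(f"cell type {cell_type!r} absent from labels")
    y = (labels.to_numpy() == cell_type)

    if config.gene_auc_mode == "resubstitution":
        b0, b1 = _fit_single_gene_batch(X, y, config.ridge_penalty)
        eta = b0[None, :] + X * b1[None, :]
    else:
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        n_splits = min(config.cv_folds, n_pos, n_neg)
        if n_splits < 2:
            warnings.warn(
                f"too few cells per class for CV on {cell_type!r}; "
                "falling back to resubstitution AUCs", stacklevel=2)
            b0, b1 = _fit_single_gene_batch(X, y, config.ridge_penalty)
            eta = b0[None, :] + X * b1[None, :]
        else:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                  random_state=_type_seed(config.seed, cell_type))
            eta = np.empty_like(X)
            for tr, te in skf.split(X, y):
                b0, b1 = _fit_single_gene_batch(X[tr], y[tr], config.ridge_penalty)
                eta[te] = b0[None, :] + X[te] * b1[None, :]

    aucs = rank_auc(y, eta)
    table = (pd.DataFrame({"gene": gene_names, "auc": aucs})
             .sort_values(["auc", "gene"], ascending=[False, True],
                          kind="mergesort")
             .reset_index(drop=True))
    return RankedGeneList(cell_type=cell_type, table=table)


def _effective_grid(grid: tuple[int, ...], n_ranked: int) -> list[int]:
    out: list[int] = []
    for k in grid:
        k = min(k, n_ranked)
        if k not in out:
            out.append(k)
    return out


def select_gene_count(train, test, labels_train: pd.Series, labels_test: pd.Series,
                      ranking: RankedGeneList, config: TrainingConfig | None = None,
                      genes=None) -> tuple[int, dict[int, float]]:
    """Pick the gene count whose top-k model scores best on the test set.

    For each candidate k the top-k ranked genes parameterize a multivariate
    one-vs-rest fit on the training cells, scored by AUC on the held-out test
    cells. Ties go to the smallest k. Grid entries larger than the ranking
    are truncated and deduplicated.
    """
    config = config or TrainingConfig()
    Xtr, gene_names = _matrix_and_genes(train, genes)
    Xte, gene_names_te = _matrix_and_genes(test, genes)
    if gene_names_te != gene_names:
        raise ValueError("train and test matrices must share the same gene order")
    ytr = pd.Series(labels_train).astype(str).to_numpy() == ranking.cell_type
    yte = pd.Series(labels_test).astype(str).to_numpy() == ranking.cell_type
    if yte.all() or not yte.any():
        raise ValueError(
            f"test set is single-class for {ranking.cell_type!r}; cannot score AUC")
    if ytr.all() or not ytr.any():
        raise ValueError(
            f"training set is single-class for {ranking.cell_type!r}")

    col = {g: i for i, g in enumerate(gene_names)}
    ranked_cols = [col[g] for g in ranking.table["gene"]]
    trace: dict[int, float] = {}
    best_k, best_auc = None, -np.inf
    for k in _effective_grid(tuple(config.gene_count_grid), len(ranked_cols)):
        cols = ranked_cols[:k]
        lr = _sklearn_lr(config.ridge_penalty, tol=1e-8, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr.fit(Xtr[:, cols], ytr)
        auc = rank_auc(yte, lr.decision_function(Xte[:, cols]))
        trace[k] = float(auc)
        if auc > best_auc:  # strict: ties keep the smaller k
            best_k, best_auc = k, auc
    return int(best_k), trace


def fit_celltype_model(reference, labels: pd.Series, ranking: RankedGeneList,
                       selected_count: int, config: TrainingConfig | None = None,
                       genes=None, test_auc: float = float("nan"),
                       auc_trace: dict[int, float] | None = None) -> CellTypeModel:
    """Fit the final one-vs-rest classifier on the full reference."""
    config = config or TrainingConfig()
    X, gene_names = _matrix_and_genes(reference, genes)
    if selected_count > len(ranking.table):
        raise ValueError("selected_count exceeds the number of ranked genes")
    y = pd.Series(labels).astype(str).to_numpy() == ranking.cell_type
    top = ranking.top(selected_count)
    col = {g: i for i, g in enumerate(gene_names)}
    cols = [col[g] for g in top]
    lr = _sklearn_lr(config.ridge_penalty, tol=1e-10, max_iter=10_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(X[:, cols], y)
    coef = lr.coef_.ravel()
    intercept = float(lr.intercept_[0])
    if not (np.all(np.isfinite(coef)) and np.isfinite(intercept)):
        raise RuntimeError(
            f"final fit for {ranking.cell_type!r} produced non-finite coefficients "
            f"(n_iter={int(np.ravel(lr.n_iter_)[0])}); increase ridge_penalty")
    return CellTypeModel(
        cell_type=ranking.cell_type, genes=top, coef=coef, intercept=intercept,
        selected_count=int(selected_count), test_auc=float(test_auc),
        auc_trace=dict(auc_trace or {}),
    )


def train_bundle(reference, labels: pd.Series, config: TrainingConfig | None = None,
                 genes=None) -> ModelBundle:
    """Run the full training procedure for every reference cell type.

    One stratified 70/30 split is drawn for the whole reference; per type the
    genes are AUC-ranked on the training partition, the gene count is
    optimized against the test partition, and the final model is refitted on
    all reference cells.
    """
    config = config or TrainingConfig()
    X, gene_names = _matrix_and_genes(reference, genes)
    labels = pd.Series(labels).astype(str)
    if isinstance(reference, AnnData):
        labels.index = reference.obs_names
    if len(labels) != X.shape[0]:
        raise ValueError("labels must cover every reference cell")
    pos = pd.Series(np.arange(len(labels)), index=labels.index)
    train_ids, test_ids = stratified_split(labels, config.train_fraction, config.seed)
    itr, ite = pos[train_ids].to_numpy(), pos[test_ids].to_numpy()
    Xtr, Xte = X[itr], X[ite]
    ytr_lab, yte_lab = labels.iloc[itr], labels.iloc[ite]

    models: dict[str, CellTypeModel] = {}
    for cell_type in sorted(labels.unique()):
        ranking = rank_genes_by_auc(Xtr, ytr_lab, cell_type, config, genes=gene_names)
        k, trace = select_gene_count(Xtr, Xte, ytr_lab, yte_lab, ranking,
                                     config, genes=gene_names)
        models[cell_type] = fit_celltype_model(
            X, labels, ranking, k, config, genes=gene_names,
            test_auc=trace[k], auc_trace=trace)
    return ModelBundle(models=models, gene_universe=list(gene_names), config=config)


def project(bundle: ModelBundle, query, genes=None,
            coverage_warn_fraction: float = 0.8) -> pd.DataFrame:
    """Score every query cell with every cell-type model.

    A model gene absent from the query contributes expression 0 (absence of
    evidence); a warning is emitted per model whose query gene coverage falls
    below ``coverage_warn_fraction``. A model with zero genes present in the
    query is an error.
    """
    X, gene_names = _matrix_and_genes(query, genes)
    if isinstance(query, AnnData):
        index = query.obs_names
    elif isinstance(query, pd.DataFrame):
        index = query.index
    else:
        index = pd.RangeIndex(X.shape[0])
    col = {g: i for i, g in enumerate(gene_names)}
    out = {}
    for cell_type in bundle.cell_types:
        model = bundle.models[cell_type]
        present = [i for i, g in enumerate(model.genes) if g in col]
        if not present:
            raise ValueError(f"no genes of model {cell_type!r} found in the query")
        coverage = len(present) / len(model.genes)
        if coverage < coverage_warn_fraction:
            warnings.warn(
                f"model {cell_type!r}: only {coverage:.0%} of its genes are present "
                "in the query; missing genes scored as 0", stacklevel=2)
        cols = [col[model.genes[i]] for i in present]
        eta = X[:, cols] @ model.coef[present] + model.intercept
        out[cell_type] = expit(eta)
    return pd.DataFrame(out, index=index)


def label_clusters(probabilities: pd.DataFrame, clusters: pd.Series,
                   ambiguity_margin: float = 0.01) -> ProjectionResult:
    """Assign each query cluster the type with the highest mean probability.

    Ties break by type-id order; a cluster whose top two mean probabilities
    differ by less than ``ambiguity_margin`` is flagged ambiguous.
    """
    clusters = pd.Series(clusters).astype(str)
    clusters = clusters.reindex(probabilities.index)
    if clusters.isna().any():
        missing = probabilities.index[clusters.isna()][:3].tolist()
        raise ValueError(f"cells without a cluster assignment, e.g. {missing}")
    probs = probabilities[sorted(probabilities.columns)]
    means = probs.groupby(clusters, observed=True).mean().sort_index()
    if (means.index == "").any():
        raise ValueError("empty cluster id")
    arr = means.to_numpy()
    order = np.argsort(-arr, axis=1, kind="stable")
    top = arr[np.arange(len(means)), order[:, 0]]
    second = arr[np.arange(len(means)), order[:, 1]] if arr.shape[1] > 1 else np.full(len(means), -np.inf)
    labels = pd.Series(np.asarray(means.columns)[order[:, 0]], index=means.index,
                       name="label")
    ambiguous = pd.Series(top - second < ambiguity_margin, index=means.index,
                          name="ambiguous")
    return ProjectionResult(cell_probabilities=probs, cluster_means=means,
                            labels=labels, ambiguous=ambiguous)


def annotation_auc(probabilities: pd.DataFrame, labels: pd.Series,
                   clusters: pd.Series) -> pd.Series:
    """Per assigned label, the AUC separating its cluster(s) from the rest.

    Positives are the cells of every cluster carrying the label; scores are
    that type's per-cell probabilities. A label covering every query cell has
    no negatives and is reported as NaN.
    """
    clusters = pd.Series(clusters).astype(str).reindex(probabilities.index)
    cell_label = clusters.map(labels)
    out = {}
    for cell_type in sorted(set(labels)):
        y = (cell_label == cell_type).to_numpy()
        if y.all():
            out[cell_type] = float("nan")
            continue
        out[cell_type] = rank_auc(y, probabilities[cell_type].to_numpy())
    return pd.Series(out, name="auc")


# ---------------------------------------------------------------------------
# model/results front end


class CellTypeAnnotator:
    """Reference-based annotation model.

    Built from a labelled, normalized reference; ``fit`` runs the whole
    ranking/selection/refit procedure and returns an
    :class:`AnnotationResult`.

    Parameters
    ----------
    reference
        Normalized expression, cells x genes (AnnData or DataFrame).
    labels
        Per-cell type labels: a Series aligned to cells, or the name of an
        ``obs`` column when ``reference`` is an AnnData (default
        ``"cell_type"``).
    config
        :class:`TrainingConfig`; defaults match the published procedure
        (70/30 split, tenfold CV gene AUCs).
    """

    def __init__(self, reference, labels="cell_type",
                 config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        if isinstance(labels, str):
            if not isinstance(reference, AnnData):
                raise TypeError("string labels require an AnnData reference")
            labels = reference.obs[labels]
        self.reference = reference
        self.labels = pd.Series(labels).astype(str)

    @classmethod
    def from_dataframe(cls, expression: pd.DataFrame, labels: pd.Series,
                       config: TrainingConfig | None = None) -> "CellTypeAnnotator":
        return cls(expression, labels=labels, config=config)

    def fit(self) -> "AnnotationResult":
        bundle = train_bundle(self.reference, self.labels, self.config)
        return AnnotationResult(self, bundle)


class AnnotationResult:
    """Fitted annotation bundle with projection and labelling methods."""

    def __init__(self, model: CellTypeAnnotator | None, bundle: ModelBundle):
        self.model = model
        self.bundle = bundle

    def summary(self) -> pd.DataFrame:
        """Per cell type: selected gene count, held-out AUC, top genes."""
        rows = []
        for t in self.bundle.cell_types:
            m = self.bundle.models[t]
            rows.append({
                "cell_type": t,
                "n_genes": m.selected_count,
                "test_auc": m.test_auc,
                "top_genes": ",".join(m.genes[:5]),
            })
        return pd.DataFrame(rows).set_index("cell_type")

    def predict(self, query, genes=None) -> pd.DataFrame:
        """Per-cell per-type prediction probabilities on a query."""
        return project(self.bundle, query, genes=genes)

    def annotate(self, query, clusters, genes=None,
                 ambiguity_margin: float = 0.01) -> ProjectionResult:
        """Project onto a clustered query and label every cluster."""
        probs = self.predict(query, genes=genes)
        result = label_clusters(probs, clusters, ambiguity_margin)
        result.label_auc = annotation_auc(probs, result.labels,
                                          pd.Series(clusters).astype(str))
        return result

    def save(self, path) -> None:
        self.bundle.save(path)

    @classmethod
    def load(cls, path) -> "AnnotationResult":
        return cls(None, ModelBundle.load(path))
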