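"""Synthetic paired reference/query single-cell datasets with known ground truth.

Emulates the statistical structure that reference-based annotation assumes:
multiple cell types with disjoint marker-gene sets, overdispersed
(gamma-Poisson) counts, a mitochondrial gene block calibrated to a target
per-cell fraction, a batch-shifted query sharing the reference cell types,
timepoint-structured appearance of types along a lineage tree, and noisy
per-sample directed lineage graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SampleGraph",
    "SyntheticAtlasPair",
    "generate_atlas_pair",
    "generate_lineage_series",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic atlas generator.

    Parameters
    ----------
    n_types
        Number of cell types shared by reference and query.
    cells_per_type
        Cells simulated per type in each dataset.
    n_genes
        Total genes, including the mitochondrial block.
    markers_per_type
        Genes up-regulated exclusively in one type; marker sets are disjoint.
    marker_log_fc
        Natural-log mean shift of a marker inside its own type; the expected
        in-type/out-of-type mean ratio is exactly ``exp(marker_log_fc)``.
    dispersion
        Negative-binomial inverse-dispersion (``size``); variance is
        ``mu + mu**2 / dispersion``, so larger values approach Poisson.
    mito_fraction_mean
        Target expected fraction of each cell's counts coming from
        mitochondrial genes.
    batch_log_fc_sd
        Standard deviation of the per-gene log batch factor applied to the
        query means; 0 makes reference and query exchangeable in expectation.
    library_size_mean
        Expected total counts per cell (before the lognormal per-cell
        size factor, which is mean-one).
    n_mito_genes
        Size of the mitochondrial block (the last gene indices, named "MT-").
    cell_size_log_sd
        Lognormal sigma of the mean-one per-cell library-size factor.
    split_type
        Optional type id whose query cells are split into two clusters
        ("<type>/a", "<type>/b") to stress cluster-level labeling.
    seed
        Root seed; all stages draw from deterministically spawned children.
    """

    n_types: int = 10
    cells_per_type: int = 200
    n_genes: int = 500
    markers_per_type: int = 10
    marker_log_fc: float = 1.0
    dispersion: float = 2.0
    mito_fraction_mean: float = 0.05
    batch_log_fc_sd: float = 0.3
    library_size_mean: int = 5000
    n_mito_genes: int = 10
    cell_size_log_sd: float = 0.25
    split_type: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_types, self.cells_per_type, self.n_genes,
               self.markers_per_type, self.library_size_mean) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_mito_genes <= 0:
            raise ValueError("n_mito_genes must be positive")
        if self.markers_per_type * self.n_types + self.n_mito_genes > self.n_genes:
            raise ValueError(
                "markers_per_type * n_types + n_mito_genes exceeds n_genes; "
                "marker sets must be disjoint and distinct from the MT block"
            )
        if self.marker_log_fc <= 0 or self.dispersion <= 0:
            raise ValueError("marker_log_fc and dispersion must be positive")
        if not 0.0 <= self.mito_fraction_mean < 1.0:
            raise ValueError("mito_fraction_mean must lie in [0, 1)")
        if self.batch_log_fc_sd < 0 or self.cell_size_log_sd < 0:
            raise ValueError("log-sd parameters must be non-negative")


@dataclass
class GroundTruth:
    """Known truth attached to one simulated dataset."""

    cell_labels: pd.Series  # cell id -> type id
    marker_sets: dict[str, list[str]]  # type id -> marker gene names
    true_graph: list[tuple[str, str]]  # directed (progenitor, derivative)
    appearance_day: dict[str, int]  # type id -> first day present

    def __post_init__(self) -> None:
        types = set(self.appearance_day)
        for src, tgt in self.true_graph:
            if src not in types or tgt not in types:
                raise ValueError(f"edge ({src}, {tgt}) names an unknown type")


@dataclass
class SampleGraph:
    """Directed cell-type edge list exported for one sample."""

    sample_id: str
    edges: list[tuple[str, str]]


@dataclass
class SyntheticAtlasPair:
    reference: AnnData
    query: AnnData
    truth_reference: GroundTruth
    truth_query: GroundTruth
    config: SimulationConfig


def _type_names(n: int) -> list[str]:
    return [f"T{i:02d}" for i in range(n)]


def _lineage_tree(n_types: int, rng: np.random.Generator) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Random tree over type indices: each non-root attaches to an earlier type."""
    edges = []
    depth = np.zeros(n_types, dtype=int)
    for i in range(1, n_types):
        parent = int(rng.integers(0, i))
        edges.append((parent, i))
        depth[i] = depth[parent] + 1
    return edges, depth


def _expected_means(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-type expected counts, (n_types, n_genes), plus the mito mask."""
    G, T = config.n_genes, config.n_types
    m = config.markers_per_type
    mito = np.zeros(G, dtype=bool)
    mito[G - config.n_mito_genes:] = True

    w = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    # calibrate the MT block so the expected mito share of a cell's counts
    # equals mito_fraction_mean (marker inflation averaged over types)
    factors = np.ones((T, G))
    for t in range(T):
        factors[t, t * m:(t + 1) * m] = np.exp(config.marker_log_fc)
    nonmito_total = float((w[None, ~mito] * factors[:, ~mito]).sum(axis=1).mean())
    if config.mito_fraction_mean > 0:
        target_mito = config.mito_fraction_mean / (1 - config.mito_fraction_mean) * nonmito_total
        w[mito] *= target_mito / w[mito].sum()
    else:
        w[mito] = 0.0

    mu = w[None, :] * factors
    mu *= config.library_size_mean / mu.sum(axis=1).mean()
    return mu, mito


def _sample_counts(mu_types: np.ndarray, labels_idx: np.ndarray,
                   config: SimulationConfig, rng: np.random.Generator) -> sparse.csr_matrix:
    n_cells = labels_idx.size
    size_factor = rng.lognormal(
        mean=-0.5 * config.cell_size_log_sd**2, sigma=config.cell_size_log_sd, size=n_cells
    )
    mu = mu_types[labels_idx] * size_factor[:, None]
    r = config.dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = r / (r + mu)
    counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    return sparse.csr_matrix(counts.astype(np.int64))


def _build_adata(counts: sparse.csr_matrix, prefix: str, types: list[str],
                 labels_idx: np.ndarray, mito: np.ndarray, marker_of: np.ndarray,
                 days: np.ndarray) -> AnnData:
    n_cells, n_genes = counts.shape
    n_mito = int(mito.sum())
    gene_names = [f"G{i:04d}" for i in range(n_genes - n_mito)]
    gene_names += [f"MT-G{i:04d}" for i in range(n_genes - n_mito, n_genes)]
    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical([types[i] for i in labels_idx], categories=types),
            "timepoint": days,
        },
        index=[f"{prefix}_{i:05d}" for i in range(n_cells)],
    )
    var = pd.DataFrame({"mito": mito, "marker_of": marker_of}, index=gene_names)
    return AnnData(X=counts, obs=obs, var=var)


def generate_atlas_pair(config: SimulationConfig) -> SyntheticAtlasPair:
    """Simulate a labeled reference atlas and a batch-shifted query.

    Counts follow a negative binomial with per-cell library-size factors;
    each marker's mean is inflated by ``exp(marker_log_fc)`` inside its own
    type; query gene means additionally carry an independent multiplicative
    factor ``exp(N(0, batch_log_fc_sd))``. Query cluster ids equal the true
    type ids unless ``split_type`` is set. Identical configs (including the
    seed) give bit-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (rng_means, rng_tree, rng_ref, rng_query,
     rng_batch, rng_days_ref, rng_days_query, rng_split) = (
        np.random.default_rng(s) for s in ss.spawn(8)
    )

    types = _type_names(config.n_types)
    mu_types, mito = _expected_means(config, rng_means)
    tree_edges, depth = _lineage_tree(config.n_types, rng_tree)
    appearance = {t: 3 + 2 * int(d) for t, d in zip(types, depth)}
    max_day = max(appearance.values()) + 4
    day_grid = np.arange(3, max_day + 1, 2)

    m = config.markers_per_type
    marker_of = np.array([""] * config.n_genes, dtype=object)
    marker_sets: dict[str, list[str]] = {}
    n_mito = int(mito.sum())
    gene_names = [f"G{i:04d}" for i in range(config.n_genes - n_mito)]
    gene_names += [f"MT-G{i:04d}" for i in range(config.n_genes - n_mito, config.n_genes)]
    for t_idx, t in enumerate(types):
        idx = np.arange(t_idx * m, (t_idx + 1) * m)
        marker_of[idx] = t
        marker_sets[t] = [gene_names[i] for i in idx]

    labels_idx = np.repeat(np.arange(config.n_types), config.cells_per_type)
    true_graph = [(types[a], types[b]) for a, b in tree_edges]

    def _days(rng: np.random.Generator) -> np.ndarray:
        days = np.empty(labels_idx.size, dtype=int)
        for t_idx, t in enumerate(types):
            valid = day_grid[day_grid >= appearance[t]]
            sel = labels_idx == t_idx
            days[sel] = rng.choice(valid, size=int(sel.sum()), replace=True)
        return days

    ref_counts = _sample_counts(mu_types, labels_idx, config, rng_ref)
    reference = _build_adata(ref_counts, "REF", types, labels_idx, mito,
                             marker_of, _days(rng_days_ref))

    batch = np.exp(rng_batch.normal(0.0, config.batch_log_fc_sd, size=config.n_genes))
    query_counts = _sample_counts(mu_types * batch[None, :], labels_idx, config, rng_query)
    query = _build_adata(query_counts, "QRY", types, labels_idx, mito,
                         marker_of, _days(rng_days_query))

    cluster = query.obs["cell_type"].astype(str)
    if config.split_type is not None:
        if config.split_type not in types:
            raise ValueError(f"split_type {config.split_type!r} is not a simulated type")
        sel = cluster == config.split_type
        halves = rng_split.random(int(sel.sum())) < 0.5
        cluster.loc[sel] = np.where(halves, f"{config.split_type}/a", f"{config.split_type}/b")
    query.obs["cluster"] = pd.Categorical(cluster)

    truth_ref = GroundTruth(reference.obs["cell_type"].astype(str),
                            marker_sets, true_graph, appearance)
    truth_query = GroundTruth(query.obs["cell_type"].astype(str),
                              marker_sets, true_graph, appearance)
    return SyntheticAtlasPair(reference, query, truth_ref, truth_query, config)


def generate_lineage_series(truth: GroundTruth, n_samples: int,
                            flip_prob: float, drop_prob: float,
                            seed: int) -> list[SampleGraph]:
    """Noisy per-sample versions of the true lineage graph.

    Each sample retains each true edge independently with probability
    ``1 - drop_prob``; a retained edge is direction-flipped with probability
    ``flip_prob`` — mimicking velocity-based direction calls that sometimes
    point the wrong way.
    """
    if not truth.true_graph:
        raise ValueError("true_graph is empty")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    for name, p in (("flip_prob", flip_prob), ("drop_prob", drop_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = []
    edges = list(truth.true_graph)
    for s in range(n_samples):
        kept = rng.random(len(edges)) >= drop_prob
        flipped = rng.random(len(edges)) < flip_prob
        out = [
            (tgt, src) if flip else (src, tgt)
            for (src, tgt), keep, flip in zip(edges, kept, flipped)
            if keep
        ]
        samples.append(SampleGraph(sample_id=f"S{s:03d}", edges=out))
    return samples
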