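"""Data-driven importance scores for sentinel-gene selection.

Three per-gene scores are computed from a log2 fold-change matrix:

* **DIS** (diversity importance): experiments are clustered with k-means on
  the leading eigengene coordinates; within each cluster the gene's summed
  squared loadings on the leading principal components measure its
  contribution to that cluster's expression diversity; the per-cluster
  values are averaged with the Tukey biweight.
* **CIS** (co-expression importance): studies are partitioned into folds;
  within each fold genes are hierarchically clustered under the
  1 - |Pearson r| distance and a gene's score is its average squared
  correlation with its cluster mates (zero for singletons); fold-wise
  values are again averaged with the Tukey biweight.
* **OIS** (overall importance): the root-mean-square of the two ascending
  ranks, normalized by the number of genes, so scores lie in (0, 1] with 1
  attained only by a gene ranked last (largest) on both criteria.

The fold-change matrix is a matrix of differential contrasts, so principal
components are taken without centering by default ("variance" = squared
singular value); gene-mean centering is available as a config switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .containers import FoldChangeMatrix, ImportanceScores, SentinelSelection
from .errors import DegenerateInputError, InputError, ParameterError
from .robust import biweight_columns

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-12  # relative singular-value threshold for numerical rank


@dataclass
class EigengeneDecomposition:
    """Truncated uncentered PCA of a genes x comparisons matrix.

    ``loadings`` (genes x G) holds orthonormal eigenvector columns,
    ``scores`` (comparisons x G) the component coordinates of each
    comparison, and ``eigenvalues`` the squared singular values of the
    retained components. G is minimal such that the retained components
    explain at least ``var_fraction`` of the total variance.
    """

    G: int
    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float


def compute_eigengenes(
    fcm: FoldChangeMatrix, var_fraction: float = 0.9, center: str = "none"
) -> EigengeneDecomposition:
    """Eigengene decomposition retaining the minimal G components that
    capture ``var_fraction`` of total variance."""
    if not (0.0 < var_fraction <= 1.0):
        raise ParameterError("var_fraction must lie in (0, 1]")
    if fcm.n_genes < 2 or fcm.n_comparisons < 2:
        raise ParameterError("need at least 2 genes and 2 comparisons")
    X = fcm.to_numpy()
    if center == "gene-mean":
        X = X - X.mean(axis=1, keepdims=True)
    elif center != "none":
        raise ParameterError(f"unknown centering mode {center!r}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s ** 2
    total = float(eigenvalues.sum())
    if total <= 0.0:
        raise DegenerateInputError("fold-change matrix has zero total variance")
    frac = np.cumsum(eigenvalues) / total
    G = int(np.argmax(frac >= var_fraction - 1e-12)) + 1
    return EigengeneDecomposition(
        G=G,
        loadings=U[:, :G],
        scores=(Vt[:G].T * s[:G]),
        eigenvalues=eigenvalues[:G],
        total_variance=total,
    )


def cluster_comparisons(
    decomp: EigengeneDecomposition, k: int = 10, seed: int = 0
) -> np.ndarray:
    """k-means labels (0..k-1) for comparisons in eigengene coordinates.

    Euclidean distance on the G-dimensional score coordinates; k-means++
    initialization with 10 restarts, deterministic for a given seed.
    """
    n = decomp.scores.shape[0]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n < k:
        raise ParameterError(f"{n} comparisons cannot form {k} clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2 ** 31))
    return km.fit_predict(decomp.scores)


def within_cluster_dis(fcm_subset: FoldChangeMatrix, G: int,
                       center: str = "none") -> pd.Series:
    """Per-gene sum of squared loadings on a cluster's leading components.

    The principal components are recomputed on the cluster's own
    comparisons; the sum runs over the first ``min(G, cluster rank)``
    components (truncation is logged). By orthonormality the scores sum to
    that count across genes.
    """
    if fcm_subset.n_comparisons < 2:
        raise ParameterError("within-cluster scores need >=2 comparisons")
    X = fcm_subset.to_numpy()
    if center == "gene-mean":
        X = X - X.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0.0:
        raise DegenerateInputError("cluster submatrix is identically zero")
    rank = int(np.sum(s > s[0] * _RANK_TOL))
    g = min(G, rank)
    if g < G:
        logger.debug("cluster rank %d < G=%d; truncating", rank, G)
    score = (U[:, :g] ** 2).sum(axis=1)
    return pd.Series(score, index=fcm_subset.gene_ids)


def compute_dis(
    fcm: FoldChangeMatrix,
    k: int = 10,
    var_fraction: float = 0.9,
    seed: int = 0,
    center: str = "none",
) -> pd.Series:
    """Diversity importance score per gene.

    Experiments are k-means clustered on the global eigengene coordinates;
    within-cluster summed squared loadings are aggregated across clusters
    with the Tukey biweight mean. Clusters with fewer than two comparisons
    cannot yield a decomposition and are skipped with a log entry.
    """
    decomp = compute_eigengenes(fcm, var_fraction=var_fraction, center=center)
    labels = cluster_comparisons(decomp, k=k, seed=seed)
    per_cluster: list[np.ndarray] = []
    comp_ids = np.array(fcm.comparison_ids, dtype=object)
    for lab in range(int(labels.max()) + 1):
        members = comp_ids[labels == lab]
        if members.size < 2:
            logger.warning("cluster %d has %d comparison(s); skipped in DIS",
                           lab, members.size)
            continue
        sub = fcm.subset_comparisons(list(members))
        per_cluster.append(
            within_cluster_dis(sub, decomp.G, center=center).to_numpy()
        )
    if not per_cluster:
        raise DegenerateInputError("no cluster had >=2 comparisons")
    stacked = np.vstack(per_cluster)  # clusters x genes
    dis = biweight_columns(stacked)
    return pd.Series(dis, index=fcm.gene_ids, name="DIS")


def partition_studies(
    study_ids: pd.Series, n_folds: int = 20, seed: int = 0
) -> pd.Series:
    """Assign each comparison a fold label 0..n_folds-1 at the study level.

    All comparisons of a study share a fold, and per-fold study counts
    differ by at most one (shuffled round-robin assignment).
    """
    study_ids = pd.Series(study_ids, dtype=object)
    studies = list(dict.fromkeys(study_ids))
    if n_folds < 1:
        raise ParameterError("n_folds must be >= 1")
    if len(studies) < n_folds:
        raise ParameterError(
            f"{len(studies)} studies cannot be split into {n_folds} folds"
        )
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    order = rng.permutation(len(studies))
    fold_of_study = {studies[idx]: pos % n_folds for pos, idx in enumerate(order)}
    return pd.Series([fold_of_study[s] for s in study_ids],
                     index=study_ids.index, dtype=int)


@dataclass
class GeneClustering:
    """Partition of genes within one fold; label per gene, clusters >= 1 gene."""

    labels: pd.Series  # gene id -> integer cluster label

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, lab in self.labels.items():
            out.setdefault(int(lab), []).append(gene)
        return out


def _fold_correlation(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gene-gene Pearson correlation; returns (corr, constant_mask).

    Genes with zero variance within the fold have undefined correlation;
    they are flagged and excluded from the correlation matrix.
    """
    const = X.std(axis=1) == 0.0
    active = ~const
    corr = np.empty((0, 0))
    if active.sum() >= 2:
        corr = np.corrcoef(X[active])
        corr = np.clip(corr, -1.0, 1.0)
    elif active.sum() == 1:
        corr = np.ones((1, 1))
    return corr, const


def cluster_genes(fcm_subset: FoldChangeMatrix, h: float = 0.9) -> GeneClustering:
    """Hierarchical gene clustering under the 1 - |Pearson r| distance.

    Average linkage; the tree is cut at height ``h``. Genes constant
    within the fold are isolated as singletons.
    """
    if fcm_subset.n_comparisons < 3:
        raise ParameterError("gene clustering needs >=3 comparisons in the fold")
    if not (0.0 < h):
        raise ParameterError("h must be positive")
    X = fcm_subset.to_numpy()
    genes = fcm_subset.gene_ids
    corr, const = _fold_correlation(X)
    labels = np.full(len(genes), -1, dtype=int)
    active_idx = np.flatnonzero(~const)
    if active_idx.size >= 2:
        dist = 1.0 - np.abs(corr)
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        labs = fcluster(Z, t=h, criterion="distance")
        labels[active_idx] = labs
    elif active_idx.size == 1:
        labels[active_idx[0]] = 1
    next_label = labels.max() + 1 if labels.max() > 0 else 1
    for i in np.flatnonzero(const):
        labels[i] = next_label
        next_label += 1
    return GeneClustering(pd.Series(labels, index=genes, dtype=int))


def fold_cis(fcm_subset: FoldChangeMatrix, clustering: GeneClustering) -> pd.Series:
    """Average squared correlation with cluster mates; 0 for singletons."""
    genes = fcm_subset.gene_ids
    if set(clustering.labels.index) != set(genes):
        raise InputError("clustering does not partition the fold's genes")
    X = fcm_subset.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    out = pd.Series(0.0, index=genes)
    for members in clustering.cluster_members().values():
        if len(members) < 2:
            continue
        idx = [gene_pos[g] for g in members]
        sub = X[idx]
        sd = sub.std(axis=1)
        if (sd == 0.0).any():
            # constant genes should have been singletons; treat r as 0
            nonconst = [i for i, s in zip(idx, sd) if s > 0]
            if len(nonconst) < 2:
                continue
            idx = nonconst
            sub = X[idx]
        r2 = np.clip(np.corrcoef(sub), -1.0, 1.0) ** 2
        np.fill_diagonal(r2, 0.0)
        vals = r2.sum(axis=1) / (len(idx) - 1)
        for i, v in zip(idx, vals):
            out.iloc[i] = v
    return out


def compute_cis(
    fcm: FoldChangeMatrix,
    n_folds: int = 20,
    h: float = 0.9,
    seed: int = 0,
) -> pd.Series:
    """Co-expression importance score per gene.

    Studies are partitioned into ``n_folds`` folds; fold-wise average
    squared within-cluster correlations are aggregated with the Tukey
    biweight mean. Folds with fewer than three comparisons are skipped
    with a warning.
    """
    folds = partition_studies(fcm.study_ids, n_folds=n_folds, seed=seed)
    per_fold: list[np.ndarray] = []
    for f in range(n_folds):
        comp_ids = list(folds.index[folds == f])
        if len(comp_ids) < 3:
            logger.warning("fold %d has %d comparison(s); skipped in CIS",
                           f, len(comp_ids))
            continue
        sub = fcm.subset_comparisons(comp_ids)
        clustering = cluster_genes(sub, h=h)
        per_fold.append(fold_cis(sub, clustering).to_numpy())
    if not per_fold:
        raise DegenerateInputError("no fold had >=3 comparisons")
    stacked = np.vstack(per_fold)
    cis = biweight_columns(stacked)
    return pd.Series(np.clip(cis, 0.0, 1.0), index=fcm.gene_ids, name="CIS")


def _ascending_ranks(values: pd.Series) -> pd.Series:
    """Ranks 1..N, smallest value -> rank 1; ties broken by ascending gene id."""
    genes = np.array(values.index, dtype=object)
    order = np.lexsort((genes, values.to_numpy()))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=values.index)


def compute_ois(dis: pd.Series, cis: pd.Series) -> ImportanceScores:
    """Combine DIS and CIS into overall importance scores.

    Both score vectors are rank-ordered ascending (largest score = rank N)
    and combined as ``OIS = sqrt((rank_CIS^2 + rank_DIS^2)/2) / N``.
    """
    if set(dis.index) != set(cis.index):
        raise InputError("DIS and CIS cover different gene universes")
    cis = cis.reindex(dis.index)
    n = len(dis)
    rank_dis = _ascending_ranks(dis)
    rank_cis = _ascending_ranks(cis)
    ois = np.sqrt((rank_cis ** 2 + rank_dis ** 2) / 2.0) / n
    table = pd.DataFrame(
        {
            "DIS": dis,
            "CIS": cis,
            "rank_DIS": rank_dis,
            "rank_CIS": rank_cis,
            "OIS": ois,
        }
    )
    table.index.name = "gene"
    return ImportanceScores(table)


def compute_scores(
    fcm: FoldChangeMatrix,
    k: int = 10,
    var_fraction: float = 0.9,
    n_folds: int = 20,
    h: float = 0.9,
    seed: int = 0,
    center: str = "none",
) -> ImportanceScores:
    """Full scoring pipeline: DIS, CIS and OIS for every gene."""
    dis = compute_dis(fcm, k=k, var_fraction=var_fraction, seed=seed,
                      center=center)
    cis = compute_cis(fcm, n_folds=n_folds, h=h, seed=seed)
    return compute_ois(dis, cis)


def select_top_n(scores: ImportanceScores, n: int = 1500) -> SentinelSelection:
    """The n genes with the largest OIS; ties broken by ascending gene id."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n > scores.n_genes:
        raise ParameterError(
            f"cannot select {n} genes from a universe of {scores.n_genes}"
        )
    tab = scores.table
    genes = np.array(tab.index, dtype=object)
    order = np.lexsort((genes, -tab["OIS"].to_numpy()))
    chosen = [str(g) for g in genes[order[:n]]]
    return SentinelSelection(
        genes=chosen,
        provenance={g: "data_driven" for g in chosen},
        parameters={"n": n},
    )
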