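"""Performance evaluation: gene-level agreement metrics, fold-change-ranked
enrichment scores, differential-pathway calls, and the cross-validation
harness.

Gene-level metrics pool all (gene, comparison) entries of the evaluated
block: Pearson correlation, concordance of the changed/unchanged call at a
fold-change threshold, overlap of the top-1%-by-magnitude entries, and
mean squared error. Pathway-level metrics apply the same four statistics
to matrices of enrichment scores computed from measured vs
sentinel+extrapolated profiles.

The enrichment score is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum over the fold-change-ranked gene list:
hits advance by |fc|^p / sum_hits |fc|^p, misses retreat by 1/(N - Nh).
With p = 0 it reduces to the classic unweighted KS statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FoldChangeMatrix, GeneSetCollection, ImportanceScores
from .errors import InputError, ParameterError, UndefinedEnrichmentError

logger = logging.getLogger(__name__)


@dataclass
class MetricSet:
    """Agreement between a measured and a predicted matrix."""

    pearson: float
    concordance: float
    significance_overlap: float
    mse: float

    def as_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "concordance": self.concordance,
            "significance_overlap": self.significance_overlap,
            "mse": self.mse,
        }


def gene_level_metrics(
    measured,
    extrapolated,
    fc_threshold: float = 1.0,
    top_fraction: float = 0.01,
) -> MetricSet:
    """Pooled-entry agreement metrics between two equal-shape matrices.

    * Pearson correlation over all entries;
    * concordance: fraction of entries whose |value| >= ``fc_threshold``
      status agrees;
    * significance overlap: |top_M ∩ top_E| / ceil(top_fraction * entries)
      where the top sets are by absolute value (ties resolved by entry
      position for determinism);
    * MSE: mean squared entrywise difference.
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(extrapolated, dtype=float)
    if m.shape != e.shape:
        raise InputError(f"shape mismatch {m.shape} vs {e.shape}")
    m = m.ravel()
    e = e.ravel()
    if m.size < 2:
        raise InputError("need at least 2 entries")
    if m.std() == 0.0 or e.std() == 0.0:
        pearson = 1.0 if np.allclose(m, e) else 0.0
    else:
        pearson = float(np.corrcoef(m, e)[0, 1])
    concordance = float(
        np.mean((np.abs(m) >= fc_threshold) == (np.abs(e) >= fc_threshold))
    )
    top_k = int(np.ceil(top_fraction * m.size))
    top_m = set(np.argsort(-np.abs(m), kind="stable")[:top_k])
    top_e = set(np.argsort(-np.abs(e), kind="stable")[:top_k])
    overlap = len(top_m & top_e) / top_k
    mse = float(np.mean((m - e) ** 2))
    return MetricSet(pearson, concordance, overlap, mse)


# ---------------------------------------------------------------------------
# enrichment scores
# ---------------------------------------------------------------------------

def _ranked(fold_changes: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Genes ranked by fold change descending; equal values by ascending id."""
    genes = np.array(fold_changes.index, dtype=object)
    vals = fold_changes.to_numpy(dtype=float)
    order = np.lexsort((genes, -vals))
    return genes[order], vals[order]


def gsea_es(
    fold_changes: pd.Series,
    gene_set,
    weight_exponent: float = 1.0,
) -> float:
    """Weighted KS running-sum enrichment score in [-1, 1].

    Genes are ranked by fold change (descending). Walking down the list,
    set members increment the running sum by |fc|^p normalized over the
    set's total hit weight; non-members decrement by 1/(universe - hits).
    The score is the running-sum value of maximum absolute deviation, so a
    set concentrated at the top scores near +1 and one at the bottom near
    -1. Degenerate all-zero hit weights fall back to equal weighting.
    """
    if not isinstance(fold_changes, pd.Series):
        fold_changes = pd.Series(fold_changes)
    members = frozenset(gene_set)
    universe = set(fold_changes.index)
    hits_in_universe = members & universe
    if not hits_in_universe:
        raise UndefinedEnrichmentError("gene set has no gene in the universe")
    if len(hits_in_universe) == len(universe):
        raise UndefinedEnrichmentError("gene set covers the whole universe")
    genes, vals = _ranked(fold_changes)
    is_hit = np.array([g in members for g in genes])
    n = genes.size
    n_hit = int(is_hit.sum())
    hit_w = np.abs(vals[is_hit]) ** weight_exponent
    total = hit_w.sum()
    if total <= 0.0:
        hit_w = np.ones(n_hit)
        total = float(n_hit)
    increments = np.zeros(n)
    increments[is_hit] = hit_w / total
    increments[~is_hit] = -1.0 / (n - n_hit)
    running = np.cumsum(increments)
    es = float(running[np.argmax(np.abs(running))])
    return float(np.clip(es, -1.0, 1.0))


def ks_pathway_pvalue(fold_changes: pd.Series, gene_set) -> float:
    """Two-sample KS p-value of in-set vs out-of-set fold changes (asymptotic)."""
    if not isinstance(fold_changes, pd.Series):
        fold_changes = pd.Series(fold_changes)
    members = frozenset(gene_set)
    mask = np.array([g in members for g in fold_changes.index])
    if not mask.any():
        raise UndefinedEnrichmentError("gene set has no gene in the universe")
    if mask.all():
        raise UndefinedEnrichmentError("gene set covers the whole universe")
    inside = fold_changes.to_numpy()[mask]
    outside = fold_changes.to_numpy()[~mask]
    p = float(stats.ks_2samp(inside, outside, method="asymp").pvalue)
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


@dataclass
class EnrichmentResult:
    """Per-pathway ES and KS p-values across comparisons."""

    es: pd.DataFrame      # pathways x comparisons
    ks_p: pd.DataFrame    # pathways x comparisons
    set_sizes: pd.Series  # pathway -> genes used (in-universe members)
    dropped: list[str] = field(default_factory=list)


def pathway_score_matrix(
    fcm: FoldChangeMatrix,
    pathways: GeneSetCollection,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """ES and KS p per pathway per comparison.

    Pathways with no gene in the universe, or covering all of it, are
    dropped with a log entry. The running sums for all pathways of one
    comparison are computed in a single vectorized pass; results agree
    with :func:`gsea_es` / :func:`ks_pathway_pvalue` applied per cell.
    """
    universe = set(fcm.gene_ids)
    genes = np.array(fcm.gene_ids, dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}
    usable: list[str] = []
    dropped: list[str] = []
    sizes: dict[str, int] = {}
    masks = []
    for name, members in pathways.items():
        inter = members & universe
        if len(inter) == 0 or len(inter) == len(universe):
            dropped.append(name)
            continue
        usable.append(name)
        sizes[name] = len(inter)
        mask = np.zeros(genes.size, dtype=bool)
        mask[[gene_pos[g] for g in inter]] = True
        masks.append(mask)
    if dropped:
        logger.info("dropped %d pathway(s) with empty hit set or complement",
                    len(dropped))
    n = genes.size
    P = len(usable)
    es = np.zeros((P, fcm.n_comparisons))
    ks = np.ones_like(es)
    if P:
        M = np.vstack(masks)                     # P x n membership
        n_hit = M.sum(axis=1).astype(float)
        n_miss = n - n_hit
        en = np.round(n_hit * n_miss / n).astype(int)
        X = fcm.to_numpy()
        for j in range(fcm.n_comparisons):
            vals = X[:, j]
            order = np.lexsort((genes, -vals))
            vs = vals[order]
            Ms = M[:, order]
            # -- weighted running sum (enrichment score) --
            w = np.abs(vs) ** weight_exponent
            hit_totals = Ms @ w
            degenerate = hit_totals <= 0.0
            hit_inc = np.where(degenerate[:, None], 1.0 / n_hit[:, None],
                               w[None, :] / np.where(degenerate, 1.0,
                                                     hit_totals)[:, None])
            inc = np.where(Ms, hit_inc, -1.0 / n_miss[:, None])
            running = np.cumsum(inc, axis=1)
            peak = np.argmax(np.abs(running), axis=1)
            es[:, j] = np.clip(running[np.arange(P), peak], -1.0, 1.0)
            # -- two-sample KS p (asymptotic), ties evaluated per group --
            asc = np.argsort(vs, kind="stable")  # ascending values
            Ma = Ms[:, asc]
            diffs = np.abs(np.cumsum(Ma, axis=1) / n_hit[:, None]
                           - np.cumsum(~Ma, axis=1) / n_miss[:, None])
            valid = np.empty(n, dtype=bool)
            valid[:-1] = vs[asc][:-1] != vs[asc][1:]
            valid[-1] = True
            d = diffs[:, valid].max(axis=1)
            ks[:, j] = np.clip(stats.kstwo.sf(d, en),
                               np.nextafter(0.0, 1.0), 1.0)
    cols = fcm.comparison_ids
    return EnrichmentResult(
        es=pd.DataFrame(es, index=usable, columns=cols),
        ks_p=pd.DataFrame(ks, index=usable, columns=cols),
        set_sizes=pd.Series(sizes, dtype=int),
        dropped=dropped,
    )


def differential_pathways(
    enrichment: EnrichmentResult,
    comparison: str | None = None,
    es_threshold: float = 0.5,
    p_threshold: float = 0.001,
) -> set[tuple[str, int]]:
    """Pathways with |ES| > es_threshold and KS p < p_threshold.

    Returns (pathway, direction) pairs with direction = sign(ES). With
    ``comparison=None`` the first (or only) column is used.
    """
    col = comparison if comparison is not None else enrichment.es.columns[0]
    es = enrichment.es[col]
    p = enrichment.ks_p[col]
    hits = (es.abs() > es_threshold) & (p < p_threshold)
    return {(name, int(np.sign(es[name]))) for name in es.index[hits]}


def recall_precision(truth: set, predicted: set) -> tuple[float, float]:
    """Recall and precision of predicted differential pathways.

    Empty truth with empty prediction scores (1.0, 1.0); empty truth with
    predictions yields recall NaN (undefined) and precision 0; empty
    prediction against non-empty truth yields recall 0 and precision NaN.
    """
    truth = set(truth)
    predicted = set(predicted)
    if not truth and not predicted:
        return 1.0, 1.0
    tp = len(truth & predicted)
    recall = tp / len(truth) if truth else float("nan")
    precision = tp / len(predicted) if predicted else float("nan")
    return recall, precision


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    fold: int
    panel_size: int
    gene_level: MetricSet
    pathway_level: MetricSet | None
    recall: float | None = None
    precision: float | None = None


@dataclass
class EvaluationReport:
    """Per-fold metric records plus mean/min/max summary rows."""

    folds: list[FoldRecord]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.folds:
            for level, ms in (("gene", rec.gene_level),
                              ("pathway", rec.pathway_level)):
                if ms is None:
                    continue
                rows.append({"fold": rec.fold, "level": level, **ms.as_dict()})
        df = pd.DataFrame(rows)
        return df

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        metrics = ["pearson", "concordance", "significance_overlap", "mse"]
        out = df.groupby("level")[metrics].agg(["mean", "min", "max"])
        return out


def evaluate_extrapolation(
    model,
    test_fcm: FoldChangeMatrix,
    pathways: GeneSetCollection | None = None,
    fc_threshold: float = 1.0,
    top_fraction: float = 0.01,
    es_threshold: float = 0.5,
    p_threshold: float = 0.001,
    weight_exponent: float = 1.0,
) -> tuple[MetricSet, MetricSet | None, float | None, float | None]:
    """Gene- and pathway-level agreement of a fitted model on held-out data.

    Gene level compares extrapolated vs measured fold changes of the
    target genes. Pathway level compares enrichment scores computed from
    the fully measured profiles against those from the
    sentinel+extrapolated profiles, and derives differential-pathway
    recall/precision pooled over the comparisons (measured calls act as
    truth).
    """
    from .extrapolation import extrapolate, full_profile

    missing = [g for g in model.sentinel_genes if g not in set(test_fcm.gene_ids)]
    if missing:
        raise InputError(f"test matrix lacks sentinel genes: {missing[:5]}")
    sentinel_fc = test_fcm.values.loc[model.sentinel_genes]
    measured_targets = test_fcm.values.loc[model.target_genes].to_numpy()
    predicted_targets = extrapolate(model, sentinel_fc)
    gene_ms = gene_level_metrics(measured_targets, predicted_targets,
                                 fc_threshold, top_fraction)
    if pathways is None or len(pathways) == 0:
        return gene_ms, None, None, None

    profile = full_profile(model, sentinel_fc).reindex(test_fcm.gene_ids)
    extr_fcm = FoldChangeMatrix(profile, test_fcm.study_ids)
    enr_meas = pathway_score_matrix(test_fcm, pathways, weight_exponent)
    enr_extr = pathway_score_matrix(extr_fcm, pathways, weight_exponent)
    common = [p for p in enr_meas.es.index if p in set(enr_extr.es.index)]
    es_m = enr_meas.es.loc[common]
    es_e = enr_extr.es.loc[common]
    pathway_ms = gene_level_metrics(
        es_m.to_numpy(), es_e.to_numpy(),
        fc_threshold=es_threshold, top_fraction=top_fraction,
    )
    truth: set = set()
    predicted: set = set()
    for comp in test_fcm.comparison_ids:
        truth |= {(comp, p, d) for p, d in differential_pathways(
            enr_meas, comp, es_threshold, p_threshold)}
        predicted |= {(comp, p, d) for p, d in differential_pathways(
            enr_extr, comp, es_threshold, p_threshold)}
    recall, precision = recall_precision(truth, predicted)
    return gene_ms, pathway_ms, recall, precision


def cross_validate(
    fcm: FoldChangeMatrix,
    pathways: GeneSetCollection | None,
    config,
    n_folds: int = 20,
    seed: int = 0,
    panel: str = "ois",
) -> EvaluationReport:
    """Study-level k-fold cross-validation of selection + extrapolation.

    Per fold: sentinels are selected on the retained folds (full scoring +
    coverage refinement, or a size-matched random panel when
    ``panel='random'``), the extrapolation operator is fitted on the same
    retained folds, and the held-out fold is predicted from its sentinel
    rows and scored at the gene and pathway level.
    """
    from .coverage import refine_selection
    from .extrapolation import fit_extrapolation
    from .scoring import compute_scores, partition_studies, select_top_n

    if panel not in ("ois", "random"):
        raise ParameterError(f"unknown panel mode {panel!r}")
    folds = partition_studies(fcm.study_ids, n_folds=n_folds, seed=seed)
    records: list[FoldRecord] = []
    rng = np.random.default_rng((int(seed) + 202) % (2 ** 31))
    for f in range(n_folds):
        test_ids = list(folds.index[folds == f])
        train_ids = list(folds.index[folds != f])
        if len(test_ids) == 0 or len(train_ids) < 4:
            logger.warning("fold %d degenerate; skipped", f)
            continue
        train = fcm.subset_comparisons(train_ids)
        test = fcm.subset_comparisons(test_ids)
        if panel == "ois":
            scores = compute_scores(
                train,
                k=config.k,
                var_fraction=config.var_fraction,
                n_folds=config.n_folds,
                h=config.h,
                seed=seed + f,
            )
            sel = select_top_n(scores, n=config.n)
            if pathways is not None and len(pathways) > 0:
                sel = refine_selection(sel, pathways, config.q, scores).selection
            panel_genes = list(sel.genes)
        else:
            panel_genes = list(
                rng.choice(np.array(fcm.gene_ids, dtype=object),
                           size=config.n, replace=False)
            )
        model = fit_extrapolation(train, panel_genes, lam=config.lam)
        gene_ms, path_ms, recall, precision = evaluate_extrapolation(
            model, test, pathways,
            fc_threshold=config.fc_threshold,
            top_fraction=config.top_fraction,
            es_threshold=config.es_threshold,
            p_threshold=config.p_threshold,
            weight_exponent=config.weight_exponent,
        )
        records.append(FoldRecord(
            fold=f, panel_size=len(panel_genes),
            gene_level=gene_ms, pathway_level=path_ms,
            recall=recall, precision=precision,
        ))
    return EvaluationReport(records)
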