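import numpy as np
import pandas as pd
import pytest

from sentinelpanel import (
    FoldChangeMatrix,
    GeneSetCollection,
    ImportanceScores,
    SyntheticSpec,
    generate_foldchange_corpus,
    generate_pathways,
)


@pytest.fixture
def tiny_fcm():
    """3 genes x 4 comparisons, two studies, hand-written values."""
    values = pd.DataFrame(
        [[1.0, 2.0, -1.0, 0.5],
         [2.0, 4.0, -2.0, 1.0],
         [0.1, -0.3, 0.2, 0.0]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3", "c4"],
    )
    studies = pd.Series(["s1", "s1", "s2", "s2"], index=values.columns)
    return FoldChangeMatrix(values, studies)


@pytest.fixture
def small_corpus():
    """Structured synthetic corpus shared by several test modules."""
    spec = SyntheticSpec(
        n_genes=120, n_comparisons=60, n_studies=12, n_modules=3,
        module_sizes=[15, 15, 15], latent_rank=3, noise_sd=0.15,
        n_pathways=10, pathway_size_range=(4, 10), seed=11,
    )
    fcm, truth = generate_foldchange_corpus(spec)
    pathways = generate_pathways(truth, spec)
    return spec, fcm, truth, pathways


def make_scores(gene_ois: dict[str, float]) -> ImportanceScores:
    """ImportanceScores stub with prescribed OIS values (ranks from OIS)."""
    genes = list(gene_ois)
    n = len(genes)
    ois = pd.Series(gene_ois, dtype=float)
    order = np.lexsort((np.array(genes, dtype=object), ois.to_numpy()))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    table = pd.DataFrame(
        {"DIS": ois, "CIS": ois, "rank_DIS": ranks, "rank_CIS": ranks,
         "OIS": ois},
        index=pd.Index(genes, name="gene"),
    )
    return ImportanceScores(table)


def make_collection(sets: dict[str, set[str]]) -> GeneSetCollection:
    return GeneSetCollection({k: frozenset(v) for k, v in sets.items()})
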