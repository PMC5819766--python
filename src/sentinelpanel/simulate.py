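"""Synthetic fold-change corpora with planted co-expression structure.

The generator emulates the statistical features the scoring pipeline
relies on: blocks of co-expressed genes driven by shared latent eigengene
factors, study-specific factor intensities (so experiment clustering has
structure to find), background genes of pure noise, and pathway
collections that overlap the planted modules to a controllable degree.

Fold changes are built as ``loading-matrix @ latent-factors + noise``:
module genes load on their module's latent factor with magnitudes uniform
on [0.5, 1.5] and random signs (so clustering under the 1 - |r| distance
must group anti-correlated partners), genes outside modules are pure
Gaussian noise, and each study scales the factor signal by its own
intensity multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FoldChangeMatrix, GeneSetCollection
from .errors import ParameterError


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic corpus; defaults give a small but
    structured dataset with 5 planted modules over 20 studies."""

    n_genes: int = 400
    n_comparisons: int = 120
    n_studies: int = 24
    n_modules: int = 5
    module_sizes: list[int] = None  # type: ignore[assignment]
    latent_rank: int = 5
    factor_scale: float = 1.0
    noise_sd: float = 0.2
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (5, 15)
    pathway_module_alignment: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [30] * self.n_modules
        if len(self.module_sizes) != self.n_modules:
            raise ParameterError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ParameterError("module sizes exceed the gene count")
        if self.latent_rank > min(self.n_genes, self.n_comparisons):
            raise ParameterError("latent_rank exceeds matrix dimensions")
        if self.n_modules > 0 and self.latent_rank < 1:
            raise ParameterError("modules require latent_rank >= 1")
        if self.noise_sd < 0 or self.factor_scale <= 0:
            raise ParameterError("noise_sd must be >=0 and factor_scale >0")
        if self.n_studies > self.n_comparisons:
            raise ParameterError("more studies than comparisons")
        if not (0.0 <= self.pathway_module_alignment <= 1.0):
            raise ParameterError("pathway_module_alignment must be in [0,1]")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ParameterError("invalid pathway_size_range")


@dataclass
class GroundTruth:
    """Planted structure of a generated corpus."""

    module_labels: pd.Series       # gene -> module name or "" for noise genes
    factors: np.ndarray            # latent_rank x n_comparisons
    loadings: np.ndarray           # n_genes x latent_rank
    pathway_modules: dict[str, str] = field(default_factory=dict)

    def module_genes(self, module: str) -> list[str]:
        return list(self.module_labels.index[self.module_labels == module])

    @property
    def all_module_genes(self) -> list[str]:
        return list(self.module_labels.index[self.module_labels != ""])


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_foldchange_corpus(
    spec: SyntheticSpec,
) -> tuple[FoldChangeMatrix, GroundTruth]:
    """Simulate a fold-change matrix with planted modules and study structure.

    Module ``j`` is driven by latent factor ``j % latent_rank``; factors
    are i.i.d. Gaussian with per-study intensity multipliers (log-uniform
    in [0.5, 2]); noise is i.i.d. Gaussian with sd ``noise_sd``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed % (2 ** 31))
    genes = _gene_ids(spec.n_genes)
    comps = [f"C{i:04d}" for i in range(spec.n_comparisons)]

    # comparisons assigned to studies in contiguous, near-equal blocks
    study_of = np.sort(np.arange(spec.n_comparisons) % spec.n_studies)
    studies = pd.Series([f"S{s:03d}" for s in study_of], dtype=object)

    intensities = np.exp(rng.uniform(np.log(0.5), np.log(2.0), spec.n_studies))
    factors = rng.normal(0.0, spec.factor_scale,
                         size=(spec.latent_rank, spec.n_comparisons))
    factors = factors * intensities[study_of][None, :]

    loadings = np.zeros((spec.n_genes, spec.latent_rank))
    labels = [""] * spec.n_genes
    pos = 0
    for j, size in enumerate(spec.module_sizes):
        fac = j % spec.latent_rank
        mags = rng.uniform(0.5, 1.5, size)
        signs = rng.choice([-1.0, 1.0], size)
        loadings[pos:pos + size, fac] = mags * signs
        for i in range(pos, pos + size):
            labels[i] = f"M{j}"
        pos += size

    values = loadings @ factors
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd,
                                     size=(spec.n_genes, spec.n_comparisons))
    fcm = FoldChangeMatrix(
        pd.DataFrame(values, index=genes, columns=comps), studies
    )
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=genes, dtype=object),
        factors=factors,
        loadings=loadings,
    )
    return fcm, truth


def generate_pathways(
    truth: GroundTruth, spec: SyntheticSpec
) -> GeneSetCollection:
    """Sample a pathway collection overlapping the planted modules.

    With probability ``pathway_module_alignment`` a pathway draws as many
    genes as possible from one module (uniformly chosen) before topping up
    at random; otherwise it is a uniform sample of the gene universe.
    Pathway sizes are uniform over ``pathway_size_range``. The
    module/pathway assignment is recorded in ``truth.pathway_modules``.
    """
    rng = np.random.default_rng((spec.seed + 7919) % (2 ** 31))
    genes = np.array(truth.module_labels.index, dtype=object)
    if spec.n_pathways > 0 and len(genes) == 0:
        raise ParameterError("cannot sample pathways from an empty universe")
    lo, hi = spec.pathway_size_range
    if lo > len(genes):
        raise ParameterError("pathway_size_range exceeds the gene universe")
    modules = sorted({m for m in truth.module_labels if m})
    sets: dict[str, frozenset[str]] = {}
    for i in range(spec.n_pathways):
        name = f"PW{i:03d}"
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        aligned = bool(modules) and rng.random() < spec.pathway_module_alignment
        if aligned:
            module = modules[int(rng.integers(len(modules)))]
            pool = np.array(truth.module_genes(module), dtype=object)
            take = min(size, pool.size)
            chosen = list(rng.choice(pool, size=take, replace=False))
            if take < size:
                rest = np.array([g for g in genes if g not in set(chosen)],
                                dtype=object)
                chosen += list(rng.choice(rest, size=size - take, replace=False))
            truth.pathway_modules[name] = module
        else:
            chosen = list(rng.choice(genes, size=size, replace=False))
            truth.pathway_modules[name] = ""
        sets[name] = frozenset(str(g) for g in chosen)
    return GeneSetCollection(sets, {n: "synthetic" for n in sets})
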