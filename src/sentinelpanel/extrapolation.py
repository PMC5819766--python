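"""Transcriptome extrapolation from sentinel genes by principal component
regression.

The sentinel fold-change submatrix (s genes x m comparisons) is decomposed
into eigengenes; components are retained while their variance stays within
a factor ``lam`` of the leading one (K = largest index with
eigenvalue_K / eigenvalue_1 >= lam). Each non-sentinel gene is regressed
on the K component coordinates — the regressors are orthogonal, so the
least-squares solution is closed-form and needs no regularization; rank
deficiency is handled by the eigenvalue cutoff itself. The composed
operator ``coefficients @ loadings.T`` maps any measured sentinel profile
directly to predicted non-sentinel fold changes.

By default fold changes enter raw (no centering), keeping the operator
linear-homogeneous: a zero sentinel profile extrapolates to zero. A
gene-mean-centered variant is available; centered models add the training
means back on application.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FoldChangeMatrix
from .errors import DegenerateInputError, InputError, ParameterError


@dataclass
class ExtrapolationModel:
    """Linear operator predicting non-sentinel from sentinel fold changes."""

    sentinel_genes: list[str]
    target_genes: list[str]
    K: int
    loadings: np.ndarray          # s x K orthonormal columns
    coefficients: np.ndarray      # t x K
    extrapolation_matrix: np.ndarray  # t x s
    eigenvalues: np.ndarray       # component variances of the sentinel matrix
    lam: float
    center: str = "none"
    sentinel_means: np.ndarray | None = None
    target_means: np.ndarray | None = None

    @property
    def n_sentinels(self) -> int:
        return len(self.sentinel_genes)

    @property
    def n_targets(self) -> int:
        return len(self.target_genes)


def fit_extrapolation(
    fcm: FoldChangeMatrix,
    sentinels: list[str],
    lam: float = 0.01,
    center: str = "none",
) -> ExtrapolationModel:
    """Fit the principal component regression extrapolation operator.

    ``sentinels`` must all be present in ``fcm``; every other gene becomes
    a regression target (in the matrix's row order).
    """
    if not (0.0 < lam <= 1.0):
        raise ParameterError("lambda must lie in (0, 1]")
    if center not in ("none", "gene-mean"):
        raise ParameterError(f"unknown centering mode {center!r}")
    gene_index = set(fcm.gene_ids)
    missing = [g for g in sentinels if g not in gene_index]
    if missing:
        raise InputError(f"sentinel genes absent from matrix: {missing[:10]}")
    if len(set(sentinels)) != len(sentinels):
        raise InputError("duplicate sentinel genes")
    sentinel_set = set(sentinels)
    targets = [g for g in fcm.gene_ids if g not in sentinel_set]
    if not targets:
        raise InputError("no non-sentinel gene to extrapolate")
    if fcm.n_comparisons < 2:
        raise ParameterError("need >=2 training comparisons")

    Xs = fcm.values.loc[list(sentinels)].to_numpy()
    Xt = fcm.values.loc[targets].to_numpy()
    s_means = t_means = None
    if center == "gene-mean":
        s_means = Xs.mean(axis=1)
        t_means = Xt.mean(axis=1)
        Xs = Xs - s_means[:, None]
        Xt = Xt - t_means[:, None]

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eigenvalues = s ** 2
    if eigenvalues.size == 0 or eigenvalues[0] <= 0.0:
        raise DegenerateInputError("sentinel matrix has zero variance")
    ratios = eigenvalues / eigenvalues[0]
    K = int(np.sum(ratios >= lam))
    loadings = U[:, :K]
    # regressors T = S * Vt are mutually orthogonal; LS solution is closed form
    coefficients = (Xt @ Vt[:K].T) / s[:K]
    extrapolation_matrix = coefficients @ loadings.T
    return ExtrapolationModel(
        sentinel_genes=list(sentinels),
        target_genes=targets,
        K=K,
        loadings=loadings,
        coefficients=coefficients,
        extrapolation_matrix=extrapolation_matrix,
        eigenvalues=eigenvalues,
        lam=lam,
        center=center,
        sentinel_means=s_means,
        target_means=t_means,
    )


def _as_sentinel_array(model: ExtrapolationModel, sentinel_fc) -> np.ndarray:
    if isinstance(sentinel_fc, pd.DataFrame):
        if list(sentinel_fc.index) != list(model.sentinel_genes):
            raise InputError("sentinel rows must match the model's gene order")
        arr = sentinel_fc.to_numpy(dtype=float)
    else:
        arr = np.asarray(sentinel_fc, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != model.n_sentinels:
        raise InputError(
            f"expected {model.n_sentinels} sentinel rows, got {arr.shape[0]}"
        )
    return arr


def extrapolate(model: ExtrapolationModel, sentinel_fc) -> np.ndarray:
    """Predict target-gene fold changes from measured sentinel fold changes.

    ``sentinel_fc`` is s x m with rows ordered as ``model.sentinel_genes``
    (a DataFrame is checked against that order). Returns a t x m array.
    """
    arr = _as_sentinel_array(model, sentinel_fc)
    if model.center == "gene-mean":
        out = model.extrapolation_matrix @ (arr - model.sentinel_means[:, None])
        return out + model.target_means[:, None]
    return model.extrapolation_matrix @ arr


def full_profile(model: ExtrapolationModel, sentinel_fc) -> pd.DataFrame:
    """Measured sentinel rows stacked over extrapolated target rows.

    Row order is sentinels then targets; callers comparing against a full
    measured matrix should reindex to its gene order.
    """
    arr = _as_sentinel_array(model, sentinel_fc)
    pred = extrapolate(model, arr)
    columns = (
        sentinel_fc.columns
        if isinstance(sentinel_fc, pd.DataFrame)
        else pd.RangeIndex(arr.shape[1])
    )
    return pd.DataFrame(
        np.vstack([arr, pred]),
        index=[*model.sentinel_genes, *model.target_genes],
        columns=columns,
    )
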