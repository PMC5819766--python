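"""Tukey biweight location estimate.

Used to summarize per-cluster diversity scores and per-fold co-expression
scores into one robust per-gene average that down-weights outlying
clusters/folds. Tuning constant c = 5 follows the Affymetrix biweight
convention; the scale is the median absolute deviation with a small
guard term so that a zero MAD does not collapse the weights.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError


def tukey_biweight_mean(
    values, c: float = 5.0, eps: float = 1e-4,
    tol: float = 1e-9, max_iter: int = 100,
):
    """Iteratively reweighted biweight location of a 1-D sample.

    The location starts at the median; the scale ``MAD + eps*median(|x|)``
    is computed once and held fixed while the location is re-estimated
    with weights ``(1 - u^2)^2`` for ``u = (x - t)/(c*scale)`` (zero
    outside ``|u| < 1``) until the update is below ``tol`` or ``max_iter``
    iterations. Constant input returns that constant exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("tukey_biweight_mean expects a 1-D sequence")
    if x.size == 0:
        raise ParameterError("tukey_biweight_mean of an empty sequence")
    return float(biweight_columns(x[:, None], c=c, eps=eps,
                                  tol=tol, max_iter=max_iter)[0])


def biweight_columns(
    x: np.ndarray, c: float = 5.0, eps: float = 1e-4,
    tol: float = 1e-9, max_iter: int = 100,
) -> np.ndarray:
    """Vectorized biweight location of each column of a 2-D array.

    Columns whose scale is exactly zero (more than half the entries tied
    at the median and a zero guard term) degrade gracefully to the plain
    arithmetic mean of the column.
    """
    if x.ndim != 2:
        raise ParameterError("biweight_columns expects a 2-D array")
    if x.shape[0] == 0:
        raise ParameterError("biweight of zero observations")
    t = np.median(x, axis=0)
    mad = np.median(np.abs(x - t), axis=0)
    scale = mad + eps * np.median(np.abs(x), axis=0)
    zero_scale = scale <= 0.0
    denom = c * np.where(zero_scale, 1.0, scale)
    for _ in range(max_iter):
        with np.errstate(over="ignore"):  # |u|>=1 gets weight 0 anyway
            u = np.clip((x - t) / denom, -1.0, 1.0)
        w = (1.0 - u * u) ** 2
        w[:, zero_scale] = 1.0  # degenerate scale: unweighted mean
        wsum = w.sum(axis=0)
        stuck = wsum <= 0.0
        if stuck.any():  # all points rejected: keep current location there
            w[:, stuck] = 0.0
            wsum = np.where(stuck, 1.0, wsum)
            t_new = np.where(stuck, t, (w * x).sum(axis=0) / wsum)
        else:
            t_new = (w * x).sum(axis=0) / wsum
        if np.max(np.abs(t_new - t)) < tol:
            t = t_new
            break
        t = t_new
    return t
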