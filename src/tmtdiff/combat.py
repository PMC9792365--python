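"""Parametric empirical-Bayes batch correction (ComBat-style).

Per-batch, per-protein location and scale effects are estimated on a
standardized matrix, shrunk toward parametric priors — Normal for the
locations, inverse-gamma for the scales — by the usual iterative
empirical-Bayes update, and removed.  An optional protected covariate
(typically the case/control group) is included in the standardization
model so that biological signal is not absorbed into the batch means,
and is restored after adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix, check_order
from .errors import DesignError, TransformError

logger = logging.getLogger(__name__)

__all__ = ["BatchModelParams", "combat_adjust"]


@dataclass
class BatchModelParams:
    """Fitted location/scale batch model.

    ``gamma_hat``/``delta2_hat`` are the raw per-batch per-protein
    estimates (proteins x batches); ``gamma_star``/``delta2_star`` the
    empirical-Bayes shrunken ones.  ``priors`` holds, per batch, the
    location-prior mean and variance and the inverse-gamma shape
    (``lambda``) and scale (``theta``) of the scale prior.
    """

    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    priors: pd.DataFrame
    iterations: pd.Series


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_iterate(
    z: np.ndarray,
    g_hat: np.ndarray,
    d2_hat: np.ndarray,
    g_bar: float,
    tau2: float,
    lam: float,
    theta: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Joint posterior-mode update for one batch (all proteins at once)."""
    n = z.shape[1]
    g_new, d2_new = g_hat.copy(), d2_hat.copy()
    for it in range(1, max_iter + 1):
        g_old, d2_old = g_new, d2_new
        g_new = (n * tau2 * g_hat + d2_old * g_bar) / (n * tau2 + d2_old)
        ss = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d2_new = (theta + 0.5 * ss) / (n / 2 + lam - 1)
        eps = 1e-12
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), eps),
            np.abs(d2_new - d2_old).max() / max(np.abs(d2_old).max(), eps),
        )
        if change < tol:
            return g_new, d2_new, it
    raise TransformError(
        f"empirical-Bayes update did not converge within {max_iter} iterations"
    )


def combat_adjust(
    matrix: NormalizedMatrix,
    batches: pd.Series | None = None,
    protect_group: pd.Series | None = None,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> tuple[NormalizedMatrix, BatchModelParams | None]:
    """Remove additive and multiplicative batch effects.

    Parameters
    ----------
    matrix
        missing-free normalized matrix (proteins x samples).
    batches
        batch label per sample; defaults to the matrix annotations.
    protect_group
        covariate protected during standardization: ``"auto"`` uses the
        case/control annotation, or pass explicit labels.  The default
        (no covariate) is right for batch-balanced designs, where the
        group contrast survives correction untouched; protecting it is
        only needed when groups are unevenly spread over batches, and
        is known to exaggerate downstream significance.
    tol, max_iter
        convergence control of the empirical-Bayes iteration.

    Returns the adjusted matrix (same shape and protein order) and the
    fitted :class:`BatchModelParams` (``None`` when only one batch is
    present, in which case the data are returned unchanged).
    """
    # re-application is allowed (it is a near-identity on corrected data)
    if "combat_adjust" not in matrix.steps:
        check_order(matrix.steps, "combat_adjust")
    if matrix.data.isna().any().any():
        raise DesignError("combat_adjust requires a missing-free matrix (run drop_missing)")
    if batches is None:
        batches = matrix.batches
    batches = pd.Series(batches).loc[matrix.data.columns]
    levels = pd.unique(batches)
    if len(levels) < 2:
        logger.info("single batch label: batch correction is the identity")
        out = NormalizedMatrix(
            matrix.data.copy(), matrix.annotations.copy(),
            steps=matrix.steps + ["combat_adjust"],
        )
        return out, None
    sizes = batches.value_counts()
    singleton = sizes[sizes < 2]
    if len(singleton):
        raise DesignError(f"singleton batch(es): {list(singleton.index)}")

    X = matrix.data.to_numpy(dtype=float)
    n = X.shape[1]
    batch_design = pd.get_dummies(batches, dtype=float)[list(levels)].to_numpy()
    design_parts = [batch_design]
    if isinstance(protect_group, str) and protect_group == "auto":
        protect_group = matrix.groups if matrix.groups.nunique() > 1 else None
    if protect_group is not None:
        cov = pd.get_dummies(pd.Series(protect_group).loc[matrix.data.columns], dtype=float)
        design_parts.append(cov.iloc[:, 1:].to_numpy())  # drop one level
    design = np.hstack(design_parts)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DesignError("confounded design: batch and protected covariate are collinear")

    # per-protein OLS fit of batch + covariate model
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    n_i = batch_design.sum(axis=0)
    grand = (n_i / n) @ beta[: len(levels)]          # weighted grand mean per protein
    resid = X.T - design @ beta
    var_pooled = (resid**2).mean(axis=0)             # divide by n, as is conventional
    if (var_pooled <= 0).any():
        raise TransformError("zero pooled variance: constant protein row(s) present")

    stand_mean = np.tile(grand, (n, 1))
    if design.shape[1] > len(levels):
        stand_mean = stand_mean + design[:, len(levels):] @ beta[len(levels):]
    sigma = np.sqrt(var_pooled)
    Z = (X.T - stand_mean) / sigma                   # samples x proteins

    gamma_hat = np.empty((len(levels), X.shape[0]))
    delta2_hat = np.empty_like(gamma_hat)
    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(gamma_hat)
    priors = []
    iterations = []
    Z_adj = Z.copy()
    for i, lev in enumerate(levels):
        in_batch = batch_design[:, i] == 1
        Zb = Z[in_batch].T                           # proteins x batch samples
        g_hat = Zb.mean(axis=1)
        d2_hat = Zb.var(axis=1, ddof=1)
        g_bar, tau2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        lam, theta = _aprior(d2_hat), _bprior(d2_hat)
        g_star, d2_star, its = _eb_iterate(
            Zb, g_hat, d2_hat, g_bar, tau2, lam, theta, tol, max_iter
        )
        gamma_hat[i], delta2_hat[i] = g_hat, d2_hat
        gamma_star[i], delta2_star[i] = g_star, d2_star
        priors.append((lev, g_bar, tau2, lam, theta))
        iterations.append(its)
        Z_adj[in_batch] = (Zb.T - g_star) / np.sqrt(d2_star)

    X_adj = (Z_adj * sigma + stand_mean).T
    out = NormalizedMatrix(
        pd.DataFrame(X_adj, index=matrix.protein_ids, columns=matrix.data.columns),
        matrix.annotations.copy(),
        steps=matrix.steps + ["combat_adjust"],
    )
    params = BatchModelParams(
        gamma_hat=pd.DataFrame(gamma_hat.T, index=matrix.protein_ids, columns=levels),
        delta2_hat=pd.DataFrame(delta2_hat.T, index=matrix.protein_ids, columns=levels),
        gamma_star=pd.DataFrame(gamma_star.T, index=matrix.protein_ids, columns=levels),
        delta2_star=pd.DataFrame(delta2_star.T, index=matrix.protein_ids, columns=levels),
        priors=pd.DataFrame(
            priors, columns=["batch", "gamma_bar", "tau2", "lambda", "theta"]
        ).set_index("batch"),
        iterations=pd.Series(iterations, index=pd.Index(levels, name="batch")),
    )
    return out, params
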