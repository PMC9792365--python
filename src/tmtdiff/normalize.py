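"""The normalization cascade for multi-batch reporter intensities.

Order is enforced: reference_normalize -> median_center -> log2_zscore
-> drop_missing -> combat_adjust (see :mod:`tmtdiff.combat`), mirroring
reference-pool division, per-protein median centring, log2 + z-score
transformation, missing-value filtering and empirical-Bayes batch
correction.  :func:`batch_pca` provides the 2-D PCA / silhouette batch
diagnostic used to judge correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import AbundanceTable, NormalizedMatrix, check_order, require_step
from .errors import DesignError, InputError, TransformError

logger = logging.getLogger(__name__)

__all__ = [
    "reference_normalize",
    "median_center",
    "log2_zscore",
    "drop_missing",
    "batch_pca",
]


def reference_normalize(table: AbundanceTable) -> AbundanceTable:
    """Divide every biological intensity by its batch's reference value.

    Each batch must carry exactly one reference (master pool) sample.
    Missing propagates: a protein whose reference value is missing in a
    batch becomes missing for all of that batch's samples.  Reference
    values of 0 are treated as missing with a warning.  The reference
    columns are dropped from the result.
    """
    check_order(table.steps, "reference_normalize")
    refs = table.annotations[table.annotations["group"] == "reference"]
    per_batch = refs.groupby("batch").size()
    all_batches = table.annotations["batch"].unique()
    bad = [b for b in all_batches if per_batch.get(b, 0) != 1]
    if bad:
        raise DesignError(f"each batch needs exactly one reference sample; offending: {bad}")

    ref_by_batch = {row["batch"]: sid for sid, row in refs.iterrows()}
    out = {}
    for sid in table.biological_samples():
        batch = table.annotations.loc[sid, "batch"]
        ref = table.data[ref_by_batch[batch]]
        n_zero = int((ref == 0).sum())
        if n_zero:
            logger.warning("batch %s: %d zero reference values treated as missing", batch, n_zero)
        ref = ref.mask(ref == 0)
        out[sid] = table.data[sid] / ref
    bio = table.biological_samples()
    return AbundanceTable(
        pd.DataFrame(out, index=table.protein_ids)[bio],
        table.annotations.loc[bio].copy(),
        steps=table.steps + ["reference_normalize"],
    )


def median_center(table: AbundanceTable) -> AbundanceTable:
    """Divide each protein row by its median over observed samples.

    All-missing rows are passed through unchanged (and logged); every
    other row has post-centring median exactly 1.
    """
    require_step(table, "reference_normalize")
    check_order(table.steps, "median_center")
    med = table.data.median(axis=1, skipna=True)
    all_missing = med.isna()
    if all_missing.any():
        logger.warning("%d all-missing protein rows passed through", int(all_missing.sum()))
    centred = table.data.div(med.where(~all_missing, 1.0), axis=0)
    return AbundanceTable(
        centred,
        table.annotations.copy(),
        steps=table.steps + ["median_center"],
    )


def log2_zscore(
    table: AbundanceTable, axis: str = "sample", ddof: int = 1
) -> NormalizedMatrix:
    """log2-transform, then z-score within each sample column.

    ``axis='protein'`` z-scores within protein rows instead (a common
    alternative convention); the default follows per-sample scaling.
    Uses the sample SD (``ddof=1``).  Non-positive observed values and
    zero-variance columns are transform errors.
    """
    require_step(table, "median_center")
    check_order(table.steps, "log2_zscore")
    if axis not in ("sample", "protein"):
        raise InputError(f"axis must be 'sample' or 'protein', got {axis!r}")
    values = table.data.to_numpy(dtype=float)
    nonpos = np.asarray((values <= 0) & ~np.isnan(values)).nonzero()
    if len(nonpos[0]):
        i, j = nonpos[0][0], nonpos[1][0]
        raise TransformError(
            f"non-positive value for protein {table.protein_ids[i]!r}, "
            f"sample {table.data.columns[j]!r}: cannot log2-transform"
        )
    logged = np.log2(values)
    ax = 0 if axis == "sample" else 1
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(logged, axis=ax, keepdims=True)
        sd = np.nanstd(logged, axis=ax, ddof=ddof, keepdims=True)
    degenerate = ~(sd > 0)
    if degenerate.any():
        which = (table.data.columns if axis == "sample" else table.protein_ids)[
            degenerate.ravel()
        ]
        raise TransformError(
            f"zero-variance {axis} column(s), z-score undefined: {list(which[:5])}"
        )
    z = (logged - mean) / sd
    return NormalizedMatrix(
        pd.DataFrame(z, index=table.protein_ids, columns=table.data.columns),
        table.annotations.copy(),
        steps=table.steps + ["log2_zscore"],
    )


def drop_missing(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Retain only proteins with zero missing entries, order preserved."""
    check_order(matrix.steps, "drop_missing")
    keep = ~matrix.data.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("drop_missing: removed %d of %d proteins", n_dropped, len(keep))
    if not keep.any():
        logger.warning("drop_missing: no proteins retained")
    return NormalizedMatrix(
        matrix.data.loc[keep].copy(),
        matrix.annotations.copy(),
        steps=matrix.steps + ["drop_missing"],
    )


def batch_pca(
    matrix: NormalizedMatrix, batches: pd.Series | None = None
) -> tuple[pd.DataFrame, float]:
    """2-D PCA of samples plus a batch-separation silhouette score.

    Samples are the observations (proteins the features).  Returns the
    sample coordinates on the first two components and the mean
    silhouette of the batch labels on those coordinates (≈0 when
    batches are indistinguishable, near 1 when fully separated).
    """
    if batches is None:
        batches = matrix.batches
    X = matrix.data.to_numpy(dtype=float).T
    if X.shape[0] < 3:
        raise InputError(f"PCA diagnostic needs >= 3 samples, got {X.shape[0]}")
    if X.shape[1] < 2:
        raise InputError(f"PCA diagnostic needs >= 2 proteins, got {X.shape[1]}")
    coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
    coords = pd.DataFrame(coords, index=matrix.data.columns, columns=["PC1", "PC2"])
    labels = pd.Series(batches).loc[matrix.data.columns]
    if labels.nunique() < 2:
        score = 0.0
    else:
        score = float(silhouette_score(coords.to_numpy(), labels.to_numpy()))
    return coords, score
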