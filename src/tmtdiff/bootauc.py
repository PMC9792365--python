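"""Bootstrap ROC/AUC differential statistic with a permutation q-value.

Each protein is scored by the AUC of its abundance as a case/control
classifier.  Stratified bootstrap resampling (cases from cases,
controls from controls, original sizes kept) yields a mean and SD of
the AUC over B resamples; the mean measures effect, the SD stability.
q-values follow a sorted-ratio procedure: observed mean AUCs are split
into an upper (> 0.5) and a lower (< 0.5) tail, and at the threshold of
each observed value the q-value is the average number of
label-permuted null mean AUCs at least as extreme divided by the
number of observed ones, clipped and monotonized within each tail.

The AUC itself uses the Mann–Whitney pair-counting identity with
midrank tie handling, so a bootstrap resample can be evaluated exactly
from the multiplicities of the resampled subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix
from .errors import ConfigurationError, InputError
from .sam import _group_masks

logger = logging.getLogger(__name__)

__all__ = [
    "BootAucConfig",
    "auc",
    "bootstrap_auc",
    "null_bootstrap_auc",
    "bootauc_q",
    "rank_by_sd",
]


@dataclass(frozen=True)
class BootAucConfig:
    """Settings of the bootstrap-AUC analysis.

    ``n_bootstrap`` is B, the resamples per protein (1000 in the study
    design this emulates); ``n_label_permutations`` the number of
    whole-matrix label permutations building the null distribution of
    mean AUCs.  ``literal_ratio`` flips the q ratio to the literal
    observed/null orientation (see methods note); the default
    null/observed orientation is the one that estimates an FDR.
    """

    n_bootstrap: int = 1000
    n_label_permutations: int = 20
    seed: int = 0
    q_threshold: float = 0.05
    stratified: bool = True
    stratify_permutations_by_batch: bool = True
    literal_ratio: bool = False

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2:
            raise ConfigurationError(f"n_bootstrap must be >= 2, got {self.n_bootstrap}")
        if self.n_label_permutations < 1:
            raise ConfigurationError(
                f"n_label_permutations must be >= 1, got {self.n_label_permutations}"
            )
        if not 0 < self.q_threshold < 1:
            raise ConfigurationError(f"q_threshold must be in (0, 1), got {self.q_threshold}")


def auc(scores, labels) -> float:
    """AUC of ``scores`` for the positive class, by pair counting.

    ``labels`` is boolean/0-1 with True marking the positive (case)
    class; ties contribute 0.5 per pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("auc needs at least one sample in each class")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _pairwise_auc_matrix(case_vals: np.ndarray, ctrl_vals: np.ndarray) -> np.ndarray:
    """(proteins x n_case x n_ctrl) win matrix: 1 win, 0.5 tie, 0 loss."""
    gt = case_vals[:, :, None] > ctrl_vals[:, None, :]
    eq = case_vals[:, :, None] == ctrl_vals[:, None, :]
    return gt + 0.5 * eq


def _bootstrap_mean_sd(
    X: np.ndarray,
    case: np.ndarray,
    ctrl: np.ndarray,
    config: BootAucConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Point AUC plus bootstrap mean/SD per protein (vectorized).

    A stratified resample with multiplicity c over cases and m over
    controls has AUC  c^T G m / (n1 n2 · scale), where G is the
    pairwise win matrix — so B resamples reduce to one einsum.
    Degenerate all-tied resamples land on 0.5 automatically (every
    pair contributes 0.5).
    """
    n1, n2 = int(case.sum()), int(ctrl.sum())
    P = X.shape[0]
    G = _pairwise_auc_matrix(X[:, case], X[:, ctrl])
    point = G.mean(axis=(1, 2))
    B = config.n_bootstrap
    if config.stratified:
        c_counts = rng.multinomial(n1, np.full(n1, 1 / n1), size=(P, B)).astype(float)
        m_counts = rng.multinomial(n2, np.full(n2, 1 / n2), size=(P, B)).astype(float)
        aucs = np.einsum("pbi,pij,pbj->pb", c_counts, G, m_counts) / (n1 * n2)
    else:
        # joint resample of all subjects, then split by class; a resample
        # lacking one class is redrawn implicitly by conditioning: we
        # resample per subject and renormalize by realized pair counts.
        n = n1 + n2
        counts = rng.multinomial(n, np.full(n, 1 / n), size=(P, B)).astype(float)
        c_counts = counts[:, :, : n1] if case[:n1].all() else None
        if c_counts is None:
            raise InputError("unstratified resampling requires contiguous class layout")
        m_counts = counts[:, :, n1:]
        pair_n = c_counts.sum(2) * m_counts.sum(2)
        raw = np.einsum("pbi,pij,pbj->pb", c_counts, G, m_counts)
        with np.errstate(invalid="ignore"):
            aucs = np.where(pair_n > 0, raw / np.maximum(pair_n, 1), 0.5)
    return point, aucs.mean(axis=1), aucs.std(axis=1, ddof=1)


def bootstrap_auc(
    matrix: NormalizedMatrix,
    groups: pd.Series | None = None,
    config: BootAucConfig = BootAucConfig(),
) -> pd.DataFrame:
    """Per-protein point AUC, bootstrap mean AUC and bootstrap SD."""
    if groups is None:
        groups = matrix.groups
    case_all, ctrl_all = _group_masks(matrix.data.columns, groups)
    pool = case_all | ctrl_all
    # contiguous case-then-control layout keeps the unstratified variant simple
    order = np.concatenate([np.flatnonzero(case_all), np.flatnonzero(ctrl_all)])
    X = matrix.data.to_numpy(dtype=float)[:, order]
    n1 = int(case_all.sum())
    case = np.zeros(X.shape[1], dtype=bool)
    case[:n1] = True
    rng = np.random.default_rng(config.seed)
    point, mean, sd = _bootstrap_mean_sd(X, case, ~case, config, rng)
    return pd.DataFrame(
        {"auc": point, "mean_auc": mean, "sd_auc": sd}, index=matrix.protein_ids
    )


def null_bootstrap_auc(
    matrix: NormalizedMatrix,
    groups: pd.Series | None = None,
    config: BootAucConfig = BootAucConfig(),
) -> pd.DataFrame:
    """Bootstrap mean AUCs under label permutations, with provenance.

    Returns one row per (permutation, protein) with the permuted-label
    bootstrap mean AUC; the ``permutation`` column records which seeded
    permutation produced each value.
    """
    if groups is None:
        groups = matrix.groups
    case_all, ctrl_all = _group_masks(matrix.data.columns, groups)
    pool_idx = np.flatnonzero(case_all | ctrl_all)
    X = matrix.data.to_numpy(dtype=float)[:, pool_idx]
    case_obs = case_all[pool_idx]
    batches = matrix.batches.to_numpy()[pool_idx]
    if config.stratify_permutations_by_batch and len(np.unique(batches)) > 1:
        strata = [np.flatnonzero(batches == b) for b in np.unique(batches)]
    else:
        strata = [np.arange(X.shape[1])]
    rng = np.random.default_rng(config.seed)
    frames = []
    for r in range(config.n_label_permutations):
        case = np.zeros(X.shape[1], dtype=bool)
        for idx in strata:
            k = int(case_obs[idx].sum())
            case[rng.choice(idx, size=k, replace=False)] = True
        # contiguous case-first layout for the resampler
        order = np.concatenate([np.flatnonzero(case), np.flatnonzero(~case)])
        Xp = X[:, order]
        case_c = np.zeros(X.shape[1], dtype=bool)
        case_c[: int(case.sum())] = True
        _, mean, sd = _bootstrap_mean_sd(Xp, case_c, ~case_c, config, rng)
        frames.append(
            pd.DataFrame(
                {
                    "permutation": r,
                    "protein": matrix.protein_ids,
                    "mean_auc": mean,
                    "sd_auc": sd,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _tail_q(
    obs_dev: np.ndarray, null_dev: np.ndarray, n_perm: int, literal: bool
) -> np.ndarray:
    """q per observed deviation-from-0.5 within one tail."""
    order = np.argsort(-obs_dev, kind="stable")
    sorted_obs = obs_dev[order]
    null_sorted = np.sort(null_dev)
    null_count = (len(null_sorted) - np.searchsorted(null_sorted, sorted_obs, side="left")) / n_perm
    obs_count = np.arange(1, len(sorted_obs) + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs_count / null_count if literal else null_count / obs_count
    ratio = np.where(np.isfinite(ratio), ratio, 0.0 if not literal else 1.0)
    q_sorted = np.clip(ratio, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bootauc_q(
    real_rows: pd.DataFrame,
    null_means: pd.DataFrame,
    config: BootAucConfig = BootAucConfig(),
) -> pd.DataFrame:
    """Attach sorted-ratio permutation q-values to a bootstrap-AUC table.

    Upper-tail proteins (mean AUC > 0.5) are compared against null mean
    AUCs above 0.5, lower-tail against those below, each sorted toward
    its extreme; proteins at exactly 0.5 get q = 1.
    """
    if null_means.empty:
        raise InputError("null distribution is empty")
    n_perm = int(null_means["permutation"].nunique())
    mean = real_rows["mean_auc"].to_numpy(dtype=float)
    null = null_means["mean_auc"].to_numpy(dtype=float)
    q = np.ones(len(mean))
    upper, lower = mean > 0.5, mean < 0.5
    for tail, obs_mask in (("upper", upper), ("lower", lower)):
        if not obs_mask.any():
            logger.info("bootauc_q: empty %s tail skipped", tail)
            continue
        obs_dev = np.abs(mean[obs_mask] - 0.5)
        null_dev = (null - 0.5) if tail == "upper" else (0.5 - null)
        null_dev = null_dev[null_dev > 0]
        q[obs_mask] = _tail_q(obs_dev, null_dev, n_perm, config.literal_ratio)
    out = real_rows.copy()
    out["q"] = q
    out["significant"] = out["q"] < config.q_threshold
    return out


def rank_by_sd(rows: pd.DataFrame, significant_only: bool = True) -> pd.Index:
    """Protein ids ordered by bootstrap-SD ascending (stable).

    Ties on SD are broken by |mean AUC - 0.5| descending, then by
    protein id — putting the most stable, most discriminative proteins
    first.
    """
    table = rows[rows["significant"]] if significant_only and "significant" in rows else rows
    key = table.assign(
        _dev=-(table["mean_auc"] - 0.5).abs(), _id=table.index
    ).sort_values(["sd_auc", "_dev", "_id"], kind="stable")
    return key.index
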