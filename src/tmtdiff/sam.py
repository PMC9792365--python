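"""SAM-style differential testing with permutation-based q-values.

The moderated statistic is d = (mean_case - mean_control) / (s + s0),
with s the pooled standard error and s0 a small stabilization constant
that damps significance at tiny effect sizes (shaping the curved
volcano-plot boundary).  q-values come from label permutations: for the
threshold at each observed |d|, the q-value is the average number of
permuted statistics at least as extreme, divided by the number of
observed ones, clipped to [0, 1] and monotonized.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, NormalizedMatrix
from .errors import ConfigurationError, DesignError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SamConfig",
    "two_sample_t",
    "shapiro_normality",
    "fold_change",
    "sam_q",
    "volcano_boundary",
]


@dataclass(frozen=True)
class SamConfig:
    """Settings of the SAM permutation analysis.

    ``s0`` is required thinking of it as an analysis choice to be
    reported, not a constant; 0.1 is a conventional volcano default.
    ``balanced`` restricts permutations to those swapping half of each
    group; the default draws uniformly from all distinct label
    assignments, which keeps the permutation null exchangeable.
    ``stratify_by_batch`` permutes labels within batches (preserving
    each batch's case count), the correct scheme for multi-batch
    designs: it keeps permuted statistics exchangeable with the
    observed one even when batch correction was imperfect.
    """

    s0: float = 0.1
    n_permutations: int = 250
    seed: int = 0
    q_threshold: float = 0.05
    equal_variance: bool = True
    balanced: bool = False
    stratify_by_batch: bool = True

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ConfigurationError(f"s0 must be >= 0, got {self.s0}")
        if self.n_permutations < 1:
            raise ConfigurationError(f"n_permutations must be >= 1, got {self.n_permutations}")
        if not 0 < self.q_threshold < 1:
            raise ConfigurationError(f"q_threshold must be in (0, 1), got {self.q_threshold}")


def _group_masks(columns: pd.Index, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(groups).loc[columns]
    case = (g == "case").to_numpy()
    ctrl = (g == "control").to_numpy()
    if case.sum() < 2 or ctrl.sum() < 2:
        raise DesignError(
            f"both groups need >= 2 samples (case={int(case.sum())}, control={int(ctrl.sum())})"
        )
    return case, ctrl


def _moderated_stats(
    X: np.ndarray, case: np.ndarray, ctrl: np.ndarray, s0: float, pooled: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (diff, s, d) per row for a case/control split."""
    n1, n2 = int(case.sum()), int(ctrl.sum())
    m1, m2 = X[:, case].mean(axis=1), X[:, ctrl].mean(axis=1)
    v1 = X[:, case].var(axis=1, ddof=1)
    v2 = X[:, ctrl].var(axis=1, ddof=1)
    diff = m1 - m2
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        s = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        s = np.sqrt(v1 / n1 + v2 / n2)
    return diff, s, diff / (s + s0)


def two_sample_t(
    matrix: NormalizedMatrix, groups: pd.Series | None = None, equal_variance: bool = True
) -> pd.DataFrame:
    """Two-sided two-sample t test per protein (pooled variance by default).

    Degenerate rows with zero variance in both groups get t = 0, p = 1
    when the means agree (identical vectors); otherwise the p-value is 0
    in the limit and is reported as such.
    """
    if groups is None:
        groups = matrix.groups
    if matrix.data.isna().any().any():
        raise InputError("two_sample_t requires a missing-free matrix")
    X = matrix.data.to_numpy(dtype=float)
    case, ctrl = _group_masks(matrix.data.columns, groups)
    res = stats.ttest_ind(X[:, case], X[:, ctrl], axis=1, equal_var=equal_variance)
    t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    diff = X[:, case].mean(axis=1) - X[:, ctrl].mean(axis=1)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & (np.abs(diff) < 1e-12), 0.0, t)
    p = np.where(degenerate & (np.abs(diff) < 1e-12), 1.0, p)
    signed_inf = np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0))
    t = np.where(~np.isfinite(t), signed_inf, t)
    p = np.where(np.isfinite(p), p, 0.0)
    return pd.DataFrame({"t": t, "p": p}, index=matrix.protein_ids)


def shapiro_normality(matrix: NormalizedMatrix) -> tuple[pd.DataFrame, float]:
    """Shapiro–Wilk W and p per protein plus the fraction with p > 0.05.

    Constant rows are flagged (NaN statistics) and excluded from the
    summary fraction.
    """
    X = matrix.data.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise InputError("Shapiro–Wilk needs >= 3 observations per protein")
    W = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    constant = np.ptp(X, axis=1) == 0
    for i in range(X.shape[0]):
        if constant[i]:
            continue
        W[i], p[i] = stats.shapiro(X[i])
    if constant.any():
        logger.warning("%d constant rows: Shapiro–Wilk undefined, flagged", int(constant.sum()))
    out = pd.DataFrame({"W": W, "p": p, "flagged": constant}, index=matrix.protein_ids)
    valid = out["p"].dropna()
    frac = float((valid > 0.05).mean()) if len(valid) else float("nan")
    return out, frac


def fold_change(table: AbundanceTable, groups: pd.Series | None = None) -> pd.Series:
    """Per-protein mean(case) / mean(control) on the linear scale.

    Meant for the median-centred relative abundances (before the log2
    transform).  A zero control mean yields +inf and is logged.
    """
    if groups is None:
        groups = table.groups
    g = pd.Series(groups).loc[table.data.columns]
    case_mean = table.data.loc[:, (g == "case").to_numpy()].mean(axis=1, skipna=True)
    ctrl_mean = table.data.loc[:, (g == "control").to_numpy()].mean(axis=1, skipna=True)
    n_zero = int((ctrl_mean == 0).sum())
    if n_zero:
        logger.warning("%d proteins with zero control mean: infinite fold change", n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = case_mean / ctrl_mean
    fc.name = "fold_change"
    return fc


def _enumerate_masks(strata: list[tuple[np.ndarray, int]], n: int) -> np.ndarray:
    """All distinct per-stratum case assignments as boolean masks."""
    per_stratum = [
        [list(c) for c in itertools.combinations(idx.tolist(), k)] for idx, k in strata
    ]
    combos = list(itertools.product(*per_stratum))
    masks = np.zeros((len(combos), n), dtype=bool)
    for r, combo in enumerate(combos):
        for part in combo:
            masks[r, part] = True
    return masks


def _permutation_masks(
    case_idx: np.ndarray,
    ctrl_idx: np.ndarray,
    config: SamConfig,
    batches: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean (n_perm x n) masks marking the permuted 'case' columns.

    With ``stratify_by_batch`` and batch labels given, labels are
    permuted within each batch, preserving the observed per-batch case
    counts.  Falls back to exhaustive enumeration (with a logged note)
    when the number of distinct assignments does not exceed the
    request.
    """
    n = len(case_idx) + len(ctrl_idx)
    n1 = len(case_idx)
    rng = np.random.default_rng(config.seed)
    all_idx = np.sort(np.concatenate([case_idx, ctrl_idx]))
    case_mask = np.zeros(n, dtype=bool)
    case_mask[case_idx] = True
    if config.stratify_by_batch and batches is not None and len(np.unique(batches)) > 1:
        strata = [
            (np.flatnonzero(batches == b), int(case_mask[batches == b].sum()))
            for b in np.unique(batches)
        ]
    else:
        strata = [(all_idx, n1)]
    total = math.prod(math.comb(len(idx), k) for idx, k in strata)
    if not config.balanced and config.n_permutations >= total:
        logger.info(
            "requested %d permutations >= %d distinct assignments: enumerating exhaustively",
            config.n_permutations, total,
        )
        return _enumerate_masks(strata, n)
    masks = np.zeros((config.n_permutations, n), dtype=bool)
    if config.balanced:
        k = n1 // 2
        for r in range(config.n_permutations):
            keep_case = rng.choice(case_idx, size=n1 - k, replace=False)
            take_ctrl = rng.choice(ctrl_idx, size=k, replace=False)
            masks[r, keep_case] = True
            masks[r, take_ctrl] = True
        return masks
    seen: set[bytes] = set()
    r = 0
    while r < config.n_permutations:
        row = np.zeros(n, dtype=bool)
        for idx, k in strata:
            row[rng.choice(idx, size=k, replace=False)] = True
        key = row.tobytes()
        if key in seen:
            continue
        seen.add(key)
        masks[r] = row
        r += 1
    return masks


def _q_from_null(observed: np.ndarray, null_pool: np.ndarray, n_draws: int) -> np.ndarray:
    """Permutation q per observed value (two-sided on pre-|.|'d inputs).

    ``observed`` and ``null_pool`` are magnitudes; ``n_draws`` is the
    number of permutations pooled into ``null_pool``.  q at the
    threshold of each observed value = (mean permuted count >= value) /
    (observed count >= value), clipped and monotonized so that q is
    non-decreasing as |d| decreases.
    """
    order = np.argsort(-observed, kind="stable")
    sorted_obs = observed[order]
    null_sorted = np.sort(null_pool)
    # permuted values >= threshold, averaged over permutations
    num = (len(null_sorted) - np.searchsorted(null_sorted, sorted_obs, side="left")) / n_draws
    den = np.arange(1, len(sorted_obs) + 1)
    q_sorted = np.clip(num / den, 0.0, 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def sam_q(
    matrix: NormalizedMatrix,
    groups: pd.Series | None = None,
    config: SamConfig = SamConfig(),
    fold_changes: pd.Series | None = None,
) -> pd.DataFrame:
    """Full SAM table: d statistic, t, p, permutation q and significance.

    Returns one row per protein with columns ``mean_diff`` (case minus
    control in z-score units), ``fold_change`` (if supplied), ``t``,
    ``d``, ``p``, ``q`` and ``significant`` (q below the configured
    threshold).
    """
    if groups is None:
        groups = matrix.groups
    case_all, ctrl_all = _group_masks(matrix.data.columns, groups)
    pool = case_all | ctrl_all
    X = matrix.data.to_numpy(dtype=float)[:, pool]
    case = case_all[pool]
    ctrl = ctrl_all[pool]
    diff, s, d = _moderated_stats(X, case, ctrl, config.s0, pooled=config.equal_variance)
    tp = two_sample_t(matrix, groups, equal_variance=config.equal_variance)

    batch_labels = matrix.batches.to_numpy()[pool]
    masks = _permutation_masks(
        np.flatnonzero(case), np.flatnonzero(ctrl), config, batches=batch_labels
    )
    null_abs = np.empty((masks.shape[0], X.shape[0]))
    for r, mask in enumerate(masks):
        *_, d_star = _moderated_stats(X, mask, ~mask, config.s0, config.equal_variance)
        null_abs[r] = np.abs(d_star)
    q = _q_from_null(np.abs(d), null_abs.ravel(), masks.shape[0])

    out = pd.DataFrame(
        {
            "mean_diff": diff,
            "t": tp["t"].to_numpy(),
            "d": d,
            "p": tp["p"].to_numpy(),
            "q": q,
            "significant": q < config.q_threshold,
        },
        index=matrix.protein_ids,
    )
    if fold_changes is not None:
        out.insert(1, "fold_change", fold_changes.reindex(out.index))
        out.insert(2, "log2fc", np.log2(out["fold_change"]))
    return out


def volcano_boundary(
    sam_rows: pd.DataFrame,
    config: SamConfig,
    n_case: int,
    n_control: int,
    effect_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Significance boundary in the (effect, -log10 p) plane.

    For each effect size (mean difference, in the units of the tested
    matrix), returns the minimal -log10 p at which a protein with that
    effect reaches the q threshold, given s0 and the minimal significant
    |d| of the fitted table.  With s0 = 0 the boundary is flat; with
    s0 > 0 it rises steeply at small effects — the curved volcano line.
    """
    if effect_grid is None:
        top = float(np.nanmax(np.abs(sam_rows["mean_diff"]))) or 1.0
        effect_grid = np.linspace(1e-3, 1.2 * top, 200)
    sig = sam_rows[sam_rows["significant"]]
    df = n_case + n_control - 2
    rows = []
    if len(sig) == 0:
        for e in effect_grid:
            rows.append((e, np.inf))
        return pd.DataFrame(rows, columns=["effect", "neg_log10_p"])
    d_star = float(np.abs(sig["d"]).min())
    for e in np.abs(effect_grid):
        s_req = e / d_star - config.s0
        if s_req <= 0:
            rows.append((e, np.inf))
            continue
        t_min = e / s_req
        p_bound = 2 * stats.t.sf(t_min, df)
        rows.append((e, -np.log10(max(p_bound, 1e-300))))
    return pd.DataFrame(rows, columns=["effect", "neg_log10_p"])
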