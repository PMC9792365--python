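"""Synthetic multi-batch TMT datasets with known ground truth.

The generator emulates a multiplexed isobaric-labelling study: several
TMT batches, each carrying one pooled reference channel (a "master
pool" combining equal amounts of every biological sample) plus a slice
of the case and control subjects.  Protein intensities are drawn on the
log2 scale — a per-protein baseline, an optional spiked group effect,
per-batch location and scale effects matching the parametric
empirical-Bayes batch model, and Normal residual noise — and
exponentiated to linear reporter-intensity scale for output.

Defaults mirror the study design this package targets: 3 batches of 11
channels, 15 cases vs 15 controls, a ±log2(1.5) effect on 10% of
proteins, and residual SD 0.208 on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .containers import AbundanceTable
from .errors import ConfigurationError, InputError

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ConfusionCounts",
    "generate_dataset",
    "evaluate_selection",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study design.

    Attributes
    ----------
    n_proteins, n_case, n_control, n_batches
        Size of the simulated study.  Biological samples are spread
        across batches as evenly as possible, one pooled reference
        channel per batch.
    spike_fraction
        Fraction of proteins carrying a true group effect.
    effect_log2fc
        Magnitude of the spiked effect on the log2 scale
        (default log2 1.5 ≈ 0.585); split 50/50 up/down.
    residual_sigma
        Within-group residual SD on the log2 scale (default 0.208).
    batch_additive_sd
        SD of the per-batch, per-protein additive log2 shift.
    batch_multiplicative_shape
        Shape of the inverse-gamma law for per-batch variance
        inflation factors (mean fixed at 1).  Larger is milder;
        ``None`` disables inflation entirely.
    missing_rate
        MCAR missing probability applied to biological entries only.
    baseline_mean, baseline_sd
        Law of the per-protein baseline log2 intensity.
    """

    n_proteins: int = 1000
    n_case: int = 15
    n_control: int = 15
    n_batches: int = 3
    spike_fraction: float = 0.10
    effect_log2fc: float = math.log2(1.5)
    residual_sigma: float = 0.208
    batch_additive_sd: float = 0.3
    batch_multiplicative_shape: float | None = 20.0
    missing_rate: float = 0.02
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_case", "n_control", "n_batches"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("spike_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.residual_sigma <= 0:
            raise ConfigurationError(f"residual_sigma must be > 0, got {self.residual_sigma}")
        if self.batch_additive_sd < 0:
            raise ConfigurationError(
                f"batch_additive_sd must be >= 0, got {self.batch_additive_sd}"
            )
        s = self.batch_multiplicative_shape
        if s is not None and not math.isinf(s) and s <= 1:
            raise ConfigurationError(
                f"batch_multiplicative_shape must be > 1 (or None to disable), got {s}"
            )
        if self.baseline_sd < 0:
            raise ConfigurationError(f"baseline_sd must be >= 0, got {self.baseline_sd}")

    def replace(self, **kwargs) -> "SyntheticConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SyntheticConfig(**current)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``gamma`` and ``delta2`` are proteins x batches frames of the
    additive log2 batch shifts and multiplicative variance-inflation
    factors actually drawn; ``true_log2fc`` is the signed case-minus
    -control effect (0 for unspiked proteins).
    """

    is_spiked: pd.Series
    true_log2fc: pd.Series
    gamma: pd.DataFrame
    delta2: pd.DataFrame
    seed: int

    @property
    def spiked_ids(self) -> pd.Index:
        return self.is_spiked.index[self.is_spiked]

    @property
    def protein_ids(self) -> pd.Index:
        return self.is_spiked.index


@dataclass(frozen=True)
class ConfusionCounts:
    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int

    @property
    def empirical_fdr(self) -> float:
        """FP / (TP + FP), with 0/0 defined as 0."""
        called = self.true_positives + self.false_positives
        return self.false_positives / called if called else 0.0

    @property
    def empirical_power(self) -> float:
        """TP / (TP + FN), with 0/0 defined as 0."""
        positives = self.true_positives + self.false_negatives
        return self.true_positives / positives if positives else 0.0


def _batch_assignment(n: int, n_batches: int) -> np.ndarray:
    """Round-robin assignment: as even as possible per group."""
    return np.arange(n) % n_batches


def generate_dataset(config: SyntheticConfig) -> tuple[AbundanceTable, SyntheticTruth]:
    """Generate a linear-scale abundance table plus its ground truth.

    The reference channel of every batch holds, per protein, the linear
    mean of all biological samples' noise-free intensities (as a pooled
    master aliquot would), shifted by that batch's additive effect.
    Biological measurements add residual noise scaled by the batch's
    variance-inflation factor, and a ``missing_rate`` fraction of
    biological entries is blanked at random.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    P = cfg.n_proteins
    proteins = pd.Index([f"P{i:05d}" for i in range(P)], name="protein")
    batches = [f"B{b + 1}" for b in range(cfg.n_batches)]

    # sample layout
    case_ids = [f"case{i + 1:02d}" for i in range(cfg.n_case)]
    ctrl_ids = [f"ctrl{i + 1:02d}" for i in range(cfg.n_control)]
    ref_ids = [f"ref_{b}" for b in batches]
    bio_ids = case_ids + ctrl_ids
    bio_batch = np.concatenate(
        [_batch_assignment(cfg.n_case, cfg.n_batches), _batch_assignment(cfg.n_control, cfg.n_batches)]
    )
    ann_rows = []
    channel_counter: dict[int, int] = {b: 0 for b in range(cfg.n_batches)}
    for sid, grp, b in zip(
        bio_ids, ["case"] * cfg.n_case + ["control"] * cfg.n_control, bio_batch
    ):
        channel_counter[b] += 1
        ann_rows.append((sid, grp, batches[b], channel_counter[b]))
    for b, sid in enumerate(ref_ids):
        ann_rows.append((sid, "reference", batches[b], channel_counter[b] + 1))
    annotations = pd.DataFrame(
        ann_rows, columns=["sample", "group", "batch", "channel"]
    ).set_index("sample")

    # per-protein baseline and spiked effects
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=P)
    n_spiked = round(cfg.spike_fraction * P)
    spiked_idx = rng.choice(P, size=n_spiked, replace=False)
    effect = np.zeros(P)
    n_up = n_spiked // 2 + (n_spiked % 2)
    signs = np.concatenate([np.ones(n_up), -np.ones(n_spiked - n_up)])
    effect[spiked_idx] = signs * cfg.effect_log2fc

    # noise-free log2 level per protein x biological sample
    is_case = np.array([g == "case" for g in ["case"] * cfg.n_case + ["control"] * cfg.n_control])
    level = mu[:, None] + np.where(is_case[None, :], effect[:, None], 0.0)

    # batch effects
    gamma = rng.normal(0.0, cfg.batch_additive_sd, size=(P, cfg.n_batches))
    shape = cfg.batch_multiplicative_shape
    if shape is None or math.isinf(shape):
        delta2 = np.ones((P, cfg.n_batches))
    else:
        delta2 = 1.0 / rng.gamma(shape, scale=1.0 / (shape - 1.0), size=(P, cfg.n_batches))

    eps = rng.normal(0.0, cfg.residual_sigma, size=(P, len(bio_ids)))
    bio_log2 = (
        level
        + gamma[:, bio_batch]
        + np.sqrt(delta2[:, bio_batch]) * eps
    )

    # pooled reference: linear mean of noise-free biological intensities.
    # Batch effects model the residual technical variation that survives
    # master-pool normalization, so they perturb biological channels only;
    # the reference column is exact in every batch.
    ref_linear = np.mean(2.0 ** level, axis=1)
    ref_log2 = np.tile(np.log2(ref_linear)[:, None], (1, cfg.n_batches))

    bio_linear = 2.0 ** bio_log2
    if cfg.missing_rate > 0:
        mask = rng.random(bio_linear.shape) < cfg.missing_rate
        bio_linear = np.where(mask, np.nan, bio_linear)

    data = pd.DataFrame(
        np.hstack([bio_linear, 2.0 ** ref_log2]),
        index=proteins,
        columns=bio_ids + ref_ids,
    )
    table = AbundanceTable(data, annotations)
    truth = SyntheticTruth(
        is_spiked=pd.Series(effect != 0.0, index=proteins, name="is_spiked"),
        true_log2fc=pd.Series(effect, index=proteins, name="true_log2fc"),
        gamma=pd.DataFrame(gamma, index=proteins, columns=batches),
        delta2=pd.DataFrame(delta2, index=proteins, columns=batches),
        seed=cfg.seed,
    )
    return table, truth


def evaluate_selection(selected_ids, truth: SyntheticTruth, universe=None) -> ConfusionCounts:
    """Score a selected protein set against the generating truth.

    ``universe`` optionally restricts scoring to the proteins actually
    tested (e.g. those surviving the missing-value filter); spiked
    proteins outside it are not counted as misses.
    """
    selected = pd.Index(sorted(set(selected_ids)))
    unknown = selected.difference(truth.protein_ids)
    if len(unknown):
        raise InputError(f"unknown protein ids in selection: {list(unknown[:5])}")
    is_spiked = truth.is_spiked
    if universe is not None:
        universe = pd.Index(universe)
        unknown = universe.difference(truth.protein_ids)
        if len(unknown):
            raise InputError(f"unknown protein ids in universe: {list(unknown[:5])}")
        stray = selected.difference(universe)
        if len(stray):
            raise InputError(f"selected ids outside the universe: {list(stray[:5])}")
        is_spiked = is_spiked.loc[universe]
    sel = is_spiked.index.isin(selected)
    spiked = is_spiked.to_numpy()
    tp = int(np.sum(sel & spiked))
    fp = int(np.sum(sel & ~spiked))
    fn = int(np.sum(~sel & spiked))
    tn = int(np.sum(~sel & ~spiked))
    return ConfusionCounts(tp, fp, tn, fn)
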