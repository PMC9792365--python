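"""In-memory containers for reporter-intensity tables and normalized matrices.

An :class:`AbundanceTable` holds linear-scale reporter-ion intensities
(rows = proteins, columns = samples) together with a sample annotation
table assigning each sample a group (``case``, ``control`` or
``reference``), a batch id and a TMT channel id.  Missing values are
``NaN``; zero intensities are treated as non-detections and converted to
``NaN`` on construction.

A :class:`NormalizedMatrix` is the downstream, statistics-ready object:
log2 z-scores over biological samples only, with a provenance record of
the normalization steps applied, in order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, StateError

logger = logging.getLogger(__name__)

GROUPS = ("case", "control", "reference")

#: canonical order of the normalization cascade
PIPELINE_ORDER = (
    "reference_normalize",
    "median_center",
    "log2_zscore",
    "drop_missing",
    "combat_adjust",
)


def _validate_annotations(data: pd.DataFrame, annotations: pd.DataFrame) -> None:
    if not data.index.is_unique:
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise InputError(f"protein ids are not unique: {dupes[:5]}")
    missing_cols = {"group", "batch"} - set(annotations.columns)
    if missing_cols:
        raise InputError(f"annotation table lacks columns: {sorted(missing_cols)}")
    if not data.columns.equals(annotations.index):
        if set(data.columns) != set(annotations.index):
            raise InputError(
                "sample columns and annotation rows disagree: "
                f"{sorted(set(data.columns) ^ set(annotations.index))[:5]}"
            )
        raise InputError("sample columns and annotation rows are ordered differently")
    bad = set(annotations["group"]) - set(GROUPS)
    if bad:
        raise InputError(f"unknown group labels {sorted(bad)}; expected one of {GROUPS}")


@dataclass
class AbundanceTable:
    """Linear-scale reporter intensities plus sample annotations.

    Parameters
    ----------
    data
        proteins x samples intensity matrix, NaN for missing.
    annotations
        one row per sample (index = sample id) with columns
        ``group``, ``batch`` and optionally ``channel``.
    steps
        normalization steps already applied, in order.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame
    steps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _validate_annotations(self.data, self.annotations)
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=np.inf) < 0:
            raise InputError("negative intensities are not valid reporter abundances")
        n_zero = int((values == 0).sum())
        if n_zero:
            logger.warning("treating %d zero intensities as missing", n_zero)
            self.data = self.data.mask(self.data == 0)

    # -- convenience views ------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def groups(self) -> pd.Series:
        return self.annotations["group"]

    @property
    def batches(self) -> pd.Series:
        return self.annotations["batch"]

    def biological_samples(self) -> pd.Index:
        return self.annotations.index[self.annotations["group"] != "reference"]

    def reference_samples(self) -> pd.Index:
        return self.annotations.index[self.annotations["group"] == "reference"]

    def subset_samples(self, samples: pd.Index) -> "AbundanceTable":
        return AbundanceTable(
            self.data[samples].copy(),
            self.annotations.loc[samples].copy(),
            steps=list(self.steps),
        )


@dataclass
class NormalizedMatrix:
    """Log2 z-score matrix over biological samples with step provenance."""

    data: pd.DataFrame
    annotations: pd.DataFrame
    steps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _validate_annotations(self.data, self.annotations)
        if (self.annotations["group"] == "reference").any():
            raise InputError("NormalizedMatrix must not contain reference samples")

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def groups(self) -> pd.Series:
        return self.annotations["group"]

    @property
    def batches(self) -> pd.Series:
        return self.annotations["batch"]


def require_step(obj: AbundanceTable | NormalizedMatrix, step: str) -> None:
    """Raise :class:`StateError` unless ``step`` has been applied."""
    if step not in obj.steps:
        raise StateError(f"operation requires prior step '{step}'; applied so far: {obj.steps}")


def check_order(steps: list[str], new_step: str) -> None:
    """Enforce the canonical cascade order when appending ``new_step``."""
    if new_step in steps:
        raise StateError(f"step '{new_step}' already applied: {steps}")
    pos = PIPELINE_ORDER.index(new_step)
    later = [s for s in steps if s in PIPELINE_ORDER and PIPELINE_ORDER.index(s) > pos]
    if later:
        raise StateError(f"cannot apply '{new_step}' after {later}")
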