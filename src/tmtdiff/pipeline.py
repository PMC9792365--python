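"""End-to-end orchestration: generate/read -> normalize -> test -> enrich.

A :class:`RunConfig` names either an on-disk abundance + annotation
pair or a synthetic design, plus the sub-configurations of every stage.
:func:`run_pipeline` executes the cascade and returns a
:class:`ResultBundle`; :func:`write_results` materializes it as TSVs
plus a JSON manifest carrying the configs, seeds and per-stage counts
needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootauc import BootAucConfig, bootauc_q, bootstrap_auc, null_bootstrap_auc
from .combat import combat_adjust
from .containers import AbundanceTable, NormalizedMatrix
from .enrichment import ora, read_gmt
from .errors import ConfigurationError, InputError
from .io import read_abundance, write_abundance, write_table, write_truth
from .normalize import batch_pca, drop_missing, log2_zscore, median_center, reference_normalize
from .sam import SamConfig, fold_change, sam_q
from .simulate import SyntheticConfig, SyntheticTruth, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "intersect_selections", "write_results"]


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run.

    Exactly one of ``synthetic`` or (``abundance_path``,
    ``annotation_path``) must be given.  The global ``seed`` derives the
    seeds of every stochastic stage (generator, SAM permutations,
    bootstrap), so one integer fully determines a run.
    """

    synthetic: SyntheticConfig | None = None
    abundance_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    zscore_axis: str = "sample"
    # in a balanced design the group contrast survives batch correction
    # untouched, and protecting it inflates downstream permutation
    # significance; protect only when the design demands it
    protect_group: bool = False
    sam: SamConfig = field(default_factory=SamConfig)
    bootauc: BootAucConfig = field(default_factory=BootAucConfig)
    enrichment_method: str = "fisher"
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.abundance_path is not None or self.annotation_path is not None
        if has_files and (self.abundance_path is None or self.annotation_path is None):
            raise ConfigurationError("abundance_path and annotation_path must be given together")
        if (self.synthetic is None) == (not has_files):
            raise ConfigurationError(
                "exactly one of a synthetic config or input paths must be provided"
            )
        if self.gmt_path is not None and not Path(self.gmt_path).is_file():
            raise ConfigurationError(f"gmt_path does not exist: {self.gmt_path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "sam" in raw:
            raw["sam"] = SamConfig(**raw["sam"])
        if "bootauc" in raw:
            raw["bootauc"] = BootAucConfig(**raw["bootauc"])
        return cls(**raw)

    def derived_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "generator": int(state[0] & 0x7FFFFFFF),
            "sam": int(state[1] & 0x7FFFFFFF),
            "bootauc": int(state[2] & 0x7FFFFFFF),
        }


@dataclass
class ResultBundle:
    table: AbundanceTable
    truth: SyntheticTruth | None
    normalized: NormalizedMatrix
    sam_rows: pd.DataFrame
    auc_rows: pd.DataFrame
    intersection: pd.DataFrame
    enrichment: pd.DataFrame | None
    manifest: dict


def intersect_selections(sam_rows: pd.DataFrame, auc_rows: pd.DataFrame) -> pd.DataFrame:
    """Proteins significant under both the SAM and the bootstrap-AUC call.

    Returns one row per common protein with its direction (up/down by
    the sign of the SAM mean difference) and the statistics of both
    methods; the frame's ``attrs`` record the three set sizes.
    """
    if not sam_rows.index.equals(auc_rows.index):
        if set(sam_rows.index) != set(auc_rows.index):
            raise InputError("SAM and bootstrap-AUC tables cover different protein universes")
        auc_rows = auc_rows.loc[sam_rows.index]
    both = sam_rows["significant"] & auc_rows["significant"]
    out = pd.DataFrame(
        {
            "direction": np.where(sam_rows.loc[both, "mean_diff"] >= 0, "up", "down"),
            "mean_diff": sam_rows.loc[both, "mean_diff"],
            "q_sam": sam_rows.loc[both, "q"],
            "mean_auc": auc_rows.loc[both, "mean_auc"],
            "sd_auc": auc_rows.loc[both, "sd_auc"],
            "q_auc": auc_rows.loc[both, "q"],
        },
        index=sam_rows.index[both],
    )
    out.attrs["n_sam"] = int(sam_rows["significant"].sum())
    out.attrs["n_auc"] = int(auc_rows["significant"].sum())
    out.attrs["n_common"] = int(both.sum())
    return out


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis cascade described by ``config``."""
    seeds = config.derived_seeds()
    truth = None
    if config.synthetic is not None:
        syn = config.synthetic.replace(seed=seeds["generator"])
        table, truth = generate_dataset(syn)
    else:
        table = read_abundance(config.abundance_path, config.annotation_path)
    gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None

    n_input = len(table.protein_ids)
    ratios = reference_normalize(table)
    centred = median_center(ratios)
    fc = fold_change(centred)
    matrix = log2_zscore(centred, axis=config.zscore_axis)
    matrix = drop_missing(matrix)
    _, sil_before = batch_pca(matrix)
    protect = "auto" if config.protect_group else None
    adjusted, _batch_params = combat_adjust(matrix, protect_group=protect)
    _, sil_after = batch_pca(adjusted)

    sam_cfg = dataclasses.replace(config.sam, seed=seeds["sam"])
    sam_rows = sam_q(adjusted, config=sam_cfg, fold_changes=fc)

    auc_cfg = dataclasses.replace(config.bootauc, seed=seeds["bootauc"])
    auc_rows = bootstrap_auc(adjusted, config=auc_cfg)
    null_means = null_bootstrap_auc(adjusted, config=auc_cfg)
    auc_rows = bootauc_q(auc_rows, null_means, auc_cfg)

    common = intersect_selections(sam_rows, auc_rows)

    enrich = None
    if gene_sets is not None:
        enrich = ora(
            common.index, adjusted.protein_ids, gene_sets, method=config.enrichment_method
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "config": {
            "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
            "sam": dataclasses.asdict(sam_cfg),
            "bootauc": dataclasses.asdict(auc_cfg),
            "zscore_axis": config.zscore_axis,
            "protect_group": config.protect_group,
            "enrichment_method": config.enrichment_method,
        },
        "counts": {
            "proteins_input": n_input,
            "proteins_after_drop_missing": int(len(adjusted.protein_ids)),
            "sam_significant": int(sam_rows["significant"].sum()),
            "auc_significant": int(auc_rows["significant"].sum()),
            "common_significant": int(len(common)),
            "enrichment_terms": int(len(enrich)) if enrich is not None else 0,
        },
        "silhouette_by_batch": {"before_combat": sil_before, "after_combat": sil_after},
        "normalization_steps": list(adjusted.steps),
    }
    return ResultBundle(table, truth, adjusted, sam_rows, auc_rows, common, enrich, manifest)


def write_results(bundle: ResultBundle, outdir) -> dict[str, Path]:
    """Write every result table plus the JSON manifest; returns the paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {outdir}: {exc}") from exc
    paths = {
        "normalized": outdir / "normalized_matrix.tsv",
        "sam": outdir / "sam_results.tsv",
        "bootauc": outdir / "bootstrap_auc_results.tsv",
        "intersection": outdir / "intersection.tsv",
        "manifest": outdir / "manifest.json",
    }
    bundle.normalized.data.to_csv(paths["normalized"], sep="\t", index_label="protein")
    write_table(bundle.sam_rows, paths["sam"])
    write_table(bundle.auc_rows, paths["bootauc"])
    write_table(bundle.intersection, paths["intersection"])
    if bundle.enrichment is not None:
        paths["enrichment"] = outdir / "enrichment.tsv"
        write_table(bundle.enrichment, paths["enrichment"], index_label="rank")
    if bundle.truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        write_truth(bundle.truth, paths["truth"])
        paths["abundance"] = outdir / "abundance.tsv"
        paths["annotations"] = outdir / "annotations.tsv"
        write_abundance(bundle.table, paths["abundance"], paths["annotations"])
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
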