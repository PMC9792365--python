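"""TSV readers/writers for abundance tables, annotations and result tables.

All tables are UTF-8, tab-separated, '.' decimal.  Result writers can
prepend the analysis configuration as ``#``-prefixed comment lines so
every output file carries what produced it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .containers import AbundanceTable
from .errors import InputError
from .simulate import SyntheticTruth


def write_abundance(table: AbundanceTable, data_path, annotation_path) -> None:
    table.data.to_csv(data_path, sep="\t", index_label="protein")
    table.annotations.to_csv(annotation_path, sep="\t", index_label="sample")


def read_abundance(data_path, annotation_path) -> AbundanceTable:
    data = pd.read_csv(data_path, sep="\t", index_col=0)
    data.index.name = "protein"
    annotations = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"batch": str})
    missing = {"group", "batch"} - set(annotations.columns)
    if missing:
        raise InputError(f"{annotation_path}: missing annotation columns {sorted(missing)}")
    return AbundanceTable(data, annotations.loc[data.columns])


def write_truth(truth: SyntheticTruth, path) -> None:
    out = pd.DataFrame(
        {"is_spiked": truth.is_spiked, "true_log2fc": truth.true_log2fc}
    )
    for b in truth.gamma.columns:
        out[f"gamma_{b}"] = truth.gamma[b]
        out[f"delta2_{b}"] = truth.delta2[b]
    out.to_csv(path, sep="\t", index_label="protein")


def write_table(df: pd.DataFrame, path, config=None, index_label="protein") -> None:
    """Write a result table, with the config echoed as comment lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            cfg = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
            fh.write(f"# config: {json.dumps(cfg, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
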