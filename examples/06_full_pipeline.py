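"""One-call pipeline run from a config, with all artifacts written to disk.

Equivalent to `tmtdiff run --config run.yaml --outdir out/` on the shell.
"""

import json
import tempfile
from pathlib import Path

from tmtdiff import BootAucConfig, RunConfig, SamConfig, SyntheticConfig, run_pipeline, write_results

config = RunConfig(
    synthetic=SyntheticConfig(n_proteins=800),
    sam=SamConfig(n_permutations=250),
    bootauc=BootAucConfig(n_bootstrap=500, n_label_permutations=20),
    seed=2024,
)
bundle = run_pipeline(config)
print(json.dumps(bundle.manifest["counts"], indent=2))
print("silhouette by batch:", json.dumps(bundle.manifest["silhouette_by_batch"]))

outdir = Path(tempfile.mkdtemp()) / "results"
paths = write_results(bundle, outdir)
print("\nwritten:")
for name, path in paths.items():
    print(f"  {name:12s} {path}")
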