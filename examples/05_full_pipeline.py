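"""Run the end-to-end pipeline into a directory and inspect the manifest.

Equivalent to `exodecomp run --outdir <dir>` with a smoke-sized config.
"""

import json
import tempfile
from pathlib import Path

from exodecomp import GeneratorConfig, RunConfig, run_pipeline

cfg = RunConfig(generator=GeneratorConfig(seed=2, n_genes=300, n_enhancers=20))
with tempfile.TemporaryDirectory() as tmp:
    out = run_pipeline(cfg, Path(tmp) / "run")
    manifest = json.loads((out / "manifest.json").read_text())
    print("stages run:", ", ".join(manifest["stages"]))
    print("outputs:", len(manifest["checksums"]), "files")
    for k, v in sorted(manifest["metrics"].items()):
        print(f"  {k}: {v:.4f}")
    summary = json.loads((out / "summary.json").read_text())
    print("class counts:", summary["class_counts"])
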