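"""End-to-end run: enrich -> xlfdr -> AP-MS filter -> map -> score models.

Generates the bundled synthetic fixture suite (structures, sequences,
crosslink candidates, quant matrix, model scores and a YAML run
configuration) in a scratch directory and executes the whole pipeline,
printing the stage manifest. Equivalent shell commands:

    phixlink simulate --seed 5 --out-dir suite/
    phixlink run-all --config suite/run_config.yaml
"""

import json
import tempfile
from pathlib import Path

from phixlink.cli import generate_suite, run_all

with tempfile.TemporaryDirectory() as tmp:
    suite = Path(tmp) / "suite"
    generate_suite(suite, seed=5)
    manifest = run_all(suite / "run_config.yaml")
    for stage in manifest["stages"]:
        print(f"stage {stage['name']:18s} {stage['status']} "
              f"({stage['seconds']:.2f} s) -> {len(stage['outputs'])} files")
    summary = (suite / "results" / "ensemble_summary.tsv").read_text()
    print("\nensemble satisfaction summary:\n" + summary)
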