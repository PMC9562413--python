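"""Run the whole pipeline from a config dict and inspect the artifacts.

Everything the per-stage APIs produce is also reachable through one call:
simulate -> preprocess -> detect -> extract -> analyze -> regress, with CSV
artifacts and a JSON manifest in the output directory.  The same run is
available from the shell as `cuffless run-all --config cfg.yaml`.
"""

import json
import tempfile
from pathlib import Path

from cuffless import run_end_to_end

out = Path(tempfile.mkdtemp(prefix="cuffless_"))
config = {
    "seed": 42,
    "synth": {"n_subjects": 6, "duration_s": 20.0},
    "gates": ["D1", "D2"],
    "models": ["LR", "RF"],
    "split": {"n_train": 4, "n_test": 2},
}
manifest = run_end_to_end(config, out_dir=out)

print("stage counts:")
for stage, info in manifest.stages.items():
    counts = {k: v for k, v in info.items() if k != "t"}
    print(f"  {stage:8s} {counts}")
print("\nartifacts in", out)
for p in sorted(out.iterdir()):
    print("  ", p.name)

prov = json.loads((out / "provenance.json").read_text())
print(f"\noverall cycle acceptance: {prov['overall_acceptance_pct']:.1f}% "
      "(complete, labeled beats kept out of all beats seen)")
print("\nRe-running with the same seed reproduces every CSV byte-for-byte; the "
      "manifest\nrecords per-stage counts so a reviewer can trace how many beats "
      "survived detection\nand gating.")
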