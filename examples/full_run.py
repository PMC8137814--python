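"""Full reproducible batch: simulate -> preprocess -> fit -> evaluate -> report.

Three dyads (the first with planted TPJ coupling, the rest null), both
model families, everything derived from one master seed. The summary
counts significant channel-pairs per family out of channels x dyads,
mirroring how multi-dyad hyperscanning results are reported.
"""

import json
import tempfile
from pathlib import Path

from interbrain.pipeline import RunConfig, run

config = RunConfig(
    n_dyads=3,
    seed=42,
    duration_s=140.0,
    B=30,
    families=("SVR", "OLS"),
    coupled_pairs={0: {(9, 9): 1.0, (10, 10): 1.0}},
)

out = Path(tempfile.mkdtemp()) / "run"
report = run(config, out_dir=out)

print(f"config hash {report.config_hash} (rerunning this config reproduces "
      "every output bit for bit)\n")
print(json.dumps(report.summary, indent=2))
print(f"\nper-dyad tables and HbO2 series written under {out}")
print("counts read as significant/evaluated channel-pairs; dyad-1 carries "
      "the planted coupling, dyads 2-3 are null. (Scaled down for a quick "
      "demo; at these short record lengths expect a few null-dyad hits — "
      "see docs/methods.md on calibration.)")
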