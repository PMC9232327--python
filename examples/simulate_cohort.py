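"""Generate a seeded synthetic cohort and write its file set.

The cohort emulates a 15-athlete two-group study: per subject and combination
a trajectory CSV (both hands, 30 Hz), an 8-channel EMG CSV (1000 Hz) and a
per-channel MVIC reference CSV, plus a JSON manifest echoing the config.
"""

import tempfile
from pathlib import Path

from armbiomech import RunConfig, simulate

config = RunConfig()  # defaults: 4 + 11 subjects, 120 bpm, seed 0
out_dir = Path(tempfile.mkdtemp()) / "cohort"
manifest = simulate(config, out_dir)

files = sorted(p.name for p in out_dir.iterdir())
print(f"wrote {len(files)} files to {out_dir}")
print("first few:", ", ".join(files[:4]))
print(f"manifest: {manifest.name}")
print("Each subject contributes 2 trajectory, 2 EMG and 1 MVIC file; the "
      "manifest records group labels, heights and the full configuration.")
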