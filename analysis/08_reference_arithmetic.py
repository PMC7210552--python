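#!/usr/bin/env python
"""Recompute the reference study's headline percent changes.

From the published whole-model summary tables (single subject, pre vs
during counterpulsation): mean AWSS +16.9% (7.90 vs 6.76 Pa), mean
AWSSG +19.6%, peak AWSSG +22.6%, OSI essentially unchanged.
"""

import json
from pathlib import Path

from eecp_hemoflow.reference import (
    reference_percent_changes,
    reproduce_reference_arithmetic,
)

OUT = Path("results/reference")
OUT.mkdir(parents=True, exist_ok=True)

pc = reference_percent_changes()
pc.to_csv(OUT / "percent_changes.csv", index=False)
print(pc.to_string(index=False))

summary = reproduce_reference_arithmetic()
(OUT / "headline.json").write_text(json.dumps(summary, indent=2) + "\n")
print("\nheadline:", json.dumps(summary, indent=2))
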