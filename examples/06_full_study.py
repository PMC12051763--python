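"""Run the whole pipeline on a synthetic cohort and print the report summary.

Stages: clearance fit → retention + imaging schedule; blood partitioning
→ stability verdict; SUV→uptake table; detectability; dose scaling.
The JSON report carries a provenance block with the seed, config hash
and every default assumption.
"""

import json

from alphapk import pipeline

report = pipeline.run_study({"seed": 1})

print(pipeline.summarize(report))
print("\nProvenance:")
print(json.dumps(report["provenance"], indent=2, default=float))
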