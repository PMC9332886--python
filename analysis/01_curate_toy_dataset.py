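#!/usr/bin/env python
"""Curate the toy inhibitor activity table.

Builds the package's toy compound set (16 small molecules covering
every atom type the descriptor grammar uses) with log-uniform EC50s
spanning the 0.3–90000 nM potency window of a typical enzyme-inhibition
series, runs curation, and writes the curated table plus flag counts.
"""

import json
from pathlib import Path

from pairqsar.dataset import curate, curation_report, write_curated_csv
from pairqsar.synthetic import toy_activity_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

records = curate(toy_activity_table(seed=1))
write_curated_csv(records, OUT / "curated_toy.csv")
report = curation_report(records)
(OUT / "curation_report.json").write_text(json.dumps(report, indent=2))

print(f"curated {report['total']} records -> {report.get('kept', 0)} kept")
for flag in ("duplicate", "multi_component", "imprecise", "unparsable"):
    if flag in report:
        print(f"  {flag}: {report[flag]}")
print(f"wrote {OUT / 'curated_toy.csv'}")
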