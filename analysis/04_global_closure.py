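#!/usr/bin/env python
"""Genome-wide chromatin closure: 50 kb window ECDFs and shift summaries.

Reproduces, on synthetic data, the signature observation that the rod
coverage distribution is left-shifted relative to every other sample: the
lower-tail area between ECDFs is positive for rods against each cone
sample and near zero within groups.
"""

from pathlib import Path

import pandas as pd

from photoclose.closure import closure_shift
from photoclose.pipeline import run_pipeline

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

res = run_pipeline({"seed": SEED, "stages": ["closure"]}, outdir="scratch/04_closure")
ecdfs = res["ecdfs"]

rows = []
for probe in ecdfs:
    for s in closure_shift(ecdfs[probe], {k: v for k, v in ecdfs.items() if k != probe}):
        rows.append(
            {"sample": probe, "reference": s.reference_id,
             "area_x1e4": round(1e4 * s.area, 3), "dominance": round(s.dominance, 3)}
        )
table = pd.DataFrame(rows)
table.to_csv(OUT / "04_closure_shift.tsv", sep="\t", index=False)
rod_rows = table[table["sample"] == "rod_1"]
print(table.to_string(index=False))
print(
    "\nrod_1 lower-tail area is positive against every non-rod sample:",
    bool((rod_rows[~rod_rows["reference"].str.startswith("rod")]["area_x1e4"] > 0).all()),
)
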