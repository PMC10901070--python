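"""Clinicopathologic summary tables from pre-tabulated level counts.

Uses the published cohort count columns of a 62-patient surgical cohort
and a 70-patient validation cohort as worked input; percentages are of
the full cohort, rounded half-up to one decimal.
"""

import pandas as pd

from common import RESULTS
from opsccrna.io_core import write_table
from opsccrna.pipeline import summarize_counts

SURGICAL = {
    "Gender": {"Male": 50, "Female": 12},
    "HPV": {"Positive": 39, "Negative": 23},
    "Vital status": {"Dead": 13, "Alive": 49},
}
VALIDATION = {
    "Gender": {"Male": 62, "Female": 8},
    "HPV": {"Positive": 45, "Negative": 25},
    "Vital status": {"Dead": 13, "Alive": 57},
}

frames = []
for cohort, tables in [("surgical", SURGICAL), ("validation", VALIDATION)]:
    for variable, counts in tables.items():
        t = summarize_counts(counts)
        t.insert(0, "variable", variable)
        t.insert(0, "cohort", cohort)
        frames.append(t)
out = pd.concat(frames, ignore_index=True)
print(out.to_string(index=False))
write_table(out.set_index("cohort"), RESULTS / "cohort_summary.tsv", index_label="cohort")
print("->", RESULTS / "cohort_summary.tsv")
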