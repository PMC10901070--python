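"""Call HPV status from viral-oncogene read counts and score against truth.

The rule: positive when E6 or E7 carries >= 500 reads, or when all eight
oncogenes together do.
"""

import pandas as pd

from common import RESULTS, default_bundle
from opsccrna.hpv import call_hpv_table, read_hpv_counts
from opsccrna.io_core import write_table

cfg, paths = default_bundle()
calls = call_hpv_table(read_hpv_counts(paths["hpv_counts"]))
truth_groups = paths["truth"]["counts"].groups

merged = calls.join(truth_groups)
accuracy = (
    ((merged["status"] == "positive") & (merged["group"] == "HPV_positive"))
    | ((merged["status"] == "negative") & (merged["group"] == "HPV_negative"))
).mean()

write_table(calls, RESULTS / "hpv_calls.tsv", index_label="sample_id")
print(calls["status"].value_counts().to_string())
print("clauses:", calls.loc[calls.status == "positive", "clause"].value_counts().to_dict())
print(f"agreement with simulated group labels: {accuracy:.1%}")
print("->", RESULTS / "hpv_calls.tsv")
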