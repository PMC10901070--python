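"""Three-step miRNA repressor triage of the hub gene.

Step 1: negative correlation screen (rho < -0.4, p < 0.05); step 2:
canonical seed site in the 3'UTR; step 3: inverse prognostic signature
(low miRNA arm with lower RMST under median split of raw counts).
"""

import json

import pandas as pd

from common import RESULTS, default_bundle
from opsccrna.expression import compute_tpm
from opsccrna.io_core import SurvivalTable, read_counts_table, read_fasta, write_table
from opsccrna.mirna import collapse_mature_duplicates, triage_candidates

cfg, paths = default_bundle()
meta = pd.read_csv(paths["metadata"], index_col="sample_id")
cm = read_counts_table(paths["counts"], paths["lengths"], metadata=meta)
surv = SurvivalTable(meta[["time_months", "event"]].assign(event=meta["event"].astype(int)))

mirna_counts = pd.read_csv(paths["mirna_counts"], sep="\t", index_col=0)
seqs = collapse_mature_duplicates(read_fasta(paths["mirna_fasta"]))
utr = next(iter(read_fasta(paths["utr_fasta"]).values()))

table, venn = triage_candidates(
    mirna_counts, compute_tpm(cm).loc["HUB_GENE"], utr, seqs, surv
)
print(table[["rho", "p", "n_sites", "best_site_type", "survival_inverted", "candidate"]]
      .round(3).to_string())
print("intersection counts:", venn)
print("candidates:", list(table.index[table["candidate"]]))

write_table(table, RESULTS / "mirna_triage.tsv", index_label="mirna")
(RESULTS / "mirna_venn.json").write_text(json.dumps(venn, indent=2))
print("->", RESULTS / "mirna_triage.tsv")
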