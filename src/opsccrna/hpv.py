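"""HPV status calling from viral-oncogene RNA read counts.

A tumor RNA-seq sample is called HPV-positive when its reads mapping to the
HPV oncogenes give at least ``threshold`` (default 500) reads for E6 or for
E7, or at least ``threshold`` reads summed over all eight oncogenes
(E1, E2, E4, E5, E6, E7, L1, L2). "At least" is read as ``>=`` in every
clause, and the combined sum includes E6 and E7.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ONCOGENES = ("E1", "E2", "E4", "E5", "E6", "E7", "L1", "L2")

DEFAULT_THRESHOLD = 500


@dataclass(frozen=True)
class HpvCall:
    sample_id: str
    status: str  # "positive" | "negative"
    clause: str  # "E6" | "E7" | "combined" | "none"
    total_reads: int


def call_hpv_status(
    sample_id: str, counts: dict[str, int], threshold: int = DEFAULT_THRESHOLD
) -> HpvCall:
    """Call one sample from its per-oncogene read counts.

    ``counts`` must contain all eight oncogene keys with non-negative
    integer values. The firing clause is reported for logging: E6 and E7
    are checked first, then the combined sum.
    """
    missing = [g for g in ONCOGENES if g not in counts]
    if missing:
        raise ValueError(f"{sample_id}: missing oncogene counts for {missing}")
    for g in ONCOGENES:
        v = counts[g]
        if v < 0 or v != int(v):
            raise ValueError(f"{sample_id}: count for {g} must be a non-negative integer, got {v!r}")
    total = int(sum(counts[g] for g in ONCOGENES))
    if counts["E6"] >= threshold:
        return HpvCall(sample_id, "positive", "E6", total)
    if counts["E7"] >= threshold:
        return HpvCall(sample_id, "positive", "E7", total)
    if total >= threshold:
        return HpvCall(sample_id, "positive", "combined", total)
    return HpvCall(sample_id, "negative", "none", total)


def call_hpv_table(counts: pd.DataFrame, threshold: int = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Vectorized calling over a sample x oncogene table.

    Returns a frame with columns status, clause, total_reads indexed by
    sample id; column order of the output TSV is fixed.
    """
    calls = [
        call_hpv_status(str(sid), {g: int(row[g]) for g in ONCOGENES}, threshold)
        for sid, row in counts.iterrows()
    ]
    return pd.DataFrame(
        {
            "status": [c.status for c in calls],
            "clause": [c.clause for c in calls],
            "total_reads": [c.total_reads for c in calls],
        },
        index=pd.Index([c.sample_id for c in calls], name="sample_id"),
    )


def read_hpv_counts(path: str | Path) -> pd.DataFrame:
    """Read the per-sample oncogene read-count TSV (sample_id + 8 columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [g for g in ONCOGENES if g not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing oncogene column(s) {missing}")
    return df[list(ONCOGENES)]
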