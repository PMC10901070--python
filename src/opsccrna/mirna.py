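"""Canonical miRNA seed-site scanning and the three-step repressor triage.

A miRNA represses a transcript through Watson-Crick pairing of its seed
(nucleotides 2-8, counted from the 5' end) with the 3'UTR. The canonical
site classes, in decreasing efficacy, are:

* 8mer      — perfect match to positions 2-8 plus an A opposite position 1,
* 7mer-m8   — perfect match to positions 2-8,
* 7mer-A1   — match to positions 2-7 plus the A,
* 6mer      — match to positions 2-7 only.

Sites are reported on the UTR sense strand, 0-based half-open; overlapping
matches at one location collapse to the highest-priority class. Pairing is
strict Watson-Crick (no G:U wobble); T and U are interchangeable.

The triage pipeline keeps a miRNA as a candidate repressor of a target
gene when (1) its expression is negatively correlated with the target
(rho < -0.4, p < 0.05 by default), (2) it has at least one canonical seed
site in the target's 3'UTR, and (3) low miRNA expression associates with
worse outcome (lower RMST in the median-split low arm) — the mirror image
of the target's own prognostic signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SurvivalTable
from .screens import correlation_screen
from .survival import survival_by_expression

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _to_dna(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{what}: non-IUPAC character(s) {sorted(bad)}")
    return s


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    start: int  # 0-based, half-open on the UTR sense strand
    end: int
    utr_match: str


def seed_sites(utr: str, mirna_mature: str, mirna_id: str = "miRNA") -> list[SeedSite]:
    """Scan a 3'UTR for canonical seed sites of one mature miRNA.

    The UTR is read 5'->3' on the mRNA sense strand; the site sequence is
    the reverse complement of the seed, with the A1 anchor appearing 3' of
    the seed match on the UTR. Each UTR location yields at most one site,
    of the highest-priority matching class.
    """
    utr_d = _to_dna(utr, "UTR")
    mir = _to_dna(mirna_mature, "miRNA")
    if len(utr_d) < 8:
        raise ValueError("UTR shorter than 8 nt")
    if len(mir) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    seed7 = mir[1:8]  # positions 2-8, 5'->3'
    seed6 = mir[1:7]  # positions 2-7
    core7 = _revcomp(seed7)  # 7mer-m8 core on the UTR
    core6 = _revcomp(seed6)
    sites: list[SeedSite] = []
    claimed: set[int] = set()  # start positions of the 6-mer core already reported

    def claim(start6: int, site_type: str, start: int, end: int) -> None:
        if start6 in claimed:
            return
        claimed.add(start6)
        sites.append(SeedSite(mirna_id, site_type, start, end, utr_d[start:end]))

    n = len(utr_d)
    for i in range(n - 5):
        if utr_d[i : i + 6] != core6:
            continue
        # the m8 match extends the core 5' on the UTR (position i-1);
        # the A1 anchor sits 3' of the core (position i+6)
        has_m8 = i >= 1 and utr_d[i - 1] == core7[0]
        has_a1 = i + 6 < n and utr_d[i + 6] == "A"
        if has_m8 and has_a1:
            claim(i, "8mer", i - 1, i + 7)
        elif has_m8:
            claim(i, "7mer-m8", i - 1, i + 6)
        elif has_a1:
            claim(i, "7mer-A1", i, i + 7)
        else:
            claim(i, "6mer", i, i + 6)
    return sites


def best_site_type(sites: list[SeedSite]) -> str | None:
    for t in SITE_PRIORITY:
        if any(s.site_type == t for s in sites):
            return t
    return None


def collapse_mature_duplicates(mirna_seqs: dict[str, str]) -> dict[str, str]:
    """Collapse miRNAs sharing a mature sequence into one entry.

    Loci producing the same mature form (e.g. mir-9-1/2/3) are represented
    once, keyed by the joined ids.
    """
    by_seq: dict[str, list[str]] = {}
    for name, seq in mirna_seqs.items():
        by_seq.setdefault(_to_dna(seq, name), []).append(name)
    return {"/".join(names): seq for seq, names in by_seq.items()}


def triage_candidates(
    mirna_expr: pd.DataFrame,
    target_expr: pd.Series,
    utr: str,
    mirna_seqs: dict[str, str],
    survival: SurvivalTable,
    rho_cutoff: float = 0.4,
    p_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Three-step miRNA repressor triage; returns the table and Venn counts.

    Step 1 screens every miRNA (rows of ``mirna_expr``, raw counts) for
    negative correlation with the target expression. Step 2 intersects the
    step-1 survivors with the miRNAs having at least one canonical seed
    site in the UTR. Step 3 median-binarizes each intersection survivor's
    raw counts and flags a prognostic inversion when the low-expression arm
    has the lower RMST. Candidates pass all three steps; the survival step
    is direction-only, with the log-rank p reported alongside.
    """
    if mirna_expr.empty:
        return (
            pd.DataFrame(
                columns=["rho", "p", "n_sites", "best_site_type", "survival_inverted", "logrank_p", "candidate"]
            ),
            {"negative_correlation": 0, "with_site": 0, "intersection": 0, "candidates": 0},
        )
    known = [m for m in mirna_expr.index if m in mirna_seqs]
    for m in mirna_expr.index:
        if m not in mirna_seqs:
            import logging

            logging.getLogger("opsccrna").warning("triage: no mature sequence for %s; excluded", m)
    expr = mirna_expr.loc[known]
    screen = correlation_screen(
        target_expr, expr, rho_cutoff=rho_cutoff, p_cutoff=p_cutoff, direction="negative"
    )
    site_map = {m: seed_sites(utr, mirna_seqs[m], m) for m in known}
    rows = []
    for m in known:
        rho = screen.loc[m, "rho"]
        p = screen.loc[m, "p"]
        neg_ok = bool(screen.loc[m, "relevant"])
        sites = site_map[m]
        site_ok = len(sites) > 0
        inverted = False
        logrank_p = np.nan
        if neg_ok and site_ok:
            res = survival_by_expression(expr.loc[m], survival, q=0.5)
            # low arm worse = lower RMST in the low arm than the high arm
            inverted = res["rmst"].difference < 0
            logrank_p = res["logrank_p"]
        rows.append(
            {
                "mirna": m,
                "rho": rho,
                "p": p,
                "n_sites": len(sites),
                "best_site_type": best_site_type(sites),
                "negatively_correlated": neg_ok,
                "survival_inverted": inverted,
                "logrank_p": logrank_p,
                "candidate": neg_ok and site_ok and inverted,
            }
        )
    table = pd.DataFrame(rows).set_index("mirna").sort_values("rho")
    venn = {
        "negative_correlation": int(table["negatively_correlated"].sum()),
        "with_site": int((table["n_sites"] > 0).sum()),
        "intersection": int((table["negatively_correlated"] & (table["n_sites"] > 0)).sum()),
        "candidates": int(table["candidate"].sum()),
    }
    return table, venn
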