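"""Normalization and differential expression for bulk RNA-seq counts.

TPM (length-normalized within-sample), median-of-ratios size factors, a
plain negative-binomial Wald differential-expression test, and qPCR
delta-delta-Ct arithmetic.

The DE test is deliberately simple and fully documented rather than a
re-implementation of any particular estimator with shrinkage: counts are
scaled by median-of-ratios size factors, a per-gene NB dispersion alpha
(variance mu + alpha mu^2) is estimated by method of moments from the
pooled within-group variance, the log2 fold change uses a 0.5 pseudocount
on normalized group means, and the Wald standard error comes from the NB
delta method. P-values are two-sided normal; FDR is Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import CountsMatrix

LOG2 = np.log(2.0)


def compute_tpm(cm: CountsMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per sample.

    rate_g = count_g / (length_g / 1000); TPM_g = rate_g / sum(rate) * 1e6.
    Raises if any sample has zero total counts (TPM undefined).
    """
    rates = cm.counts / (cm.gene_lengths_bp[:, None] / 1000.0)
    colsum = rates.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[cm.sample_ids[j] for j in zero]}")
    tpm = rates / colsum * 1e6
    return pd.DataFrame(tpm, index=cm.gene_ids, columns=cm.sample_ids)


def size_factors(cm: CountsMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Over genes with nonzero counts in every sample, factor_j is the median of
    count_gj / geometric-mean_g(count_g.).
    """
    counts = cm.counts.astype(float)
    everywhere = np.all(counts > 0, axis=1)
    if not everywhere.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = counts[everywhere]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=cm.sample_ids, name="size_factor")


@dataclass
class DEResult:
    """Per-gene differential-expression table (group A vs group B)."""

    table: pd.DataFrame  # gene-indexed: baseMeanA, baseMeanB, log2FC, SE, stat, pvalue, FDR, significant
    group_a: str
    group_b: str
    lfc_cutoff: float
    fdr_cutoff: float

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _nb_wald_one_contrast(
    norm: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """LFC and Wald SE for one two-group contrast on normalized counts.

    Returns (log2FC, SE). Dispersion is method-of-moments from the pooled
    within-group variance (Bessel-corrected), floored at 1e-8; the delta
    method gives Var(log2 mean) = (1/ln2)^2 * (1/mu + alpha) / n per group.
    """
    na, nb = len(a_idx), len(b_idx)
    xa, xb = norm[:, a_idx], norm[:, b_idx]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    # pooled within-group variance; dispersion from pooled mean
    va = xa.var(axis=1, ddof=1) if na > 1 else np.zeros(norm.shape[0])
    vb = xb.var(axis=1, ddof=1) if nb > 1 else np.zeros(norm.shape[0])
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    mu_pool = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu_pool) / mu_pool**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, 1e-8)

    pc = 0.5
    lfc = np.log2(mu_a + pc) - np.log2(mu_b + pc)
    var_log2_a = (1.0 / LOG2**2) * (1.0 / (mu_a + pc) + alpha) / na
    var_log2_b = (1.0 / LOG2**2) * (1.0 / (mu_b + pc) + alpha) / nb
    se = np.sqrt(var_log2_a + var_log2_b)
    return lfc, se


def de_test(
    cm: CountsMatrix,
    group_col: str,
    group_a: str | None = None,
    group_b: str | None = None,
    batch_col: str | None = None,
    lfc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.05,
) -> DEResult:
    """Two-group NB Wald test with optional batch stratification.

    ``group_a``/``group_b`` default to the first two labels in sorted order;
    LFC is reported as A vs B (positive = higher in A). With ``batch_col``
    set, the contrast is estimated within each batch and pooled by
    inverse-variance weighting; each batch must contain both groups with at
    least two samples each.
    """
    groups = cm.metadata[group_col]
    labels = sorted(groups.dropna().unique())
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, found {labels}")
        group_a, group_b = labels[0], labels[1]
    sf = size_factors(cm)
    norm = cm.counts / sf.to_numpy()[None, :]

    def idx(label: str, mask: np.ndarray) -> np.ndarray:
        sel = np.flatnonzero((groups.to_numpy() == label) & mask)
        if len(sel) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples in a stratum")
        return sel

    if batch_col is None:
        all_mask = np.ones(cm.n_samples, bool)
        lfc, se = _nb_wald_one_contrast(norm, idx(group_a, all_mask), idx(group_b, all_mask))
    else:
        batches = cm.metadata[batch_col]
        num = np.zeros(cm.n_genes)
        den = np.zeros(cm.n_genes)
        for b in sorted(batches.dropna().unique()):
            mask = (batches == b).to_numpy()
            l_b, s_b = _nb_wald_one_contrast(norm, idx(group_a, mask), idx(group_b, mask))
            w = 1.0 / s_b**2
            num += w * l_b
            den += w
        lfc = num / den
        se = np.sqrt(1.0 / den)

    stat = lfc / se
    pval = 2.0 * stats.norm.sf(np.abs(stat))
    _, fdr, _, _ = multipletests(pval, method="fdr_bh")
    a_mask = (groups == group_a).to_numpy()
    b_mask = (groups == group_b).to_numpy()
    table = pd.DataFrame(
        {
            "baseMeanA": norm[:, a_mask].mean(axis=1),
            "baseMeanB": norm[:, b_mask].mean(axis=1),
            "log2FC": lfc,
            "SE": se,
            "stat": stat,
            "pvalue": pval,
            "FDR": fdr,
            "significant": (np.abs(lfc) > lfc_cutoff) & (fdr < fdr_cutoff),
        },
        index=pd.Index(cm.gene_ids, name="gene"),
    )
    return DEResult(table, group_a, group_b, lfc_cutoff, fdr_cutoff)


@dataclass(frozen=True)
class DdctResult:
    delta_ct: float
    delta_ct_control: float
    delta_delta_ct: float
    relative_expression: float


def ddct_fold_change(
    ct_target: float, ct_ref_mean: float, ct_target_ctrl: float, ct_ref_mean_ctrl: float
) -> DdctResult:
    """Relative qPCR quantification: 2^(-ddCt) against a reference gene and
    a control condition (control maps to relative expression 1)."""
    for name, v in [
        ("ct_target", ct_target),
        ("ct_ref_mean", ct_ref_mean),
        ("ct_target_ctrl", ct_target_ctrl),
        ("ct_ref_mean_ctrl", ct_ref_mean_ctrl),
    ]:
        if not (0.0 < v < 45.0):
            raise ValueError(f"{name}={v} outside the valid Ct range (0, 45)")
    d = ct_target - ct_ref_mean
    d0 = ct_target_ctrl - ct_ref_mean_ctrl
    dd = d - d0
    return DdctResult(d, d0, dd, 2.0 ** (-dd))
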