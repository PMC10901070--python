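"""Spearman correlation screens and constrained-least-squares deconvolution.

The correlation screens follow the relevance rules used throughout the
analysis: |rho| above a cutoff (0.4 by default) with p < 0.05 in the
configured direction. Immune deconvolution is a generic non-negative
least-squares fit of cell-type fractions against a marker-gene signature
matrix with the fractions constrained to sum to at most one; the remainder
is reported as the uncharacterized compartment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger("opsccrna")


def spearman(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Spearman rho (mid-ranks for ties) and its p-value.

    Pairwise-complete: rows where either value is NaN are dropped. The
    p-value uses the t approximation with n-2 df; for n <= 10 (or
    ``exact=True``) an exact permutation p over all orderings is computed
    instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < len(x):
        logger.info("spearman: dropped %d incomplete pair(s)", int(len(x) - ok.sum()))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact is None:
        exact = n <= 8
    if exact:
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        denom = np.sqrt((pc**2).sum(axis=1) * (rxc**2).sum())
        rs = num / denom
        p = float(np.mean(np.abs(rs) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class CorrelationRecord:
    partner: str
    rho: float
    p: float
    relevant: bool


def correlation_screen(
    anchor: pd.Series,
    partners: pd.DataFrame,
    rho_cutoff: float = 0.4,
    p_cutoff: float = 0.05,
    direction: str = "positive",
) -> pd.DataFrame:
    """Correlate an anchor vector against every row of ``partners``.

    ``direction`` selects the relevance rule: ``positive`` flags
    rho > +cutoff, ``negative`` flags rho < -cutoff, ``both`` flags
    |rho| > cutoff; all additionally require p < p_cutoff. Output is sorted
    by rho descending (waterfall-ready).
    """
    if direction not in {"positive", "negative", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    shared = [s for s in partners.columns if s in anchor.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared samples")
    a = anchor.loc[shared].to_numpy(float)
    rows = []
    for partner, vals in partners[shared].iterrows():
        rho, p = spearman(a, vals.to_numpy(float), exact=False)
        if direction == "positive":
            hit = rho > rho_cutoff
        elif direction == "negative":
            hit = rho < -rho_cutoff
        else:
            hit = abs(rho) > rho_cutoff
        rows.append(CorrelationRecord(str(partner), rho, p, bool(hit and p < p_cutoff)))
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("partner")
    return out.sort_values("rho", ascending=False)


def correlation_matrix(expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p matrices over the rows (genes) of ``expr``.

    Symmetric with unit diagonal; a constant gene yields NaN in its row and
    column rather than an error.
    """
    genes = list(expr.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    k = len(genes)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r, p = spearman(expr.iloc[i], expr.iloc[j], exact=False)
            except ValueError:
                r, p = np.nan, np.nan
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return (
        pd.DataFrame(rho, index=genes, columns=genes),
        pd.DataFrame(pmat, index=genes, columns=genes),
    )


@dataclass
class DeconvolutionResult:
    fractions: pd.Series  # per cell type, >= 0
    other: float  # 1 - sum(fractions)
    residual_norm: float
    rank_deficient: bool


def deconvolve(mixture: pd.Series, signature: pd.DataFrame) -> DeconvolutionResult:
    """Estimate cell-type fractions f >= 0 with sum(f) <= 1 from a mixture.

    Solves min ||S f - m||^2 after total-normalizing the mixture onto the
    signature's scale (so the answer is invariant to the mixture's units).
    The sum constraint is enforced by a non-negative slack fraction, solved
    with NNLS on an augmented system; 1 - sum(f) is returned as the
    uncharacterized remainder.
    """
    missing = [g for g in signature.index if g not in mixture.index]
    if missing:
        raise ValueError(f"mixture lacks signature marker gene(s): {missing[:5]}")
    s = signature.to_numpy(float)
    m = mixture.loc[signature.index].to_numpy(float)
    rank_def = np.linalg.matrix_rank(s) < s.shape[1]
    if rank_def:
        logger.warning("deconvolve: signature matrix is rank-deficient")
    # bring the mixture onto the signature scale: a pure single-type mixture
    # should map exactly onto that signature column
    col_tot = s.sum(axis=0).mean()
    m_tot = m.sum()
    if m_tot <= 0:
        raise ValueError("mixture has non-positive total on the marker genes")
    m_scaled = m / m_tot * col_tot
    # augmented NNLS: [S | 0; lam*1 | lam] [f; slack] = [m; lam] forces
    # sum(f) + slack = 1 with slack >= 0, i.e. sum(f) <= 1
    lam = 1e6 * max(1.0, np.abs(s).max())
    n_types = s.shape[1]
    a = np.vstack([np.hstack([s, np.zeros((s.shape[0], 1))]), lam * np.ones((1, n_types + 1))])
    b = np.concatenate([m_scaled, [lam]])
    sol, _ = optimize.nnls(a, b)
    f = sol[:n_types]
    resid = float(np.linalg.norm(s @ f - m_scaled))
    fractions = pd.Series(f, index=signature.columns, name="fraction")
    return DeconvolutionResult(fractions, float(max(0.0, 1.0 - f.sum())), resid, bool(rank_def))


def deconvolve_samples(tpm: pd.DataFrame, signature: pd.DataFrame) -> pd.DataFrame:
    """Deconvolve every sample (column) of a TPM matrix; adds an 'other' column."""
    rows = {}
    for sample in tpm.columns:
        res = deconvolve(tpm[sample], signature)
        rows[sample] = pd.concat([res.fractions, pd.Series({"other": res.other})])
    return pd.DataFrame(rows).T.rename_axis("sample_id")
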