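"""Preranked gene-set enrichment analysis (GSEA).

Weighted Kolmogorov-Smirnov running-sum enrichment score on a ranked gene
list, gene-permutation null, NES normalization by the mean same-sign null
ES magnitude, nominal p with a +1 pseudo-count, and a pooled-null FDR with
positive and negative branches handled separately. The leading edge is the
set members at or before the running-sum extremum (mirrored for negative
scores).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import GeneSetCollection

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500


@dataclass
class RankedList:
    """Genes ordered best-to-worst with their ranking statistic."""

    genes: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene id in ranked list")
        self.stats = np.asarray(self.stats, float)
        if not np.all(np.isfinite(self.stats)):
            raise ValueError("ranking statistics must be finite")
        if len(self.genes) != len(self.stats):
            raise ValueError("genes/stats length mismatch")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(de, mode: str = "stat") -> RankedList:
    """Build a ranked list from a DE table, descending by ``stat`` or ``lfc``.

    Ties are broken by lexicographic gene id so ranking is deterministic.
    """
    col = {"stat": "stat", "lfc": "log2FC"}[mode]
    tab = de.table if hasattr(de, "table") else de
    order = sorted(zip(tab.index, tab[col]), key=lambda kv: (-kv[1], kv[0]))
    return RankedList([g for g, _ in order], np.array([s for _, s in order]))


def _es_from_positions(
    positions: np.ndarray, absstat_p: np.ndarray, n: int
) -> tuple[float, int]:
    """ES and the extremum hit index for hits at sorted ``positions``.

    ``absstat_p`` is |stat|^p over the whole ranked list. Candidate extrema
    of the running sum occur just after each hit (local peaks) and just
    before each hit (local troughs); the ES is the extremum of maximal
    absolute value, the positive one on an exact magnitude tie. Returns
    (ES, index into positions of the extremum hit).
    """
    k = len(positions)
    w = absstat_p[positions]
    tot = w.sum()
    if tot == 0:
        raise ValueError("all hit statistics are zero: hit weights undefined")
    dec = 1.0 / (n - k)
    cum = np.cumsum(w) / tot
    i = np.arange(k)
    after = cum - (positions - i) * dec  # just after hit i
    before = np.concatenate(([0.0], cum[:-1])) - (positions - i) * dec  # just before hit i
    top = float(after.max())
    bottom = float(before.min())
    # positive extremum wins on a (numerical) magnitude tie
    if top >= -bottom - 1e-12:
        return top, int(np.argmax(after))
    return bottom, int(np.argmin(before))


def _es_many(positions: np.ndarray, absstat_p: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES over an (m, k) array of sorted hit positions."""
    m, k = positions.shape
    w = absstat_p[positions]
    tot = w.sum(axis=1, keepdims=True)
    if np.any(tot == 0):
        raise ValueError("a permutation draw has all-zero hit statistics")
    dec = 1.0 / (n - k)
    cum = np.cumsum(w, axis=1) / tot
    i = np.arange(k)[None, :]
    after = cum - (positions - i) * dec
    before = np.concatenate([np.zeros((m, 1)), cum[:, :-1]], axis=1) - (positions - i) * dec
    top = after.max(axis=1)
    bottom = before.min(axis=1)
    return np.where(top >= -bottom - 1e-12, top, bottom)


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum and leading edge for one gene set.

    Hits increment the running sum by |stat|^p / sum_hits |stat|^p, misses
    decrement by 1/(N - N_hits). For ES > 0 the leading edge is the hits at
    or before the extremum; for ES < 0, at or after it.
    """
    n = len(ranked)
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in ranked.genes), bool, n)
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if k == n:
        raise ValueError("gene set covers the whole ranked list: no misses")
    absstat_p = np.abs(ranked.stats) ** weight_p
    positions = np.flatnonzero(hit_mask)
    es, j = _es_from_positions(positions, absstat_p, n)

    w = absstat_p[positions]
    steps = np.where(hit_mask, 0.0, -1.0 / (n - k))
    steps[positions] = w / w.sum()
    running = np.cumsum(steps)

    if es >= 0:
        leading = [ranked.genes[p] for p in positions[: j + 1]]
    else:
        leading = [ranked.genes[p] for p in positions[j:]]
    return es, running, leading


@dataclass
class GseaResult:
    table: pd.DataFrame  # set-indexed: size, ES, NES, pval, FDR, significant, leading_edge
    nperm: int
    seed: int | None


def gsea_significance(
    ranked: RankedList,
    sets: GeneSetCollection,
    nperm: int = 1000,
    weight_p: float = 1.0,
    seed: int | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    fdr_cutoff: float = 0.05,
    exhaustive: bool = False,
) -> GseaResult:
    """Permutation GSEA over a gene-set collection.

    The null for a set of size k is the ES of k genes drawn uniformly
    without replacement from the ranked list (gene permutation). With
    ``exhaustive=True`` every k-subset is enumerated instead (small lists
    only). NES = ES / mean(|null ES| of matching sign); nominal p uses the
    same-sign null tail with a +1 pseudo-count; FDR compares the observed
    NES values against the pooled null NES distribution, positive and
    negative branches separately.
    """
    import logging

    if nperm < 100 and not exhaustive:
        logging.getLogger("opsccrna").warning("nperm=%d is very low; p-values will be coarse", nperm)
    n = len(ranked)
    absstat_p = np.abs(ranked.stats) ** weight_p
    in_list = set(ranked.genes)

    eligible: dict[str, list[str]] = {}
    for name, genes in sets.items():
        k = len(in_list.intersection(genes))
        if min_size <= k <= max_size and k < n:
            eligible[name] = genes
    if not eligible:
        raise ValueError("no eligible gene set after size filtering")

    rng = np.random.default_rng(seed)
    es_obs: dict[str, float] = {}
    leading: dict[str, list[str]] = {}
    sizes: dict[str, int] = {}
    for name, genes in eligible.items():
        es, _, le = enrichment_score(ranked, genes, weight_p)
        es_obs[name] = es
        leading[name] = le
        sizes[name] = len(in_list.intersection(genes))

    # one null ES sample per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes.values())):
        if exhaustive:
            combos = np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)
            null_by_size[k] = _es_many(combos, absstat_p, n)
        else:
            draws = np.empty((nperm, k), dtype=np.intp)
            for m in range(nperm):
                draws[m] = np.sort(rng.choice(n, size=k, replace=False))
            null_by_size[k] = _es_many(draws, absstat_p, n)

    rows = []
    nes_null_pool_pos: list[np.ndarray] = []
    nes_null_pool_neg: list[np.ndarray] = []
    nes_obs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for name in eligible:
        es = es_obs[name]
        null = null_by_size[sizes[name]]
        pos, neg = null[null >= 0], null[null < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        if es > 0:
            nes = es / mean_pos if np.isfinite(mean_pos) else np.nan
            # 1e-12 slack so exact-arithmetic ties are not split by float noise
            p = (1.0 + np.sum(pos >= es - 1e-12)) / (1.0 + pos.size)
        elif es < 0:
            nes = -(abs(es) / mean_neg) if np.isfinite(mean_neg) else np.nan
            p = (1.0 + np.sum(neg <= es + 1e-12)) / (1.0 + neg.size)
        else:
            nes, p = 0.0, 1.0
        nes_obs[name] = nes
        pvals[name] = p
        if np.isfinite(mean_pos):
            nes_null_pool_pos.append(pos / mean_pos)
        if np.isfinite(mean_neg):
            nes_null_pool_neg.append(-(np.abs(neg) / mean_neg))

    pool_pos = np.concatenate(nes_null_pool_pos) if nes_null_pool_pos else np.empty(0)
    pool_neg = np.concatenate(nes_null_pool_neg) if nes_null_pool_neg else np.empty(0)
    obs_vals = np.array([nes_obs[name] for name in eligible])

    for name in eligible:
        nes = nes_obs[name]
        if nes >= 0:
            null_frac = np.mean(pool_pos >= nes) if pool_pos.size else 1.0
            obs_frac = np.mean(obs_vals[obs_vals >= 0] >= nes)
        else:
            null_frac = np.mean(pool_neg <= nes) if pool_neg.size else 1.0
            obs_frac = np.mean(obs_vals[obs_vals < 0] <= nes)
        fdr = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        rows.append(
            {
                "set": name,
                "size": sizes[name],
                "ES": es_obs[name],
                "NES": nes,
                "pval": pvals[name],
                "FDR": fdr,
                "significant": fdr < fdr_cutoff,
                "leading_edge": ",".join(leading[name]),
            }
        )
    table = pd.DataFrame(rows).set_index("set").sort_values("NES", ascending=False)
    return GseaResult(table, nperm=nperm, seed=seed)
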