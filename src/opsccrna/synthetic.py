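"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of a two-group bulk
RNA-seq tumor cohort (an HPV-negative and an HPV-positive arm) without any
download: negative-binomial counts with a planted differentially expressed
gene set, a planted hub gene sharing a latent factor with partner genes at
configured Spearman levels, exponential survival with a log-hazard linear
in standardized expression, a miRNA/target system with one true repressor,
and textured scratch-assay images with a smooth wound band of known area.

Every generator is a pure function of (config, seed): the same
configuration yields byte-identical outputs. Ground-truth records carry
everything needed to score downstream stages without re-deriving
simulation internals.

Default conditions mirror the cohort the pipeline targets: 23 vs 39
samples (the HPV-negative / HPV-positive split of a 62-patient cohort),
a 50-gene planted set at +2 log2 fold change in the negative arm, hub
partner Spearman targets (0.62, 0.82, 0.69), and ~79% censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CountsMatrix, SurvivalTable

GROUP_A = "HPV_negative"
GROUP_B = "HPV_positive"

DEFAULT_SEED = 20240228


@dataclass
class SimulationConfig:
    """Knobs for all generators; every size/level has a cohort-like default."""

    n_genes: int = 2000
    n_samples_per_group: tuple[int, int] = (23, 39)
    nb_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 of NB means
    nb_dispersion: float = 0.1  # alpha in var = mu + alpha mu^2
    planted_set_size: int = 50
    planted_lfc: float = 2.0  # log2, group A over group B
    hub_gene_id: str = "HUB_GENE"
    hub_partner_rhos: tuple[float, ...] = (0.62, 0.82, 0.69)
    hazard_coefficient: float = 1.0  # log-hazard per SD of expression
    censoring_rate: float = 0.79
    baseline_median_months: float = 60.0
    batch_shift_log2: float = 0.0  # two-level batch effect on a random 20% of genes
    wound_fraction_trajectory: tuple[float, ...] = (0.4, 0.2, 0.1)
    image_size: tuple[int, int] = (256, 256)
    texture_noise_sd: float = 40.0
    n_background_mirnas: int = 10
    mirna_rho: float = -0.7  # copula level of the planted repressor
    utr_length: int = 500
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or min(self.n_samples_per_group) <= 0:
            raise ValueError("sizes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.planted_set_size > self.n_genes:
            raise ValueError("planted_set_size exceeds n_genes")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if any(not 0 <= f <= 1 for f in self.wound_fraction_trajectory):
            raise ValueError("wound fractions must be in [0, 1]")
        if self.utr_length < 8:
            raise ValueError("UTR must be at least 8 nt")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _nb_params(mu: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """scipy nbinom (n, p) for mean mu and dispersion alpha."""
    n = 1.0 / alpha
    p = n / (n + mu)
    return n, p


def _nb_from_latent(z: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """Map standard-normal latents to NB(mu, alpha) counts via the Gaussian
    copula (probability integral transform), preserving rank dependence."""
    u = stats.norm.cdf(z)
    n, p = _nb_params(np.full_like(z, mu, dtype=float), alpha)
    return stats.nbinom.ppf(np.clip(u, 1e-12, 1 - 1e-12), n, p).astype(np.int64)


@dataclass
class CountsTruth:
    planted_genes: list[str]
    true_lfc: pd.Series  # log2, A over B, per gene
    hub_gene: str
    partner_rhos: dict[str, float]  # partner gene -> target Spearman
    hub_latent: pd.Series  # per-sample latent factor of the hub gene
    groups: pd.Series
    batch_genes: list[str] = field(default_factory=list)


def gen_counts(config: SimulationConfig) -> tuple[CountsMatrix, CountsTruth]:
    """Two-group NB count matrix with a planted DE set and a hub gene.

    Genes in the planted set (which includes the hub) have expected log2
    fold change ``planted_lfc`` in group A over group B. The hub and its
    partners share a per-sample latent factor through a Gaussian copula at
    Pearson levels chosen so the resulting Spearman correlations match
    ``hub_partner_rhos`` (rho_P = 2 sin(pi rho_S / 6)).
    """
    rng = _rng(config, 1)
    n_g = config.n_genes
    n_a, n_b = config.n_samples_per_group
    n_s = n_a + n_b
    alpha = config.nb_dispersion

    gene_ids = [f"G{i:05d}" for i in range(1, n_g + 1)]
    partner_ids = [f"PARTNER_{i+1}" for i in range(len(config.hub_partner_rhos))]
    special = [config.hub_gene_id, *partner_ids]
    gene_ids[: len(special)] = special

    lo, hi = config.nb_mean_log_range
    base_mu = 10.0 ** rng.uniform(lo, hi, size=n_g)

    # the hub and its partners stay out of the planted DE set: their
    # cross-sample variation is the copula latent factor, not a group shift
    n_special = 1 + len(config.hub_partner_rhos)
    planted_idx = n_special + rng.choice(
        n_g - n_special, size=config.planted_set_size, replace=False
    )
    lfc = np.zeros(n_g)
    lfc[planted_idx] = config.planted_lfc

    groups = pd.Series(
        [GROUP_A] * n_a + [GROUP_B] * n_b,
        index=[f"S{j:03d}" for j in range(1, n_s + 1)],
        name="group",
    )
    mu = np.outer(base_mu, np.ones(n_s))
    mu[:, :n_a] *= 2.0 ** lfc[:, None]

    batch = pd.Series(np.where(np.arange(n_s) % 2 == 0, "batch1", "batch2"), index=groups.index, name="batch")
    batch_genes: list[str] = []
    if config.batch_shift_log2 != 0.0:
        bidx = rng.choice(n_g, size=max(1, n_g // 5), replace=False)
        mu[np.ix_(bidx, np.flatnonzero(batch.to_numpy() == "batch2"))] *= 2.0**config.batch_shift_log2
        batch_genes = [gene_ids[i] for i in sorted(bidx)]

    # independent gamma-poisson for the bulk of genes
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    counts = rng.poisson(lam).astype(np.int64)

    # hub + partners: Gaussian copula on a shared latent factor
    z_hub = rng.standard_normal(n_s)
    counts[0] = _nb_from_latent_rowwise(z_hub, mu[0], alpha)
    partner_rhos: dict[str, float] = {}
    for k, rho_s in enumerate(config.hub_partner_rhos):
        r_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        eps = rng.standard_normal(n_s)
        z = r_p * z_hub + np.sqrt(1.0 - r_p**2) * eps
        counts[1 + k] = _nb_from_latent_rowwise(z, mu[1 + k], alpha)
        partner_rhos[partner_ids[k]] = rho_s

    lengths = rng.integers(500, 10001, size=n_g)
    metadata = pd.DataFrame({"group": groups, "batch": batch})
    cm = CountsMatrix(gene_ids, list(groups.index), counts, lengths, metadata)
    truth = CountsTruth(
        planted_genes=[gene_ids[i] for i in sorted(planted_idx)],
        true_lfc=pd.Series(lfc, index=gene_ids),
        hub_gene=config.hub_gene_id,
        partner_rhos=partner_rhos,
        hub_latent=pd.Series(z_hub, index=groups.index),
        groups=groups,
        batch_genes=batch_genes,
    )
    return cm, truth


def _nb_from_latent_rowwise(z: np.ndarray, mu_row: np.ndarray, alpha: float) -> np.ndarray:
    u = np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12)
    n, p = _nb_params(mu_row.astype(float), alpha)
    return stats.nbinom.ppf(u, n, p).astype(np.int64)


@dataclass
class SurvivalTruth:
    hazard_coefficient: float
    true_hazard_ratio_per_sd: float
    censoring_rate: float


def gen_survival(
    expression: pd.Series, config: SimulationConfig, stream: int = 2
) -> tuple[SurvivalTable, SurvivalTruth]:
    """Exponential event times with log-hazard linear in standardized
    expression, plus independent uniform censoring at the configured rate.

    Censoring times are Uniform(0, c_max), independent of the event times,
    with c_max calibrated so the expected censored fraction equals
    ``censoring_rate``; the observed time is min(T, C). Times are in
    months with a baseline median of ``baseline_median_months``.
    """
    x = expression.to_numpy(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("expression must be finite")
    rng = _rng(config, stream)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    lam0 = np.log(2.0) / config.baseline_median_months
    rate = lam0 * np.exp(config.hazard_coefficient * z)
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        c_max = _calibrate_uniform_censoring(rate, config.censoring_rate)
        t_cens = rng.uniform(0.0, c_max, len(x))
        censored = t_cens < t_event
        t_obs = np.minimum(t_event, t_cens)
    else:
        censored = np.zeros(len(x), bool)
        t_obs = t_event
    t_obs = np.maximum(t_obs, 1e-6)
    df = pd.DataFrame(
        {"time_months": t_obs, "event": (~censored).astype(int)},
        index=pd.Index(expression.index, name="sample_id"),
    )
    return SurvivalTable(df), SurvivalTruth(
        config.hazard_coefficient, float(np.exp(config.hazard_coefficient)), config.censoring_rate
    )


def _calibrate_uniform_censoring(rates: np.ndarray, target: float) -> float:
    """c_max of Uniform(0, c_max) censoring giving the target censored
    fraction, P(C < T) averaged over the subjects' exponential rates."""
    from scipy.optimize import brentq

    def censored_frac(c: float) -> float:
        rc = rates * c
        return float(np.mean((1.0 - np.exp(-rc)) / rc))

    lo, hi = 1e-9, 1e9
    return float(brentq(lambda c: censored_frac(c) - target, lo, hi, xtol=1e-9))


def gen_scratch_images(
    config: SimulationConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Scratch-assay image series with ground-truth wound masks.

    Each timepoint is an 8-bit grayscale image: speckle-textured "cell"
    regions (Gaussian noise, sd ``texture_noise_sd``) flanking a smooth
    vertical wound band whose pixel area equals the configured fraction of
    the frame up to rasterization error. The band edges carry a zero-mean
    sinusoidal perturbation (whole periods) so the boundary is not a
    straight line.
    """
    if not config.wound_fraction_trajectory:
        raise ValueError("wound trajectory is empty")
    if config.texture_noise_sd <= 0:
        raise ValueError("texture_noise_sd must be positive: a noise-free cell region is indistinguishable from the wound")
    h, w = config.image_size
    if min(h, w) < 22:  # 2x the default entropy footprint (disk radius 5)
        raise ValueError("image smaller than 2x the entropy footprint")
    rng = _rng(config, 3)
    images, masks = [], []
    y = np.arange(h)
    for t, frac in enumerate(config.wound_fraction_trajectory):
        band = frac * w
        cx = w / 2.0
        amp = min(8.0, band / 4.0)
        periods = 3
        left = cx - band / 2.0 + amp * np.sin(2 * np.pi * periods * y / h)
        right = cx + band / 2.0 + amp * np.sin(2 * np.pi * periods * y / h + 2.0)
        x = np.arange(w)[None, :]
        mask = (x >= left[:, None]) & (x < right[:, None])
        if frac == 0:
            mask = np.zeros((h, w), bool)
        cell = np.clip(rng.normal(128.0, config.texture_noise_sd, (h, w)), 0, 255)
        wound = np.clip(rng.normal(120.0, 1.5, (h, w)), 0, 255)
        img = np.where(mask, wound, cell).astype(np.uint8)
        images.append(img)
        masks.append(mask)
    return images, masks


def gen_signature_mixtures(
    config: SimulationConfig,
    n_markers: int = 40,
    n_types: int = 6,
    n_mixtures: int = 20,
    noise_sd: float = 0.0,
    full_sum: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Signature matrix + synthetic mixtures with known fractions.

    The signature has log-normal marker profiles with columns normalized
    to a common total (cell types expressed on a shared library scale);
    mixtures are S @ f with Dirichlet fractions plus optional Gaussian
    noise. With ``full_sum`` the fractions sum to one; otherwise each type
    gets dedicated marker support (block structure) plus an extra marker
    block carrying an unmodeled "other" profile that fills the library to
    the common total, so the deconvolver's remainder is well defined.
    Returns (signature, mixtures, true_fractions), sample-indexed.
    """
    rng = _rng(config, 6)
    types = [f"type{chr(ord('A') + t)}" for t in range(n_types)]
    frac = rng.dirichlet(np.ones(n_types), size=n_mixtures)
    if full_sum:
        markers = [f"M{i:03d}" for i in range(1, n_markers + 1)]
        s = rng.lognormal(mean=2.0, sigma=1.0, size=(n_markers, n_types))
        s = s / s.sum(axis=0) * 1000.0  # common column total
        mix = frac @ s.T
    else:
        block = max(2, n_markers // (n_types + 1))
        n_markers = block * (n_types + 1)
        markers = [f"M{i:03d}" for i in range(1, n_markers + 1)]
        s = np.zeros((n_markers, n_types))
        for t in range(n_types):
            s[t * block : (t + 1) * block, t] = rng.lognormal(2.0, 1.0, size=block)
        s[n_types * block :, :] = 1e-9  # keep marker rows non-degenerate
        s = s / s.sum(axis=0) * 1000.0
        other = np.zeros(n_markers)
        other[n_types * block :] = rng.lognormal(2.0, 1.0, size=block)
        other = other / other.sum() * 1000.0
        frac *= rng.uniform(0.5, 0.9, size=(n_mixtures, 1))
        mix = frac @ s.T + np.outer(1.0 - frac.sum(axis=1), other)
    if noise_sd > 0:
        mix = np.maximum(mix + rng.normal(0, noise_sd, mix.shape), 0)
    samples = [f"MX{j:02d}" for j in range(1, n_mixtures + 1)]
    return (
        pd.DataFrame(s, index=markers, columns=types),
        pd.DataFrame(mix, index=samples, columns=markers),
        pd.DataFrame(frac, index=samples, columns=types),
    )


_BASES = np.array(list("ACGT"))

_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp_dna(s: str) -> str:
    return "".join(_DNA_COMP[c] for c in reversed(s))


@dataclass
class MirnaSystem:
    mirna_counts: pd.DataFrame  # miRNA x sample raw counts
    mirna_seqs: dict[str, str]  # mature sequences, 5'->3', RNA alphabet
    utr: str  # target 3'UTR, DNA alphabet, sense strand
    target_expr: pd.Series  # per-sample target (hub) expression
    survival: SurvivalTable
    repressor: str  # the miRNA that should survive triage
    decoy_anticorr_nosite: str
    decoy_site_uncorrelated: str
    background: list[str]


def gen_mirna_system(
    config: SimulationConfig,
    target_latent: pd.Series | None = None,
    survival: SurvivalTable | None = None,
) -> MirnaSystem:
    """miRNA expression + UTR with one true repressor planted.

    Emits (a) a repressor miRNA anti-correlated with the target and with a
    canonical 8mer site in the UTR, (b) an equally anti-correlated miRNA
    with no site, (c) a miRNA with a site but near-zero correlation, and
    background miRNAs. Target expression drives survival (high = worse),
    so the repressor's low-expression arm inherits the worse outcome.

    ``target_latent``/``survival`` let the system ride on a cohort
    generated elsewhere (e.g. the hub latent of :func:`gen_counts`);
    by default a self-contained target and follow-up are drawn.
    """
    rng = _rng(config, 4)
    if target_latent is not None:
        samples = list(target_latent.index)
        n_s = len(samples)
        z_t = target_latent.to_numpy(float)
        z_t = (z_t - z_t.mean()) / z_t.std()
    else:
        n_s = sum(config.n_samples_per_group)
        samples = [f"S{j:03d}" for j in range(1, n_s + 1)]
        z_t = rng.standard_normal(n_s)
    target = pd.Series(
        _nb_from_latent_rowwise(z_t, np.full(n_s, 200.0), config.nb_dispersion),
        index=samples,
        name="target",
    ).astype(float)
    if survival is None:
        survival, _ = gen_survival(pd.Series(z_t, index=samples), config, stream=5)
    surv = survival

    def mirna_counts_from(z: np.ndarray, mu: float = 500.0) -> np.ndarray:
        return _nb_from_latent_rowwise(z, np.full(n_s, mu), config.nb_dispersion)

    r_p = 2.0 * np.sin(np.pi * config.mirna_rho / 6.0)

    def anticorr_latent() -> np.ndarray:
        eps = rng.standard_normal(n_s)
        return r_p * z_t + np.sqrt(1.0 - r_p**2) * eps

    names = ["mir-REP", "mir-DECOY-NOSITE", "mir-DECOY-SITE"] + [
        f"mir-BG{i+1}" for i in range(config.n_background_mirnas)
    ]
    rows = {
        "mir-REP": mirna_counts_from(anticorr_latent()),
        "mir-DECOY-NOSITE": mirna_counts_from(anticorr_latent()),
        "mir-DECOY-SITE": mirna_counts_from(rng.standard_normal(n_s)),
    }
    for name in names[3:]:
        rows[name] = mirna_counts_from(rng.standard_normal(n_s))
    counts = pd.DataFrame(rows, index=samples).T

    seqs = {name: "".join(rng.choice(_BASES, size=22)).replace("T", "U") for name in names}
    utr = _plant_utr(config, rng, seqs)
    return MirnaSystem(
        counts, seqs, utr, target, surv, "mir-REP", "mir-DECOY-NOSITE", "mir-DECOY-SITE", names[3:]
    )


def gen_hpv_read_counts(config: SimulationConfig, groups: pd.Series) -> pd.DataFrame:
    """Per-sample HPV-oncogene read counts consistent with the group labels.

    HPV-positive samples express E6/E7 strongly (plus backbone genes);
    HPV-negative samples carry only sparse noise reads well below the
    calling threshold.
    """
    from .hpv import ONCOGENES

    rng = _rng(config, 7)
    rows = {}
    for sid, grp in groups.items():
        if grp == GROUP_B:  # the HPV-positive arm
            e67 = rng.poisson(3000, size=2)
            others = rng.poisson(300, size=6)
            vals = np.concatenate([others[:4], e67, others[4:]])
        else:
            vals = rng.poisson(5, size=8)
        rows[sid] = dict(zip(ONCOGENES, vals.astype(int)))
    return pd.DataFrame(rows).T.rename_axis("sample_id")[list(ONCOGENES)]


def gen_gene_sets(config: SimulationConfig, truth: CountsTruth, n_decoy_sets: int = 10):
    """A GMT-ready collection: the planted set plus random decoy sets."""
    from .io_core import GeneSetCollection

    rng = _rng(config, 8)
    all_genes = list(truth.true_lfc.index)
    non_planted = [g for g in all_genes if g not in set(truth.planted_genes)]
    sets = {"PLANTED_SET": list(truth.planted_genes)}
    for i in range(n_decoy_sets):
        size = int(rng.integers(20, 80))
        sets[f"DECOY_SET_{i+1:02d}"] = list(rng.choice(non_planted, size=size, replace=False))
    return GeneSetCollection(sets, source="synthetic")


def write_bundle(outdir, config: SimulationConfig) -> dict[str, object]:
    """Generate every synthetic input class and write it via io_core formats.

    Produces counts TSV + gene-length sidecar, sample metadata CSV (group,
    batch, survival), a GMT, HPV oncogene read counts, miRNA counts +
    mature FASTA + UTR FASTA, a deconvolution signature TSV and PNG wound
    images; returns the path map plus the ground-truth records.
    """
    import imageio.v3 as iio

    from . import io_core

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = gen_counts(config)
    surv, surv_truth = gen_survival(truth.hub_latent, config)
    paths: dict[str, object] = {}

    paths["counts"] = str(outdir / "counts.tsv")
    paths["lengths"] = str(outdir / "gene_lengths.tsv")
    io_core.write_counts_table(cm, paths["counts"], paths["lengths"])

    meta = cm.metadata.copy()
    meta["time_months"] = surv.data["time_months"]
    meta["event"] = surv.data["event"]
    paths["metadata"] = str(outdir / "metadata.csv")
    meta.to_csv(paths["metadata"], index_label="sample_id", float_format="%.6g")

    paths["gmt"] = str(outdir / "gene_sets.gmt")
    io_core.write_gmt(gen_gene_sets(config, truth), paths["gmt"])

    paths["hpv_counts"] = str(outdir / "hpv_oncogene_counts.tsv")
    gen_hpv_read_counts(config, truth.groups).to_csv(paths["hpv_counts"], sep="\t")

    system = gen_mirna_system(config, target_latent=truth.hub_latent, survival=surv)
    paths["mirna_counts"] = str(outdir / "mirna_counts.tsv")
    system.mirna_counts.astype(int).to_csv(paths["mirna_counts"], sep="\t", index_label="mirna")
    paths["mirna_fasta"] = str(outdir / "mirna_mature.fasta")
    io_core.write_fasta(system.mirna_seqs, paths["mirna_fasta"])
    paths["utr_fasta"] = str(outdir / "target_3utr.fasta")
    io_core.write_fasta({"TARGET_3UTR": system.utr}, paths["utr_fasta"])

    sig, _, _ = gen_signature_mixtures(config)
    # markers must be cohort genes so the pipeline can deconvolve cohort TPM
    sig.index = cm.gene_ids[-len(sig) :]
    paths["signature"] = str(outdir / "signature.tsv")
    sig.to_csv(paths["signature"], sep="\t", index_label="gene", float_format="%.6g")

    images, masks = gen_scratch_images(config)
    image_paths = []
    for i, img in enumerate(images):
        p = str(outdir / f"wound_t{i}.png")
        iio.imwrite(p, img)
        image_paths.append(p)
    paths["images"] = image_paths

    paths["truth"] = {"counts": truth, "survival": surv_truth, "mirna": system, "masks": masks}
    return paths


def _plant_utr(config: SimulationConfig, rng: np.random.Generator, seqs: dict[str, str]) -> str:
    """Random UTR with 8mer sites planted for mir-REP and mir-DECOY-SITE and
    all seed matches of mir-DECOY-NOSITE scrubbed."""
    from .mirna import seed_sites  # local import to avoid a cycle at module load

    n = config.utr_length
    utr = list("".join(rng.choice(_BASES, size=n)))

    def site_for(mirna: str) -> str:
        seed7 = mirna.replace("U", "T")[1:8]
        return _revcomp_dna(seed7) + "A"  # 8mer: seed match + A1 anchor

    pos_rep = n // 4
    pos_decoy = 3 * n // 4
    for pos, name in [(pos_rep, "mir-REP"), (pos_decoy, "mir-DECOY-SITE")]:
        s = site_for(seqs[name])
        utr[pos : pos + 8] = list(s)
    utr_s = "".join(utr)

    # scrub accidental seed matches of the no-site decoy (keep planted sites intact)
    protected = set(range(pos_rep, pos_rep + 8)) | set(range(pos_decoy, pos_decoy + 8))
    for _ in range(50):
        hits = seed_sites(utr_s, seqs["mir-DECOY-NOSITE"], "scrub")
        hits = [h for h in hits]
        if not hits:
            break
        utr_l = list(utr_s)
        for h in hits:
            mid = (h.start + h.end) // 2
            target_pos = mid if mid not in protected else next(
                (p for p in range(h.start, h.end) if p not in protected), None
            )
            if target_pos is None:
                continue
            cur = utr_l[target_pos]
            utr_l[target_pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
        utr_s = "".join(utr_l)
    return utr_s
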