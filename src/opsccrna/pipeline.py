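"""End-to-end orchestration: cohort summary and the staged analysis run.

``run_pipeline`` executes the full analysis from files on disk — HPV
calling, TPM + differential expression, preranked GSEA, expression-
binarized survival of an anchor gene, correlation/deconvolution screens,
miRNA triage, and (optionally) wound-image quantification — writing every
stage's output as a TSV with fixed float rendering plus a JSON manifest,
so a rerun with the same config and seed is byte-identical. Stages hand
off through files, never in-memory state, and are individually skippable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__, expression, gsea, hpv, imaging, io_core, mirna, screens, survival

logger = logging.getLogger("opsccrna")


# ---------------------------------------------------------------------------
# cohort summary


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(records: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable level counts and percentages of the whole cohort.

    Percentages use the full cohort size as denominator, rounded half-up
    to one decimal; missing values are counted as their own level. Output
    columns: variable, level, n, pct.
    """
    if records.empty:
        raise ValueError("empty cohort table")
    if variables is None:
        variables = list(records.columns)
    n_total = len(records)
    rows = []
    for var in variables:
        col = records[var]
        counts = col.value_counts(dropna=True)
        for level, n in counts.items():
            rows.append({"variable": var, "level": str(level), "n": int(n), "pct": _round_half_up_1dp(100.0 * n / n_total)})
        n_missing = int(col.isna().sum())
        rows.append({"variable": var, "level": "Missing", "n": n_missing, "pct": _round_half_up_1dp(100.0 * n_missing / n_total)})
    return pd.DataFrame(rows)


def summarize_counts(level_counts: dict[str, int]) -> pd.DataFrame:
    """Cohort summary from pre-tabulated level counts of one variable."""
    n_total = sum(level_counts.values())
    if n_total == 0:
        raise ValueError("empty cohort")
    return pd.DataFrame(
        [
            {"level": lvl, "n": n, "pct": _round_half_up_1dp(100.0 * n / n_total)}
            for lvl, n in level_counts.items()
        ]
    )


# ---------------------------------------------------------------------------
# pipeline config and runner


@dataclass
class PipelineConfig:
    outdir: str
    counts_path: str | None = None
    lengths_path: str | None = None
    metadata_path: str | None = None  # CSV: sample_id, group, batch, time_months, event
    gmt_path: str | None = None
    hpv_counts_path: str | None = None
    mirna_counts_path: str | None = None
    mirna_fasta_path: str | None = None
    utr_fasta_path: str | None = None
    signature_path: str | None = None
    image_paths: list[str] = field(default_factory=list)
    anchor_gene: str = "HUB_GENE"
    group_col: str = "group"
    batch_col: str | None = None
    lfc_cutoff: float = 1.0
    fdr_cutoff: float = 0.05
    rho_cutoff: float = 0.4
    p_cutoff: float = 0.05
    nperm: int = 1000
    quantile: float = 0.75
    entropy_radius: int = 5
    seed: int = 20240228

    def validate(self) -> None:
        for name in (
            "counts_path",
            "lengths_path",
            "metadata_path",
            "gmt_path",
            "hpv_counts_path",
            "mirna_counts_path",
            "mirna_fasta_path",
            "utr_fasta_path",
            "signature_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for p in self.image_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"image: {p}")
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def run_pipeline(config: PipelineConfig, skip: set[str] | None = None) -> dict:
    """Run every configured stage, writing outputs and a manifest JSON.

    Returns the manifest. A stage whose inputs are not configured is
    skipped and omitted from the manifest; an explicit ``skip`` set
    suppresses stages by name. Any stage failure aborts with the stage
    name and the partial manifest attached.
    """
    config.validate()
    skip = skip or set()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "lfc_cutoff": config.lfc_cutoff,
            "fdr_cutoff": config.fdr_cutoff,
            "rho_cutoff": config.rho_cutoff,
            "p_cutoff": config.p_cutoff,
            "nperm": config.nperm,
            "quantile": config.quantile,
            "entropy_radius": config.entropy_radius,
        },
        "stages": {},
    }

    def record(stage: str, files: dict[str, str]) -> None:
        # manifest paths are relative to outdir so identical runs are
        # byte-identical wherever they land
        manifest["stages"][stage] = {
            k: str(Path(v).relative_to(outdir)) for k, v in files.items()
        }

    def out(name: str) -> Path:
        return outdir / name

    cm = tpm = de = surv_table = None
    try:
        if config.hpv_counts_path and "hpvcall" not in skip:
            stage = "hpvcall"
            calls = hpv.call_hpv_table(hpv.read_hpv_counts(config.hpv_counts_path))
            io_core.write_table(calls, out("hpv_calls.tsv"), index_label="sample_id")
            record(stage, {"calls": str(out("hpv_calls.tsv"))})

        if config.counts_path:
            stage = "load_counts"
            meta = pd.read_csv(config.metadata_path, index_col="sample_id") if config.metadata_path else None
            cm = io_core.read_counts_table(config.counts_path, config.lengths_path, metadata=meta)
            if meta is not None and {"time_months", "event"} <= set(meta.columns):
                ok = meta.dropna(subset=["time_months", "event"])
                surv_table = io_core.SurvivalTable(
                    ok[["time_months", "event"]].assign(event=lambda d: d["event"].astype(int))
                )

        if cm is not None and "de" not in skip:
            stage = "de"
            tpm = expression.compute_tpm(cm)
            io_core.write_table(tpm, out("tpm.tsv"), index_label="gene")
            de = expression.de_test(
                cm,
                group_col=config.group_col,
                batch_col=config.batch_col,
                lfc_cutoff=config.lfc_cutoff,
                fdr_cutoff=config.fdr_cutoff,
            )
            io_core.write_table(de.table, out("de.tsv"), index_label="gene")
            record(stage, {"tpm": str(out("tpm.tsv")), "de": str(out("de.tsv"))})

        if de is not None and config.gmt_path and "gsea" not in skip:
            stage = "gsea"
            ranked = gsea.rank_genes(de, mode="stat")
            res = gsea.gsea_significance(
                ranked,
                io_core.read_gmt(config.gmt_path),
                nperm=config.nperm,
                seed=config.seed,
                fdr_cutoff=config.fdr_cutoff,
            )
            io_core.write_table(res.table, out("gsea.tsv"), index_label="set")
            record(stage, {"gsea": str(out("gsea.tsv"))})

        if tpm is not None and surv_table is not None and "survival" not in skip:
            stage = "survival"
            anchor = tpm.loc[config.anchor_gene]
            res = survival.survival_by_expression(anchor, surv_table, q=config.quantile)
            r = res["rmst"]
            tab = pd.DataFrame(
                [
                    {"arm": "low", "n": r.n_low, "events": int(res["arm_low"].event.sum()), "RMST": r.rmst_low},
                    {"arm": "high", "n": r.n_high, "events": int(res["arm_high"].event.sum()), "RMST": r.rmst_high},
                ]
            ).assign(
                tau=r.tau,
                difference=r.difference,
                logrank_chisq=res["logrank_chisq"],
                logrank_p=res["logrank_p"],
            )
            io_core.write_table(tab.set_index("arm"), out("survival.tsv"), index_label="arm")
            record(stage, {"survival": str(out("survival.tsv"))})

        if tpm is not None and "correlate" not in skip:
            stage = "correlate"
            anchor = tpm.loc[config.anchor_gene]
            partners = tpm.drop(index=config.anchor_gene)
            screen = screens.correlation_screen(
                anchor, partners, rho_cutoff=config.rho_cutoff, p_cutoff=config.p_cutoff, direction="positive"
            )
            io_core.write_table(screen, out("correlation_screen.tsv"), index_label="partner")
            files = {"screen": str(out("correlation_screen.tsv"))}
            if config.signature_path:
                sig = pd.read_csv(config.signature_path, sep="\t", index_col=0)
                fracs = screens.deconvolve_samples(tpm.reindex(sig.index).dropna(), sig)
                io_core.write_table(fracs, out("deconvolution.tsv"), index_label="sample_id")
                files["deconvolution"] = str(out("deconvolution.tsv"))
            record(stage, files)

        if (
            config.mirna_counts_path
            and config.mirna_fasta_path
            and config.utr_fasta_path
            and tpm is not None
            and surv_table is not None
            and "mirna" not in skip
        ):
            stage = "mirna"
            mirna_counts = pd.read_csv(config.mirna_counts_path, sep="\t", index_col=0)
            seqs = mirna.collapse_mature_duplicates(io_core.read_fasta(config.mirna_fasta_path))
            utr = next(iter(io_core.read_fasta(config.utr_fasta_path).values()))
            table, venn = mirna.triage_candidates(
                mirna_counts,
                tpm.loc[config.anchor_gene],
                utr,
                seqs,
                surv_table,
                rho_cutoff=config.rho_cutoff,
                p_cutoff=config.p_cutoff,
            )
            io_core.write_table(table, out("mirna_triage.tsv"), index_label="mirna")
            (out("mirna_venn.json")).write_text(json.dumps(venn, indent=2, sort_keys=True))
            record(stage, {"triage": str(out("mirna_triage.tsv")), "venn": str(out("mirna_venn.json"))})

        if config.image_paths and "wound" not in skip:
            stage = "wound"
            images = [iio.imread(p) for p in config.image_paths]
            meas = imaging.quantify_series(images, radius=config.entropy_radius)
            tab = pd.DataFrame(
                [
                    {
                        "timepoint": m.timepoint,
                        "threshold_bits": m.threshold_bits,
                        "area_px": m.area_px,
                        "open_wound_pct": m.open_wound_pct,
                    }
                    for m in meas
                ]
            ).set_index("timepoint")
            io_core.write_table(tab, out("wound.tsv"), index_label="timepoint")
            record(stage, {"wound": str(out("wound.tsv"))})
    except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
        raise StageError(stage, exc, manifest) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
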