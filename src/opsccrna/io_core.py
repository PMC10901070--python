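"""Readers and writers for the tabular/sequence formats the pipeline touches.

Formats: GMT gene-set files, gene x sample count tables (TSV) with a gene
length sidecar, survival tables (CSV), FASTA (via Biopython), and a flat
``key=value`` / YAML config. Gene identifiers are opaque case-sensitive
symbols; no aliasing is attempted. Floats in written tables are rendered
with 6 significant digits so repeated runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("opsccrna")

FLOAT_FMT = "%.6g"


class ParseError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class CountsMatrix:
    """Gene x sample integer count matrix with gene lengths and metadata.

    ``metadata`` is indexed by sample id and may carry group/batch labels and
    optional survival columns (``time_months``, ``event``); missing fields
    are NA. Survival consumers refuse samples lacking time/event rather than
    imputing.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    gene_lengths_bp: np.ndarray  # (n_genes,) positive ints
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths_bp = np.asarray(self.gene_lengths_bp)
        n_g, n_s = self.counts.shape
        if len(self.gene_ids) != n_g or len(self.sample_ids) != n_s:
            raise ValueError("counts shape does not match id lists")
        if len(set(self.gene_ids)) != n_g:
            raise ValueError("gene ids are not unique")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("sample ids are not unique")
        if self.counts.size and (
            np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            raise ValueError("counts must be non-negative integers")
        if len(self.gene_lengths_bp) != n_g:
            raise ValueError("gene_lengths_bp length mismatch")
        if np.any(self.gene_lengths_bp <= 0):
            raise ValueError("gene lengths must be positive")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            if set(self.metadata.index) != set(self.sample_ids) or self.metadata.index.has_duplicates:
                raise ValueError("metadata must cover every sample exactly once")
            self.metadata = self.metadata.loc[self.sample_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (the GMT content model)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time in months (> 0) and event flag (1 = death)."""

    data: pd.DataFrame  # columns: time_months, event; index: sample_id

    def __post_init__(self) -> None:
        d = self.data
        if not {"time_months", "event"} <= set(d.columns):
            raise ValueError("survival table needs time_months and event columns")
        if len(d) and (not np.all(np.isfinite(d["time_months"])) or np.any(d["time_months"] <= 0)):
            raise ValueError("survival times must be finite and positive")
        if len(d) and not d["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a duplicate set name or a line with fewer than three
    fields raises :class:`ParseError`.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            dropped = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dropped += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dropped:
                logger.warning("GMT set %s: dropped %d duplicate gene(s)", name, dropped)
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# counts


def read_counts_table(
    path: str | Path,
    lengths_path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> CountsMatrix:
    """Read a gene x sample TSV plus a ``gene<TAB>length_bp`` sidecar.

    Genes without a length entry are dropped (count logged). Non-integer or
    negative cells raise with the offending gene/sample named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0) | (arr.astype(float) % 1 != 0)
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: cell ({df.index[gi]}, {df.columns[si]}) = {arr[gi, si]!r} "
            "is not a non-negative integer"
        )
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    keep = [g for g in df.index if g in lengths.index]
    n_dropped = len(df.index) - len(keep)
    if not keep:
        raise ParseError(f"{path}: no gene has a length entry in {lengths_path}")
    if n_dropped:
        logger.warning("read_counts_table: %d gene(s) dropped (no length entry)", n_dropped)
    df = df.loc[keep]
    return CountsMatrix(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=df.to_numpy().astype(np.int64),
        gene_lengths_bp=lengths.loc[keep].to_numpy().astype(np.int64),
        metadata=metadata if metadata is not None else pd.DataFrame(),
    )


def write_counts_table(cm: CountsMatrix, path: str | Path, lengths_path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    pd.Series(cm.gene_lengths_bp, index=cm.gene_ids, name="length_bp").to_csv(
        lengths_path, sep="\t", index_label="gene_id"
    )


# ---------------------------------------------------------------------------
# survival


def read_survival_table(path: str | Path) -> SurvivalTable:
    """Read a CSV with columns sample_id, time_months, event.

    Rows with a missing time or event are excluded (count logged); a
    non-positive time or an event outside {0, 1} raises.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "time_months", "event"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    n0 = len(df)
    df = df.dropna(subset=["time_months", "event"])
    if n0 - len(df):
        logger.warning("read_survival_table: excluded %d row(s) with missing time/event", n0 - len(df))
    if (df["time_months"] <= 0).any():
        raise ParseError(f"{path}: non-positive survival time")
    if not df["event"].isin([0, 1]).all():
        raise ParseError(f"{path}: event values must be 0 or 1")
    df = df.set_index("sample_id")[["time_months", "event"]]
    df["event"] = df["event"].astype(int)
    return SurvivalTable(df)


def write_survival_table(table: SurvivalTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping (order preserved)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# config


DEFAULT_CONFIG = {
    "lfc_cutoff": 1.0,
    "fdr_cutoff": 0.05,
    "rho_cutoff": 0.4,
    "p_cutoff": 0.05,
    "nperm": 1000,
    "quantile": 0.75,
    "entropy_radius": 5,
    "seed": 20240228,
}


def read_config(path: str | Path) -> dict:
    """Read a YAML (or flat ``key=value``) config; unknown keys pass through."""
    text = Path(path).read_text()
    if "=" in text and ":" not in text:
        cfg = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            cfg[k.strip()] = yaml.safe_load(v.strip())
    else:
        cfg = yaml.safe_load(text) or {}
    out = dict(DEFAULT_CONFIG)
    out.update(cfg)
    return out


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a TSV with fixed 6-significant-digit float rendering."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index_label is not None, index_label=index_label)
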