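# opsccrna

Analysis toolkit for contrasting **HPV-negative vs HPV-positive
oropharyngeal squamous cell carcinoma (OPSCC)** bulk transcriptomes and
triaging candidate driver genes. The package re-implements, as tested and
reusable Python, a complete tumor-profiling workflow: HPV status calling
from viral oncogene reads, negative-binomial differential expression,
preranked gene-set enrichment analysis (GSEA), expression-binarized
survival analysis, immune-correlate screens, miRNA repressor triage, and
entropy/Otsu quantification of scratch (wound-healing) assays. A
first-class synthetic-data module generates every input class with known
ground truth, so the entire pipeline is exercised and scored end to end
without any external download.

Intended users: computational biologists analysing two-group bulk RNA-seq
tumor cohorts who want transparent, documented implementations of these
stages — and a planted-truth harness to validate them.

## Methods at a glance

- **HPV calling** — a sample is HPV-positive when E6 or E7 carries ≥ 500
  RNA-seq reads, or the eight oncogenes E1–E7/L1/L2 together do.
- **Expression** — TPM (`rate_g = c_g/(l_g/10³)`, scaled to 10⁶ per
  sample), median-of-ratios size factors, and a plain NB Wald test:
  per-gene dispersion α (Var = μ + αμ²) by method of moments,
  LFC = log₂ of normalized group means (+0.5 pseudocount), delta-method
  SE, normal p, Benjamini–Hochberg FDR; significant ⇔ |LFC| > 1 and
  FDR < 0.05. Batch designs are handled by per-batch estimation and
  inverse-variance pooling.
- **GSEA** — weighted running-sum ES (weight p = 1), gene-permutation
  null (1000 draws), NES = ES / mean |same-sign null ES|, +1 pseudo-count
  nominal p, pooled-null FDR, leading-edge extraction.
- **Survival** — Q3 (genes, TPM) or median (miRNAs, raw counts)
  binarization at the type-7 quantile, Kaplan–Meier product-limit curves,
  two-group log-rank, and RMST = ∫₀^τ Ŝ(t) dt with
  τ = smaller arm maximum.
- **Screens** — Spearman correlation (mid-ranks; t approximation, exact
  permutation for small n) with relevance at |ρ| > 0.4 and p < 0.05, and
  constrained least-squares immune deconvolution
  (min ‖S f − m‖², f ≥ 0, Σf ≤ 1) with an "other" remainder.
- **miRNA triage** — canonical seed sites (8mer > 7mer-m8 > 7mer-A1 >
  6mer, strict Watson–Crick on miRNA positions 2–8), then a three-step
  filter: negative correlation with the target, a seed site in its 3′UTR,
  and an inverse prognostic signature.
- **Wound imaging** — per-pixel Shannon entropy in a disk (radius 5 px),
  Otsu threshold on the entropy map, open-wound area A = pixels below
  threshold, and open-wound % = 100 · A_t / A_0.

## Worked example

Running the numbered drivers in `analysis/` regenerates the synthetic
cohort (23 HPV-negative vs 39 HPV-positive samples, a planted 50-gene set
at +2 log₂FC, a hub gene with three correlated partners driving survival)
and analyses it stage by stage:

```sh
cd analysis
python 01_simulate.py && python 04_gsea.py && python 05_survival.py
```

prints, among other things:

```
top set: PLANTED_SET (NES 2.67, FDR 0, leading edge 50 genes)

       n  events    RMST     tau  difference  logrank_chisq  logrank_p
low   46       9  15.866  18.099       2.487           5.25      0.022
high  16       6  13.379  18.099       2.487           5.25      0.022
high arm loses 2.5 RMST months vs low arm (tau 18.1)
```

i.e. the planted gene set is recovered as the top enrichment with FDR
below 0.05, and the hub-high quartile shows significantly worse survival
(log-rank p = 0.022) with a 2.5-month RMST deficit over the common
18-month window. `07_mirna_triage.py` recovers exactly the planted
repressor miRNA (ρ = −0.78, one 8mer site, inverted prognosis), and
`08_wound_assay.py` maps a planted wound trajectory of 0.4 → 0.2 → 0.1
area fractions to open-wound percentages 100 / 49.1 / 23.9.

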