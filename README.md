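# tscdyn

Transcriptome and CpG-island (CGI) methylation dynamics of trophoblast
stem cell (TSC) derivation time courses.

## The problem

Mouse TSC lines are derived from blastocysts over five stages — E3.5
trophectoderm (TE3.5), E4.5 trophectoderm (TE4.5), attached outgrowth,
first-passage TSCs (TSC_P1) and established lines (TSC_Pn) — under three
conditions: natural fertilization (NF), somatic cell nuclear transfer (NT)
and NT with the HDAC inhibitor Scriptaid (SNT). Cloned (NT) embryos derive
TSCs inefficiently, and the defects are visible both in the transcriptome
(key transcription factors fail to come up at outgrowth) and in the
methylome (CGIs stay aberrantly methylated, many inherited from the donor
cumulus cell genome). `tscdyn` implements the analysis stack for such a
study as a tested, reusable library:

* **Dynamic genes** — log2(RPM+1) normalization, selection of the genes in
  the top 5% of absolute PC1/PC2 loadings, Ward clustering of their stage
  trends into six groups labeled Pro / Down / Transient.
* **Panel pseudotime** — for a replicate with normalized expression
  Exp\_i over a panel of n transcription factors,

      T = Σ_i Exp_i · λ_i

  where λ is the PC1 loading vector of the panel genes from a PCA
  restricted to the NF samples; λ is reused unchanged for NT/SNT
  replicates. A resampling null re-derives λ for random same-size TF
  panels (default 5,000 draws) and reports the per-replicate mean.
* **CGI methylation dynamics** — CpG calls filtered at coverage > 4 in
  every replicate, CGI methylation as the unweighted mean CpG ratio over
  islands with > 4 detected CpGs per sample; differential CGIs at
  |Δratio| > 0.25 with two-sided Fisher p < 0.05 on pooled counts;
  PHIM-CGIs (progressively highly increased methylation; adjacent-stage
  jump > 0.25) grouped by K-means (k = 5) on the jump profile; AHM/ALM
  calls versus the NF counterpart stage; Scriptaid rescue accounting and
  donor-origin attribution (aberrant in cumulus cell vs MII oocyte);
  promoter CpG-density classes (HCP/ICP/LCP) and CGI–gene association
  within 5 kb of the TSS.
* **Enrichment statistics** — hypergeometric overlap test, representation
  factor RF = k/(n\_A·n\_B/N), over-representation score
  log2(RF)·(−log10 p), paired t with Holm adjustment, Benjamini–Hochberg.
* **Synthetic data** — a generator that plants all of the above structures
  (expression clusters, driver TFs, NT repression with SNT rescue,
  PHIM groups, donor-inherited/de novo/FGF4-driven aberrations) with truth
  tables, so every stage has a parameter-recovery test.

## Worked example

```python
from tscdyn.simulate import SimulationConfig, simulate_expression, driver_panel
from tscdyn import expression as ex, pseudotime as pt

cfg = SimulationConfig(seed=11)
matrix, truth = simulate_expression(cfg)
nf = matrix.subset_samples(s.sample_id for s in matrix.samples_where(condition="NF"))

lam = pt.compute_lambda(nf.norm, nf.samples, driver_panel(cfg))
T = pt.infer_pseudotime(nf.norm, driver_panel(cfg), lam)
d = pt.stage_ordering_diagnostics(T, nf.samples)
print(d.spearman, d.fully_separated)
```

prints

```
0.9819805060619657 True
```

the Spearman correlation of the 15 NF replicates' pseudotime with their
stage index (0.982 is the maximum attainable with three tied replicates
per stage; the stage-mean Spearman is exactly 1) and the fact that every
between-stage gap exceeds the within-stage spread — the panel resolves the
five derivation stages.

The full study narrative lives in `analysis/01...06`, thin drivers that
regenerate the same synthetic study from one seed and write their tables
to `results/`. Running `python analysis/05_aberrant_rescue_origin.py`
prints, per stage, lines such as

```
TE3.5: 646/807 NT AHM-CGIs corrected in SNT (80%); donor-inherited fraction 0.60
```

— of the 807 CGIs aberrantly highly methylated in NT TE3.5, 80% are no
longer aberrant under Scriptaid and 60% trace back to the donor genome,
matching the planted rescue and donor fractions.

A `tscdyn` command-line interface mirrors the library
(`tscdyn simulate|normalize|cluster-genes|deg|pseudotime|cgi|phim|aberrant|origin|enrich`);
all outputs are plain TSV/JSON and reruns with the same seed are
byte-identical.

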