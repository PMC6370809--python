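# lysoflux

A tested, reusable pipeline for asking whether a curated family of genes —
here, lysosomal/autophagic genes in adipose tissue — is *coordinately*
regulated, and which member sits at the hub of its co-expression network.
It re-implements the computational core of a bulk-transcriptomics study
design: two-group RNA-seq differential expression with explicit fold-change
and FDR gates, short-time-series profile clustering of a cytokine
(TNFα) stimulation course, gene-set overlap and z-score composites,
hypergeometric and GSEA enrichment, and a Pearson co-expression network with
k-core hub ranking. Every stage can be exercised end-to-end on synthetic
data with planted signal, so the whole analysis is testable without any
download.

Intended users: computational biologists who want the individual statistical
stages as a library, and analysts who want the config-driven `lysoflux`
command-line pipeline.

## The statistics at the core

* **Differential expression.** Counts are normalized by median-of-ratios
  size factors (s_j = median_g k_gj / (∏_j k_gj)^(1/n)); each gene gets a
  negative-binomial Wald test on the log fold change, with per-gene moment
  dispersion (Var = μ + αμ²) shrunk toward a log-linear mean–dispersion
  trend, and a t reference on n_A + n_B − 2 df. Genes are called up/down
  under gates such as FC > 1.2 or < 0.833 with BH FDR < 0.2 (human contrast)
  or FC > 2 or < 0.5 with p < 0.05 (time-course pre-filter).
* **Profile clustering.** For T ordered time points, all (2c+1)^(T−1) − 1
  non-flat unit-change templates are enumerated (26 for T = 4, c = 1); each
  gene's anchored series joins its nearest template (Euclidean distance),
  and a profile is significant when it captures more genes than a per-gene
  time-permutation null expects (one-sided binomial tail, BH-corrected).
* **Set statistics.** Venn-style intersections; per-sample mean z over a
  gene set compared between groups by Mann–Whitney U; one-sided
  hypergeometric term over-representation P(X ≥ k) with BH correction; and
  qPCR ΔΔCT relative quantification 2^(−ΔΔCT) against a reference gene and
  control group.
* **GSEA.** Signal-to-noise ranking, weighted running-sum enrichment score
  (hits add |metric|^p / N_R, misses subtract 1/(N − |S|)), phenotype- or
  gene-set-permutation null, sign-matched NES, add-one permutation p.
* **Co-expression hubs.** All gene pairs tested via t = r·√((n−2)/(1−r²)),
  BH across pairs, edges kept at FDR < 0.05; genes ranked by coreness (the
  largest k surviving iterative peeling of degree < k vertices), with
  correlation strength breaking ties.

## Worked example

Run the bundled synthetic end-to-end analysis (negative-binomial counts with
40 planted fold-change-2 genes in the "obese" group of a 10 vs 10 design, a
4-point TNFα-style time course with 120 genes planted into model profiles,
and a 12-gene co-expression module whose planted hub has the largest factor
loading):

```bash
lysoflux run --seed 1 --out demo/
```

prints

```
pipeline complete: 11 stages → demo/
  degs_total: 43
  degs_up: 40
  degs_down: 3
  overlap_common: 40
  zscore_mannwhitney_p: 0.00018267179110955002
  profiles_significant: 3
  gsea_focus_nes: 1.7235919485662334
  gsea_focus_p: 0.004975124378109453
  deg_sensitivity: 1.0
  deg_false_discoveries: 3
  profile_recovery: 0.9833333333333333
  hub_rank_of_true_hub: 1
```

Reading the funnel: 43 genes pass the FC/FDR gates (40 up, 3 down); all 40
planted genes are among them (`deg_sensitivity: 1.0`) with 3 false calls.
The 40-gene overlap with the focus set, the z-score composite shift
(Mann–Whitney p ≈ 2·10⁻⁴) and the positive GSEA enrichment (NES 1.72,
p ≈ 0.005) all point the same way — the planted set is coordinately up in
the "obese" group, mirroring how a real analysis would conclude coordinate
upregulation of a lysosomal/autophagic program. In the time course, 98% of
planted genes land back in their true profile; in the network, the planted
hub is ranked 1 by coreness/strength — the analogue of nominating CTSB as
the key regulatory gene. Each stage also writes a TSV under `demo/`, plus a
`manifest.json` whose per-file checksums are byte-identical across re-runs
with the same seed.

Individual stages are available as subcommands (`lysoflux diffexp`,
`profiles`, `overlap`, `zscore`, `enrich`, `ddct`, `gsea`, `coexpr`,
`simulate`) and as plain library functions:

```python
from lysoflux import enumerate_profiles
len(enumerate_profiles(n_timepoints=4, unit_change_bound=1))  # 26
```

## Layout

```
src/lysoflux/
  io_core.py       matrices, annotations, gene sets; TSV/GMT readers/writers
  synthetic.py     seeded generators with planted truth (counts, series, module)
  diffexp.py       normalization, NB Wald test, BH FDR, gate classification
  profiles.py      profile enumeration, assignment, permutation significance
  enrichment.py    overlap, z-score composite, hypergeometric terms, ΔΔCT
  gsea.py          ranking metrics, running-sum ES, permutation significance
  coexpression.py  correlation network, k-core decomposition, hub ranking
  pipeline.py      config-driven orchestration, manifest with checksums
  cli.py           click command-line interface
docs/methods.md    model assumptions, parameter defaults, limitations
```
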