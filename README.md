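# citegate

Antibody-gated CITE-seq analysis of CD8 T cells in coronary artery disease
(CAD), rebuilt as a tested, reusable Python pipeline and exercised end to
end on synthetic data with planted ground truth.

CITE-seq measures surface proteins (antibody-derived tags, ADT) and mRNA in
the same single cells. The analysis style implemented here identifies cell
populations the way a flow cytometrist would — by **thresholded surface
antibodies**, not by transcriptome clustering — and only then asks how gene
expression differs between CAD-high and CAD-low subjects (dichotomized by
angiographic Gensini score: > 30 high, < 6 low, intermediate excluded).

The pipeline stages, in order:

1. **Normalization** — ADT counts are centered-log-ratio (CLR) transformed
   per cell on the log2 scale: `clr(c,a) = log2(x+1) − mean_a' log2(x+1)`.
   RNA counts are log2-normalized per gene (each gene's counts scaled by the
   gene total to one million) with per-cell CPM as an alternative mode.
2. **Thresholding** — per antibody, a two-component normal mixture
   (ambient background vs positive population) is fitted to the CLR values
   by EM; the positivity threshold is the point `t` between the component
   means where the weighted densities cross, `π₁ φ(t; μ₁,σ₁) = π₂ φ(t; μ₂,σ₂)`
   (posterior probability 0.5). Antibodies with degenerate or ill-separated
   fits are flagged undetermined and excluded from clustering.
3. **Three-stage doublet removal** — (i) sample-tag demultiplexing
   (mixture thresholds per tag; ≥ 2 positive tags ⇒ multiplet), (ii)
   artificial-nearest-neighbor doublet scoring (fraction of synthetic
   doublets among each cell's k nearest neighbors in PC space), (iii)
   "biological doublet" removal: gated CD8 cells positive for ≥ 2 myeloid
   conflict markers (CD14/CD33/CD11c).
4. **Gating and clustering** — CD8 T cells are gated as
   CD19− CD14− CD16− CD3+ CD4− CD8+; cells are clustered on the CLR values
   of the selected (thresholded, expressed) antibodies only, via PCA (20
   components), a shared-nearest-neighbor graph and Louvain at resolution
   0.15, seed 42; clusters are named by gating rules (Naive: CD45RA+CCR7+,
   Em: CD45RO+CCR7−, Emra: CD45RA+CCR7−, MAIT: CD161+CD127+, …).
5. **Differential expression** — per gene, a two-sided Wilcoxon rank-sum
   test (exact enumeration for ≤ 12 cells per group, corrected normal
   approximation otherwise), Seurat-style `avg_log2FC`, expressing-cell
   fractions `pct.1`/`pct.2`, Bonferroni adjustment, and the standard
   filters (adjusted p < 0.05, log2FC > 0, optionally pct.1/pct.2 > 2.5);
   plus subject-level expressing-proportion rank tests.
6. **Importance** — a random-forest classifier with subject-grouped 3-fold
   cross-validated grid search; genes ranked by permutation importance
   (mean held-out score drop), scaled to 0–100.
7. **Enrichment** — one-sided Fisher exact over-representation of the
   up-regulated DE genes against GMT gene-set libraries, Bonferroni
   adjusted, with the tested panel as the universe.

The deposited cohort this design emulates is GEO accession **GSE190570**
(60 multiplexed subjects, 4 per plate, 49 antibodies, 496-gene targeted
panel). No download is needed: `citegate.simulate` generates experiments of
that shape with known thresholds, populations, doublets and effect genes,
so every stage can be scored against planted truth.

## Worked example

```bash
python analysis/01_simulate_experiment.py --seed 42   # writes results/fixture
python analysis/02_threshold_antibodies.py
python analysis/04_cluster_and_name.py
```

which prints (seed 42):

```
wrote 3789 cells (496 genes, 49 antibodies) to results/fixture
planted doublets: 189 (5.0% of cells)
...
thresholds determined: 49 / 49 antibodies
max |threshold - truth|: 0.182 CLR units (mean 0.061)
positivity-call accuracy on singlets: 100.00%
...
gated 2766 CD8 cells; clustered on 29 antibodies
6 clusters at resolution 0.15, seed 42; ARI vs planted populations 0.961
  cluster 0: n=758, named 'Naive'
  cluster 1: n=727, named 'Em'
  cluster 2: n=552, named 'Emra'
  cluster 3: n=369, named 'CD38+ Emra'
  cluster 4: n=342, named 'MAIT'
  cluster 5: n=18, named 'Naive'
```

Every fitted threshold lands within 0.25 CLR units of the planted one and
Louvain on thresholded antibodies reproduces the five planted CD8
phenotypes (the 18-cell sixth cluster consists of planted doublets — this
script deliberately clusters *before* doublet removal; the full pipeline
removes them first). The remaining scripts (`03_remove_doublets.py`,
`05_differential_expression.py`, `06_importance_and_enrichment.py`) score
doublet removal (tag-multiplet recall 100%, heterotypic ANN recall 100% at
a 5% flag rate), recover the ten planted CAD-effect genes by
Wilcoxon/Bonferroni (10/10, with 20 of 496 genes significant), rank all
ten planted discriminative genes inside the permutation-importance top 15,
and find the TCR-signaling (−log10 adjusted p = 15.8) and cytotoxicity
(4.6) gene sets enriched among the up-regulated genes — mirroring the
biological claim the pipeline was built to test.

The same flow is available as a library call
(`citegate.run_pipeline(PipelineConfig(...))`) or from the shell
(`citegate simulate`, `citegate run`).

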