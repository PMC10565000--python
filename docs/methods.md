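# Methods

This note documents the models, defaults and design choices behind
`citegate`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic experiment generator

The generator (`citegate.simulate`) emulates a multiplexed case/control
CITE-seq study: `n_subjects = 60` with `n_cases = 30` labeled CAD-high via
simulated Gensini scores (cases uniform on (31, 100), controls on (0, 5.9),
so the labeling rule — > 30 high, < 6 low — reproduces the design exactly),
assigned round-robin to plates of `subjects_per_plate = 4`, each subject
contributing `n_cells_per_subject = 60` cells by default (a desk-scale
default; the statistical benchmarks below state their own sizes).

**Populations.** Eight archetypes with frequencies summing to 1: five CD8
subsets (Naive 0.20, Em 0.20, Emra 0.15, CD38+ Emra 0.10, MAIT 0.10) plus
CD4 T 0.05, B 0.10 and myeloid 0.10 cells so that lineage gating and
biological-doublet removal are non-trivial. Each population is defined by
positive/negative surface markers (e.g. Emra: CD45RA+ CCR7− CD57+ KLRG1+)
and an expression profile over named panel genes (e.g. naive cells carry
TCF7/SELL/CCR7/LEF1; the CD38+ Emra subset carries the strongest
GZMB/PRF1/GNLY program). In addition, every population up-regulates a
disjoint random block of 30 otherwise-unremarkable panel genes (fold 2–6).
Real CD8 subsets differ across large portions of a targeted immune panel,
not just a handful of canonical markers; without these programs the
simulated transcriptome would carry almost no population structure and any
transcriptome-based method (doublet detection in particular) would be
starved of signal that real data does provide.

**RNA counts** are negative binomial (gamma–Poisson) with gene-level
dispersion 0.5 — the standard single-cell count model — over baseline means
drawn log-normally (median ≈ 0.4 counts/cell, clipped to [0.05, 20]).
Planted case/control effects multiply the mean by `2^effect` in case cells:
ten DE genes at log2FC = 1 (GZMB, PRF1, GNLY, ZAP70, CTSW, GNAI2, TCF7,
ITGB2, JUNB, KLRK1) and a disjoint set of ten discriminative genes at
log2FC = 1.5 for the classifier benchmark. Effect genes have their baseline
mean floored at 1 count/cell: an "effect" planted on a gene with
essentially no counts would be unmeasurable by construction and would
benchmark nothing.

**ADT counts.** Per antibody, log2 intensity is normal around
`log2(ambient_adt_mean)` (ambient mean 30 counts) for marker-negative cells
and shifted by `positive_adt_shift = 3.0` log2 units for marker-positive
cells, with SD `adt_log2_sd = 0.35`; counts are Poisson around `2^intensity`.
After CLR the two components are ≈ 6–7 component SDs apart — the
well-separated regime; a "hard" stress setting is obtained by passing
`positive_adt_shift ≈ 0.9` (≈ 2 SD). A small per-plate log2 offset
(SD 0.05) provides the batch covariate for the optional per-plate
centering. So that the CLR centering term is identical across populations,
marker-positive sets are padded to equal cardinality using filler
antibodies that no population claims explicitly; every antibody ends up
with a genuine positive population. The **planted threshold** for an
antibody is the midpoint of the empirical CLR means of its negative and
positive singlet cells — strictly between the component means by
construction.

**Sample tags.** Each singlet carries one dominant tag (Poisson mean 400)
over background (Poisson mean 1.5) on the 4 within-plate tags; the
(plate, tag) pair keys the subject assignment.

**Doublets.** A configurable fraction (default 5%) of cells are formed by
summing the raw RNA, ADT and tag counts of two freshly generated cells
from the same plate — summing, not averaging, conserves UMIs. Three
mechanisms: tag multiplets (two subjects, hence two dominant tags),
transcriptomic doublets (same subject, two distinct populations), and
biological doublets (a CD8 subset plus a myeloid cell). Every doublet's
mechanism and constituent populations are recorded in the ground truth.

## Thresholding

Two-component univariate normal mixture by EM: deterministic
initialization from the 25th/75th percentiles (no seed needed; optional
random restarts are off by default), SD floor `σ_min = 0.05` CLR units to
prevent variance collapse, convergence when the log-likelihood improves by
< 1e-8, with a per-iteration assertion that the likelihood never decreases.
The threshold is the posterior-0.5 crossing solved by bisection on
(μ₁, μ₂); if the weighted densities do not cross there (pathological
weight/SD imbalance) the midpoint is used with a warning. Fits whose means
are within one component SD of each other are ill-separated: the antibody
is undetermined, excluded from clustering, and a negative-reference
fallback (the 0.99 quantile of a known-negative cell type's CLR values)
can be configured per antibody. Cells exactly at a threshold are called
negative (strict inequality for positive). Where the original analysis
resolved ambiguous antibodies by manual ridgeline inspection, this
implementation substitutes the deterministic rule above and records full
fit diagnostics; a `manual` override per (antibody, context) is supported.

## Doublet removal

*Demultiplexing* applies the same mixture machinery to log2(tag count + 1);
exactly one positive tag ⇒ singlet, two or more ⇒ multiplet, none ⇒
undetermined. A tag whose threshold cannot be determined aborts
demultiplexing — without it subjects cannot be separated.

*Artificial-nearest-neighbor scoring* synthesizes artificial doublets by
**summing the raw counts of random cell pairs** and normalizing them
jointly with the real cells (log2 CPM), embeds everything with PCA (20
components), and scores each real cell by the fraction of artificial
doublets among its k nearest neighbors (k = 1% of cells, clipped to
[10, 100]); the top expected-rate fraction (default 5%) is flagged. Summing
raw counts makes the artificial doublets statistically exchangeable with
real doublets — same mixed profile, same inflated library size, same
sampling noise. The alternative of averaging already-normalized profiles
was evaluated and rejected: averaged log-profiles have half the noise
variance and no library-size excess, which in a ~500-gene panel places them
on a visibly smaller noise shell than real doublets (mean PC norm ~28 vs
~52 here), so real doublets never neighbor them and detection fails
outright. Homotypic doublets (two cells of one population) remain largely
undetectable by construction; heterotypic doublets are the detectable
class. The parameter-sweep heuristics of DoubletFinder are replaced by the
fixed settings above. Pair selection happens in a content-sorted index
space so scores are equivariant under permutations of cell order.

*Biological doublets*: among gated CD8 cells, any cell positive for ≥ 2 of
the configured myeloid conflict markers (default CD14, CD33, CD11c) is
removed and logged. Note an interaction with the full CD8 gate: planted
CD8×myeloid doublets are CD14-positive and are therefore already excluded
by the CD19− CD14− CD16− CD3+ CD4− CD8+ gate, so in the default end-to-end
run this stage is a safety net that typically removes nothing. The stage is
validated behind a reduced CD3+CD8+ gate, where it removes > 90% of planted
biological doublets; in real data, partial antigen masking can leave such
cells inside the full gate, which is why the stage is retained.

## Gating, clustering, naming

Gating uses strict `>` for required-positive and `≤` for required-negative
markers. Clustering operates **only** on the CLR values of the selected
antibodies: determined thresholds, not a gate negative for the context
(CD19, CD4, CD14, CD16 for CD8 cells), and ≥ 1% positive cells within the
gate. Pipeline: optional per-plate mean centering (a deliberately simple
stand-in for mixture-based batch integration, which is out of scope), PCA
to min(20, n_antibodies − 1) components, shared-nearest-neighbor graph
(k = 20, Jaccard edge weights), Louvain (igraph multilevel) at resolution
0.15 with the seed fed to the RNG igraph uses; clusters are relabeled by
decreasing size. The 2-D embedding is for visualization only and is never
used in statistics; it defaults to the first two PCs for speed and exact
reproducibility, with UMAP available by option.

Cluster naming applies ordered gating rules to per-cluster positivity
fractions (cutoff 0.5): MAIT before the memory rules (MAIT cells are also
CD45RO+ CCR7−), then CD38+ Emra, Naive, Emra, Em; unmatched clusters are
"unassigned". A cluster positive for both sides of a mutually exclusive
lineage pair (CD3/CD14, CD3/CD19, CD3/CD33, CD8/CD4) is flagged a likely
doublet cluster and excluded from downstream DE.

## Differential expression

Wilcoxon rank-sum, two-sided: for groups of ≤ 12 cells each the exact
permutation distribution of the midrank sum is computed by a
generating-function DP (doubled midranks are integers), with the two-sided
p defined symmetrically as `P(|W − E[W]| ≥ |w_obs − E[W]|)`; larger groups
use the normal approximation with tie and continuity corrections.
`avg_log2FC = log2(mean(2^v − 1) + 1) − log2(…)` (pseudocount 1, Seurat
convention), `pct1/pct2` are nonzero-count fractions, Bonferroni is applied
over the genes actually tested (detected in ≥ 1% of cells in either group —
the expression filter itself is configurable since the original rule is not
stated). Pooled case/control DE across cells accepts pseudoreplication by
design (matching the emulated analysis); the subject-level
expressing-proportion rank test is provided as the robustness companion.

## Importance and enrichment

The random-forest ranking uses cell-level classification with
subject-grouped 3-fold cross-validation — no subject contributes to both
training and validation, which is the leakage-safe reading of an
unspecified design. Grid search (default: trees {100, 300},
depth {∞, 10}, features/split {√p, 0.3p}) maximizes mean validation
accuracy; permutation importance is the mean held-out accuracy drop over
folds and 10 shuffles per gene, floored at 0 and scaled so the maximum is
100 (ties in rank broken by gene name). The default end-to-end pipeline
uses a reduced grid (trees {100, 300}, depth {10}), 3 shuffles and a
deterministic cap of 1000 cells for the RF stage so the full run stays in
the minutes range; the module defaults above apply when the ranking is run
on its own.

Enrichment is the one-sided Fisher exact (upper hypergeometric tail) of
the up-regulated DE genes against each GMT set intersected with the
universe, Bonferroni over sets tested, odds ratios with Haldane 0.5
correction. **The universe is the tested panel genes**, not the genome: on
a ~496-gene targeted panel a genome-wide background would inflate every
overlap into significance. Sets with < 2 universe genes are skipped. A
small curated library (TCR signaling, cytotoxicity, exhaustion,
naive/memory, MAIT, B, myeloid, plus decoy sets) ships with the package
for testing; any user GMT is accepted.

## What the benchmark shows — and what it does not

Passing tests demonstrate that each stage recovers what was planted under
the stated noise model: mixture thresholds within 0.25 CLR units and
positivity calls ≥ 98% accurate at ~6 SD separation; tag-multiplet recall
≥ 95% with ≤ 2% false multiplets; heterotypic doublet recall ≥ 0.6 with
≥ 5× enrichment; ARI ≥ 0.9 against the planted CD8 phenotypes; exact
agreement of the Wilcoxon and Fisher implementations with enumeration
oracles; ≥ 90% DE sensitivity at ≤ 5% false positives for log2FC = 1 with
~500 cells per group; and recovery of all planted discriminative genes in
the importance top 15. The generator does **not** model ambient-RNA
contamination, isotype/Fc background correlated across antibodies,
cell-cycle or activation continua, subject-level expression random effects,
or read-level artifacts; population separations are cleaner than in real
tissue. Results on real data will be noisier — in particular mixture
thresholds for weakly expressed antigens and homotypic doublets remain
genuinely hard and are not claimed.

## Numerical and reproducibility notes

All randomness flows through explicit seeds (numpy Generators; Python's
`random` for igraph). The EM is deterministic given the data; pipeline
reruns with the same configuration are bit-identical (verified on the CSV
outputs). Degenerate inputs are handled without crashing: all-zero ADT
panels give zero CLR rows, zero gene/cell totals give zero normalized
values, variance-free antibody distributions raise a fit error that
downgrades the antibody to undetermined, identical cells cluster as one,
and tied rank tests return p = 1.
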