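# Methods

## Model and scope

`cernet` implements the desk half of a ceRNA (competing endogenous RNA)
candidate-discovery study. The biological premise: lncRNAs carry miRNA
response elements and can titrate ("sponge") miRNAs away from their mRNA
targets, so a lncRNA whose expression shifts during disease progression
and which shares many miRNAs with shifted mRNAs is a candidate regulator.
The pipeline operationalizes this as (i) two-group differential
expression of mRNAs and lncRNAs, (ii) a tripartite lncRNA–miRNA–mRNA
graph built from curated interaction resources restricted to the DE
genes, and (iii) degree-based ranking of lncRNAs with per-lncRNA
subnetwork enrichment. It starts from a pre-summarized probe × sample
matrix: CEL-level processing (background correction, probe summarization)
is out of scope, as are live database/annotation retrieval and network
visualization (exports target Cytoscape instead).

## Preprocessing

* **Unexpressed-row filter** — keep rows with > `min_value` in at least
  `min_fraction` of samples; defaults (0, 1.0) remove rows that are ≤ 0
  everywhere. This is deliberately the weakest defensible reading of
  "remove zero-expression genes"; both knobs are exposed.
* **Quantile normalization** — the across-sample normalization step that
  array pipelines embed in RMA, applied at the level of data the package
  accepts. Every column receives the common distribution of mean order
  statistics; ties within a column get the mean of the target values their
  positions span, which makes the operation deterministic and idempotent.
  A single-column matrix passes through with a warning.
* **log2 transform** — `log2(x + offset)`, default offset 1; applying it
  to an already-log2 matrix is an error (double-log guard). The simulator
  emits linear-scale values, so the demo pipeline uses the same path as
  real data.
* **Probe collapse** — gene expression is the arithmetic mean of the
  gene's probes, per sample, computed before DE testing. The alternative
  (test probes, then aggregate statistics) was rejected because it leaves
  gene-level logFC undefined.

## Differential expression

logFC is mean(group_b) − mean(group_a) on the log2 scale. The unpaired
test is Welch's t (unequal variances, Welch–Satterthwaite df) — never
worse-calibrated than the pooled-variance t and robust to the unequal
group spreads typical of treatment-timepoint designs. A paired mode
(one-sample t on within-pair differences, pairing by column order within
group) is provided because diagnosis/day-8 samples may come from the same
patients; unpaired is the default since pairing metadata is often absent.
Zero-variance genes get t = 0, p = 1 rather than an error: a constant gene
carries no evidence. BH adjustment is the standard step-up procedure
(delegated to statsmodels behind `adjust_bh`); reporting thresholds are
strict inequalities |logFC| > 1 and q < 0.05 by default — note that 0.01
is also defensible for the FDR cut in this family of analyses, which is
why `fdr_max` is a named config key rather than a constant.

## Network construction

Edges are undirected; direction is recoverable from node types. After
unioning the lncRNA–miRNA and (validated-by-both-databases, DE-restricted)
miRNA–mRNA edge sets, the graph is pruned to a fixed point: a miRNA
without a neighbor on *both* sides cannot mediate competition and is
dropped, then newly isolated lncRNA/mRNA nodes are dropped, repeating
until stable. Without pruning, dangling miRNAs would inflate lncRNA
degrees. Hub ranking is by degree with lexicographic tie-break so runs are
byte-reproducible. A subnetwork for lncRNA L contains L, its miRNAs, the
mRNA targets of those miRNAs, and exactly the edges touching L's miRNAs;
consequently the union of all subnetworks recovers the parent edge set
(asserted on random instances in the tests). Expression-direction
consistency between lncRNA and mRNA is *not* enforced — the design has no
miRNA expression data to anchor the sign.

## Over-representation

One-sided hypergeometric upper tail (equivalently one-tailed Fisher's
exact), computed through the survival function for numerical stability,
BH-corrected across sets, default threshold q < 0.01. The universe
defaults to the mRNAs that survived the expression filter — the
conservative choice matching what was actually tested — and is
configurable. Rank-based (GSEA-style) scoring is out of scope.

## qPCR quantification

Replicates are averaged on the Ct scale (field convention), ΔCt is taken
against a same-sample reference gene, relative expression is 2^−ΔCt with
no efficiency correction (ΔCt, not ΔΔCt). A constant Ct shift applied to
every well of a sample cancels exactly. Group comparison dispatches on
group count: two → Welch's t, more → one-way ANOVA; the test name is
recorded in the output. An optional flag compares log2 relative expression
(i.e. −ΔCt) instead of the linear scale, which symmetrizes fold changes;
linear is the default.

## Synthetic data: what it emulates and what it does not

The simulator emulates the *structure* of the study inputs, with
Gaussian noise on the log2 scale (the simplest model consistent with
t-test assumptions): probe-level intensities where probes of a gene share
the gene's group mean; planted DE genes with a ±`effect_size` day-8 shift;
interaction tables where each planted hub lncRNA has exactly `hub_degree`
miRNA partners whose DE-mRNA targets are written to *both* target
databases (so hubs survive the validated-by-both rule by construction),
plus Bernoulli background pairs of which a fraction `db_overlap_frac`
lands in both databases; gene sets of which the planted ones draw ≥ 70% of
members from the DE mRNAs; and a triplicate Ct table whose case groups are
shifted by −logFC cycles. Background lncRNA–miRNA pairs exclude the hubs
so the planted degree is exact.

It does **not** emulate probe-level hybridization physics, batch or
spatial artifacts, heavy-tailed or intensity-dependent variance,
correlated genes, or realistic identifier nomenclature (symbols are
MRNA0001/LNC0001/MIR0001). Passing recovery tests therefore demonstrates
the pipeline's correctness and calibration under its own assumptions, not
performance on real arrays.

Reference conditions (the package defaults, chosen once): 2000 genes, 5%
lncRNA (the approximate lncRNA share of a filtered hgu133Plus2 array), 2
probes per gene, 20 samples per group, 180 DE mRNAs + 10 DE lncRNAs with
effect 2.0 log2-units and noise sd 0.5 (no variance estimates exist for
the motivating dataset; these make recovery comfortably attainable while
keeping nulls realistic), baseline log2 intensity 8, 60 miRNAs, 6 hubs of
degree 10 against a background interaction probability of 0.02 (background
degree expectation 1.2, so hubs exceed it five-fold), database overlap
0.3, 50 gene sets of 20–60 genes with 5 planted enriched. The qPCR cohort
defaults to 15 controls and three case subgroups of 9, 17 and 7 — the
shape of a small clinical validation panel.

## Calibration studies

`cernet.evaluate` scores the pipeline against the planted truth: over 50
simulated studies at the reference DE regime (10% planted effects), the
false-discovery proportion of the q < 0.05 discovery set stays below the
nominal level plus Monte-Carlo slack, and sensitivity of the full
reporting rule exceeds 95%. FDP is measured on the FDR rule alone because
adding the |logFC| > 1 filter drives it to ~0 and would make the check
vacuous. With nothing planted, p-values are KS-uniform and random-query
enrichment yields slightly under 5% of sets at p < 0.05 (the
hypergeometric null is discrete, hence conservative). Study sizes (1000 —
5000 genes, 20–50 seeds) keep the full suite under a minute while leaving
Monte-Carlo error well inside the asserted margins.

## Numerical and degenerate-input choices

* Derived per-replicate seeds are `(base·100003 + i) mod (2^31 − 1)`.
* All serialized floats use `%.6g`; reruns with the same config and seed
  are byte-identical (manifest timestamps and the log excepted).
* Empty DE lists abort the pipeline at the network stage with a named
  stage error; empty interaction tables and empty networks warn but
  serialize to valid (empty) documents.
* `adjust_bh` rejects p-values outside [0, 1]; `hypergeometric_test`
  rejects inconsistent (k, K, n, N).

## Known limitations

Moderated-variance (limma-style) testing, covariate adjustment, miRNA
expression integration, statistical ceRNA-pair tests (shared-miRNA
hypergeometric), and centrality measures beyond degree are deliberately
absent. Real miRcode/TargetScan/miRTarBase exports use inconsistent miRNA
nomenclature; the reader supports per-dialect column names and an
explicit alias map, but ships no mapping of its own.
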