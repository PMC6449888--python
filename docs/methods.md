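# Methods

## The statistical model of the funnel

### Paired differential expression

For gene g and patient i the analysis works on within-patient differences
D_gi = x_g(i, 12W) − x_g(i, 0W). For a balanced paired design this is
exactly equivalent to the patient-blocked linear model: the treatment
coefficient equals mean_i D_gi, and the blocked model's residual variance
is half the difference variance with the same residual degrees of freedom
(n − 1) and an identical t statistic. The difference formulation is used
because it is simpler to verify; the test suite checks the equivalence
against an explicit design-matrix least-squares fit.

Variance moderation assumes the gene variances follow a scaled inverse
chi-square prior, equivalently s²_g ~ s²₀·F(d, d₀) marginally. The prior
is fitted by the method of moments on log variances using the
digamma/trigamma identities

    E[log s²_g] = log s²₀ + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2)
    Var[log s²_g] = ψ′(d/2) + ψ′(d₀/2)

with ψ′ inverted by Newton iteration. When the observed spread of
log s² does not exceed the chi-square sampling floor ψ′(d/2), the prior
is degenerate: d₀ = ∞ and s²₀ is the geometric mean of the positive
variances (so that constant variances map to themselves). This is
slightly simpler than the bias-corrected variant some implementations
apply in that branch; the difference only affects the degenerate case.
The simulation-recovery test (50 000 genes drawn from the scaled-F model)
recovers (d₀, s²₀) within 10 %.

Posterior variances are s²_post = (d₀s²₀ + d·s²_g)/(d₀ + d); the
moderated t uses d₀ + d reference degrees of freedom (normal reference
when d₀ = ∞). Setting d₀ = 0 reproduces the ordinary paired t-test
exactly — this is asserted gene-by-gene against an independent
implementation. DEG calls use strict inequalities: BH-adjusted p < 0.05
AND |logFC| ≥ log2(1.55) (the fold-change bound itself is inclusive; the
1.55-fold threshold is interpreted on the log2 scale, both directions).
Because both conditions are combined by AND, the order of fold-change
filtering versus adjustment does not change the called set.

### Co-expression modules

Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^β with β = 6 by
default (a `pick_soft_threshold` operation chooses the smallest power on
a grid whose scale-free fit R² reaches 0.8, falling back to the
R²-maximizing power, then to β = 6 when the connectivity distribution is
degenerate). Topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

is computed by one matrix product; tests cross-check it against a naive
O(n³) triple loop and the uniform-adjacency closed form TOM_ij = a.

Modules come from average-linkage clustering of 1 − TOM with a **static
cut at absolute height 0.9** and the minimum module size of 30. The
initially considered cut at a fraction (0.995) of the maximum merge
height was implemented and measured first: it fails on block-structured
data because average linkage chains unrelated background genes into
module clusters just below the top of the tree (planted-partition ARI
0.1–0.7). An absolute cut exploits the boundedness of TOM dissimilarity:
genuinely co-expressed genes overlap topologically far above 0.1, while
unrelated pairs sit near 1. With the absolute cut the planted partition
is recovered at ARI 0.90–0.99 across seeds. The full dynamic-tree-cut
recursion of the reference WGCNA implementation remains out of scope;
the cut height is configurable (`cut_height`). Module merging by
eigengene similarity is available behind a flag but off by default.

Each module's eigengene is the first principal component of its
standardized (per-gene mean 0, SD 1) expression, scaled to unit variance,
with the sign oriented so that it correlates non-negatively with the
module's mean standardized profile — a deterministic resolution of the
PC sign ambiguity. Module–trait association is the Pearson correlation
of the eigengene with the trait codes (0W = 1, 12W = 2) and its two-sided
p from t = r√(n−2)/√(1−r²). Selected modules satisfy |r| > 0.5 and
p < 0.05 (strict); M_DEG = DEG ∩ genes of selected modules, with grey
(unassigned) genes excluded.

### Enrichment and pathway activity

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with the set size K computed inside the expressed-gene
background only. Raw p-values are reported deliberately unadjusted; the
subsequent trait-correlation filter is the false-positive control for
this stage. Filters are strict: K < 100, p < 0.1. Pathway activity
reuses the identical eigengene and trait-correlation procedures with the
stricter |r| > 0.7, p < 0.01; sets with fewer than two expressed genes
are recorded as unevaluable. GO_DEG = M_DEG ∩ genes of selected
pathways. The nesting GO_DEG ⊆ M_DEG ⊆ DEG ⊆ expressed is asserted at
run time on every funnel execution.

### QC, clustering and clinical utilities

Sample QC is a PCA on standardized genes with an outlier flag at 3× the
median distance to the score centroid. The separation score clusters
samples by average linkage on Euclidean distances of the standardized
(optionally gene-subset) matrix, cuts into two groups, and reports the
best-assignment fraction of samples whose group matches their timepoint
(0.5 ≈ chance for balanced designs, 1.0 = perfect separation). Percent
PASI decrease is 100·(PASI₀ − PASI₁₂)/PASI₀ rounded half-up to one
decimal to match clinical reporting; PASI75 means a decrease ≥ 75 %.

## The synthetic world

Gene-level log2 expression:

    x(g, i, t) = baseline_g + patient_i + loading·φ_{m(g), i}
                 + Δ_g·1[t = 12W] + ε_{g,i,t}

- `baseline_g ~ U(6, 12)` log2 units — typical microarray signal range.
- `patient_i ~ N(0, 0.2²)`, shared by all genes of a patient — a global
  patient offset.
- `φ_{m,i} ~ N(0, 1)` — one latent factor per (module, patient), weighted
  by `module_loading` (default 0.8), shared by the patient's two samples.
  This induces within-module correlation ≈ loading²/(loading² + noise²)
  across the 12 samples while cancelling out of the paired differences.
  An alternative with a fresh factor per sample was considered and
  rejected: it injects 2·loading² of variance into every paired
  difference of module genes, which no realistic paired design shows
  (real paired cohorts cluster by patient, not by draw) and which would
  make gene-level effects of ~1 log2 unit undetectable at n = 6.
- `Δ_g = treatment_effect` (default 1.0 log2) for every gene of the
  responsive modules (default 3 of 8 modules of 100 genes), 0 otherwise —
  true DE status is unambiguous and responsive genes ⊆ responsive
  modules by construction.
- `ε ~ N(0, 0.25²)` per gene × sample.

The probe layer expands each gene into 3 probes (fixed per-probe offsets
N(0, 0.25²), probe noise N(0, 0.1²), all on log2 scale, then
exponentiated) and adds an additive array background equal to the
per-sample mean of the simulated negative controls (log2 intensities
N(5, 0.5²)), so that the stated background subtraction removes it
exactly. Detection p-values are empirical exceedance: the fraction of
that sample's negative controls whose intensity strictly exceeds the
probe's.

Gene sets: 50 sets of 10–80 genes; 30 % are "true" sets drawing 80 % of
their members from responsive genes (`true_set_overlap`, configurable),
the rest are decoys sampled uniformly from non-responsive genes. With no
planted effect every set is a decoy.

### What the generator does **not** emulate

No scanner or spatial artifacts, no batch effects, no bead-level
replicate counts, no probe cross-hybridization, no heavy-tailed noise,
and module memberships are disjoint blocks rather than the overlapping,
hierarchical structure of real transcriptional programs. A green
recovery test therefore establishes that the pipeline's operations are
implemented correctly and behave as designed on data matching their
assumptions — not that the original study's gene lists would reproduce.

### A deliberate realism limit worth knowing

Quantile normalization forces every sample onto a common distribution.
When 15 % of genes carry a large planted shift (the default world at
effect sizes ≥ 2 log2), normalization redistributes part of that shift
onto null genes as spurious negative fold changes — a genuine
compositional property of the method, visible here because the synthetic
world's responsive fraction is far larger than in typical studies.
Recovery properties (sensitivity, FDR, module ARI, separation) are
therefore asserted on the gene-level simulation route, which corresponds
to where those quantities are defined; the probe-level route is covered
by round-trip, nesting and determinism tests.

## Numerical and convention choices

- Quantile normalization maps each column onto the cross-sample mean of
  order statistics; ties receive the mean of the reference values their
  positions span; an all-equal column maps to the global reference mean.
- Detection-group rule: a probe fails a timepoint group when p > α in
  **every** sample of the group (most conservative removal); a group-mean
  rule is available (`detection_group_rule: mean`).
- A gene counts as detected in a sample when any of its probes has
  detection p ≤ 0.05 there; the ≥3-samples filter uses these counts.
- Negative post-background intensities are floored at 1 before log2
  (offset 0), keeping the transform monotone.
- Zero-variance genes are permitted in differential expression
  (moderation gives s²_post > 0 whenever d₀s²₀ > 0; fully degenerate
  genes get t = ±∞, p = 0 and an explicit flag) but are dropped from
  eigengenes and excluded from network connectivity, with warnings.
- All thresholds are strict inequalities except the fold-change bound
  (|logFC| ≥ log2 fc); q = 0.05 exactly is **not** a DEG.
- Writers use 6-significant-digit formatting; identical seed and
  configuration give byte-identical output files.
- Seeds: the probe layer and the gene-set sampler use child streams of
  the main seed, so the gene-level matrix is reproducible on its own.

## Known limitations

- The static cut cannot split nested modules that merge below the cut
  height; strongly co-responding modules (shared large Δ) may fuse into
  one trait-correlated module. This does not affect the funnel's gene
  sets (the union of selected modules is what matters downstream).
- At n = 6 pairs the trait-correlation filters have limited power;
  modules whose activity shifts by less than ≈ 1 log2 unit routinely
  fail |r| > 0.5, and pathways below ≈ 1.4 fail |r| > 0.7. This mirrors
  the small-cohort design the pipeline targets.
- Occasionally (≈ 1 seed in 10 at effect 3.0) one patient's module
  factors are extreme enough that one of their samples lands in the
  wrong timepoint cluster — the same single-sample misclassification
  behaviour reported for real cohorts of this size.
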