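# Methods

## The model

The pipeline treats aortic gene expression as governed by a fixed regulatory
network whose *activation pattern*, not structure, changes between
conditions. Two working assumptions follow: (i) genes whose expression moves
always in the same, or always the opposite, direction across conditions are
tightly coupled, so the magnitude and sign of their marginal correlation is
the meaningful edge annotation; (ii) condition effects act on groups of
coupled genes (subnetworks) rather than isolated genes, so drug effects are
summarized per subnetwork.

### Responsive-gene selection

Per contrast (two experimental conditions), a gene is selected when a
two-sample t-test on log2 intensities gives p < 0.01 **and** the linear fold
change `2^(mean_a − mean_b)` is > 4 or < 0.25. Both gates are strict
inequalities (a fold change of exactly 4 is not "more than 4"). No
multiple-testing correction is applied at this step: the raw-p + fold-change
double gate is itself stringent, and the downstream network — not the gene
list — is the inferential object.

The default per-gene test pools the two group variances (Student t,
df = n₁ + n₂ − 2). With 3–4 replicates per condition, Welch's
unequal-variance test is noticeably conservative — its Satterthwaite df
estimate sits below the pooled df, which at n = 4 vs 4 depresses the
realized null rate of the p < 0.01 gate to ≈ 0.006–0.007 — while the pooled
test is exact under the homoscedastic noise model the simulator (and, to a
good approximation, normalized single-channel microarray data) follows.
`DEGConfig(test="welch")` switches to Welch for heteroscedastic data, and
`welch_t` is exposed directly with the conventions: both variances zero and
equal means → p = 1; both zero and unequal means → p = 0 (t = ±inf).

### Coupling and structure learning

Coupling is the Pearson correlation of log2 profiles across **all** samples
of all conditions pooled; constant-profile genes get zero coupling by
convention. Structure learning is greedy hill climbing over DAGs
(add / delete / reverse moves) maximizing the decomposable Gaussian BIC

    score(G) = Σ_v [ ll(v | parents(v)) − ½ (|parents(v)| + 2) log n ]

with the move space restricted to candidate pairs with |coupling| ≥ 0.6 and
in-degree capped at 3. The restriction makes the search tractable at ~10³
nodes and encodes the coupling semantics: an edge asserts strong marginal
co-regulation. Local scores are computed from covariance blocks (rank-one
Schur updates for candidate-parent sweeps), cycle checks use bitset
reachability, and score deltas live in a lazy priority queue; one search
over ~240 genes takes a few seconds. Ten restarts are run — the first from
the empty DAG, the rest from random DAGs drawn on the candidate skeleton
(random topological order, 20 % edge retention) — and the best-scoring DAG
is kept. Everything is deterministic given the seed: node order is sorted,
ties break by insertion order.

Edge sign and weight come from the **marginal** coupling (not regression
coefficients), because the edge annotation is meant to be read as
positive/negative correlation. Edge directions are a by-product of score
maximization and carry no causal claim.

### Subnetworks and activation

Subnetworks are Louvain communities of the learned network's undirected
|weight| skeleton. Two numerical choices matter:

- **Resolution 0.7** (not the conventional 1.0). A DAG with ≤ 3 parents per
  node is sparse (mean degree ≈ 5); at γ = 1 modularity over-partitions
  80-gene blocks of such graphs into 40–50-gene fragments. γ = 0.7 was
  calibrated once on the synthetic benchmark as the value that neither
  fragments planted modules nor merges distinct ones; it is exposed as a
  parameter.
- **Best of 5 seeded Louvain runs** by modularity, making the partition
  stable across seeds at negligible cost.

Communities smaller than `min_size` (default 20) are reported as
"unassigned" rather than as subnetworks. The partition is a function of the
network alone — never of layout coordinates.

A subnetwork's activation score under a contrast is the mean over member
genes of (mean log2 group A − mean log2 group B), read directly from the
expression matrix. Calls: induced if score > +0.5 log2, suppressed if
< −0.5, else unchanged (strict at the boundary). The 0.5 log2 default
(≈ 1.4-fold at the subnetwork mean) is configurable; published analyses of
this design report calls qualitatively only.

The 2-D "organic" layout (weighted Fruchterman–Reingold; attraction grows
with |coupling|) is presentation-only. Its extent is normalized, so only
relative distances are meaningful. A single node is placed at the origin.

### Enrichment

Per-term significance is the upper-tail hypergeometric probability of the
query/term overlap in a user-supplied universe (default: all genes on the
matrix), BH-adjusted across terms. Annotation clusters link terms whose
membership indicator vectors over the universe agree with Cohen's κ ≥ 0.5;
clusters are connected components of the link graph, scored by −log10
geometric-mean member p (equivalently the mean of −log10 p). The κ-linkage
and score follow DAVID's published definitions, but annotation databases
are version-dependent, so analyses against public GO releases will not
reproduce any particular published table row — only the machinery is fixed.

### Cohort statistics

`fisher_2x2` / `fisher_rx2` use the probability-mass two-sided convention:
p is the total probability of all tables with the observed margins whose
probability is ≤ the observed table's. All such probabilities share the
denominator C(N, C₁), so the comparison is done on exact integer numerators
(products of binomial coefficients) and the sum as an exact `Fraction` —
no floating-point tie tolerance, unlike implementations that need a
(1 + 1e-7) relief factor. The r×2 enumeration is guarded at N ≤ 200; larger
tables raise rather than silently switching to an approximation. Note that
mid-p or doubling conventions give different values; the probability-mass
convention is the one used by mainstream exact-test software.

Lesion length: a position along a segment counts as lesioned when its
diameter is ≥ 1.5× (inclusive) the segment's reference diameter; the
segment's lesion length is the summed width of lesioned sampling intervals,
and segments (arch, thoracic descending, suprarenal, infrarenal) are kept
separate because their reference calibres differ.

`group_compare` takes the parametric path (one-way ANOVA, then pairwise
pooled-variance t tests with Bonferroni) iff every group passes
D'Agostino–Pearson normality **and** Bartlett's variance test at α = 0.05;
otherwise Kruskal–Wallis followed by Dunn's rank-based z tests (tie-corrected,
Bonferroni-adjusted — the adjustment choice for Dunn is a convention, stated
here because it is not universal). D'Agostino–Pearson requires n ≥ 8; any
smaller group routes the whole comparison to the nonparametric path with a
note in the report.

## The synthetic-data generator

`SynthExprConfig` plants disjoint co-regulated modules: gene g in module m
has mean `baseline + effect_matrix[m][c]` in condition c and i.i.d. Gaussian
noise on the log2 scale. Defaults encode the study conditions: 2,000 genes,
three 80-gene modules, conditions (DMSO, BA, Rapa, BA+Rapa), 4 replicates
per condition, noise SD 0.4 log2 (typical replicate scatter for normalized
single-channel arrays), baseline 8 log2. The effect matrix is

| module | DMSO | BA | Rapa | BA+Rapa | reading |
|---|---|---|---|---|---|
| 1 | 0 | +3 | 0 | 0 | challenge-activated, normalized by rapamycin |
| 2 | 0 | +3 | 0 | +3 | challenge-activated, rapamycin-indifferent |
| 3 | 0 | +3 | +2 | +5 | challenge-activated, further activated by rapamycin |

Module 3's response to rapamycin alone is deliberate: it gives the three
modules distinct condition signatures. Without it, modules 2 and 3 share
the profile shape (0, 3, 0, x) and their planted cross-module correlation
at noise 0.4 reaches ≈ 0.94 — statistically near-collinear blocks that no
community detector can separate, which would say nothing about the
pipeline and everything about a degenerate simulation. Distinctness is the
realistic regime: real subnetworks that appear as separate clusters are
separable by construction.

What the generator does **not** emulate: probe-level effects, dye bias,
normalization artifacts, gene-specific variances (a multiplier is available
but off by default), correlated noise within modules beyond the shared mean
shift, and overlapping module membership. Passing tests therefore
demonstrate correct recovery under clean module structure, not robustness
to array-specific artifacts.

`SynthCohortConfig` draws per-group AD+ status as Bernoulli and, for AD+
animals, a lesion length from a Gamma distribution parameterized by the
group mean/SD (shape = (m/s)², scale = s²/m; a lesion is never below one
sampling interval). The lesion is laid down as a contiguous run at 1.6× the
reference diameter starting at a random position; healthy tissue jitters in
[0.92, 1.08]× capped at 1.45×, so AD− animals never cross the 1.5× call
threshold. Defaults encode a therapeutic-intervention design: groups of
27/10/13 animals with incidences 48.1 % / 100 % / 69.2 % and lesion
means 4.11 / 8.53 / 3.84 mm; the SDs (6.50 / 5.57 / 5.59 mm) are the
published SEMs scaled by √n. Segments are 10 mm at 0.1 mm sampling with
references 1.2 / 1.0 / 0.9 / 0.8 mm.

## Problem sizes and determinism

The test suite runs the full pipeline once at the native fixture size
(2,000 genes → ~240 selected; a few minutes) and all other tests on scaled
fixtures (~300 genes, seconds). The exact-test oracle sweep covers every
2×2 table with N ≤ 40 (~53,000 tables). A single global seed fans out to
per-stage seeds by hashing stage names, so adding a stage never perturbs
earlier stages' randomness; identical config + seed reproduces identical
output files checksum-for-checksum.

## Known limitations

- Edge directions from BIC hill climbing are not causal statements; only
  the skeleton + signs are interpreted.
- The coupling threshold (0.6) trades recall for tractability; weakly
  coupled regulation is invisible to the network stage by construction.
- The printed 1,221-gene selection of the motivating study is not a
  reproduction target: it depends on the unpublished per-gene test, probe
  filtering and the original arrays. Likewise published enrichment-table
  values depend on an annotation-database version.
- Freeman–Halton enumeration is exponential in groups; the N ≤ 200 guard
  keeps r = 3 designs instant but very large cohorts need a different test.
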