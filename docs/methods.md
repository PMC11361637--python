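# Methods

This note documents the models and procedures implemented in `mgregen`,
the defaults they run at, and the choices made where the design was open.

## The synthetic regeneration model

The simulator emulates the structure of a single-cell study of retinal
ganglion cell (RGC) regeneration: Müller glia (MG) activate after ablation,
pass through a progenitor (RPC) state, and differentiate into neurons.

**Trajectory.** Each cell carries a latent position `t ∈ [0,1]`. Control
cells draw `t ~ Uniform(0,1)`; ablated cells draw `t ~ Beta(1.5, 3)`,
piling up early where MG re-activate — reproducing the early-trajectory
enrichment of ablated samples seen in such experiments. States are assigned
by fixed thresholds: MG `[0, 0.33)`, progenitor `[0.33, 0.66)`, neuron
`[0.66, 1]` (three comparable compartments; real data gives no quantitative
state boundaries).

**Regulators.** TFs are assigned round-robin to three lineage modules (MG /
progenitor / neuron). Each TF's activity is a Gaussian bump over `t`; the
per-TF centers are spread evenly across the module's window (MG
0.02–0.31, progenitor 0.35–0.64, neuron 0.68–0.97, ±0.01 jitter) and the
per-TF widths are 0.7–1.15 × `activity_width` (default 0.13). Spreading the
centers matters: if module mates shared one center, their activities would
correlate at ≈0.98 and edge attribution would be ill-posed for *any*
inference method — regulators must be correlated but distinguishable for a
recovery benchmark to be meaningful.

**Drivers.** The first TF of each module is the module's fate driver,
modeled on the strong proneural activators that specify retinal lineages
(the ascl1a/atoh7 role): its edges are all activating with weights from the
upper half of the weight range, and it owns the module's largest regulon —
twice the per-TF target share in modules of ≥3 TFs, with its module mates
splitting the remainder so the network's total edge count is exactly
`n_tfs × targets_per_tf`. Both asymmetries are necessary for "the driver"
to be a well-defined recovery target: with exchangeable module TFs the
top-of-ranking position is a coin flip among mates, and because the
hypergeometric specificity score rewards larger regulons at equal
enrichment, a driver distinguished only by edge strength still loses to
mates whose retained sets are inflated by correlation-driven false edges.

**Counts.** A target gene's log-rate is `baseline + Σ sign·weight·activity`
over its incoming edges (baselines `N(0, 0.3)`); a TF transcript tracks its
own activity with amplitude 2. Rates are normalized per cell, scaled by a
log-normal library size (default mean 2500, σ 0.35), and counts drawn
negative-binomial with shared dispersion `r = 2` (variance `m + m²/r`) —
the common overdispersion model for UMI counts. Knockout zeroes the
knocked-out TF's activity and adds `ko_module_shift` (default +0.3) to the
neuron module's activities, biasing progenitor output toward the
RGC/neuron fate as TF knockouts of this kind do.

**Defaults** (the study conditions): 1000 cells per condition (so the
paired designs hold 2000 cells), 300 genes, 20 TFs, 10 targets per TF, 25%
repressive edges, weights U(0.8, 1.6). Sub-streams of one seed drive each
condition, so paired datasets share their network and differ only in
sampling.

**What the generator does not emulate.** Chromatin accessibility, doublets,
ambient RNA, batch effects, cell-cycle structure, branching lineages, and
secondary bystander cell death are all absent. Passing recovery tests shows
the methods work when their assumptions hold at realistic noise; it does
not certify performance on real retinas, where regulator activities are not
Gaussian bumps and marker sets are imperfect.

## Preprocessing

QC removes low-complexity cells first (fewer than 200 detected genes OR
fewer than 1000 total UMIs), then genes detected in fewer than 3 surviving
cells; the two-pass order is fixed and the operation is idempotent. The
UMI rule is read as "<1000", parallel to the detected-genes rule.
Normalization is `log1p(10⁴ · count / cell total)` (the toolkit default in
this field). Variable genes are ranked by a binned normalized dispersion:
variance z-scored within equal-frequency bins of mean expression (bins
capped so each holds ≥10 genes), ties broken by gene id.

Marker/DEG calling mirrors findMarkers semantics: log2 fold change of
pseudocounted (default 1) means of `expm1`(normalized) expression,
detection fractions, pre-filtering by |log2FC| and max-of-groups min.pct,
then a two-sided Wilcoxon rank-sum test — exact enumeration for tie-free
pooled samples of ≤25, otherwise the tie-corrected normal approximation.
Rows failing the α criterion are flagged, not dropped. Presets: condition
DEGs (log2FC > 0.2, raw p < 0.05), cell-type markers (log2FC > 0.5,
BH-adjusted p < 0.05), timepoint DEGs (log2FC > 0.25 ≡ FC > 1.18,
BH-adjusted p < 0.05), all at min.pct 0.05.

## Pseudotime and condition deltas

All conditions are embedded jointly (a common trajectory): PCA on the top
HVGs (30 PCs), a minimum-spanning path through cluster centroids walked
from the MG root, orthogonal projection of cells onto the piecewise-linear
path, then principal-curve refinement — the curve is re-estimated as a
running mean over cells ordered by current `t` (odd window, ~5% of cells)
and cells re-projected, until the mean assignment change is <1e-3 or 50
iterations. `t` is min-max scaled to [0,1] with the root at the low end.
Ties in `t` (cells clamped to a curve terminus) are ordered by cell id, so
the fit is invariant to cell order; the same clamping makes root-reversal
exact only in the curve interior (Spearman ρ ≈ −0.993 rather than −1 on
line-shaped data). This single-lineage principal-curve method is a
deliberate stand-in for general trajectory tools: the MG→RPC→neuron
topology here is one path, so nothing more is required.

Condition density along `t` is a Gaussian KDE per condition, renormalized
to integrate to 1 on [0,1]; the comparison output is the pointwise
log-ratio.

Delta profiles use 50 equal-width bins. Per condition, the bin profile is
a **count-weighted running mean**: window-pooled sums divided by
window-pooled cell counts (window = `smoothing_span × n_bins`, default 5
bins). Windows pooling fewer than `min_bin_cells` (default 5) cells carry
no usable evidence and are treated like empty bins — interpolated, with
endpoint values carried. This matters because the ablated `t` distribution
leaves ~1% of cells beyond `t ≈ 0.9`: an unweighted mean over 2–5 cells
has noise comparable to real effect sizes and would plant spurious profile
extrema of arbitrary sign in the tail. The per-gene delta (second minus
first condition) is scaled by its maximum |smoothed delta| so the extreme
bin is ±1 (flat genes are left at 0 with a recorded scale factor of 0).
Significance is a permutation test on the max-|delta| statistic over
condition labels (default 200 permutations; the evidence floor applies
identically to every permutation, so null p-values remain uniform). The
permutation test replaces a GAM-based per-bin differential test with a
statistic that is directly oracle-checkable. Profile shapes are grouped by
k-means on per-gene z-scored profiles (k = 11 by default, 10 restarts,
labels renumbered by descending cluster size).

## Signed network inference

For each gene, an extremely-randomized-trees regression (100 fully grown
trees, √(#TFs) candidate features per split — the GENIE3-published
configuration, chosen over bagged random forests for ~3× speed at equal or
better recovery) predicts its expression from all TF expressions; TF genes
are predicted from the other TFs. Importance is impurity reduction summed
over trees, normalized per target to sum to 1. Edges are then filtered in
three fixed steps:

1. **Pooled quantile.** The 95th percentile (linear interpolation between
   order statistics) is computed over *all* scored pairs pooled — matching
   the singular "the 95th quantile" convention — and pairs at or above it
   are kept. A per-target variant is not provided by default.
2. **Sign rule.** Pearson correlation on log-normalized expression over
   all cells, computed as `dot/√(ssₓ·ss_y)` on centered vectors (exact for
   integer fixtures); strictly `> 0.03` → positive, `< −0.03` → negative,
   anything else — including undefined correlations from zero-variance
   genes — discarded and counted in the run log.
3. **Progenitor expression.** TFs detected (count > 0) in fewer than 5% of
   progenitor-cluster cells lose all their edges, reusing the min.pct
   convention as the definition of "expressed".

Recovery is evaluated as area under precision–recall over TF→non-TF pairs
against the planted edges, reported alongside the planted-edge density
(the AUPR of a random ranking).

## Fate bias and TF specificity

Lineage tallies count significant progenitor DEGs inside each cell type's
marker set, split by direction (positive log2FC = higher in the knockout,
the fates the perturbation favors); a gene in several marker sets counts in
each. TF specificity is the upper-tail hypergeometric probability
`P(X ≥ k)` of the observed regulon/marker overlap, with population N = the
gene universe (default: all genes surviving QC), K = |marker set|,
n = |regulon ∩ universe|. The upper tail is the enrichment tail; no
multiplicity correction is applied by default (a BH switch exists). TFs
with no in-universe targets are reported with p = 1 and flagged rather
than dropped. Because the exact test is discrete, its null p-values are
superuniform (conservative), not uniform — the validity property tested is
`P(p ≤ α) ≤ α`.

## Screen statistics

Relative YFP is each ablated well's fluorescence divided by the mean of
its plate's unablated wild-type control wells (≥2 required per plate); no
cross-plate calibration beyond this is applied. The sample-size design is
the two-sample, two-sided normal approximation
`n = ⌈2(z₁₋α/₂ + z₁₋β)² / d²⌉` — at α 0.05, power 0.80 this gives n = 16
at d = 1.0 and n = 8 at d = 1.41, the screen's design point for a 30%
effect. The plate simulator's noise SD is `cv × control_mean` in *both*
arms: the assay noise floor is a property of the measurement (estimated
once from wild-type ablated larvae), not of each arm's mean, and the
default cv = 0.30/1.41 ≈ 0.213 is back-calculated from that design point
because the underlying SD is not published. Empirical power counts
rejections of the pooled-variance two-sample statistic against the
*normal* critical value — the same approximation the design formula uses —
which reproduces the designed 0.80 at (d = 1.41, n = 8) exactly (the exact
t reference would give 0.75, a mismatch of approximations, not of
implementations).

Each crispant's ablated wells are compared with the wild-type ablated
reference by a one-way ANOVA F (the two-group case, equivalent to a
two-sided pooled t). The per-gene p family is corrected by the
Benjamini–Krieger–Yekutieli two-stage sharpened step-up: stage 1 is BH at
`q' = q/(1+q)`, the true-null count is estimated as `m₀ = m − r₁`, stage 2
is BH at `q'·m/m₀`. The procedure returns decisions, so adjusted p-values
are defined by inversion: the smallest q on a 1e-4 grid at which the gene
is rejected. Hits are classified solely from adjusted p: significant at
≤ 0.01, trending in (0.01, 0.1], otherwise no effect; direction is
enhanced/inhibited by the gene's mean relative YFP against the reference
mean. The default simulated screen plants 7 inhibited and 11 enhanced
genes (±50% of the reference level, d ≈ 2.35) among 73 nulls at 16 wells
per gene, mirroring the hit structure such screens report.

## Problem sizes and verification

The test suite verifies exact operations against independent oracles
(exhaustive enumeration for the hypergeometric and rank-sum tests, hand
computation for the two-stage FDR plus a statsmodels cross-check,
order-statistics for the quantile filter) and the statistical pipeline
against the simulator's ground truth at the default scale: 2000-cell
paired datasets for pseudotime (Spearman ≥ 0.9), network recovery (AUPR
≥ 5× density; ~10× typical), sign annotation (≥90%; 100% typical) and
knockout-delta direction (≥90%; ~97% typical). Replicated checks use
reduced sizes chosen for tight feedback loops: the 10-seed driver-ranking
loop runs 30-tree ensembles (ranking is insensitive to ensemble size), the
null-calibration screens use 500–2000 replicates, and the planted-screen
sensitivity/FDR check uses 60 replicates. `scripts/acceptance.py` re-runs
the full stack at the default sizes in roughly five minutes on one core.

## Known limitations

- The trajectory method is single-lineage by design; branching topologies
  are out of scope.
- Principal-curve endpoints clamp out-of-range cells, so pseudotime is
  compressed at the termini and root-reversal is exact only in the
  interior.
- Adjusted BKY p-values are grid-quantized at 1e-4; decisions at any level
  coarser than the grid are exact.
- The hypergeometric specificity score treats the regulon as an unordered
  set; edge weights and signs do not enter the overlap test (signs are
  available for signed variants downstream).
- The plate model's constant assay SD and truncation at zero are
  idealizations; heteroscedastic plates would need a variance model the
  published design does not constrain.
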