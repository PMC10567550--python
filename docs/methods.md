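# Methods

`dediff` analyses a wound-healing dedifferentiation experiment of the
following design: differentiated Gata6-lineage (lin⁺) epidermal cells and
lineage-negative (lin⁻) cells are collected from unwounded skin (day 0) and
from wounds at days 6, 9 and 11, profiled by plate-based (Smart-seq2-style)
scRNA-seq in two batches per timepoint, and asked whether wounded lin⁺ cells
travel *backwards* along the normal differentiation trajectory. Two
independent biophysical branches quantify tissue stiffness from AFM
force–distance maps and actin-network architecture from binary masks.

## The synthetic study

Everything the pipeline consumes can be generated with planted ground truth.

**Latent coordinate.** Each cell carries a differentiation coordinate
z ∈ [0, 1]: z = 0 is the Lrig1-high stem-like state, z = 1 the Gata6-high
differentiated state. Unwounded lin⁺ cells sit at z = 0.8 + 0.2·Beta(2, 2).
lin⁻ cells are a 75/25 mixture of basal Beta(1.2, 4) and differentiated
Beta(6, 1.5) components — the differentiated tail is what makes the
"forward-differentiating" gate non-empty, as in real unwounded epidermis.
Wounded lin⁺ cells are shifted toward the stem state by
z ← z·exp(−r·max(0, t − 6)) with reversal rate r (default 0.4/day): day-6
wounds resemble day 0, day-9/11 wounds are strongly shifted. The 6-day lag
reflects the observed latency between wounding and transcriptional reversal.

**Counts.** Negative-binomial counts with mean
μ_gc = lib_c · exp(b_g + e_g·f_g(z_c) + w_g·[t_c > 0] + s_gB(c)) and a single
shared inverse-dispersion (default 2, Smart-seq2-scale overdispersion).
Program shapes f are monotone-up (z), monotone-down (1 − z) or a transient
bump exp(−(z − 0.5)²/2σ²), σ = 0.15. The default design plants five
compartment programs (uHF, SD up; IFE, OB down; SG transient; 160 genes
total, effect 5 natural-log units over a low baseline so markers are
switch-like: near-zero counts off, ~10² counts on), switch-like `Lrig1`
(down) and `Gata6` (up) single-gene markers, four wound-induced genes,
per-gene-per-batch log-normal shifts (sd 0.3) and log-normal library sizes.
Default sizes: 684 cells over 2 lineages × 4 timepoints × 2 batches, 800
genes. The cell count matches the study design; the gene count is scaled to
desk-scale runtime — program genes dominate variance exactly as marker genes
dominate a real HVG selection, which is the property the downstream stages
need. What the generator does *not* emulate: doublets, ambient RNA,
cell-cycle structure, and gene–gene correlation beyond the shared programs;
passing tests therefore validate the estimators' behaviour under planted
truth, not their robustness to those artefacts.

**Force curves.** Approach curves invert the spherical-indenter Hertz
relation F = 4E√R·δ^{3/2}/(3(1 − ν²)) with ν = 0.5, solving
δ + F(δ)/k = z − z₀ per sample so the cantilever's own bending (spring
constant k, default 0.25 N/m; tip radius 2.5 µm) is part of the forward
model. Gaussian noise is added on the force channel; deflection is stored in
volts via a sensitivity constant, as an instrument would.

**Fiber masks.** Straight 1-px segments rasterized into binary images; the
ground-truth length is the sum of Euclidean endpoint distances.

## Single-cell core

* **QC**: cells detecting < 200 genes are removed (strict boundary: 199
  removed, 200 kept).
* **Normalization**: size factor = cell total / median total;
  value = log(1 + count/sf). Natural log, pseudocount 1; the Lrig1 gate
  threshold (below) is interpreted in these units.
* **Batch correction**: parametric empirical-Bayes location/scale adjustment
  (ComBat): standardize per gene on the batch-design residual variance,
  estimate per-batch location γ̂ and scale δ̂², shrink via a normal prior on γ
  and a moment-matched inverse-gamma prior on δ², iterate the posterior
  fixed point to 1e-10, remove, and restore the grand mean/variance. The
  batch-size-weighted per-gene grand mean is restored exactly (vanilla
  ComBat preserves it only to O(1/n)). A single batch is returned unchanged.
* **HVG**: dispersion (var/mean) z-scored within 20 quantile bins of mean
  expression; deterministic, no fitting.
* **PCA**: genes centred/unit-scaled, optional per-gene least-squares
  residualization of a cell covariate first, full-SVD PCA (deterministic),
  default 15 components.
* **Clustering**: Gaussian-kernel KNN graph (local bandwidth = distance to
  the k-th neighbour, symmetrized by max), Louvain modularity communities
  with a resolution parameter (default 0.5), seeded; labels ordered by size.
* **Signature scores**: mean expression of the set minus mean of
  expression-bin-matched control genes (25 bins, 100 controls per gene,
  seeded) — the module-score scheme; it replaces reference-atlas anchor
  transfer, which needs an external atlas.
* **Wilcoxon DE**: genes kept when detected in ≥ min.pct (0.25) of either
  group and |lfc| ≥ 0.25, where lfc = log((mean₁+1)/(mean₂+1)) in expm1
  space; two-sided rank-sum p by exhaustive assignment enumeration when both
  groups ≤ 10, otherwise tie-corrected normal approximation with continuity
  correction; BH adjustment over tested genes only. Note the kept-then-test
  pattern (as in the Seurat convention) conditions the BH family on the lfc
  filter, so a handful of null genes with chance 2σ mean differences reach
  small adjusted p at n ≈ 30 — visible in the reversal scatter as on-diagonal
  points.

## Trajectory

The principal graph is a Euclidean minimum spanning tree over seeded k-means
centroids (default 20) in PC space. Pseudotime: geodesic node distance from
the root, with every cell projected onto its nearest tree edge and
interpolated between the edge's node distances; clipped at 0 and min–max
scaled to [0, 1]. The root is the node maximizing the mean
differentiated-compartment signature score (explicit override available), so
pseudotime *increases* toward the stem state on wounded data — recovery
checks use |Spearman|. The default pipeline additionally relaxes raw
pseudotime over the KNN graph (t ← (t + Pt)/2, twice) to suppress local
projection noise; this lifts planted-coordinate recovery from ≈0.92 to
≈0.96 |Spearman|.

The directed transition matrix damps each KNN edge by
exp(−max(0, t_i − t_j)/σ) and row-normalizes. σ defaults to the median
per-step neighbour spacing (neighbour-t spread divided by the number of
neighbour intervals): damping at the scale of one Markov step, which makes
forward mass dominate for ~99% of interior cells. Using the full
neighbourhood spread instead leaves forward/backward nearly balanced and is
deliberately not the default.

Gene trends are single-pass tricube local-linear fits on a fixed 100-point
pseudotime grid (span 0.3), vectorized across genes (each grid value is a
linear functional of y, so all genes share one weight vector); no
robustness iterations. Modules are Louvain communities of the gene–gene KNN
graph on z-scored trends.

## Reversal statistic

Populations are gated strictly: differentiating = lin⁻, day 0, Lrig1 < 1
(log-normalized units); dedifferentiating = lin⁺, day > 0, Lrig1 > 1; a cell
at exactly 1 joins neither. Within HVGs, Wilcoxon DE between the populations
(BH < 0.05; if fewer than 50 genes pass, the top 50 by raw p are retained so
the statistic stays defined on weak-signal data), per-gene medians in each
population, a loess curve (span 0.75, display only), and
R = Pearson correlation of the raw median pairs (Spearman reported
alongside). Strongly negative R means genes high in forward differentiation
are low in dedifferentiation and vice versa.

The permutation test shuffles population labels over the pooled cells and
recomputes the *full* statistic, gene retention included. The p-value is
one-sided in the reversal direction: p = (1 + #{R_perm ≤ R_obs})/(n_perm+1).
One-sided is the right calibration here because label shuffles produce
strongly *positive* R (the two pseudo-populations share per-gene baselines,
so their medians co-vary across genes); a two-sided |R| comparison would be
dominated by that baseline correlation and could not detect even a perfect
planted reversal. Under the null the one-sided p remains uniform.
Permutations for which the statistic is undefined count toward the tail
(conservative). Volcano flagging uses the linear fold change, strictly
greater than 1.6 (or below 1/1.6).

## AFM

Units are SI throughout; summaries report kPa. Per curve: the deflection
baseline is the median over the earliest 20% of the approach (pre-contact on
a proper ramp); the contact point z₀ minimizes the residual sum of squares
of the through-origin fit of F on δ^{3/2} (with δ = (z − z₀) − d), located by
a 60-point coarse scan plus golden-section refinement; "no contact" is
flagged when the fit explains < 50% of the force variance. The Hertz fit
itself uses only points with 20% ≤ F/Fmax ≤ 80% (inclusive) and converts the
slope m to E = 3m(1 − ν²)/(4√R). QC rejects no-contact curves, r² < 0.9 and
E above a configurable cap ("unphysically stiff", substrate artefacts).
Maps are (row, col) 0-based grids (default 24 × 24 over 40 × 40 µm) with an
exclusion mask (hair shaft); region comparison is a two-tailed Mann–Whitney
U (exact for n ≤ 8 per group, tie-corrected normal otherwise). The
instrument's own contact-point algorithm is unknown, so absolute moduli from
published figures are not comparison targets; the generator→fitter round
trip (≤ 1e-6 relative noiseless, median ≤ 5% at 1% force noise) is.

## Actin metrics

Total length: skeletonize, then sum adjacency steps — orthogonal pairs 1 px,
diagonal pairs √2 px, a diagonal counted only when its two pixels do not
already share an orthogonal skeleton neighbour (otherwise corners
double-count). This makes straight lines exact (101 px → 100 µm) and removes
the √2 staircase bias. Lacunarity: gliding r×r box at stride 1,
Λ(r) = var(mass)/mean(mass)² + 1, box sizes {2, 4, 8, 16} capped by the
image; Λ = 1 for homogeneous patterns and grows with gappiness. Reported
absolute values depend on the box-size set, which published macros do not
document, so only relative comparisons are meaningful.

## Orchestration and determinism

One global seed spawns per-stage seeds via `numpy.random.SeedSequence`;
every stochastic stage (generator, k-means, Louvain, permutations, controls
sampling) takes an explicit seed; PCA uses full SVD. Numeric outputs are
written with fixed float formatting, so identical config + seed reproduce
byte-identical files (verified by SHA-256 in the run report). Stage failures
halt the run with the stage name. In synthetic mode the pipeline generates
its own regulon table (one planted TF per program plus decoys), a 24 × 24
AFM grid (soft/stiff half-fields) and a fiber mask, then reads them back
through the same file interfaces used for real data.

## Known limitations

* The enrichment table's secondary filter (`effect_rank` > 0.9, a normalized
  odds-ratio rank) is a documented non-canonical stand-in for an undefined
  tool-specific score; treat it as configurable.
* The Wilcoxon exact path enumerates assignments only when both groups ≤ 10;
  mid-sized groups rely on the tie-corrected normal approximation.
* The principal graph is a single MST ordering; branching trajectories are
  represented but not separately modelled (no branch-specific pseudotime).
* Lacunarity and skeleton length are computed on given masks; segmentation
  quality is out of scope.
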