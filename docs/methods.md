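# Methods

This note documents the models and numerical choices behind each module:
what is computed, under which assumptions, which defaults matter, and what
the synthetic generators do and do not emulate.

## TaqI-3C quantification (`threec`)

TaqI-3C reads out the abundance of a proximity-ligation junction by qPCR
on four templates: ligated and digested-only crosslinked chromatin
(Lig3C, DO3C) and ligated and digested-only purified genomic DNA
(LiggDNA, DOgDNA). Every template carries a reference amplicon at a
TaqI-free locus (ARS504). The chain of corrections:

1. **Fold over reference**: `2^(Ct_ARS504 − Ct_target)` per template. The
   no-template-control (NTC) terms cancel algebraically but are retained
   for a below-detection warning (target Ct at or beyond the NTC Ct flags
   the replicate; the value is still returned, never silently clipped).
2. **Ligation-dependent signal**: `LDS = fold(Lig) / fold(DO)`, isolating
   ligation-specific product from primer-dimer and background amplification.
3. **Digestion-efficiency correction**: each branch's LDS is divided by the
   product of the two flanking sites' efficiencies, measured per branch as
   `eff = 1 − 2^−ΔΔCt` with `ΔΔCt = (CtR − CtARS504)_DO − (CtR −
   CtARS504)_UND`. This expression is the unique reading that yields 0 for
   an uncut site (DO ≡ UND) and → 1 for complete digestion. A ΔΔCt below
   −0.5 cycles (digested template apparently more abundant) is a
   data-quality error; efficiencies below 0.10 are errors, below 0.50
   warnings.
4. **Normalized frequency**: ratio of the corrected chromatin LDS to the
   corrected gDNA LDS.

Replicate handling: technical-replicate Cts are averaged per (template,
primer pair, biological replicate) before any exponentiation; frequencies
are then summarized across biological replicates as mean ± SD. The default
structure is 2 biological × 4 technical replicates.

The gDNA branch may be corrected either with its own measured
efficiencies (`gdna_efficiencies="measured"`, the default when UND-gDNA
rows are present) or with the chromatin values (`"chromatin"`); both are
exposed because the appropriate choice depends on whether the gDNA
control was digested in the same reaction.

## ΔΔCt expression (`expr`)

`ΔCt = Ct(target) − Ct(normalizer)` per condition; fold change
`2^−(ΔCt_cond − ΔCt_ref)`. The normalizer is a transcript whose abundance
is condition-independent (SCR1, a Pol III transcript, in the heat-shock
setting). Technical replicates are averaged on the Ct scale *before*
exponentiation (configurable in principle, but averaging cycle thresholds
is the variance-stabilized choice for a quantity that is exponential in
Ct); ΔΔCt is computed within each biological replicate and summarized as
mean ± SD. Fold-change matrices from expression tables use replicate-mean
ratios; genes with a zero denominator are excluded and flagged rather
than propagated as infinities.

## Double-mutant-cycle epistasis (`epistasis`)

Two mutations act independently on expression when their log fold changes
add: `E[log2FC(double)] = log2FC(m1) + log2FC(m2)`. The deviation
`ε = observed − expected` is computed per gene (replicates collapsed to
means first; genes with nonpositive expression are excluded with a flag),
and a two-tailed paired t-test across genes asks whether observed and
expected are distinguishable. Verdict "independent" when p ≥ α (default
0.05). Log base 2 is used throughout (the base cancels in the test).
Degenerate zero-variance ε vectors return p = 1 (ε ≡ 0) or p = 0
(constant nonzero ε) with an explicit flag instead of NaN. At least three
genes are required. The test is calibrated: under the additive null with
10% replicate noise, 42 genes, and 2 replicates, the measured type-I
error at α = 0.05 sits near nominal (the acceptance script reports it),
and the per-gene noise biases cancel exactly in ε because wild-type,
single-mutant, and double-mutant log means enter with coefficients
(+1, −1, −1, +1).

## 3D focus detection (`foci`)

The detector follows the staged scheme of saddle-aware local-maxima
segmentation (as popularized by the FindFoci ImageJ plugin), with the
parameterization used for yeast nuclear confocal stacks:

1. Background `B = mean + k·SD` of intensities inside the nuclear ROI
   (default k = 1).
2. Seeds: plateau-collapsed local maxima strictly above B under the
   chosen connectivity (default 26; a flat plateau yields one seed at its
   lexicographically smallest (z, y, x) coordinate).
3. Supra-background voxels are partitioned among seeds by descending
   watershed flooding; saddle voxels join the higher peak.
4. A sub-peak merges into its neighbor across the highest connecting
   saddle unless `(peak − saddle) ≥ merge_fraction · (peak − B)` (default
   0.2). Merging is applied lowest peak first until stable, so raising
   the merge fraction can only reduce the focus count.
5. Each surviving region is cut at `B + search_fraction · (peak − B)`
   (default 0.3) and regions smaller than `min_size` (default 1 voxel)
   are discarded. The reported centroid is the background-subtracted
   intensity-weighted mean of the region.

All thresholds are relative to the in-ROI mean and SD, so detection is
exactly invariant (voxel-identical regions) under positive affine
intensity transforms; centroids agree to floating-point precision.
Internal plugin orderings differ across FindFoci versions; the staged
order above is fixed here and validated against hand-enumerable oracles
on tiny arrays rather than bitwise plugin equivalence.

Colocalization matches channel-A foci to channel-B foci greedily by
nearest centroid (each B focus usable once), with z distances scaled by
the physical z-step-to-xy-pixel ratio; the default match radius is 2
xy-pixel units. Per-cell statistics report the mean focus count and the
percentage of cells with more than a threshold number of foci (default
threshold 2, the convention for scoring condensate-positive cells).

## Clustering and fitness (`report`)

- **PCA**: input matrices are log2(x+1)-transformed and gene-centered by
  default, matching common practice for normalized expression.
- **k-means elbow**: k-means is run for k = 1..k_max with 10 restarts per
  k. The elbow is the k maximizing the second difference of **log**
  within-cluster SS. Working on relative drops makes the rule invariant
  to data scale and robust to elongated cluster geometries: on
  near-collinear three-cluster data the raw-SS curvature peaks at k = 2
  even at 10σ separation, while the log-scale curvature correctly peaks
  at k = 3. A second-difference rule cannot express k = 1, so when even
  the first relative drop (W1 − W2)/W1 is below 0.25 the data are treated
  as unclustered; the 0.25 gate separates the ~order-of-magnitude drops of
  genuinely clustered fixtures from the few-percent drops of a single
  high-dimensional blob.
- **Hierarchical clustering**: samples are clustered on a
  `1 − Spearman ρ` distance (rank ties by average rank; distances lie in
  [0, 2]) with average linkage. Constant samples have undefined ρ and are
  dropped with a flag.
- **Growth fitness**: integrated growth is the trapezoidal area of
  OD(t) − OD(0). Subtracting the initial OD makes the integral insensitive
  to inoculum density while keeping it sensitive to lag-phase length;
  relative fitness is the replicate-mean AUC ratio against the designated
  wild type.

## Synthetic data (`synth`)

Generators exist so that every stage can be verified against known ground
truth; their defaults encode the experimental design they emulate.

- **qPCR model**: ideal doubling per cycle — a template at relative
  amount `a` crosses threshold at `Ct = ct_ref − log2(a)` — matching the
  base-2 exponentials of the quantification formulas; amplification-
  efficiency deviations are out of scope. Gaussian noise on the Ct scale,
  default SD 0.15 cycles (typical technical qPCR scatter). NTC wells sit
  at the instrument ceiling (Ct 40); amounts below the implied detection
  floor clip to it. Replicates default to 2 biological × 4 technical.
  The 3C generator inverts the full quantification chain (junction
  amounts set so that `LDS_3C = F · e1·e2 · LDS_gDNA / (e1g·e2g)`) and
  emits the digestion-check amplicons for both branches, so a noiseless
  table quantifies back to truth to ≤1e-9 relative error, digestion
  correction included. gDNA digestion efficiencies default to the
  chromatin values (the sites are the same sequence).
- **Expression matrices**: WT/m1/m2/double samples with effects additive
  in log2 plus an interaction term γ, under mean-preserving multiplicative
  lognormal noise of a given coefficient of variation. The 42-gene default
  matches the size of the HSR regulon scored in such studies.
- **Image stacks**: 8 z-planes (0.25 µm steps) of a nuclear ellipsoid at
  a flat background with planted 3D Gaussian foci (default σ 1.5 voxels,
  amplitudes 10–16 shot-noise SDs). The rendered image emulates
  *post-deconvolution* data: Poisson shot noise is drawn, and its residual
  is smoothed (σ 1.3) to stand in for the noise suppression of
  Richardson–Lucy deconvolution while the underlying scene stays sharp.
  Smoothing the whole image instead would darken the mask edge and
  corrupt the in-ROI background statistics; leaving raw shot noise would
  make the mean+1SD background threshold fire on noise maxima that real
  deconvolved images do not show. The truth sampler places foci inside a
  morphologically eroded mask (clipped regions bias the intensity-weighted
  centroid) with a minimum pairwise separation of 4σ. The generator does
  **not** emulate PSF anisotropy, chromatic shifts, cell-to-cell
  background variation, or out-of-focus light, so passing detection tests
  certify the algorithm, not robustness to those artifacts.
- **Growth curves**: lagged logistic OD(t) with optional Gaussian reading
  noise; defaults (inoculum 0.15 A600, capacity 1.5, rate 0.35 h⁻¹, lag
  2 h, 30-min readings over 48 h) mirror a plate-reader growth assay.

All generators are bit-reproducible under their seed.

## Problem sizes

Monte-Carlo checks use the sizes the corresponding claims are stated at:
100 noiseless + 500 noisy 3C round trips, 1000 null + 200 interaction
epistasis simulations, 200 planted-focus stacks plus 50 affine-invariance
images, and 50 three-cluster elbow fixtures. These complete in well under
a minute each on a single CPU.

## Known limitations

- The 3C quantifier assumes one junction primer pair per locus pair and a
  shared ARS504 reference per template; multi-junction designs need one
  table per junction set.
- The epistasis test treats genes as exchangeable pairing units; strong
  inter-gene correlation (co-regulation) would make the paired t-test
  anticonservative. Under the independent-noise generator it is
  calibrated; on real regulon data the p-value should be read with that
  caveat.
- The focus detector operates per nucleus on a provided ROI mask; it does
  not segment cells or nuclei and does not track foci over time.
- Elbow-based model selection is a heuristic; the 0.25 first-drop gate is
  a package choice, configurable at the call site via `k_max` and
  documented rather than asserted as universal.
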