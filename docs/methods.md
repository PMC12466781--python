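# Methods

This note documents the models and procedures `somacount` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show about
real cleared-brain data.

## Segmentation and voxel correction

Cells are segmented by binarizing at an intensity threshold *t* (voxels with
intensity ≥ *t* are foreground) and labelling 3D connected components.
Connectivity defaults to 26 (full 3D neighbourhood) and is configurable to 6
or 18; 26 is the most permissive choice and errs toward keeping a
noise-bridged soma as one object rather than splitting it. Component
centroids are the unweighted means of member voxel indices, reported as
0-based (z, y, x) coordinates of the segmented grid. Components touching the
volume border are kept.

When a volume was downsampled f×f in-plane before segmentation (block mean,
partial border blocks truncated so plane dimensions floor-divide by f), a
component of *n* voxels represents *n·f²* voxels at acquisition resolution.
Cell volumes in μm³ are therefore `n·f² · vx·vy·vz` with the *original*
acquisition voxel size (default 0.946 × 0.946 × 2.5 μm). The acquisition
voxel size is deliberately never rescaled on downsampled volumes; the f²
correction carries the bookkeeping instead, which keeps the printed gate
values interpretable.

Segmentation thresholds are expressed on the intensity scale of the
processed volume. No attempt is made to map thresholds from any external
tool's internal scale.

## Threshold selection

Practitioners choose one segmentation threshold per animal by visual
inspection of QC regions. As an automatic, deterministic surrogate,
`select_threshold` evaluates the total gated cell count C(t) in the QC
regions over an ascending threshold list and picks the threshold t_i that
minimizes the forward relative step |C(t_{i+1}) − C(t_i)| / C(t_i) — the
start of the flattest plateau of the count-vs-threshold curve, where the
result is least sensitive to the exact cutoff. Ties break toward the
smaller threshold (more sensitive segmentation); a manual override always
wins; all-zero QC counts are an error that demands an override rather than a
silent guess.

## Volume gates and illumination merge

Detections are kept iff `min(region) ≤ corrected voxels ≤ max`, bounds
inclusive. Defaults: minimum 20 corrected voxels, maximum 4000, with
per-region minima (e.g. 12) available for regions whose somata are genuinely
small, such as the medial habenula. The gates operate on *corrected*
(acquisition-scale) voxel counts; whether published gate values refer to
pre- or post-correction voxels is ambiguous in general, so the gate spec is
explicit config and the alternative reading is a one-line change.

Because one light-sheet illumination side dims with depth into the tissue,
each brain is recorded from both sides and the per-subregion cell count is
the **maximum** of the left and right counts. A subregion observed on only
one side keeps that side's count. The merge is idempotent and commutative.

## Region hierarchy and composite pooling

The atlas is consumed as an integer labelmap co-registered to the segmented
grid (registration itself is out of scope). A detection's region is the
labelmap value at its centroid rounded half-up per axis; background
(id 0) detections are excluded from counts but tallied in the run manifest —
no record is dropped silently.

Subregion counts are pooled into composite regions — the unit of statistical
comparison — primarily via an explicit `{composite: [subregions]}` JSON
(auditable, reproducible), falling back to the region tree's parent edges.
Composites whose total count over all reference-genotype animals falls below
a floor (default 25) are merged into a same-major-region sibling:
iteratively, the most deficient composite is absorbed by the sibling with
the smallest reference total (ties by id), until all composites meet the
floor; a deficient composite with no sibling is flagged excluded. The floor
is interpreted against the reference-genotype *group* total, not per animal,
since a single fixed composite map must serve all animals. Major-region
counts are sums over composites; major-region volume summaries are
*unweighted* means of per-composite means per animal.

## Negative-binomial genotype contrasts

Per composite region, counts are modelled NB2 with a log link:
E[y] = μ_g, Var[y] = μ + μ²/θ (one θ per region model; larger θ means less
overdispersion, θ → ∞ is Poisson). The design is reference-coded genotype
indicators, so exp(intercept) is the reference-group mean and each contrast
coefficient exponentiates to a rate ratio. Fitting alternates IRLS for the
coefficients at fixed θ with a bounded profile-likelihood maximization of
log θ until the joint log-likelihood changes by < 1e-8 (≤ 100 outer
iterations). For indicator designs the fitted group means equal the sample
group means exactly, independent of θ — a property the tests verify against
a brute-force likelihood grid and against an external MLE implementation.
θ estimates above 1e7 are flagged as the Poisson limit and inference falls
back to Poisson weights; a group with all-zero counts is flagged
`separated`, given a −∞ sentinel coefficient, and excluded from downstream
tables with an explicit exclusion record.

**Small-sample inference.** Wald statistics are referred to a *t*
distribution with n − p residual degrees of freedom rather than the
asymptotic normal, and CIs use the matching t quantile. With ~8 animals per
genotype, plug-in estimation of θ makes normal-quantile tail p-values
anticonservative enough to matter after multiplicity adjustment (in null
simulations with 108 regions, z-based BH at 0.01 produced a rejection in
~15% of replicates; t-based, ~0%), and t-based 95% CIs cover the true rate
ratio at ~94% versus ~91% for z-based. The cost is conservatism: power
against a true halving of counts at baseline mean 50, θ = 5, 8 + 8 animals
is ~0.55 (z-based would be ~0.69) — at these sample sizes a rate-ratio
halving is simply not reliably detectable at α = 0.01, whatever the
reference distribution.

P-values are Benjamini–Hochberg adjusted across regions within one contrast
family (the standard reading of "FDR adjustment"; families can be split per
config, e.g. when one genotype was acquired under different optimal
thresholds and must be compared to the reference separately). Adjusted
p-values are reported as log worth = −log₁₀(FDR p); significance is
FDR p ≤ 0.01 ⇔ log worth ≥ 2, and the volcano table carries the reference
lines (rate ratio 1, log worth 2) as plot metadata.

## Mixed model on cell volumes

To verify that segmented soma volumes are comparable across genotypes,
per-animal major-region mean cell volumes are log₁₀-transformed and fit with
fixed effects genotype + major region + genotype×region and a random
intercept per animal (within-animal correlation across regions). The
interaction — "does the genotype effect on soma volume differ by region?" —
is assessed by a likelihood-ratio test of ML fits with and without the
interaction. The raw chi-square reference is anticonservative at realistic
animal counts (mean null p ≈ 0.45 instead of 0.5), so the p-value uses the
monotone F transform of the likelihood ratio, F = (e^{LRT/N} − 1)(N − p)/q
referred to F(q, N − p) — exact for fixed-variance linear models and, in
null simulations at 10 animals × 8 regions, indistinguishable from uniform
(mean p 0.498, KS D 0.039 over 200 replicates). Degenerate zero-residual
designs are decided by exact OLS residuals (perfect additive fit ⇒ p = 1).

## Clustering and efficiency summaries

Two-way hierarchical clustering of the animal × region count matrix uses
Ward linkage, rows and columns clustered independently; the input transform
(none vs log1p) is a config switch because counts span orders of magnitude
across regions. Merge heights are non-decreasing and the implementation is
checked against exhaustive Lance–Williams agglomeration on small instances.

Co-labeling efficiency (reporter⁺marker⁺ / marker⁺ per slice) is averaged
over slices within animal, then summarized across animals per region:
mean, Tukey box statistics (linear-interpolation quartiles, whiskers at the
extreme data values inside the 1.5·IQR fences, outliers beyond them), and a
four-bin class with left-closed bins [0, 0.10), [0.10, 0.50), [0.50, 0.75),
[0.75, 1.0]. The first bin is read as "<10%": a bottom bin is the only
reading consistent with the three higher bins partitioning the rest of the
range. Records with zero marker cells carry no ratio information and are
excluded with a log entry.

## Synthetic data: what it emulates, what it does not

The generator renders somata as isotropic Gaussian blobs truncated at 3σ,
with σ = radius / √(2 ln 2) so the half-peak isosurface sits exactly at the
nominal radius — giving an analytic ground-truth voxel count (the digital
ball of that radius) for any half-peak threshold. Illumination attenuation
multiplies each blob's peak by exp(−d/decay_length) with d the distance from
the left or right x face, matching the dimming of the side distal to the
light sheet; vessels are random bright cylinders that exist solely to
exercise the volume gates. Noise is Gaussian or Poisson–Gaussian. Count
tables are drawn from the gamma–Poisson mixture, giving exactly the NB2
variance μ + μ²/θ.

Default study conditions used in tests and the acceptance script: baseline
composite mean 50 cells, dispersion θ = 5, 8 animals per genotype, 108
regions for multiplicity studies, rate ratio 0.5 for effect-recovery
studies; end-to-end recovery uses 5 regions × 25–50 cells on a 64×96×96
grid with peaks 800–1200 on background 100 and, in the noisy variant,
Gaussian sd of 10% of the nominal peak. Intensity statistics of real somata
vs background are not published for this modality at this resolution, so
the rendering defaults are free parameters chosen to be comfortably
segmentable, not claims about real data.

Not emulated: refraction, stripe artifacts, tile shading, PSF anisotropy,
registration error between image and labelmap, and anatomically realistic
region shapes (regions are cuboids). Passing the synthetic tests therefore
demonstrates the *pipeline arithmetic* — segmentation, gating, merging,
pooling, inference — is correct under known ground truth; it does not
validate threshold choice or gate values for any particular real dataset,
which remain study-specific QC decisions.

## Other numerical choices

- Stitching is translation-only at nominal tile origins with optional
  integer-shift refinement by normalized cross-correlation in the overlap;
  overlap blending is voxelwise maximum, avoiding seam dimming that would
  bias threshold-based segmentation. Refined shifts larger than the search
  radius are distrusted and replaced by the nominal placement (warning).
- Denoising offers `none`, Gaussian, and median filters. A learned denoiser
  would need paired training data and is out of scope; the classical filters
  are adequate for the synthetic noise models used in testing.
- All generators, the pipeline, and the statistics are deterministic given
  (config, seed); per-side and per-stage RNG streams are derived from the
  master seed.
- Demo and test problem sizes (≤ 96³ grids, ≤ 200 simulation replicates)
  were chosen so the full suite runs in a few minutes on one CPU while
  keeping Monte-Carlo standard errors well inside the asserted bounds.

## Known limitations

- The rate-ratio power analysis above: genotype effects smaller than ~2×
  are unlikely to reach FDR p ≤ 0.01 with 8 animals per group at θ = 5.
- The automatic plateau rule for threshold selection is a surrogate for
  expert visual QC, not a validated replacement.
- The composite sibling-merge fallback is deterministic but heuristic; the
  explicit composite-definition JSON is the recommended path.
- Out-of-atlas detections are excluded from counts (with manifest
  accounting); brains whose labelmap registration is poor will silently
  shift counts between neighbouring regions — a data problem the pipeline
  can only surface via QC tables, not fix.
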