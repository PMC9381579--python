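# Methods

This note documents the models behind each analysis layer, the defaults
and why they were chosen, what the synthetic benchmarks emulate (and what
they deliberately do not), and the numerical decisions that affect
results.

## Morphometry

**Model.** A junction-stained epithelial monolayer is treated as a planar
partition: bright anti-junction signal along cell borders, dark interiors.
Segmentation is deterministic: grayscale maximum filter (radius
`max_filter_radius_px`, default 2 px) closes gaps in the staining;
Gaussian smoothing (`gaussian_sigma_px`, default 2 px) suppresses
speckle; Otsu thresholding binarises (a fixed threshold is available for
calibrated acquisitions). Cell interiors are the connected components of
the inverted mask (4-connectivity by default, so diagonally touching
interiors remain distinct); every junction pixel is then assigned to the
nearest interior by Euclidean distance (influence zones computed from the
distance transform), making label ownership a total function — the sum of
label areas always equals the number of assigned pixels, exactly.
Post-filtering fills enclosed holes, dilates labels by 1 px without
overwriting neighbours, removes labels touching any image border (their
shape is censored by the field of view) and labels below
`min_cell_area_px` (default 50 px, debris). These defaults are
conservative values that recover the generator's ground truth on
noise-free images; all are exposed in `MorphometryConfig`.

**Shape descriptors.**
- *Area*: raw pixel count. Optional µm² conversion via `pixel_size_um`;
  pixel size is a parameter, never assumed.
- *Perimeter*: Crofton 4-direction estimator (the standard estimator in
  the morphometry plugins this pipeline mirrors; swappable in principle
  since the convexity ratio is what matters downstream).
- *Convexity*: convex perimeter / perimeter, where the convex perimeter
  defaults to the polygon length of the convex hull of boundary-pixel
  centres (`hull_polygon`). A matched-estimator variant (`crofton_hull`,
  Crofton perimeter of the filled hull image) is available; both stay
  within 5 % of the continuous value on cells ≥ 20 px across. Values may
  slightly exceed 1 on digitised convex shapes; this discretisation
  allowance is bounded by 0.05 in practice.
- *Geodesic diameter*: longest within-cell shortest path under chamfer
  weights 1 (axial) and √2 (diagonal) on the 8-connected pixel graph
  (`unit_8conn` gives unweighted steps instead). Computed by
  farthest-point propagation: one sweep from the centre of the maximal
  inscribed disk, a second sweep from the farthest pixel found (the
  classic double sweep), then an iterative-fringe refinement — pixels are
  processed in decreasing centre distance and swept from until twice the
  remaining centre distance cannot exceed the current bound, at which
  point the bound is provably the maximum. The refinement matters: the
  plain double sweep underestimates some shapes (thick spirals, near-tied
  diameters in convex cells) by up to a few pixels. Exactness is defined
  against a Dijkstra all-pairs oracle under the same weights, not against
  continuous geometry; the chamfer metric itself overestimates Euclidean
  length by up to ~8 % depending on direction.

A single-pixel label has geodesic diameter 0 and undefined convexity; it
is flagged `excluded` rather than dropped, and excluded records are
omitted (and counted) by the distribution summariser.

**Group comparison.** Distributions are summarised per group (histogram,
median, IQR, CV) and compared with the Kruskal–Wallis rank test plus an
epsilon-squared effect size. Cells are pooled across replicate
images/differentiations by default; per-replicate averaging is a caller
choice (pass per-replicate records). Note the omnibus test detects
location shifts; the spread (IQR) comparison is reported separately
because dysmorphic monolayers mainly widen the shape distribution.

## Synthetic epithelium

Seeds are placed uniformly at random, relaxed by `lloyd_iterations`
centroidal (Lloyd) steps toward a regular honeycomb, then displaced by
Gaussian jitter of SD `jitter_sigma_px`. Relaxation and jitter are
deliberately orthogonal controls: regularity first, irregularity second.
The Voronoi tessellation of the final seeds, clipped to the foreground
rectangle, is both the truth (exact shapely polygons with area,
perimeter, hull perimeter, convexity, diameter) and the image source: a
junction band of width `junction_width_px` (default 3 px) is drawn where
the two nearest seeds are near-equidistant, interiors are dark
(intensity 0.12 vs 0.95), then Gaussian blur (default 1 px) and additive
Gaussian noise (default SD 0.02) are applied and the field is quantised
to 16-bit. Identical specs (seed included) are bit-identical. Seeds
closer than twice the junction width after jitter trigger a bounded
retry, then an error.

Edge contact (`touches_margin`) is defined at pixel level on the interior
the measurement sees (owned pixels outside the band): continuous-geometry
contact can disagree with rasterised contact for corner slivers narrower
than the band.

**What this emulates, and what it does not.** The generator reproduces
the statistical structure the morphometry pipeline assumes — a bright
connected junction network, dark interiors, tunable shape irregularity —
so truth-recovery tests validate segmentation, partition and measurement
logic. It does **not** produce non-convex cells (Voronoi cells of any
seed configuration are convex), staining dropouts, intensity gradients,
out-of-focus regions or multi-layered tissue. Consequently, passing
truth-recovery says nothing about robustness to broken junction staining,
and the convexity signal between regular and jittered groups comes from
cell-size/elongation variety interacting with discretisation, not from
genuinely concave outlines; its median shift is small even when the IQR
ratio is large (~1.7 between jitter 0 and 8 px at the default geometry).

## Differential-expression selection

The DE statistics themselves (normalisation, dispersion estimation,
testing) are an upstream tool's job and are consumed as input. The layer
implemented here is the selection logic: expression floor, fold-change/
significance filter, z-scoring, clustering, cluster selection.

- TPM floor: ≥ 5 (inclusive) in at least one sample, or in at least one
  group mean — both readings occur in practice and `tpm_mode` selects
  one; per-sample is the default.
- DEG filter: |log₂FC| ≥ 1 (inclusive — "fold change of 2" includes 2)
  and FDR < 0.05 (strict) or p < 0.05, per `alpha_column`. Organoid-stage
  analyses conventionally use the raw p column; the epithelium stage uses
  FDR.
- z-profiles: group means of log₂(TPM+1) (pseudo-count 1), standardised
  across groups with the population SD, so a 2-group profile is exactly
  (−1, +1). Genes constant across groups carry no pattern and are
  dropped with a log message.
- Clustering: agglomerative Ward linkage on Euclidean distances between
  z-profiles, cut into exactly K clusters. K defaults to 15 and is a
  display-resolution choice, not an inference; the selection rule below
  is insensitive to moderate K changes because it operates on centroids.
  Rows are sorted by gene id before linkage so the partition (as a set of
  sets) is invariant to input order; with continuous z values ties in
  merge heights are measure-zero.
- Selection: cluster selected iff its centroid satisfies
  |z(affected) − z(g)| ≥ δ for every control-like group g, δ = 1 by
  default. This formalises the manual "pick the clusters where only the
  affected line moves" step; it is monotone in δ (larger δ, fewer genes)
  and is an explicit rule, not a claim about how any particular manual
  selection was made.

**Synthetic tables.** Per-gene baseline means are log-normal
(`baseline_log_mean` 5.5, `baseline_log_sd` 1.5, natural log — median
~250 counts); planted gene sets receive per-group log₂ offsets; replicate
counts are negative-binomial with dispersion 0.05 (biological CV ~22 %,
typical of isogenic cell-line triplicates). `dispersion=0` is defined as
the noiseless limit (counts = rounded means) so closed-form checks are
exact. Genes have unit length, so TPM is counts rescaled to 10⁶ per
sample — gene length never enters any downstream filter. The stand-in DE
statistics use the empirical log₂ ratio of group-mean TPM (pseudo-count
0.5) and a moderated t-test on log₂(TPM+1): per-gene pooled variances are
squeezed toward a prior fitted by trigamma moment matching, and the
moderated t uses residual-plus-prior degrees of freedom. An unmoderated
two-sample test is structurally inadequate at n = 3 per group — its
p-values floor near 10⁻³, which cannot clear a genome-wide BH cutoff —
whereas variance sharing across genes is exactly what real small-n
RNA-seq testing relies on; with it, planted-pattern recovery through the
full filter→cluster→select pipeline exceeds 99 % and null tables select
≲ 0.1 % of genes. One realistic artefact is retained deliberately:
planting 300 genes up 8-fold inflates the affected samples' library
sizes, so null genes acquire a small negative log₂FC (compositional
bias, as in real un-TMM-normalised TPM), and a minority of them pass the
filters; they do not affect planted-gene recovery.

## Splice-event selection

Events are parsed from the rMATS JC dialect with type-specific coordinate
columns (0-based starts, 1-based ends, preserved verbatim), per-replicate
junction-count vectors and comma-separated PSI lists with `NA` for
missing. Event identity across comparisons is the full coordinate tuple
plus type, chromosome, strand and gene id — strict coordinate matching,
no re-anchoring.

Filters (conjunction): max per-sample inclusion+skipping count ≥ 2
(inclusive), FDR < 0.05 (strict), |ΔPSI| > 0.10 (strict, matching "more
than 10 %"), and mean PSI ≥ 0.10 in at least one group (inclusive — the
event is actually included somewhere; the alternative "both groups within
[0.1, 0.9]" reading is available as `psi_mode="both_within"`). An
optional host-gene TPM ≥ 5 floor (group-mean) serves organoid-style
analyses and requires an expression table. Events with an all-missing PSI
group are dropped and counted. Tightening any threshold never grows the
selection, and the filter equals the brute-force conjunction of its
predicates by construction — tests assert this on every fixture,
including rows placed exactly on each boundary.

Mutation-specific logic: intersection of the per-comparison significant
sets minus the union of the exclusion sets — `(A ∩ B) \ C` for the
three-comparison design; a two-comparison intersection (no exclusion)
covers the isogenic-pair design. Duplicate event keys collapse with a
logged warning; the result is invariant to row order.

**Synthetic tables.** Every comparison shares one event catalogue
(otherwise cross-comparison set logic would be vacuous). Junction depths
are Poisson (`mean_junction_depth`, default 60) + 1, inclusion reads
binomial around the group PSI, p-values from a two-proportion z-test on
summed counts, BH-adjusted per comparison — the pipeline consumes p/FDR
columns and never re-derives the upstream likelihood. PSIs are rounded
to 3 decimals *before* the inclusion-level difference is computed, so the
record invariant |ILD − (mean PSI₁ − mean PSI₂)| ≤ 10⁻⁶ survives a text
round-trip. At the default depth, a null event has ΔPSI noise SD ≈ 0.05,
so ~2–3 % of null events clear |ΔPSI| > 0.10 by chance — real tables
behave the same way, and the demo keeps this. The truth-recovery
benchmark, whose assertion is *exact* equality between the filtered
intersection and the planted flags, instead uses `mean_junction_depth`
300, where a chance pass is a ~4σ event; exact recovery is a property of
that deep-coverage regime, not of the method at arbitrary noise.

## Assay quantification

All maps are pure closed forms, vectorised, and validated against scalar
recomputation on randomised fixtures:

- TER: (raw − blank) Ω × membrane area cm² → Ω·cm². Sub-blank wells give
  negative values returned as-is with a warning — the sign is
  information, not an error.
- Phagocytosis: internalised = quenched/DAPI, bound =
  (total − quenched)/DAPI; pre-clamping, internalised + bound =
  total/DAPI identically. Quench noise can push bound below 0; it is
  clamped at 0 with a warning by default.
- Western: ratio = target/loading; fold = ratio / reference-group mean
  ratio (arithmetic mean of replicate ratios — the geometric mean is a
  defensible alternative the implementation does not use; folds of
  near-zero references error out).
- Marker fraction: 100 × marker / DAPI, with marker ≤ DAPI enforced.
- ONL density: count / region area, in the caller's area unit.
- qPCR: ΔCt = Ct(target) − Ct(housekeeping); fold over reference
  = 2^−(ΔCt − ΔCt_ref). Base-2 amplification is assumed (no efficiency
  correction — the ΔCt method as commonly practised).
- Group tests: Kruskal–Wallis with Dunn's post-hoc (rank z-comparisons
  with tie correction, Holm-adjusted; implemented here because no
  installed dependency provides Dunn's test) or one-way ANOVA with
  Tukey's HSD; groups need n ≥ 3; mean ± SD reported per group.

## Pipeline

One `RunConfig` drives the DAG synthetic → {morphometry, deg, splice,
assay}; each stage draws its seed from the global seed by mixing in the
stage name (multiplier + CRC32, reduced mod 2³¹−1), so stages are
statistically independent but the run is reproducible file-for-file —
the manifest records a config hash (paths and log level excluded),
per-stage seeds and row counts. A failed stage aborts with the stage
name, keeping completed outputs. Demo sizes (512² image with 150 cells,
5,000-gene table with 300 planted, 3 × 2,000-event splice tables, 9
replicates per assay group) complete in a few seconds on one CPU; the
full verification script is sized to run in about a minute.

## Known limitations

- Truth convexity is degenerate (always 1): the generator cannot plant
  concave cells, so convexity fidelity is validated by deviation from 1
  and by spread differences, not by rank correlation against truth.
- Chamfer (1, √2) geodesic lengths are exact against the graph oracle
  but biased against continuous geometry; per-cell ranks of measured vs
  true diameters correlate at ρ ≈ 0.96, limited by this anisotropy and
  by junction-band erosion of the measured interiors.
- The moderated-t stand-in emulates the power profile of a real DE fit
  but not its count model; absolute p-values are not comparable to
  edgeR's, only their genome-wide behaviour is.
- The manual cluster-selection step of real analyses is replaced by the
  centroid-margin rule; agreement with any particular hand selection is
  out of scope.
- rMATS parsing covers the JC dialect actually consumed (header-name
  lookup, so column order is free); JCEC files and novel-splice-site
  annotation columns are not modelled.
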