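# Methods

`cortexmx` re-implements, as a tested pipeline, the quantitative analysis
of iterative multiplexed immunofluorescence (MxIF) of cortical fields: a
400-µm-wide region of interest (ROI) running from the pial surface
through the cortical depth and 100 µm into the white matter (WM), imaged
for a 28-marker panel, with one DAPI-segmented object per cell and mean
intensities in three compartments (Nucleus; Cell = nucleus + 2-µm
expansion; Cytoplasm = Cell − Nucleus).  Because no raw data accompany
the study design this package emulates, a first-class synthetic
generator produces cell tables, layer boundaries and images with known
ground truth, and every downstream stage is validated against planted
parameters.

## Laminar geometry

Depth is measured in µm from the pia at the nucleus centroid and
increases downward.  Layer membership uses half-open `[top, bottom)`
intervals so every depth maps to exactly one label; L2 and L3 are never
split; the 100-µm WM band beyond the L6/WM line is sampled and anything
deeper is excluded.  In primary-visual-style fields L4 is subdivided
into 4A, 4B, 4Cα and 4Cβ at fixed fractions of L4 depth — 10%, 20%, 20%
and 50%.  Layer areas are width × thickness rectangles except L1, whose
curved pial boundary can be supplied as a polygon (shoelace area).  The
normalized depth scale is linear with pia = 0 and the WM line = 100;
values above 100 are legitimate within the WM band.  How cells exactly
on a boundary are resolved is a genuine free choice; the half-open
centroid rule was adopted because it is unambiguous and matches raster
conventions.

## Intensity normalization and gating

Raw per-cell mean intensities are log-normal, so the working scale —
mean grayscale intensity (MGI) — is `z(ln(raw + 1))`, the z-score taken
per tissue section with the sample (n−1) standard deviation.  The
grouping of the per-section z-score is computed per marker ×
compartment, because gate thresholds are defined on that scale; z-scoring
across all markers jointly would make thresholds depend on the panel
composition.  Tail trimming drops `⌈frac·n⌉` values per tail (0.2%
default; 1% for sparse microglia) with stable-order tie-breaking.

Marker gates compare a cell's MGI against a threshold; calls are
strictly "above ⇒ positive", so equality is negative.  Thresholds
normally ship in configuration.  For synthetic runs the analogue of
manually thresholding in a reference cell type is
`gates_from_reference`, which places each marker's threshold midway
between the mean MGI of reference-positive and reference-negative
cells.  The generator's default positive/negative separation is six
log-scale standard deviations, which puts each class mean three
standard deviations from the midpoint gate; the expected call error is
then ≈ Φ(−3) ≈ 0.13% per side, which is what the ≥99% gating-accuracy
check exercises.

## Phenotyping

Classification is deterministic: a class is hit when any of its
defining markers is positive (HuD/NeuN → neuron; ALDH1L1/GFAP →
astrocyte; Iba1 → microglia; Olig2 → oligodendrocyte), except
endothelial cells, which require collagen IV *and* vimentin or
containment in a vessel object.  A per-class exception list tolerates
known cross-class expression (Olig2 in a subset of astrocytes) without
triggering "Multiple"; residual conflicts are "Multiple", no hits is
"Other", and both are excluded before any statistic.  The exception
list is a declared convention standing in for expert review, not a
reconstruction of one.  Subtypes are gated from ordered positivity
tuples (HuD/NeuN; GAD67/GAD65 with PV/CB; GFAP/ALDH1L1;
Olig2/CNPase/BCAS1), mutually exclusive and exhaustive by construction.
GAD gating undercounts interneurons by design — GAD65/GAD67 do not
label all inhibitory cells — and no correction is applied.

## Composition statistics

Counts, planar densities (cells/mm²), within-layer proportions and
across-layer distributions are tabulated per case × area × layer ×
class; WM is excluded from across-layer distributions because only a
100-µm band is sampled.  Headline ratios (non-neuronal:neuron,
glia:neuron, excitatory:inhibitory over L2/3–L6) are computed from
pooled counts, stored unrounded, and displayed at 2 dp.

Group comparisons use a split-plot mixed-design ANOVA with subject as
the random block.  Rather than asymptotic Wald tests from a numerical
mixed-model fit, the strata are computed exactly: the subject stratum
is the extra sum of squares of the subject term after the fixed
factors, between-subject factors are tested against it, and
within-subject factors and interactions against the remaining residual.
For balanced nested designs this reproduces the classical split-plot F
tests with exact finite-sample reference distributions — which the
type-I-error calibration requires — and the extra-SS formulation stays
well-defined for unbalanced membership.  When subjects contribute
fields in both areas (as in an 11-field, 7-case design), area must be
declared within-subject; the implementation enforces this.  Densities
are compared on the log scale, matching their multiplicative error
structure.  Post-hoc pairwise contrasts of marginal means are
Šidák-adjusted within a family, with Bonferroni available across
families — the two-tier scheme.

## Fiber profiles

A fixed grid of 20 × 20 µm tiles starts at the pial surface; incomplete
right/bottom edge tiles are discarded so tile statistics are unbiased
and the tile count is deterministic.  Per-tile means are normalized
(ln(x+1), z-score per image × marker over all tiles), averaged per row
to an average-at-depth profile, mapped to the normalized depth scale and
assigned layers.  Constant images propagate the degenerate-variance
error rather than emitting NaNs.

## Vessels

Vessel objects are connected components of a positive-pixel mask
(collagen IV; explicit thresholds, with Otsu as fallback — note Otsu is
unreliable when the foreground fraction is very small).  Outlines are
marching-squares contours smoothed with a short periodic moving average
(window 5), which removes the half-pixel staircase that otherwise
inflates perimeters by ~5%; with it, a 20-µm-radius circle at 0.5 µm/px
measures circularity ≈ 0.994.  Area is the outline polygon's shoelace
area, perimeter its arc length, circularity `4πA/P²` (the QuPath
convention; the value is clipped at 1 + 0.05 for raster diagnostics).
Objects with perimeter > 400 µm are flagged and excluded.  Per-vessel
statistics assign one layer by outline centroid; occupancy is pixel-wise
per layer, so straddling vessels contribute to every layer they touch
and per-layer occupied areas sum to the total.

## Multivariate analysis

Field feature vectors (per case × area × layer, optionally per cell
type) carry mean MGIs of the 21 non-fiber/non-vessel markers plus
optional marker-positive cell densities, each variable z-scored across
fields.  Feature manifests are configuration: the default uses 21
intensity + 16 density variables with a 21 + 14 variant, and the
neuronal (15 intensity + 9 or 8 densities) and glial (13 + 6) schemes
ship as presets — the variable counts are internally inconsistent in
the source material, so both variants are provided without arbitration
and the manifest used is recorded with every run.

PCA retains the fewest leading components reaching 80% cumulative
explained variance.  t-SNE embeds the Euclidean (or squared-Euclidean)
distance matrix at perplexity 15 with a mandatory seed; perplexity is
auto-reduced with a warning when n is small.  One-way MANOVA solves the
between/within scatter eigenproblem; canonical coefficients are scaled
to unit pooled within-group variance, per-dimension significance uses
Bartlett's chi-square approximation to the sequential Wilks Λ, feature
influence is ranked by |coefficient|, and group means in canonical
space are clustered by average linkage (the linkage was unspecified;
average was chosen and documented) and exported as Newick text.  A
singular within scatter is ridge-regularized with a warning.

## The synthetic generator

The generator defines the study conditions; its defaults are not tuned.
Geometry: A46-like fields have layer thicknesses (L1–L6) of
150/700/200/300/350 µm; A17-like 120/500/400/250/330 µm, with the L4
sublayer partition above.  Densities are a qualitative laminar template
in round numbers of the right magnitude for primate neocortex (e.g.
neurons 1600/mm² in A46 L2/3–L6, doubled in A17 L2/3–L6; oligodendrocyte
density rising with depth to 1200/mm² in WM); the absolute values are
only available graphically in the source material, so they are template
choices, recorded here once.  Subtype mixtures are the published pooled
proportions: HuD/NeuN 96/1/3% (A46) vs 91/4/5% (A17); GAD67-only /
GAD65-only / double 8/7/5% vs 5/3/4% (making 20% vs 12% of neurons
GABAergic, i.e. E:I 4:1 vs ≈7.3:1); astrocytes 76/23/1% vs 78/18/4%
(GFAP+ALDH1L1 / ALDH1L1-only / GFAP-only), with Olig2 in 4% vs 34% of
astrocytes; oligodendrocytes 78/19/2/1% vs 69/25/4/2%
(Olig2-only/+CNPase/+BCAS1/all three).  About 4% of cells are planted
confusables, half "Other" (all markers negative), half "Multiple"
(conflicting neuronal + microglial markers).

Intensities are log-normal with log-mean ln 50, log-s.d. 0.4, and a
6-s.d. positive shift; pathology markers get a small class-conditional
offset (0.5 s.d. in A46 neurons) so the multivariate stage has realistic
area structure.  Cells are placed uniformly within their layer
rectangle (fixed-count mode, the deterministic test default, or
Poisson); when images are rendered, placement enforces non-overlapping
nuclei (discs of radius 4 µm plus a two-pixel guard) by bounded
retry-with-jitter, and failure raises a diagnostic rather than silently
overlapping.  Vessels are elliptical rings (semi-major 4–22 µm,
60/mm²), 30% SMA-positive; fibrillar channels follow depth-graded mean
profiles with an L4 bump for myelin markers in A17-like fields and a
MAP2 dip in L4.  Cohorts apply one multiplicative log-normal density
factor and one additive log-intensity shift per case (s.d. 0.10) — the
subject random block.  With seven cases the default membership is six
A46 + five A17 fields.

What the generator does **not** emulate: optics and point-spread,
marker bleed-through, autofluorescence, 3-D tissue context, staining-
round registration error, or spatial interactions between cells.
Passing tests therefore demonstrate that the *computations* recover
planted truth under the stated statistical model, not that the pipeline
is robust to those real-data artifacts; for real data the cell-table
CSV boundary is the intended entry point, with upstream segmentation
quality out of scope.

## Problem sizes and numerical choices

Desk-scale experiment sizes were chosen once: density-ratio recovery
uses 20 seeds of paired fields at 0.3× template density (only a ratio is
estimated, so absolute counts are irrelevant); gating accuracy one field;
ANOVA calibration 1000 null and 100 power replicates of a 10-case-per-arm,
5-layer split-plot design with 10% subject and residual s.d.; the
multivariate checks use 40-observation simulations, 100 label
permutations, and a 6-case two-area cohort whose areas differ only in
neuronal co-expression mixtures (glial mixtures, densities and
pathology offsets shared), so any glial-scheme separation would be an
artifact.  Tolerances: z-score contract to 1e-9; hand-computed examples
to 1e-3; sublayer fractions sum to 1 within 1e-9; circularity clipped at
1.05.  Degenerate inputs (constant z-score input, single-field feature
tables, single-subject designs, singular scatter) raise explicit errors
or warnings rather than returning silently wrong numbers; the constant-
input check compares extremes rather than the computed s.d. because the
mean of n identical floats can differ from them by one ulp.

## Known limitations

* The simple nucleus segmenter (global threshold + connected components)
  does not split touching nuclei; rendered test fields enforce
  non-overlap, and real data are expected to arrive as cell tables.
* Bartlett's chi-square MANOVA significance is asymptotic; with many
  features and few fields the ridge-regularized path should be treated
  as descriptive.
* Endothelial identification by co-positivity plus vessel containment
  is cruder than curated review; the vessel-containment path requires
  rendered or supplied vessel objects.
* E:I ratios depend entirely on GAD gating and inherit its undercount.
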