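# Methods

## The assay being modelled

Each microfluidic chip carries a perfused endothelial microvessel grown
against a collagen-1 gel.  A gradient of angiogenic factors drives
sprouting into the gel; anti-angiogenic compounds suppress it.  After
fixation and staining (nuclei + F-actin), each chip is imaged as two
overlapping confocal z-stacks (nominally 2048×2048 px at 0.677 µm/px,
80 z-planes at 1 µm, 10% overlap between sites) and quantified on the
stitched maximum projection.  Working on max projections deliberately
discards 3D topology: branch/node counts are not meaningful on a
projection and are not computed.

## Per-chip readouts

Let y increase toward the gel, with the monolayer/gel boundary at the
baseline `b` (default 400 µm — the empirical average boundary position of
negative-control chips under the standard imaging layout; configurable,
with `metrics.estimate_baseline` available to recalibrate from the nuclei
density profile on a new layout).

* **Migration distance**: mean y of the k = 10 furthest nuclei with
  y > b, minus b.  If fewer than k nuclei lie beyond the baseline all of
  them are averaged, and zero eligible nuclei give distance 0: complete
  inhibition must map to a finite minimum signal rather than an error.
  Ties at the k-th value are resolved by (y, x) ordering for determinism.
* **Total sprout area**: area of the vessel mask restricted to y > b,
  summed only over connected components containing at least one nucleus
  centroid — anucleate debris and matrix texture do not count.
* **Nuclei in sprouts**: nuclei with y > b falling inside the vessel mask.
* **Total length**: edge-weighted length of the morphological skeleton
  (1 px per orthogonal step, √2 per diagonal, times pixel size).

Across the two sites of a chip, intensive quantities (distance) are
averaged and extensive ones (area, counts, length) summed.  Whether the
"10 furthest nuclei" should be pooled across sites instead is genuinely
ambiguous in the assay's description; per-site-then-average is the
default and the k parameter and aggregation live in one place
(`metrics.quantify_chip`) so the alternative is a small change.

## Segmentation

The screening microscope's vendor module publishes only its outputs, so
segmentation here is a standard, fully parameterised pipeline whose
accuracy is scored against synthetic ground truth (the acceptance surface
is ground-truth recovery, not bit-parity with any vendor):

* nuclei: white-tophat background removal (footprint = max nucleus
  diameter), Gaussian smoothing (σ = 2 px), Otsu threshold, watershed on
  the distance transform seeded at maxima ≥ one min-diameter apart,
  equivalent-diameter filter (7–25 µm default);
* vessels: Gaussian smoothing, Otsu, closing (r = 2 px), hole filling,
  removal of objects < 100 µm²;
* blank images short-circuit to empty results — a fully inhibited chip is
  a legitimate observation, not an error.

All thresholds are config-exposed (`SegmentationParams`).

## Plate performance statistics

`SW`, `Z′` and `AVR` are defined in the README.  Implementation choices:

* The guard-band terms use **per-group** n (15 max-controls vs 14
  min-controls is the characteristic control design), since equal group
  sizes are the exception on real plates.
* Sample SD uses the n−1 denominator, the convention of the assay-guidance
  literature the acceptance thresholds come from.
* Negative SW/Z′ are returned unclamped; the acceptance flags (Z′ ≥ 0.4,
  SW ≥ 2, CVmax ≤ 20%, SDmin ≤ SDmax) do the thresholding.  AVR < 0.6 is
  an advisory recommendation, reported but not a pass/fail flag.
* `reconstruct_group_params` inverts the Z′ definition at AVGmax = 1:
  with SDmax = CVmax and SDmin = CVmin·AVGmin,
  `AVGmin = (1 − 3·CVmax/√n_max − Z′) / (1 + 3·CVmin/√n_min − Z′)`.
  This makes a published summary table (Z′, CVs, group sizes) sufficient
  to recompute the SW and AVR it implies — the strongest consistency
  check available when per-chip data are not published.

## Dose-response fitting

The 4PL inhibition curve is evaluated in **linear** concentration, so
vehicle controls (c = 0) sit exactly on the top plateau; IC50 is optimised
as log10(IC50) for conditioning (bounds: within 3 decades of the sampled
dose range; hill ∈ [10⁻³, 10]; bottom ≥ 0).  Initialisation: top at the
lowest-dose mean, bottom at the highest-dose mean floored at 0, IC50 at
the geometric mean of the positive doses.  The common alternative of
placing c = 0 at a pseudo-log position below the lowest dose is kept for
plotting only (`log_position`); using it in the fit biases the top
plateau by the residual Hill term at the pseudo-position.

A fit is flagged non-converged (no exception, so compound loops continue)
when the optimiser fails, the plateau span is below 2% of the response
scale or below twice the residual SD (no resolvable dose dependence), or
the fitted IC50 extrapolates more than 1.5 decades outside the sampled
doses.

IC50 confidence intervals are case-resampling bootstrap percentile
intervals on log10(IC50) (default 1000 resamples; seeded, hence
reproducible).  Wald intervals are avoided because chip screens often run
at n = 2 per concentration.  If more than 20% of resamples fail to refit,
a warning marks the interval as potentially too narrow.

## Synthetic data generator

The generator is phenomenological: no sprouting dynamics are modelled,
only the geometry and statistics of the measured endpoints, which is what
the downstream analysis consumes.

* **Dose model**: expected distance `E(c) = D0·(1 − Imax·c^h/(c^h + IC50^h))`.
  Defaults: D0 = 250 µm (a plausible uninhibited sprout extent; control
  sprout lengths are not published for this assay, so this is a package
  default, not a measured value), Imax = 1, IC50 = 20 nM, h = 1.
* **Between-chip noise**: distance ~ Normal(E(c), cv_chip·E(c)) truncated
  at 0 (distances are non-negative); cv_chip defaults to 0.13, the
  control-group CV of the distance readout on a characterised plate.
  Companion readouts (area, nuclei count, length) are derived from the
  distance with independent lognormal factors so the three readouts carry
  distinct CVs, as on real plates.
* **Renders**: monolayer band (dense nuclei + textured F-actin) below the
  400 µm baseline; each sprout a jittered polyline extending in +y with
  F-actin tube intensity (14 µm width) and nuclei splatted as 3D Gaussian
  blobs every 25 µm along it; Poisson shot noise + Gaussian read noise
  (σ = 8 grey levels) on a 100-count background; 16-bit output.
  Sub-pixel centroids are preserved by bilinear splatting, so localisation
  accuracy is testable to < 1 px.  Default frame 512×512 px at 2.7 µm/px
  with 8 z-planes at 5 µm — the full field of view at reduced sampling,
  chosen so a render takes under a second; the full-resolution geometry is
  `ChipGeometry.full_resolution()`.
* **Ground truth** returned with every render: all nucleus positions,
  sprout centrelines, the true distance (computed from the placed sprout
  nuclei with the same top-10 rule the metrics use), true tube area
  beyond the baseline, and the sprout-nucleus count.

What the generator does **not** emulate: lumen formation and hollow tube
cross-sections, filopodia, uneven illumination and vignetting, chip-edge
artefacts, monolayer retraction at high inhibitor doses, and real
point-spread-function anisotropy.  Passing ground-truth-recovery tests
therefore shows the pipeline is correct on well-behaved data of the
assumed structure, not that segmentation parameters are optimal for any
particular microscope.  Detection accuracy is scored on the gel region
(y > baseline): the monolayer band is rendered confluent, where
blob-level recall is not meaningful — mirroring the real assay, in which
quantification only concerns nuclei beyond the baseline.

## Numerical and reproducibility choices

* Every stochastic routine takes a seed (`numpy.random.default_rng`);
  identical seeds give bit-identical stacks and tables.
* Stitching refines the nominal offset by phase correlation on strips
  spanning the overlap plus the admissible misalignment; a refined offset
  deviating more than 10% of the frame from nominal is treated as
  spurious and the nominal offset is used, with a warning.  Overlap rows
  are fused with a linear ramp strictly inside (0, 1) so seam-edge rows
  remain pure single-site data.
* Watershed seed ties are resolved by the deterministic ordering of
  distance-transform maxima (intensity, then raster order).
* Metric tables carry a configuration hash and package version; the QC
  and dose-response steps reject tables mixing hashes.

## Problem sizes used in the checks

The consistency checks on the reported performance table are exact
algebra (instant).  Simulation-based checks use 200 control-plate
repetitions (15 + 14 chips each) and 100 dose-response screens per cell
type (7 concentrations × 8 chips); image-based checks run on a handful of
default-geometry renders.  These sizes give stable medians and rates
while keeping the whole suite at desk scale.

## Known limitations

* The AVR formula is reported-value–calibrated: it reproduces published
  plate characterisations within rounding, but other labs occasionally
  define the variability ratio with √n scaling; check before comparing
  across sources.
* Skeleton length on thick, blobby masks depends on skeletonisation
  artefacts (spurs); the 100 µm² minimum object size suppresses most of
  them but the length readout is the least robust of the four.
* The 4PL bottom is constrained ≥ 0, which is correct for distances but
  would need relaxing for baseline-subtracted readouts.
* Stitching assumes a pure translation between sites (no rotation or
  scale), matching a fixed stage layout.
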