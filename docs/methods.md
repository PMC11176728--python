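# Methods

This note documents the models, conventions and design choices behind
`pollensize`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and what
the synthetic tests do and do not demonstrate.

## Measurement model

**Raster convention.** Masks are row-major binary rasters with pixel (0,0)
at the top left and pixel centers on the integer lattice. A mask may be a
crop of a larger field of view; it carries its offset and the source shape
so border contact is judged against the original image bounds.

**Area.** `area = n_foreground × c²` where `c` is the calibration in μm/px.
This is the occupied area in a polar-view image, not a curved surface area.
No boundary smoothing or sub-pixel correction is applied; rasterization
error for grain-sized disks (radius ≥ 25 px) is well under 1%.

**Rotational mean width.** The width at rotation θ is the Feret diameter at
angle θ: the extent of the projection of the grain onto an axis at θ. The
mean width averages 180 such widths at 1° steps. Two implementation choices:

* Widths are computed by projecting the convex-hull vertices of the
  foreground pixel centers onto the rotated axis, not by re-rasterizing the
  rotated image. The two routes are equivalent up to interpolation error;
  projection has none. Equivalence is asserted in the tests against a
  supersampled rotate-and-measure oracle (agreement within 1 px at every
  degree on a battery of shapes).
* **+1 px convention:** one pixel is added to the projected extent of pixel
  *centers* so a 1-pixel-wide object has width 1 px rather than 0, and a
  k-pixel row has width k. Ground-truth comparisons account for this.

Because the projection extent equals the convex hull's extent, concave
indentations (e.g. near pores) never reduce a width. For convex shapes,
Cauchy's formula gives mean width = perimeter/π; the test grid (ellipses,
rectangles, disks at radii 25–50 px) verifies this within 2%. For generic
`n_angles`, the profile samples the half-turn at step 180/n; the default
n = 180 is the 0°…179° at 1° convention, and n = 360 (half-degree step)
changes the mean by < 0.5% on smooth convex masks.

**Focus selection.** For image stacks, the layer maximizing the variance of
a 3×3 Laplacian response is used. The metric is a stand-in for an
unspecified "highest contrast" criterion: Laplacian variance is a standard
focus measure, strictly decreasing under Gaussian blur and argmax-invariant
under common affine intensity rescaling. Ties break to the lowest index.

**Fallback segmentation.** Otsu threshold (dark objects), hole filling,
removal of border-touching objects, and a calibrated area gate
(default 150–1500 μm², generously bracketing birch grains at 300–480 μm²).
This is deliberately simple plumbing that makes the pipeline end-to-end
runnable; masks from any external segmentation tool can be imported instead
(any nonzero pixel is foreground, disjoint blobs are split).

**Screening.** Suitability is judged by explicit rules — border contact,
solidity < 0.90, area outside the gate, more than one component — standing
in for a trained suitable/unsuitable classifier whose decision rule is not
published. The rules encode the same intent (intact single grains in polar
view) and are replaceable per grain via an `external_suitable` CSV column.
Solidity uses the convex hull of the mask; folded or fused grains score low,
mildly lobed triporate outlines stay near 0.97 and pass. On the generator's
classes the rules separate cleanly (≥ 99% of clean grains suitable, ≥ 99%
of border-clipped and fused objects unsuitable), which says nothing about
the error rate of any learned classifier on real slides.

## Statistical post-processing

**Z-score filter.** Per analysis unit, values with |z| > 2.5 are removed;
the pass is applied twice, with mean and sample SD re-estimated on the
survivors between passes (a one-pass reading would make the second
application a no-op). Guards: a pass removes nothing when SD = 0 or fewer
than three values remain — the rule's source is silent on these cases.
Sample SD uses the n−1 denominator throughout (matching R defaults). The
filter is applied per pooled analysis unit by default (configurable); the
alternative (per 1-cm sample before pooling) is equally defensible.

**Known bias.** On strongly unbalanced mixtures the filter eats the
minority component's tail: with a 10% dwarf share, minority grains sit
2–3 SD from the pooled mean and some are removed as outliers, biasing the
estimated minority share toward zero (visible in the README example). This
is a property of the published filtering rule, not of the optimizer; it is
within the end-to-end tolerance we verify (±0.1) but worth remembering when
interpreting small shares.

**Pooling.** Consecutive samples are concatenated in groups of five
(1-cm samples → 5-cm bins); a trailing partial bin is kept and flagged
incomplete. Pooling is a pure data operation; the minimum-count gate of 25
grains is applied downstream at the unmixing stage, so other consumers can
choose their own gate.

**Density estimates.** Gaussian KDE with the nrd0 rule-of-thumb bandwidth
`0.9·min(sd, IQR/1.34)·n^(−1/5)` (the default of R's `density()`, and hence
of typical published size-frequency diagrams), evaluated on a grid spanning
the data ± 4 bandwidths so the curve integrates to 1 within 1%.

## Proportion estimation (compound distribution)

The model: observed sizes are i.i.d. from `f(x) = Σᵢ pᵢ N(x; μᵢ, σᵢ)` with
K ≤ 4 components whose (μᵢ, σᵢ) are **fixed** inputs measured on modern
reference material; only the proportions p are free. Fixing the components
is essential — reference and fossil material must share preparation and
mounting medium, since acetolysis and glycerol swelling shift sizes
systematically. An optional shared location shift (default off, bounded
±3 μm) can absorb a uniform preparation offset; it does not model
differential swelling.

**Objective.** The similarity between the theoretical compound distribution
and the observed one is not uniquely defined; the default is the mean
negative log-likelihood (smooth, statistically principled, and optimal
weights coincide with the maximum-likelihood weights that EM finds). A
binned L2 distance between the empirical histogram density and the model
density is available (`objective="hist_l2"`) as a more literal
curve-similarity reading. Densities are floored at 1e-300 so a stray
observation far from all components degrades rather than breaks the fit.

**Optimizer.** Differential evolution (scipy, `best1bin`) over K raw
weights in (0, 1] normalized by their sum, population 10 per parameter,
F = 0.8, CR = 0.9, 200 generations, followed by an L-BFGS-B polish; fully
deterministic for a fixed seed. The simplex reparameterization keeps box
constraints trivial; the lower bound 1e-9 excludes the measure-zero
all-zero candidate. Components are canonically ordered (by mean, then name)
before optimization and the result unpermuted afterwards, so permuting the
component list permutes the output exactly. K = 1 returns (1.0) without
optimization. Samples with zero variance are fitted but flagged
non-converged. Verified properties: agreement with an independent
EM-for-weights oracle within 0.01 per coordinate at n = 500, and mean
absolute recovery error < 0.05 over 50 seeded replicates on the
*B. nana* / *B. pubescens* width components (means 5 μm apart at σ ≈ 1 μm;
recovery is necessarily worse for closer pairs such as
*B. humilis* / *B. pendula*, whose width means differ by 0.27 μm).

**Metric choice.** Width and area are supported identically and never
converted into one another. The CLI defaults to mean width, whose reference
components are better separated relative to their SDs.

## Synthetic data

The generator exists so every stage is testable against known ground truth:

* **Silhouettes**: `r(φ) = base_radius + pore_amplitude·max(0, cos 3φ)³`,
  a disk with three soft bulges at 120° — the simplest analytic stand-in
  for a triporate polar view. Ground-truth area comes from a ≥10×
  supersampled rasterization oracle and agrees with the closed form
  ½∮r²dφ within 0.5%; ground-truth mean width from projecting the exact
  boundary.
* **Scenes** place silhouettes (plus optional elliptical detritus blobs)
  on a noisy background, with controlled fused pairs and border-clipped
  grains, all labeled, all deterministic per seed.
* **Size datasets** are exact draws from the specified normal mixtures
  with retained component labels.
* **Stratigraphic image records** draw per-grain widths from each depth's
  mixture and render disks whose measured mean width reproduces the drawn
  value (radius = (w/c − 1)/2 px, inverting the +1 px convention). Disks
  rather than lobed silhouettes are used here so the drawn width maps to a
  radius in closed form; the lobed shapes are exercised separately in the
  geometry and screening tests. Default record: 10 samples × 20 grains at
  0.25 μm/px with a dwarf-share step 0.1 → 0.6 — grain counts at the low
  end of what the pooling rule (5-sample bins, ≥ 25 grains) is designed
  for, so the end-to-end check runs at realistic per-sample scarcity.

What the generator does **not** emulate: real pollen texture and internal
structure, out-of-focus and oblique (non-polar) grains, halo effects of
learned outline detectors, glycerol-swelling drift over storage time, and
the full failure spectrum of crowded fossil slides. Passing the synthetic
end-to-end checks therefore validates the computational chain, not the
performance of any neural segmentation/screening front end on real slides;
real masks enter through `import_masks` and external suitability verdicts.

## Numerical and interface details

* Degenerate point sets (single pixels, collinear pixels) bypass the hull
  and project raw coordinates.
* `summarize` of a single value reports SD 0 with a `sd_undefined_n1` note.
* Per-unit fit seeds in `unmix_record` are derived as
  `(seed·9973 + index) mod 2³¹` so stratigraphic tables are reproducible
  yet units are independently seeded.
* All CLI runs write a JSON manifest (config, seed, versions, per-stage
  counts `detected / suitable / measured`); identical inputs + manifest
  seed reproduce outputs bit for bit.

## Limitations

* The screening rules are proxies; they make no claim of matching a
  trained classifier's ~5% error regime on real material.
* The z-score filter biases small minority shares downward (see above).
* Components with strongly overlapping size distributions are not
  practically separable at realistic n; the optimizer will return a valid
  simplex whose individual coordinates carry little information (the
  objective is nearly flat along the ambiguous direction).
* Width and area measurements assume polar-view, roughly convex grains;
  strongly folded grains must be screened out, not measured.
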