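# Methods

`nirscalib` estimates how sensitive a continuous-wave fNIRS channel is to
absorption changes at a given cortical depth, and inverts that relationship
into probe-separation recommendations. The chain has four stages: layered
head phantoms, Monte Carlo photon transport, the depth-sensitivity (SAD)
statistic, and a Gaussian-process surrogate that is queried in both
directions.

## Head phantoms

A phantom is a stack of planar slabs along the depth axis +z (z = 0 at the
outer scalp surface): scalp-muscle, cranium, cerebrospinal fluid (CSF) and
brain, the brain filling whatever the measured layers leave of the 64 mm
domain. Eight cadaveric geometries (measured layer thicknesses) ship as a
CSV fixture together with a 735 nm optical-property table (absorption
coefficient mu_a, scattering coefficient mu_s, Henyey-Greenstein anisotropy
g, refractive index n per layer).

Layer boundaries are kept continuous in millimetres rather than snapped to
the voxel raster. Two of the packaged heads have sub-voxel CSF layers
(0.68 and 0.6 mm) that a 1 mm label grid would erase, and slab transport
needs no label volume; the 64x64x64 voxel grid at 1 mm resolution exists
only as the fluence tally raster. A point exactly on a boundary belongs to
the deeper layer (half-open [lower, upper) intervals). Thickness summary
statistics use the sample (n-1) standard deviation and are reported at two
decimals.

## Photon transport

Weighted-packet Monte Carlo in the slab stack, continuous-wave only (no
time gates):

* Packets launch at z = 0+ just inside the scalp from a cone source
  (default half-angle 70 degrees, matching a bare fNIRS LED), uniform over
  the spherical cap. No specular entry loss is applied at launch; packets
  that later return to the top surface undergo scalp-to-air Fresnel
  reflection and may re-enter the tissue. An alternative launch mode
  (`launch_in_exterior`) samples the cone in air and refracts it at the
  scalp with a Fresnel entry loss; in these strongly scattering tissues
  the two modes are indistinguishable (launch direction decorrelates
  within the first millimetre), so the simpler in-tissue launch is the
  default.
* Free paths are exponential at the layer-local mu_t = mu_a + mu_s. Steps
  are truncated at slab interfaces and the remaining optical path is
  resampled, which is exact for exponential (memoryless) steps.
* At every scattering event the packet deposits the absorbed fraction
  (mu_a/mu_t) of its weight and is deflected by a Henyey-Greenstein polar
  angle (inverse CDF; g = 0 reduces to isotropic) with uniform azimuth.
* Interfaces with a refractive-index step apply unpolarized Fresnel
  reflectance with Snell refraction, including total internal reflection;
  the reflect/transmit decision is sampled. Packets crossing the top
  surface inside the detector disk (default radius 1.5 mm, a typical
  detector aperture; configurable because real apertures vary) are recorded
  with their exit weight, total path length and exit position. The lateral
  and bottom domain faces apply the same exterior-medium Fresnel test;
  transmitted packets are terminated as escaped. (At this domain size the
  wall reflections are inconsequential: packets are rouletted long before
  reaching a wall by diffusion.)
* Fluence is tallied as weight x path length per voxel along every
  sub-step (the standard CW estimator; sub-steps crossing voxel boundaries
  are split by Amanatides-Woo traversal). Because the SAD statistic is a
  ratio of fluence sums, this estimator yields the same normalized profile
  as a per-visit weight sum while having lower variance.
* Russian roulette below weight 1e-4 with survival probability 0.1
  (survivors' weight is divided by 0.1) keeps the expectation unbiased. An
  energy ledger tracks launched = absorbed + escaped + roulette residual
  exactly; the residual has zero mean, so launched ~ absorbed + escaped
  statistically (observed closure well within 0.5% at 1e5 packets).

Reproducibility: each packet owns a counter-seeded xorshift128+ substream
derived from the root seed, so a run is bit-reproducible and independent of
batching. The kernel is sequential (single-threaded) by design; identical
results do not depend on thread count.

Numerical choices: interface crossings nudge the position 1e-9 mm into the
receiving layer; media with mu_t = 0 (void) propagate in straight lines to
the next boundary; a packet whose weight reaches zero (pure absorber) is
terminated as absorbed; positions and tallies are validated finite after
every run.

## Sensitivity at depth

The raw source fluence only ever decays away from the source, so it cannot
describe what a *channel* (source plus detector) is sensitive to: that is
the banana-shaped photon-measurement density, the sensitivity of the
detected signal to a local absorption change. For continuous-wave
transport this field is the voxelwise product of the source fluence and
the detector's adjoint fluence. In a laterally homogeneous slab with the
standard symmetric optode placement, optical reciprocity makes the adjoint
field the source field mirrored through the channel midplane, so one
transport run per channel suffices (`sensitivity_volume`). The two noisy
factors of the product are correlated near the midplane, which introduces
a small positive bias there; it is second order in the relative Monte
Carlo error and negligible at the packaged photon counts.

SAD(z) is the percentage of a volume's signal inside a 10 mm-radius
in-plane disk centred on the source-detector midpoint, per 1 mm depth
layer:

    SAD(z) = 100 * sum_{(x,y) in ROI} S(x,y,z) / denominator

Two denominators are supported. The generic default sums over the whole
volume (profile sums to the in-cylinder fraction, at most 100). The
pipeline uses the ROI-cylinder denominator — the share of the channel's
in-ROI sensitivity located at each depth, summing to exactly 100 — which
is the reading under which the calibration levels (a few percent at
10-20 mm depth, rising with separation) take the magnitudes practitioners
quote. ROI membership is decided by voxel-centre distance (fractional
voxel overlap would change membership only for a ring of boundary voxels
and largely cancels in cross-head means). Depth layer z covers
[z, z+1) mm. SAD is invariant to rescaling the volume.

With the sensitivity field, SAD at cortical depths *rises* with
separation while the detected intensity falls — exactly the trade-off the
calibration explores.

Cross-head summaries are unweighted means per depth; box statistics use
linear-interpolation quantiles with 1.5 IQR whiskers so they are exactly
reproducible. Path-length histograms bin detected packets uniformly over
[min, max] path length and report mean packet weight per bin, the weighted
analogue of a photon-count histogram.

## Surrogate and calibration

The calibration dataset is the cross-head mean SAD on the grid of 11
separations (19-39 mm, step 2) x 11 depths (10-20 mm, step 1): 121 rows.
The depth window covers the prefrontal targets the tool is meant for; means
across structurally different heads are used (rather than per-head rows,
available behind a flag) so the surrogate generalizes across anatomy.
Inputs and response are z-score standardized.

The primary surrogate is Gaussian-process regression with a squared
exponential kernel (per-dimension length-scales) plus a white-noise term;
hyperparameters maximize the log marginal likelihood from multiple
restarts under a fixed seed, and a 1e-8 jitter on the standardized scale
keeps the Cholesky factor stable. The comparison surrogate is RBF-kernel
support vector regression with fixed data-driven heuristics: kernel scale
from the median pairwise distance, box constraint IQR(y)/1.349, epsilon
tube IQR(y)/13.49. Fit quality is the adjusted R-squared with p = 2
predictors, reported both at the training points and under leave-one-out
cross-validation with per-fold refitting (on the smooth 121-point surface
the two are nearly identical; the training-fit value is the headline
number because the GPR operates in the near-interpolation regime).

Calibration inverts the surrogate on a 0.1 mm grid with bisection
refinement to 0.01 mm, reporting at 0.1 mm precision:

* separation-from-depth: the smallest separation whose predicted SAD
  crosses each requested level (1-6% by default); smallest because larger
  separations cost source power. A level is infeasible when the predicted
  maximum over the separation range stays below it; feasibility is
  therefore downward-closed in the level.
* depth-from-separation: the deepest depth still achieving each level, so
  the target depth is guaranteed at least that sensitivity.

The GPR posterior mean drives the inversion; the posterior standard
deviation is attached to reports as advisory uncertainty only.

## Problem sizes and what the defaults emulate

The packaged defaults run 1e5 packets per (head, separation) pair - 88
simulations for the full pipeline, a few minutes of CPU - which gives
smooth cross-head mean SAD surfaces and stable surrogate fits. Reference
laboratory practice for this geometry is 1e9 packets per run on a GPU;
`n_photons` is a plain configuration field for users who want that scale.

Two desk-scale consequences are worth knowing:

* Detected-packet statistics through the 1.5 mm detector disk are sparse
  (tens of packets at 19 mm separation, approaching zero beyond ~33 mm), so
  detector-count trends across separations are Poisson-noisy at 1e5
  packets even though the underlying expectation decays monotonically.
  Fluence-based quantities (SAD) do not suffer from this because every
  packet contributes along its whole path.
* Absolute detector counts depend on the aperture geometry, which real
  systems vary; only relative trends are meaningful.

The synthetic phantoms are ideal planar slabs: no surface curvature, no
lateral thickness variation, no vasculature or pigmentation. Passing tests
therefore demonstrate the transport physics, the statistic and the
calibration logic - not that a recommendation transfers unchanged to a
curved, living head.

## Known limitations

* Planar slabs only; curved geometries change incidence angles at
  interfaces and are out of scope.
* Continuous-wave transport; no time-of-flight or frequency-domain
  quantities.
* The detector is an ideal disk with no numerical aperture or acceptance
  angle cut.
* Surrogate validity is restricted to the training box (separation
  19-39 mm, depth 10-20 mm); queries outside it are rejected rather than
  extrapolated.
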