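# Methods

## The problem

Super-resolution ultrasound maps microvasculature by following intravascular
microbubbles (MBs) through contrast-enhanced ultrasound (CEUS) frame
sequences. The classical route, ultrasound localization microscopy (ULM),
localizes isolated bubbles frame by frame and links them into tracks; it
fails when bubbles overlap, which is the norm in tumors, where dense chaotic
vasculature and a thick elevational slice project many vessels onto the same
pixels. This package implements a tracking-free alternative: **pattern
recognition of microcirculation (PARM)**. A moving bubble traces a
continuous bright tube — a *trail spread function* (TSF) — through the 3D
spatio-temporal stack (t, z, x). The orientation of that tube encodes the
instantaneous velocity, so per-voxel velocimetry needs no detection or
association step. Clustering the resulting (speed, direction) samples splits
the bubble population into hemodynamic patterns; each pattern's voxels form
a sparser sub-sequence that is reconstructed separately into a
super-resolved map; the pattern geometry itself yields heterogeneity
metrics, and skeleton morphometrics plus circular statistics yield the
structural and functional metrics.

## Trail velocimetry

For stack intensity I(t, z, x), gradients are Gaussian derivatives (sigma
`gradient_sigma`, default 1 voxel) and the structure tensor is their outer
product averaged in a Gaussian window (sigma `window_sigma`, default 2
voxels). With eigenvalues l1 >= l2 >= l3, the tube axis is the eigenvector
of l3; the sign is fixed so u_t >= 0, which makes the in-plane components
point along physical flow. Velocity is

    vx = a * (u_x / u_t) * pixel_size / frame_interval,   vz likewise,

where `a` (`time_scale`) is the voxel anisotropy factor: the time axis is
scaled so that one frame corresponds to `a` pixels of expected travel before
the tensor is formed. With a = 1 (default) the estimator is accurate for
displacements of roughly 0.2–2 px/frame (verified: median speed error < 10%,
median direction error < 10 degrees on noise-free single-vessel phantoms).
For slower regimes, setting `a` near the expected px/frame widens the
angular separation between tube orientations; the sub-pixel-separation
experiment uses a = 0.2 for its 0.08–0.32 px/frame flows.

Tube-ness is measured by the coherence (l2 − l3)/(l2 + l3) in [0, 1] — 1
for an ideal line, 0 for isotropic texture. Two sample-rejection rules play
the role of overlap-distortion elimination:

* voxels with coherence below `min_coherence` (default 0.5) are dropped —
  interference between nearby trails produces distorted orientations at
  intermediate coherence (empirically 0.5–0.9 for confidently wrong
  samples at tube margins; pristine tube cores sit at ~1.0, so strict
  studies can raise the floor to 0.9);
* samples whose implied speed exceeds `v_max` are clipped and flagged, and
  flagged samples are excluded from clustering. `v_max` defaults to half
  the tensor-window extent traversed per frame; setting it to a
  physiological cap (e.g. 12 mm/s for tumor microflow) additionally rejects
  phantom fast streaks created by bubbles crossing in opposite directions.

MB voxels are detected as intensities at or above the `detect_threshold`
quantile of the positive voxels (default 0.99: after clutter filtering
roughly half the voxels carry small positive residuals while true MB voxels
occupy ~1% of the volume). On clutter-free sequences a lower quantile
(0.95) is appropriate, because there the positives are blob tails rather
than noise and the top 1% can be monopolized by coincidentally overlapping
double-bubbles.

## Clutter filtering and motion screening

Tissue clutter is removed by truncating the leading components of the SVD
of the Casorati matrix (pixels x frames). The cutoff is either fixed (use
the known rank on simulated data) or adaptive: the largest positive second
difference of the log singular-value curve over the first half of the
spectrum. The filter is a linear projection; negative ripple is clipped at
zero. A known limitation, reproduced faithfully here: the quasi-static
component of a steadily perfused vessel is indistinguishable from tissue
and is removed with it, so recovery fidelity improves with sparser bubble
traffic and longer windows.

Bulk motion is screened before filtering: both frames of any adjacent pair
whose Pearson correlation falls below `motion_threshold` (default 0.8) are
excluded, and the surviving frames are split into contiguous segments
(minimum length 50 frames) that are filtered and analyzed independently, so
velocimetry never spans a temporal gap.

## Pattern clustering

Feature points are embedded as (min-max normalized speed, cos theta,
sin theta); the circular encoding keeps flows at +/-180 degrees adjacent,
and spatial coordinates are deliberately excluded so patterns are purely
functional. K-means (squared Euclidean, 10 seeded restarts) is fit for
each K in 2..k_max; the K with the best mean silhouette wins, and K = 1 is
declared when even the best silhouette is below 0.25. Silhouettes are
evaluated on a seeded 2,000-point subsample; above 100,000 points the
K-means itself fits on a seeded 100,000-point subsample and assigns the
rest to the nearest center. Everything is deterministic given the seed.

Two caveats are documented rather than hidden. First, the silhouette floor
calibrates "no structure" for isotropic blobs (structureless data scores
~0.23 in 3D but ~0.53 in 1D), so a single flow whose speed spread survives
min-max stretching can still be split in two; on real single-vessel data
prefer inspecting the selection scores. Second, min-max normalization is
sensitive to speed outliers, which is one reason flagged (speed-clipped)
samples are excluded upstream.

## Heterogeneity metrics

With K patterns, centers C_n and occupancies M_n:

* **PC** = K, the pattern count;
* **PD** = max over pairs of ||C_i − C_j|| in the normalized feature space
  (0 when K = 1);
* **PV** = variance of the occupancy ratios R_n = M_n / sum(M). The default
  divisor is K − 1 (sample variance); the population divisor is available
  via `pv_ddof=0` because the choice changes values materially at small K.
  Note that ratios summing to 1 bound the population variance by
  (K−1)/K², e.g. 2/9 at K = 3; published PV values approaching 0.9
  therefore imply some additional rescaling that their source does not
  specify. This package computes the definition literally.

## Super-resolved reconstruction

The production route is an in-package implementation of super-resolution
radial fluctuations (SRRF): for each magnified pixel, the image gradient is
sampled (bilinearly) at `ring_axes` points on a ring of `ring_radius`
input pixels; each sample contributes sign(inward) * max(0, 1 − d/r) where
d is the perpendicular distance of the gradient line from the ring center;
the mean over the ring, floored at zero, is the radiality. Defaults follow
the standard plugin parameterization — ring radius 8, magnification 3,
8 axes. Per-frame radiality is aggregated by the temporal mean (variance
mode available) and normalized to [0, 1]; the pre-normalization scale is
kept in the map provenance. No drift correction and no intensity weighting
are applied. All-zero frames contribute zero radiality, so each frame is
evaluated on a padded bounding box of its nonzero support and pasted into
the accumulator — exact, and much cheaper on sparse per-pattern
sequences. Radiality maps show ring-radius sidelobes around sharp masked
edges; ridge localization in the validation experiments therefore works in
a band around the detected MB support.

The ULM baseline is deliberately minimal — per-frame peak detection,
Gaussian-weighted centroid localization, greedy nearest-neighbor linking —
and exists as the comparator whose localization degrades under bubble
overlap (asserted in its tests), not as a contribution.

The sentinel microvasculature is the per-pattern map whose feature points
have the highest mean speed; the non-sentinel composite is the pixel-wise
maximum of the remaining maps. Ties resolve to the lowest pattern index
with a warning.

## Structural and functional metrics

Maps are binarized (Otsu on the nonzero values by default), cleaned of
objects smaller than `min_object_size` pixels, and skeletonized. Junction
nodes are connected clusters of skeleton pixels with >= 3 skeleton
neighbors; branches are the skeleton paths left when junction pixels are
removed, extended to the adjacent junction centroids. Branch arc length is
measured on the ordered path resampled every 3 pixels, which removes the
staircase bias of raw 8-connected step counting (up to ~8% on smooth
curves); this is what makes the semicircle arc/chord test land at pi/2
within discretization error. Metrics: VD = vessel area fraction; VN =
branch count; NN = node count; VNP = VN per ROI pixel; VT = mean
arc/chord over branches with chord >= 2 px (1 if no branch qualifies).
Functional metrics from the feature points: MS = mean speed; SE = Shannon
entropy (bits) of the speed histogram over `speed_bins` = 32 equal bins on
[0, v_max]; OV = circular variance 1 − |mean unit direction vector|.

Longitudinal arithmetic: tumor volume V = a b²/2 from caliper axes;
volume change as printed, (V_b − V_a)/V_a, with a `baseline_first=False`
switch for the change-from-baseline convention used by the relative-change
formula (value_day_N − value_day_12)/value_day_12; Spearman rank
correlation with average ranks for ties.

## The synthetic CEUS generator

The generator emulates: point scatterers entering streamlines as Poisson
arrivals, advected at constant speed along a polyline with a fixed per-MB
lateral offset (sigma `lumen_sigma`), rendered as isotropic Gaussian PSF
blobs of amplitude 1; plus low-rank tissue clutter — exactly
`clutter_rank` separable components, each a smooth non-negative random
spatial field times a slow sinusoidal envelope at 0.5–5 Hz (the
respiratory/cardiac band of small-animal imaging, chosen so the clutter
components are temporally distinct within a 3 s window) — and additive
Gaussian noise scaled to the mean intensity, clipped at zero. The nominal
acquisition is 1,500 frames at 500 Hz on a 128 x 128 grid of 50 um pixels
with a 100 um PSF sigma.

What it does *not* emulate — and hence what passing tests do not show
about real data: no wave propagation, beamforming or speckle; no nonlinear
bubble oscillation, attenuation or depth-dependent PSF; plug flow without
pulsatility or lumen-width velocity profiles; clutter that is exactly
low-rank rather than approximately so; amplitude-1 bubbles without
concentration-dependent shadowing. The validation experiments use
flux-proportional arrival rates (equal bubble concentration implies flux
proportional to volumetric flow).

## Validation experiment sizes

The bundled experiments run at the nominal acquisition (1,500 frames,
128 x 128): two- and three-streamline pattern-count recovery under rank-2
clutter (fixed SVD cutoff 2, k_max 10), and the 24 um parallel-vessel
discrimination (clutter-free, detection quantile 0.95, a = 0.2, v_max
12 mm/s, SRRF magnification 3). Unit and pipeline tests use shorter
windows (150–300 frames) and smaller grids where the property under test
does not depend on the full problem size; the clutter-recovery
correlation test keeps the full 1,500-frame window because the
filter's selectivity genuinely depends on it.

## Known limitations

* Per-voxel (not per-bubble) feature points weight patterns by trail
  volume, so occupancy ratios reflect voxel counts, not bubble counts;
  slow vessels accumulate more voxels per bubble.
* The adaptive SVD cutoff is a stated convention (largest curvature of the
  log spectrum), not a recovered rule.
* Velocity estimates degrade where trails from different vessels overlap
  within the tensor window; the coherence and speed-cap gates reject most
  but not all such samples.
* The vessel graph is 2D per plane; no elevational stitching.
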