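# Methods

## Coordinate system and projections

All analyses run in an embryo-centric spherical frame: the origin at the
centre of the best-fit embryo sphere, the polar axis through the animal
pole, longitude θ ∈ (−π, π] zeroed at the dorsal midline, latitude
ϕ ∈ [−π/2, π/2] with the animal pole at −π/2. The sign convention puts
epiboly (animal → vegetal spreading) at dϕ/dt > 0 and dorsal convergence at
d|θ|/dt < 0. Cartesian↔spherical conversion is exact away from the poles
(round trip < 1e-6 µm); the centre itself is a flagged degenerate point.

Datasets are aligned by subtracting the fitted sphere centre and applying
an explicit rotation. Because interactive manual alignment is not
reproducible, the rotation is either supplied directly or estimated from
≥ 3 landmark pairs by orthogonal Procrustes with a proper-rotation
constraint.

The sphere is mapped to the plane by the conformal Mercator projection
u = θ, v = arctanh(sin ϕ) (identical to ln tan(π/4 + ϕ/2), but exactly odd
in ϕ). Latitudes are clamped at 85° so v stays finite; clamped points are
counted, never dropped. Conformality means directions and angles survive
the projection unchanged, which is what the flow-field statistics need;
areas do not: a true surface patch of area A at latitude ϕ projects to
area A·sec²ϕ.

**Area correction.** Sample counts accumulated on a regular grid in the
projection therefore under-represent high latitudes: for uniform surface
density the count per grid cell falls off as cos²ϕ. Wherever counts feed a
density-like quantity (streamline widths, per-band counts), the count is
divided by the cell's true area — equivalently multiplied by sec²ϕ
evaluated at the cell centre — so that a uniformly populated sphere yields
flat corrected values. The central-point evaluation of sec²ϕ introduces a
small finite-band bias (< 2% at 12 bands over |ϕ| < 1.2 rad), which the
tests budget for explicitly.

## Synthetic embryo

The simulator generates the statistical structure the analysis assumes and
nothing more. Cells start uniformly (by area) on the animal cap of a
350 µm sphere, within a 50 µm sub-surface shell (the occupied blastoderm
band), inside a 550 µm chorion. Kinematics per frame (default 120 s; the
interval is configurable since acquisition protocols vary between 2 and
2.5 min):

* epiboly: dϕ/dt = rate(t), default a Gaussian bump peaking at 7 hpf
  (0.45 rad/h peak — illustrative, chosen so the blastoderm covers the
  yolk in about 6 h; no quantitative flow magnitudes are asserted);
* convergence: θ moves toward 0 at rate(t), default bump peaking at
  10 hpf (0.30 rad/h);
* internalization: a configurable fraction of mesendoderm cells, seeded
  near the shield (|θ| small, near the margin), steps radially inward by
  30 µm over 0.5 h starting at 5.5 hpf and thereafter drifts toward the
  animal pole at 0.25 rad/h. Internalization is deterministic given the
  per-cell flag — a stochastic cell-autonomous switching model was
  rejected because it makes cluster-recovery tests ill-posed.

Germlayer identity is dynamic: every cell is epiblast before mezzo onset
(4.5 hpf); mesendoderm-fated cells (40% by default) switch label at onset;
an endoderm subset of the mesendoderm lineage (20% of it) switches again
at sox17 onset (6.5 hpf). Expression traces rise first-order
(1 − exp(−Δt/τ), τ = 0.5 h) after onset, hence are monotone.

Observed tracks add isotropic Gaussian positional noise (default 1 µm per
frame) and optional geometric fragmentation (per-frame cut probability).
The ground truth retains noise-free unfragmented tracks, per-cell fates,
internalization flags, the programmed rate profiles, and the
fragment-to-cell map.

Randomness uses one counter-derived substream per cell
(`SeedSequence([seed, cell_index])`), so cell k's trajectory is invariant
under changes of the requested cell count above k, and identical seeds
give bit-identical output.

What the simulator does **not** emulate: realistic PSFs and light-sheet
shadowing, cell division (parent ids are bookkeeping only), density-driven
mechanical interactions, or tracking errors other than noise and
fragmentation. Passing tests therefore demonstrate correctness of the
statistics under the stated kinematic model, not robustness to every
artifact of real segmentation.

## Image preprocessing

**Focus filtering.** Transmission stacks are filtered plane-wise with a
difference-of-Gaussians, I′ = |I − G_σ * I| with σ = 1 voxel, which keeps
in-focus edges and suppresses defocused background.

**Two-sphere fit.** After 3×3 plane-wise median filtering, voxels above a
global threshold (exposed as a parameter; default the 99.5th percentile,
since the appropriate cut depends on the acquisition) are treated as
surface samples. Two sphere models, both initialized at the stack centre
with radii 350 and 550 µm, are refined EM-style: the E-step assigns each
voxel to the sphere with the nearest *surface* (|‖p − c‖ − R|), ties going
to the smaller sphere for determinism; the M-step refits each sphere by an
algebraic least-squares (Kåsa) solve followed by a few fixed-point steps
minimizing the geometric surface distance. An M-step that would increase
the summed squared surface distance is rejected, making the objective
non-increasing by construction. A starved model (empty or < 4-point
assignment) is flagged unconverged with the iteration index. The smaller
sphere is the embryo.

**Shell mask and masked storage.** Only a band around the embryo surface
(default ±150 µm, a 300 µm shell) carries information. The mask is the
sorted list of linear voxel indices (z-major C order, little-endian
uint32) whose signed surface distance lies in the band; it is stored once
(`header.json` + `index.idx`) and each timepoint is a bare concatenation
of the masked intensities (`t_XXXX.blob`). Reading reconstitutes a full
stack with a declared fill value; a blob whose length disagrees with the
index table raises a corrupt-file error quoting both lengths.

**Nucleus detection.** Stacks are Gaussian-smoothed (σ = 1 voxel); local
maxima above an intensity threshold (default 150) are kept only if they
rise at least 30 gray levels above the saddle to any neighbouring retained
maximum. The "separated by 30 gray levels" rule is implemented as saddle
prominence via grayscale h-maxima — the interpretation that makes the rule
topological rather than dependent on arbitrary neighbour pairing.

**Rigid time registration.** Consecutive-timepoint detections are aligned
by ICP: nearest-neighbour correspondences (k-d tree) alternate with a
closed-form rigid solve (SVD with det(R) = +1 enforced) until the RMS
residual stabilizes. A trimmed variant drops the worst fraction of
matches per iteration for robustness to detection outliers; the default
uses all points.

**Channel subtraction.** With ch1 = endoderm nuclei, ch2 = mesendoderm
cytoplasm, ch3 = all nuclei: epiblast = clamp₀(ch3 − s·ch2),
mesendoderm = clamp₀(ch3 − epiblast), mesoderm = clamp₀(mesendoderm −
s′·ch1), endoderm = ch1 unchanged. Two choices make the arithmetic
meaningful across fluorophores: channels are rescaled so their 99.9th
percentile foreground intensities match (raw cross-fluorophore
subtraction has no common scale), and ch2 is first morphologically closed
with a nucleus-sized ball so the cytoplasmic signal covers the nuclear
footprints it is meant to cancel.

**Expression readout.** The reporter signal is averaged in a 3×3×3 voxel
window around each tracked position (truncated at stack edges) and
normalized to [0, 1] by the global minimum and maximum across all frames
and positions of the run; a constant signal normalizes to all zeros with a
warning.

## Track statistics

Straightness uses non-overlapping windows aligned to track start
(default 10 frames ≈ 20 min), avoiding the autocorrelation that
overlapping windows would inject into the SI-vs-position scatter.
Stationary windows (zero path length) have undefined SI and are excluded
from aggregates, with the exclusion flagged.

Prediction ellipses assume bivariate normality of the (coordinate, SI)
scatter: the 90% ellipse has Mahalanobis radius √χ²₂(0.90) ≈ 2.146 about
the sample mean and covariance; layers with fewer than three windows get
no ellipse.

Radius/latitude drift is measured on non-overlapping 10-min pieces
(last-minus-first per piece, averaged per track); tracks shorter than one
piece are excluded and counted. Shield-region filtering keeps tracks whose
longitudes stay within [−π/8, π/8] over the analysis window, with a
completeness mode that drops tracks not spanning the window — required
before latitude-profile clustering, which k-means the per-frame latitude
vectors (default k = 3; k = 2 separates epiboly from
internalize-then-animal-ward motion). The internalizing cluster is
identified automatically as the one whose centroid latitude velocity
(5-frame moving average) changes sign.

Fragmented tracklets are aggregated by greedy linking: a fragment's end
connects to the nearest unclaimed fragment start within a frame gap and a
link radius, smallest distance first, ties broken by cell id — a
deterministic stand-in for statistical trajectory-aggregation methods,
adequate at the fragmentation rates the simulator produces.

## Flow fields and decomposition

Consecutive-frame displacements are unit-normalized in the Mercator plane
(direction only; speed is deliberately discarded so dense slow regions do
not dominate), assigned to the 40×40 grid cell and time interval of their
start point, and averaged per cell; the resultant length is kept as a
coherence magnitude and the count as the weight. Interval spans default to
total duration / 10 (≈ 1.5 h for a 14–15 h recording) rather than a
hard-coded 1.5 h. Multi-embryo averaging renormalizes the mean of the
per-embryo unit vectors and sums weights; exact cancellation is flagged
incoherent (zero vector).

Circular correlation between two layers' directions α, β uses the
zero-mean form ρ = Σw sin α sin β / √(Σw sin²α · Σw sin²β) over shared
populated sites, weighted by w = min(w_A, w_B). With directions on a
projected sphere the circular means are not identifiable, so both are set
to zero; the uncentered second moments in the denominator then make
ρ(α, α) = 1 and ρ(α, α+π) = −1 exactly, which a centered variance would
not.

Movement decomposition projects the unit flow onto in-plane reference
directions — conformality makes pure epiboly (0, +1) and pure convergence
(−sign(u), 0) exact at every grid centre, degenerate on the dorsal
midline and the ventral seam where convergence has no defined sign. The
projection s = cos(angle) maps to a proportion p = 1 − (2/π)·arccos(s)
for s > 0, else 0. The formulation without the 1/π normalization produces
values outside [0, 1] for angles beyond ≈ 60° and cannot be a proportion;
the adopted form is the unique affine-in-angle map with p(parallel) = 1,
p(orthogonal) = 0, p(45°) = ½. Per-interval summaries o(t) are
observation-weighted means of p over populated, non-degenerate sites — a
convex combination, so min p ≤ o(t) ≤ max p always.

Streamlines are integrated per interval with fixed-step RK2 (step = ¼ cell
width, ≤ 200 steps, nearest-cell direction lookup, termination on empty
cells or the grid boundary), seeded at every populated cell centre. Widths
encode the start cell's count per unit true area (the sec²ϕ correction
above).

Local motion correlation and relative layer motion both use end-to-end
motion vectors over 10-min windows and k = 6 nearest neighbours found by
3D Euclidean (not geodesic) search — layers are radially separated, and
geodesic distance would erase exactly that separation. Motion vectors are
split into physical spherical components (Δr; r·cos ϕ·Δθ; r·Δϕ, in µm at
the window midpoint). Correlation is Spearman per component per frame over
all (cell, neighbourhood-mean) pairs; zero-variance components are NaN.
Residual motion subtracts the epiblast neighbourhood mean from each
mesendoderm cell's motion, excludes cells without an epiblast neighbour
within a cutoff (counted), averages residuals on the Mercator grid, and
summarizes radial components as Gaussian KDEs per interval (the radial
information is otherwise lost in the 2D maps).

## Visualization exports

Edge bundling follows the force-directed formulation: polylines resampled
to a common vertex count, pairwise compatibility scored by angle, scale,
position and visibility of the end-to-end chords (threshold 0.6), interior
vertices relaxed under internal springs plus attraction between compatible
pairs over 6 cycles with step halving; endpoints are pinned and the
polyline count preserved. Bundling runs within k-means pre-clusters of the
resampled coordinates. The schedule constants are declared defaults — the
technique's parameters are not standardized — and the default rendering
transparency is 0.95 so bundled mains and outlier silhouettes both stay
visible.

Space-time exports emit per-track (u, v, t) polylines plus a vertical
reference line for a stationary object. The viewer JSON decimates each
trajectory to every fifth vertex (endpoints always kept; factor 1 is
lossless), attaches per-vertex normalized expression (clipped to [0, 1]
with a warning if out of range), and round-trips through a validating
reader.

## Pipeline

A single YAML config drives simulate → preprocess → tracks → flows →
export. Config validation (including existence of input paths for enabled
stages) happens before any stage runs; a stage failure aborts with the
stage named and partial outputs retained and flagged in the manifest.
Every output is hashed (SHA-256) into `manifest.json`; identical
config + seed reproduces identical hashes, and re-running a completed
manifest is a no-op without `--force`. The default pipeline sizes
(500 cells, 8 µm preprocessing voxels on 144³ stacks) keep a full run in
the tens of seconds while exercising every stage; analyses intended for
publication-scale data should raise the cell count and grid resolution in
the config.

## Numerical choices and known limitations

* Two-sphere fitting assumes roughly concentric shells with distinct
  radii; heavily overlapping or non-spherical geometries (late somite
  stages, adaptive-shell acquisitions) are out of scope.
* The EM fit's threshold default is percentile-based and should be tuned
  per acquisition; the objective-monotonicity guarantee holds regardless.
* KMeans uses a fixed `random_state` (10 restarts) so clustering, and
  everything hashed downstream of it, is reproducible.
* The latitude clamp (85°) means trajectories crossing the poles are
  projected to the clamp ring; polar dynamics are not meaningfully
  represented in Mercator-based analyses (true of the projection, not the
  implementation).
* Greedy tracklet linking is order-deterministic but not globally
  optimal; at high fragment densities an assignment-problem solver would
  link better.
* Windowed statistics quietly shrink at track ends (truncated windows are
  dropped, not padded); counts of exclusions are reported wherever this
  happens.
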