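# Methods

`bundleseg` compares two strategies for extracting named white-matter bundles
from a whole-brain tractogram — classical ROI-based filtering and
streamline-space clustering with template-guided selection — and quantifies
the difference with a per-bundle paired analysis of a compactness index
(irregularity). Because clinical tractograms cannot be redistributed, the
package ships a synthetic phantom generator that reproduces the geometric
structure the comparison hinges on: four association bundles with
characteristic trajectories and the recurrent artefact streamline
populations that contaminate ROI-based dissections.

## Phantom model

**Space.** A 180 x 216 x 180 voxel grid at 1 mm isotropic resolution with an
identity affine (world mm == voxel index), MNI-like extents. Bundles occupy
the left hemisphere; the mid-sagittal plane sits at x = 90 mm.

**Bundles.** Each bundle is defined by a centerline through hand-placed
control points, interpolated with a natural cubic spline:

* **AF** (arcuate fasciculus): frontal origin, antero-posterior longitudinal
  course, arc around the Sylvian-fissure level, dorso-ventral descent into
  the temporal lobe.
* **AF_ant** (indirect anterior segment / SLF III): fronto-parietal, stays
  dorsal, no temporal descent.
* **AF_post** (indirect posterior segment): temporo-parietal, entirely
  posterior to the frontal-segregation plane.
* **IFOF**: long antero-posterior course at ventral depth, funnelled through
  a narrow external/extreme-capsule stem.

A streamline is the centerline plus (i) a per-streamline constant transverse
offset in the local normal plane whose magnitude is Rayleigh-distributed
(scale 2.2 mm), (ii) low-frequency sinusoidal jitter (1-2 cycles along the
bundle, amplitude ~0.8 mm) in both normal directions, and (iii) random end
trimming up to 4 mm per end. Points are spaced ~2 mm. These defaults give
bundles ~7 mm across with frayed, non-cylindrical boundaries — deliberately
on the compact side of clinical reality so that the designed artefact
populations, not tube noise, dominate the between-method contrast. Defaults:
500 streamlines per bundle.

**Artefact populations** (100 streamlines each by default, plus 1000
unstructured background clutter streamlines):

| pattern | geometry | designed confound for |
|---|---|---|
| `parietal_ending` | follows the AF longitudinal course, dips through the temporal waypoint territory, bends back up to a parietal terminus | AF recipe |
| `u_fiber` | short (<40 mm) arcs next to the coronal or the temporal waypoint (50/50) | AF_ant / AF_post recipes |
| `dorsal_loop` | passes the IFOF stem then curves back dorsally; the turn position varies uniformly along the course | IFOF recipe |
| `projection_vertical` | vertical course crossing the AF waypoint territory | removed by the insula-level exclusion |
| `commissural` | arcs crossing the midline | removed by the midline slice filter |
| `background` | random smooth polylines anywhere in the volume | non-specific clutter |

The `parietal_ending` population crosses *both* AF waypoint ROIs (its dip
reaches the axial temporal box) — that is what makes it leak into the AF
under conjunction semantics while being excluded from both indirect segments
by their segregation planes. The `dorsal_loop` turn height is heterogeneous
on purpose: loops turning close behind the stem are caught by the axial
extension of the dorsal exclusion ROI, posterior-turning loops evade it, so
the refined IFOF recipe removes part but not all of the population.

**Subjects.** Per-subject variability is a rigid rotation plus anisotropic
scaling about the hemisphere centre, applied to all control points. The
default config samples rotations uniform in +/-5 deg per axis and scale
factors in +/-5%; hard caps of 10 deg / 10% are enforced by `SubjectSpec`.
The envelope is chosen so that every bundle still crosses its fixed recipe
boxes under worst-case displacement (~7 mm at the bundle extremes). The
cohort master seed fans out to per-subject seeds as `master_seed + i`.

## ROI segmentation engine

A bundle recipe is a conjunction of terms evaluated per streamline:

* **ROI terms**: a parametric axis-aligned box in world mm (the reproducible
  stand-in for ROIs drawn by hand on a colour-FA map) or a binary NIfTI
  mask, with *Any Part* (waypoint: some sample falls inside) or *No Part*
  (veto) logic. Membership samples the vertices plus supersampled segment
  points at <=0.5 mm spacing, so thin ROIs pierced between vertices are
  caught.
* **Slice filters**: a plane whose crossers are discarded; crossing requires
  points strictly on both sides, so a streamline merely touching the plane
  survives. The midline filter (x = 90) is part of every recipe.

Default recipes: AF = coronal deep-white-matter waypoint + axial temporal
waypoint + insula-level exclusion + midline; AF_ant = coronal waypoint +
temporal/parietal segregation plane (No Part) + midline; AF_post = axial
temporal waypoint + frontal segregation plane (No Part) + midline; IFOF =
stem waypoint + dorsal and ventral exclusions above/below the stem, with
axial extensions of both + midline. `refined=False` drops the insula
exclusion and the IFOF extensions, exposing the base waypoint heuristics.
Box coordinates are free parameters of the phantom study design, recorded in
`bundleseg.roi.default_recipes`.

## Streamline segmentation engine

**Metric.** Minimum average direct-flip (MDF) distance: both streamlines are
resampled to 20 equidistant points; the distance is the smaller of the mean
pointwise Euclidean distance in direct and in reversed order. Flip
invariance matches the arbitrary orientation of tracked streamlines.

**Clustering.** Dissimilarity representation: each streamline is embedded by
its MDF distances to p = min(40, n) reference streamlines chosen by
farthest-first traversal; k-means partitions the embedding; a
k-medoids-style alternation in the original MDF space then extracts one
medoid prototype per cluster and reassigns members to their nearest
prototype (ties to the lowest cluster index) until stable, capped at 6
sweeps. At the fixed point the partition equals a brute-force
nearest-prototype assignment. Medoid scoring is exact up to 300 members and
uses a deterministic evenly-spaced co-member subsample beyond that.

**Selection.** The interactive operations of prototype-based dissection are
scripted primitives: pick, invert, select-all, remove-unselected, and expand
(select clusters whose prototype lies within a radius of a selected one).
`auto_segment_by_template` composes them into a reproducible surrogate for
operator judgment: cluster the active set with k from the schedule
{50, 100, 200, 400}; pick every cluster whose prototype has MDF < tau_select
(15 mm) to the nearest template streamline; remove the rest; repeat with
finer k until the schedule is exhausted or k reaches the active-set size;
finally keep individual streamlines with MDF < tau_final (8 mm) to the
template. On phantoms the template is the subject's deformed bundle
centerline — not its member streamlines — so the surrogate cannot trivially
copy the ground-truth labels. All three policy parameters are config-exposed;
they stand in for an operator's visual inclusion criterion, which no fixed
threshold can claim to model exactly.

## Shape analysis

The selected streamlines are voxelized on the anatomical grid: the exact set
of voxels traversed by any segment, computed from the half-integer boundary
crossings of each segment under the voxel-centre convention. (Fixed-step
point sampling was measured to miss 13-15% of traversed voxels on diagonal
courses and was replaced by the exact traversal.) From the mask and the
streamlines:

* mean_length — mean streamline arc length (mm)
* span — mean endpoint-to-endpoint distance (mm)
* volume — voxel count x voxel volume (mm^3)
* surface_area — exposed voxel faces (6-connectivity) x face area (mm^2)
* diameter = 2 sqrt(volume / (pi mean_length)) — the equal-volume cylinder
* **irregularity = surface_area / (pi diameter mean_length)** — surface
  relative to the equal-volume cylinder's lateral surface; deviating
  streamlines add surface without commensurate volume and push it up
* curl = mean_length / span; elongation = mean_length / diameter (derived
  extras, not part of the comparison)

Exposed-face counting is deterministic and exactly testable (a straight
100 mm column on a 1 mm grid has volume 101 mm^3 and surface 4*101+2 =
406 mm^2, irregularity ~1.140). The trade-off is a known Manhattan bias: the
face-count lateral surface of a digital cylinder is 8r per unit length
rather than 2*pi*r, so the cylinder minimum of the index is 4/pi + r/L
(~1.27-1.33), not the analytic 1. The bias is a common-mode factor across
segmentations of the same geometry and cancels in the direction of the
between-method comparison. A marching-cubes mesh estimator would remove the
bias at the cost of exact testability; it is not used.

## Statistical comparison

Per bundle, the irregularity of the ROI-based and the streamline-based
segmentation of the same subject form a paired sample. The pipeline runs a
Shapiro-Wilk gate on the paired differences (warn, never abort, at
p <= 0.05), a two-sided paired t-test (SciPy `ttest_rel`), and Cohen's d on
the paired differences d = mean(x-y)/sd(x-y), which satisfies
t = d sqrt(n) exactly. Descriptive tables report mean, sd (n-1), min,
linear-interpolation quartiles and max per bundle and method. Significance
level alpha = 0.05; no multiple-comparison correction is applied across the
four bundles. The normality gate is evaluated per difference vector.

## Numerical and design choices

* All stochastic operations take explicit seeds; a cohort is a pure function
  of (config, master seed). Pairwise-distance kernels run in float32
  (mm-scale coordinates; error ~1e-4 mm), everything else in float64.
* Tractogram downsampling is uniform without replacement; upsampling by
  duplication must be requested explicitly because duplicates bias
  density-based measures.
* Slice-crossing ties (a point exactly on the plane) count as not crossing;
  voxel membership uses half-open voxel extents [i-0.5, i+0.5).
* Degenerate inputs fail loudly: empty segmentations, single-point
  streamlines, recipes without an inclusion term, paired samples with zero
  difference variance (except the exact x == y case, which reports t = 0,
  p = 1 by convention).
* Problem sizes: the default experiment uses 25 subjects x 3500 streamlines.
  This is deliberately desk-scale — large enough for the artefact-driven
  contrast to be decisive (observed effect sizes d > 3), small enough that a
  full run takes minutes on one CPU. The million-streamline scale of
  clinical tractograms is exercised by the resampling operation, not by the
  cohort loop.

## What the phantoms do and do not show

The generator reproduces the *geometric mechanism* of the comparison: ROI
conjunctions admit anatomically implausible streamlines that happen to
satisfy waypoint logic, streamline-space selection rejects them by shape,
and the irregularity index registers the difference. Passing tests therefore
validate the engines, the index, and the statistics — not clinical effect
sizes. The phantoms have no diffusion signal, no tracking errors beyond the
injected populations, no lesions or mass effect, no inter-rater variability,
and artefact prevalences are free parameters (no quantitative prevalence is
established for real data). Absolute irregularity values on phantoms are
smaller than on clinical bundles, whose richer fray and partial-volume
effects add surface; only the direction and the paired design transfer.

## Known limitations

* The scripted template policy is a surrogate for interactive expert
  selection, not a model of it; its thresholds are honest free parameters.
* Face-count surface area carries the 4/pi staircase factor discussed above.
* Recipe boxes are tuned to the phantom's deformation envelope; real-data
  use requires per-subject ROI placement (mask ROIs are supported).
* The k-means initialisation of the clustering depends on the seed; medoid
  refinement removes most but not all of that dependence. All reported
  results fix their seeds.
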