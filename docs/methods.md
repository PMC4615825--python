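# Methods

This note documents the models, numerical conventions and design choices
behind `mcthick`, and what the synthetic validation does and does not
establish about real data.

## Tissue model and assumptions

The cortical depth is modeled as two discrete tissue classes — a lightly
myelinated superficial band (GM) and a heavily myelinated deep band (mGM) —
sitting on subcortical white matter (WM), with image intensity increasing
monotonically with myelin content (c_GM < c_mGM < c_WM). This two-band
approximation is coarse: real myeloarchitecture varies by region, and in
some areas the transition between lightly and heavily myelinated laminae is
diffuse rather than sharp. The method further assumes the input has enough
intracortical contrast-to-noise for three-class clustering, and that a
cerebrum mask (cortex + underlying WM, no subcortical structures or
ventricles) is supplied or phantom-generated; skull stripping, whole-brain
labeling and registration are outside the package's scope, and volumes are
processed in their stored voxel lattice without resampling.

## Ratio image

`compute_ratio_image` divides T1w by a median-filtered PDw volume. Only the
PDw image is filtered. The kernel is specified in millimetres and converted
per axis to the nearest odd voxel window (ties toward the smaller window;
never below one voxel); a 5 mm kernel on a 1 mm grid is a 5×5×5 window.
Edges are handled by reflection, and the whole volume is filtered before
masking — the filter's behavior at the mask rim therefore depends on the
PDw background, which in a whole-head acquisition is real tissue signal.
The ratio background is forced to exactly 0 by the mask, since an
unconstrained ratio background is ill-behaved and would corrupt the
clustering. A division guard rejects inputs whose filtered PDw falls below
10⁻⁶ of its masked median.

## Fuzzy clustering

`FuzzyCMeans` minimizes

    J = Σ_j Σ_k u_jk^q (y_j − c_k)² + (β/2) Σ_j Σ_k u_jk^q Σ_{n∈N_j} Σ_{m≠k} u_nm^q

over memberships u (a partition of unity per voxel) and class centroids c,
with N_j the 6-neighborhood. β = 0 recovers plain fuzzy c-means, which is
the package default: it is exactly verifiable (alternating optimization is
provably monotone, and on noiseless inputs the solution is the generating
classes), and the spatial term is exposed for noisy data. For β > 0 the
standard Picard fixed-point updates are used; the objective trace is
recorded and a warning (not an error) is raised in the rare event of an
increase. Parameters: fuzziness q = 2 (conventional choice; q > 1
required), β = 0 by default, convergence at 10⁻⁶ relative objective change,
200-iteration cap with warn-and-return-best on non-convergence.

Initialization places centroids at the 25th/50th/75th percentiles of the
masked intensities — deterministic, so identical inputs give identical
results; the seed argument is reserved for optional random restarts.
Voxels exactly at a centroid receive a one-hot membership. Classes are
sorted by centroid after convergence so GM is always the lowest-intensity
class and WM the highest.

## Thresholding and cleanup

Hard labels are assigned sequentially and exclusively with strict
inequalities: WM := u_WM > 0.1, then mGM := u_mGM > 0.5 among the rest,
then GM := u_GM > 0.5 among the rest; mask voxels passing no threshold stay
background (they fall on the CSF side of the pial boundary). The loosened
WM threshold counters partial-volume shrinkage of thin gyral WM blades and,
because WM is carved out first, provably moves only the mGM/WM boundary.
Strictness at 0.5 is a documented choice; an inclusive reading would differ
only on measure-zero ties.

Cleanup operations, in order, with fixed connectivity conventions
(26-connectivity for component analysis, 6-connectivity for erosion):

* **Largest WM component.** Smaller 26-connected WM islands are demoted to
  mGM; equal-size ties keep the component containing the lexicographically
  smallest voxel index.
* **Inner-boundary smoothing.** The mGM+WM region is opened then closed
  with a discrete ball of diameter 2 mm (per-axis voxel radius
  round(1 mm/spacing), minimum 1). Opening-then-closing is one reasonable
  reading of "morphological smoothing" — the original operation's exact
  semantics are tool-specific and undocumented — and is recorded as an
  approximation. WM is re-unioned afterwards and the result clipped to the
  cortex so nesting is never violated.
* **Pial stripping.** Inner tissue intersected with the 1-voxel
  6-connectivity erosion of the cortex; demoted voxels become GM, so no
  mGM/WM voxel touches the pial surface.

The nesting invariant R_WM ⊆ R_inner ⊆ R_cortex is asserted after every
operation.

## Levelsets and thickness

`signed_distance` computes the exact Euclidean distance transform
(scipy.ndimage) to opposite-class voxel centers, subtracts half the
smallest voxel size, and signs the result positive inside. This places the
zero crossing on the voxel faces between labeled and unlabeled voxels
(half-voxel convention) and keeps boundary voxels within half a voxel
diagonal of the zero set. The convention shifts absolute distances by up to
half a voxel, but the shift largely cancels in the levelset differences
that define the thickness metrics. The exact transform was preferred over
fast marching because it admits an independent brute-force oracle
(nearest-neighbor search against opposite-class voxel centers) to
10⁻⁶ mm.

The pial band is the set of voxels with |φ_CSF/GM| under half a voxel
diagonal. There, G = φ_CSF/GM − φ_GM/mGM, T = φ_CSF/GM − φ_mGM/WM,
M = T − G (exact by construction) and P = M/T with P = 0 where T = 0.
Values are propagated to every cortex voxel by nearest-pial-voxel
assignment — the propagation rule is a package choice, as is evaluating on
a half-diagonal band rather than only at exact zero crossings. Non-cortex
voxels hold NaN in memory and 0 on disk next to a validity mask. Negative
M (non-nested segmentations) is counted and logged but never clamped, so
quality control can see it.

On digital geometry two caveats apply: individual pial voxels can deviate
from analytic truth by up to ~0.75 voxel (lattice quantization), so
accuracy statements are about pial means; and the finite-difference
gradient magnitude of φ dips below 0.8 at a minority of boundary voxels
where the digital surface is faceted.

## Synthetic phantoms

`generate_phantom` builds cerebrum-masked ratio images with analytic
ground truth. The default spherical shell uses pial / GM-mGM / mGM-WM
radii of 24 / 20 / 17 mm on a 64³ 1 mm grid — T = 7, G = 4, M = 3 mm,
proportions in the physiological range — with unit class contrast
(intensities 1, 2, 3) and additive Gaussian noise of sd 0.05 (5% of the
adjacent-class contrast). Gaussian rather than Rician noise is used
because the intended inputs are high-SNR magnitude sums where the Gaussian
approximation is adequate. The bias field is a degree-2 polynomial in
normalized coordinates scaled to a peak fractional amplitude; its
smoothness guarantees near-cancellation in the ratio. The paired T1w/PDw
generator gives the PDw channel whole-grid coverage (as in a whole-head
acquisition) so the median filter sees no signal void at the mask rim.
A folded-shell geometry perturbs all layer radii by a common sinusoidal
term — the radial layer separations, and hence the stated truth, are
unchanged, though the true perpendicular thickness deviates slightly from
radial for strongly folded surfaces. Optional ×3 supersampling with
box-averaging simulates partial volume at interfaces (off by default).

Cohorts (`make_cohort`) jitter the layer thicknesses between subjects
(default fractional sd 0.02) and scale the G and/or M layer of the case
group by (1 − effect), rebuilding radii from a fixed inner radius so the
two layers vary independently. For calibration studies that need hundreds
of cohorts, `simulate_summary_cohort` draws subject-level ROI means
directly from Gaussian group models instead of generating images.

What phantom validation shows: the segmentation, levelset and statistics
machinery recover known laminar geometry to sub-voxel accuracy under noise
and bias. What it does not show: performance under real cortical folding,
partial-volume mixing at 1 mm, regionally varying myelination, or
segmentation-contrast failure modes — phantom class intensities are exactly
piecewise-constant, which real cortex is not.

## Group statistics

ROI summaries are means/sds over ROI voxels with defined metrics (undefined
voxels excluded and counted). Atlas averaging is a voxelwise mean over
co-registered subjects, restricted to voxels defined in ≥ 50% of them.
`group_compare` runs a one-way ANOVA with Tukey HSD at α = 0.05; the
Anderson–Darling normality test (per group) and Levene's variance test
(chosen for robustness to non-normality) are reported as gates that warn
but do not abort. With two groups the ANOVA is equivalent to the two-sample
t-test and the t statistic is exposed. No multiple-testing correction is
applied across metrics or ROIs by default. `detectable_effect` solves the
two-sided two-sample noncentral-t power equation for the standardized
effect size and reports it as a percent of the control mean; doubling the
control sd exactly doubles the result.

Problem sizes for the calibration studies — 400 null cohorts for the
type-I error rate, 200 replicate cohorts for empirical power, 10⁴
Monte-Carlo replicates for the power curve, n = 10 per group — are the
package's standard validation settings and run at summary level, where a
full imaging simulation would add nothing to the statistical question.

## Known limitations

* The two-band laminar model ignores regional myeloarchitecture variants
  (e.g. discontinuous Bands of Baillarger).
* The morphological-smoothing semantics are an approximation of an
  undocumented operation; results near high-curvature GM/mGM boundaries
  depend on it.
* Thickness is measured from levelset differences at the pial band, not
  from coupled surfaces or streamlines; for strongly curved cortex the
  metrics are a radial-style approximation.
* Only the WM membership threshold mitigates partial volume; no explicit
  partial-volume model is fitted.
* Atlas averaging assumes inputs are already co-registered on a shared
  grid; no registration is performed or checked beyond grid compatibility.
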