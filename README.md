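# mcthick — myelinated cortical thickness mapping

`mcthick` measures how much of the cerebral cortex's depth is myelinated,
from a single MRI volume with strong intracortical contrast. Intracortical
myelin concentrates in the deep cortical layers (IV–VI), so on a heavily
T1-weighted image the cortical depth splits into a lightly myelinated
superficial band and a heavily myelinated deep band. The package segments
the cerebrum into three intensity classes — lightly myelinated gray matter
(GM), heavily myelinated gray matter (mGM) and white matter (WM) — and
turns the nested class boundaries into four thickness metrics. It is aimed
at neuroimaging researchers who want a morphological (thickness-based)
rather than signal-based readout of intracortical myelin, e.g. for group
studies of psychiatric or neurodegenerative disease.

## Method

1. **Ratio image.** The T1-weighted volume is divided by a median-filtered
   (5 × 5 × 5 mm kernel) proton-density-weighted volume. Both acquisitions
   share the receive-field inhomogeneity, so the quotient cancels it while
   keeping the myelin-driven T1w contrast. The result is masked to the
   cerebrum (cortex + underlying white matter).
2. **Three-class segmentation.** The masked ratio image is clustered by
   fuzzy c-means with an optional spatial regularization term that
   penalizes neighborhood disagreement over the 6-neighborhood. Membership
   functions are binarized sequentially with strict thresholds —
   WM: u_WM > 0.1 (loosened from 0.5 to counter partial-volume erosion of
   thin gyral WM blades; this moves only the mGM/WM boundary), then
   mGM: u_mGM > 0.5, then GM: u_GM > 0.5 — giving nested regions
   R_WM ⊆ R_inner ⊆ R_cortex. Cleanup: WM keeps its largest connected
   component; the GM/mGM boundary is smoothed with a 2 mm morphological
   kernel; inner-tissue voxels on the pial surface are stripped.
3. **Levelset thickness.** Each boundary (CSF/GM, GM/mGM, mGM/WM) gets a
   signed Euclidean distance function φ (mm, positive inside). At the pial
   surface,

       G = φ_CSF/GM − φ_GM/mGM        (unmyelinated thickness)
       T = φ_CSF/GM − φ_mGM/WM        (total cortical thickness)
       M = T − G                      (myelinated thickness)
       P = M / T                      (proportional myelinated thickness)

   and the values are propagated through the cortical ribbon and embedded
   in 3D volumes.
4. **Group statistics.** Subject-level ROI means feed a one-way ANOVA with
   Tukey HSD (gated by Anderson–Darling normality and Levene
   equal-variance checks), plus a noncentral-t power analysis that reports
   the minimal detectable percent difference in group means at a given
   sample size, α and power.

Because no scan data ship with the package, a synthetic-phantom module
generates cerebrum-masked ratio images (spherical shells, folded shells or
slabs) with known layer thicknesses, additive Gaussian noise and a smooth
multiplicative bias field, so the whole pipeline can be validated against
analytic ground truth.

## Worked example

```python
import mcthick as mt

spec = mt.PhantomSpec(seed=42)          # 64³ 1 mm shell, truth T=7, G=4, M=3 mm
ratio, truth = mt.generate_phantom(spec)

mem = mt.fcm_segment(ratio, truth.mask)
labels = mt.build_nested_labels(mem)     # WM > 0.1, mGM > 0.5, GM > 0.5
labels = mt.keep_largest_component(labels)
labels = mt.smooth_inner_boundary(labels, kernel_mm=2.0)
labels = mt.strip_pial_voxels(labels)

maps, levelsets = mt.thickness_from_labels(labels)
pial = maps.pial
print(f"centroids: {mem.centroids.round(3)}")
for k, true in (("T", truth.T), ("G", truth.G), ("M", truth.M), ("P", truth.P)):
    v = getattr(maps, k)[pial].mean()
    print(f"{k}: measured {v:.2f} (truth {true:.2f})")
```

prints

```
centroids: [1. 2. 3.]
T: measured 6.69 (truth 7.00)
G: measured 3.74 (truth 4.00)
M: measured 2.95 (truth 3.00)
P: measured 0.44 (truth 0.43)
```

The clustering recovers the three class intensities exactly, and the
pial-mean thicknesses land within half a voxel of the analytic truth; the
identities M = T − G and P = M/T hold by construction at every defined
voxel.

The same pipeline is available from the shell:

```bash
mcthick phantom --out-dir work/                      # synthetic inputs
mcthick preprocess --t1w work/t1w.nii.gz --pdw work/pdw.nii.gz \
    --mask work/mask.nii.gz --out work/ratio.nii.gz
mcthick segment --ratio work/ratio.nii.gz --mask work/mask.nii.gz \
    --out-labels work/labels.nii.gz
mcthick thickness --labels work/labels.nii.gz --out-prefix work/subj1_
mcthick run --out-dir work/full/                     # all stages + provenance
```

`mcthick run` writes every artifact with a manifest and the effective
configuration, and skips stages whose inputs and parameters are unchanged.

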