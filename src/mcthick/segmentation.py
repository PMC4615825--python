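"""Three-class tissue segmentation of the cerebrum-masked ratio image.

The cerebrum is clustered into lightly myelinated gray matter (GM),
heavily myelinated gray matter (mGM) and white matter (WM) with a fuzzy
c-means algorithm carrying an optional spatial regularization term that
penalizes neighborhood disagreement (a Pham-style membership penalty
over the 6-neighborhood). T1-weighted signal increases with myelin
density, so after sorting the class centroids by intensity, GM is the
lowest-intensity class and WM the highest.

Hard labels are then obtained by sequential, exclusive thresholding of
the membership functions — WM first (threshold 0.1, loosened from 0.5 to
counter partial-volume erosion of thin gyral white-matter blades), then
mGM (0.5), then GM (0.5) — followed by morphological cleanup: the WM
mass is reduced to its largest connected component, the inner (mGM+WM)
boundary is smoothed, and any inner-tissue voxel touching the pial
surface is stripped back to GM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import MaskVolume, Volume3D, require_grid_compatible

__all__ = [
    "MembershipSet",
    "NestedLabels",
    "FuzzyCMeans",
    "fcm_segment",
    "build_nested_labels",
    "keep_largest_component",
    "smooth_inner_boundary",
    "strip_pial_voxels",
    "fcm_objective",
]

CLASS_NAMES = ("GM", "mGM", "WM")
LBL_BG, LBL_GM, LBL_MGM, LBL_WM = 0, 1, 2, 3

# connectivity conventions, fixed across the package:
# 26-connectivity for connected-component analysis, 6-connectivity for erosion
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MembershipSet:
    """Soft three-class memberships on the cerebrum mask.

    ``memberships[..., k]`` is the probability of class ``k`` with classes
    ordered GM < mGM < WM by centroid intensity. Memberships are 0 outside
    the mask and sum to 1 on every mask voxel.
    """

    memberships: np.ndarray          # (nx, ny, nz, 3)
    centroids: np.ndarray            # (3,) strictly increasing
    mask: np.ndarray                 # boolean cerebrum mask
    affine: np.ndarray
    objective_trace: list = field(default_factory=list)
    converged: bool = True

    def class_volume(self, k: int) -> Volume3D:
        return Volume3D(self.memberships[..., k].astype(np.float32),
                        affine=self.affine, unit="probability")

    @property
    def u_gm(self) -> np.ndarray:
        return self.memberships[..., 0]

    @property
    def u_mgm(self) -> np.ndarray:
        return self.memberships[..., 1]

    @property
    def u_wm(self) -> np.ndarray:
        return self.memberships[..., 2]


@dataclass
class NestedLabels:
    """Hard labels {0: background, 1: GM, 2: mGM, 3: WM} with nested regions.

    The derived masks satisfy R_WM ⊆ R_inner ⊆ R_cortex.
    """

    labels: np.ndarray               # int8 volume
    affine: np.ndarray

    @property
    def r_wm(self) -> np.ndarray:
        """White matter region."""
        return self.labels == LBL_WM

    @property
    def r_inner(self) -> np.ndarray:
        """mGM + WM: everything inside the GM/mGM boundary."""
        return self.labels >= LBL_MGM

    @property
    def r_cortex(self) -> np.ndarray:
        """GM + mGM + WM: everything inside the pial (CSF/GM) boundary."""
        return self.labels >= LBL_GM

    def check_nesting(self) -> None:
        if not (self.r_wm <= self.r_inner).all() or not (self.r_inner <= self.r_cortex).all():
            raise AssertionError("label nesting R_WM ⊆ R_inner ⊆ R_cortex violated")

    def volume(self) -> Volume3D:
        return Volume3D(self.labels.astype(np.int16), affine=self.affine, unit="label")

    def copy(self) -> "NestedLabels":
        return NestedLabels(self.labels.copy(), self.affine.copy())


def _neighbor_sum(x: np.ndarray) -> np.ndarray:
    """Sum of x over the 6-neighborhood of each voxel (zero outside grid)."""
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1
    return ndimage.correlate(x, kernel, mode="constant", cval=0.0)


def fcm_objective(y: np.ndarray, u: np.ndarray, c: np.ndarray, q: float,
                  beta: float, mask: np.ndarray) -> float:
    """Value of the regularized clustering objective

    J = Σ_j Σ_k u_jk^q (y_j − c_k)² + (β/2) Σ_j Σ_k u_jk^q Σ_{n∈N_j} Σ_{m≠k} u_nm^q

    with N_j the 6-neighborhood of voxel j, summed over mask voxels.
    """
    uq = np.where(mask[..., None], u, 0.0) ** q
    d2 = (y[..., None] - c[None, None, None, :]) ** 2
    data_term = float(np.sum(uq * d2, where=mask[..., None]))
    if beta == 0:
        return data_term
    nsum = np.stack([_neighbor_sum(uq[..., k]) for k in range(uq.shape[-1])], axis=-1)
    total = nsum.sum(axis=-1, keepdims=True)
    penalty = float(np.sum(uq * (total - nsum), where=mask[..., None]))
    return data_term + 0.5 * beta * penalty


class FuzzyCMeans:
    """Spatially regularized fuzzy c-means over a masked 3D image.

    Parameters
    ----------
    n_classes : int
        Number of intensity classes (3 for GM/mGM/WM).
    q : float
        Fuzziness exponent, > 1. ``q=2`` is the conventional choice.
    beta : float
        Weight of the neighborhood-disagreement penalty; 0 recovers
        plain fuzzy c-means.
    tol : float
        Convergence threshold on the relative change of the objective.
    max_iter : int
        Iteration cap; non-convergence yields a warning and the best
        iterate, never an exception.
    seed : int
        Reserved for optional random restarts; the default percentile
        initialization is deterministic and ignores it.
    """

    def __init__(self, n_classes: int = 3, q: float = 2.0, beta: float = 0.0,
                 tol: float = 1e-6, max_iter: int = 200, seed: int = 0):
        if q <= 1:
            raise ValueError("fuzziness q must be > 1")
        if beta < 0:
            raise ValueError("spatial weight beta must be >= 0")
        self.n_classes = n_classes
        self.q = q
        self.beta = beta
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _init_centroids(self, values: np.ndarray) -> np.ndarray:
        # percentiles spread evenly in (0, 100): 25/50/75 for three classes
        ps = 100.0 * (np.arange(1, self.n_classes + 1)) / (self.n_classes + 1)
        c = np.percentile(values, ps)
        # nudge coincident centroids apart so distances are distinct
        for k in range(1, len(c)):
            if c[k] <= c[k - 1]:
                c[k] = c[k - 1] + 1e-6 * max(1.0, abs(c[k - 1]))
        return c

    def fit(self, image: np.ndarray, mask: np.ndarray,
            affine: np.ndarray | None = None,
            init_centroids=None) -> MembershipSet:
        """Cluster masked voxels; returns memberships sorted by centroid."""
        y = np.asarray(image, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        vals = y[mask]
        if vals.size == 0:
            raise ValueError("mask is empty")
        if np.unique(vals).size < self.n_classes:
            raise ValueError(
                f"need at least {self.n_classes} distinct intensities inside the "
                f"mask, found {np.unique(vals).size} (degenerate clustering)"
            )
        c = (np.sort(np.asarray(init_centroids, dtype=float))
             if init_centroids is not None else self._init_centroids(vals))
        q, beta = self.q, self.beta
        expo = 1.0 / (q - 1.0)
        m4 = mask[..., None]
        u = np.zeros(y.shape + (self.n_classes,))
        trace: list[float] = []
        converged = False

        for _ in range(self.max_iter):
            # membership update: u_jk ∝ d_jk^{-1/(q-1)} with
            # d_jk = (y_j - c_k)^2 + beta * Σ_{n∈N_j} Σ_{m≠k} u_nm^q
            d = (y[..., None] - c[None, None, None, :]) ** 2
            if beta > 0:
                uq = u ** q
                nsum = np.stack([_neighbor_sum(uq[..., k])
                                 for k in range(self.n_classes)], axis=-1)
                d = d + beta * (nsum.sum(axis=-1, keepdims=True) - nsum)
            zero = d <= 0
            any_zero = zero.any(axis=-1, keepdims=True)
            inv = np.where(any_zero, 1.0, d) ** (-expo)
            u = np.where(any_zero,
                         zero / np.maximum(zero.sum(axis=-1, keepdims=True), 1),
                         inv / inv.sum(axis=-1, keepdims=True))
            u = np.where(m4, u, 0.0)

            # centroid update (the spatial penalty does not involve c)
            uq = u ** q
            num = np.einsum("xyzk,xyz->k", uq, y)
            den = uq.reshape(-1, self.n_classes).sum(axis=0)
            c = num / np.maximum(den, 1e-300)

            j = fcm_objective(y, u, c, q, beta, mask)
            if trace and j > trace[-1] * (1 + 1e-12):
                warnings.warn(f"objective increased at iteration {len(trace)} "
                              f"({trace[-1]:.6g} -> {j:.6g})", RuntimeWarning)
            trace.append(j)
            if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= self.tol * max(abs(trace[-2]), 1e-300):
                converged = True
                break

        if not converged:
            warnings.warn(f"fuzzy c-means did not converge in {self.max_iter} "
                          "iterations; returning best iterate", RuntimeWarning)

        order = np.argsort(c)
        c = c[order]
        u = u[..., order]
        if not np.all(np.diff(c) > 0):
            raise ValueError("class centroids collapsed; clustering is degenerate")
        return MembershipSet(
            memberships=u, centroids=c, mask=mask,
            affine=np.eye(4) if affine is None else np.asarray(affine),
            objective_trace=trace, converged=converged,
        )


def fcm_segment(ratio: Volume3D, mask: MaskVolume, n_classes: int = 3,
                q: float = 2.0, beta: float = 0.0, tol: float = 1e-6,
                max_iter: int = 200, seed: int = 0) -> MembershipSet:
    """Cluster the cerebrum-masked ratio image into tissue classes.

    Returns memberships with classes sorted by centroid intensity
    (GM lowest, WM highest).
    """
    require_grid_compatible(ratio, mask)
    mask.require_nonempty()
    model = FuzzyCMeans(n_classes=n_classes, q=q, beta=beta, tol=tol,
                        max_iter=max_iter, seed=seed)
    return model.fit(ratio.data, mask.bool_data, affine=ratio.affine)


def build_nested_labels(m: MembershipSet, wm_threshold: float = 0.1,
                        mgm_threshold: float = 0.5,
                        gm_threshold: float = 0.5) -> NestedLabels:
    """Binarize memberships into nested hard labels.

    Assignment is sequential and exclusive with strict inequalities:
    WM := u_WM > wm_threshold; then mGM := u_mGM > mgm_threshold among the
    rest; then GM := u_GM > gm_threshold among the rest. Mask voxels that
    pass no threshold stay background (CSF side of the pial boundary).
    Because WM is carved out of the inner region first, lowering
    ``wm_threshold`` moves only the mGM/WM boundary; the GM/mGM boundary
    (the union of WM and mGM voxels) is untouched.
    """
    for name, t in (("wm", wm_threshold), ("mgm", mgm_threshold), ("gm", gm_threshold)):
        if not 0 < t < 1:
            raise ValueError(f"{name}_threshold must lie in (0, 1), got {t}")
    labels = np.zeros(m.memberships.shape[:3], dtype=np.int8)
    inside = m.mask
    wm = inside & (m.u_wm > wm_threshold)
    mgm = inside & ~wm & (m.u_mgm > mgm_threshold)
    gm = inside & ~wm & ~mgm & (m.u_gm > gm_threshold)
    labels[wm] = LBL_WM
    labels[mgm] = LBL_MGM
    labels[gm] = LBL_GM
    out = NestedLabels(labels, m.affine)
    out.check_nesting()
    return out


def keep_largest_component(labels: NestedLabels) -> NestedLabels:
    """Keep only the largest 26-connected WM component; demote the rest to mGM.

    Ties between equal-size components are broken toward the component
    containing the lexicographically smallest voxel index.
    """
    wm = labels.r_wm
    if not wm.any():
        raise ValueError("white-matter region is empty")
    comp, n = ndimage.label(wm, structure=_STRUCT_26)
    if n > 1:
        sizes = np.bincount(comp.ravel())[1:]
        best = int(np.argmax(sizes)) + 1  # argmax takes the first (lowest
        # label id) maximum; label ids follow raster order, so the tie-break
        # is the component with the lexicographically smallest voxel
        out = labels.copy()
        out.labels[wm & (comp != best)] = LBL_MGM
        out.check_nesting()
        return out
    return labels.copy()


def _ellipsoid_element(radius_vox: np.ndarray) -> np.ndarray:
    """Discrete ball/ellipsoid structuring element with per-axis voxel radii."""
    r = np.maximum(np.asarray(radius_vox, dtype=int), 1)
    grids = np.ogrid[tuple(slice(-ri, ri + 1) for ri in r)]
    return sum((g / ri) ** 2 for g, ri in zip(grids, r)) <= 1.0


def smooth_inner_boundary(labels: NestedLabels, kernel_mm: float = 2.0,
                          spacing=None) -> NestedLabels:
    """Morphologically smooth the GM/mGM boundary.

    The inner region (mGM + WM) is opened then closed with a ball element
    of diameter ``kernel_mm`` (per-axis voxel radius round(kernel_mm/2 /
    spacing), minimum 1). WM voxels are re-unioned afterwards so the
    WM region itself never changes, and the smoothed inner region is
    clipped to the cortex so nesting is preserved.
    """
    inner = labels.r_inner
    if not inner.any():
        raise ValueError("inner (mGM+WM) region is empty")
    if spacing is None:
        spacing = np.linalg.norm(np.asarray(labels.affine)[:3, :3], axis=0)
    radius = np.maximum(np.round(kernel_mm / 2.0 / np.asarray(spacing)), 1).astype(int)
    elem = _ellipsoid_element(radius)
    smoothed = ndimage.binary_closing(ndimage.binary_opening(inner, structure=elem),
                                      structure=elem)
    smoothed = (smoothed | labels.r_wm) & labels.r_cortex
    if not smoothed.any():
        raise ValueError("morphological smoothing removed the entire inner region")
    out = labels.copy()
    out.labels[labels.r_inner & ~smoothed] = LBL_GM      # demoted to GM
    out.labels[smoothed & ~labels.r_inner] = LBL_MGM     # filled by closing
    out.labels[labels.r_wm] = LBL_WM
    out.check_nesting()
    return out


def strip_pial_voxels(labels: NestedLabels) -> NestedLabels:
    """Remove inner-tissue voxels from the outermost cortical shell.

    The inner region is intersected with the 1-voxel (6-connectivity)
    erosion of the cortex, so no mGM or WM voxel lies on the pial
    surface; demoted voxels become GM.
    """
    cortex = labels.r_cortex
    if not cortex.any():
        raise ValueError("cortex region is empty")
    eroded = ndimage.binary_erosion(cortex, structure=_STRUCT_6, border_value=0)
    if not eroded.any():
        raise ValueError("1-voxel erosion removed the entire cortex")
    out = labels.copy()
    demote = labels.r_inner & ~eroded
    out.labels[demote] = LBL_GM
    out.check_nesting()
    return out
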