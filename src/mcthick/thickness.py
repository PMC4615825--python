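"""Levelset-based cortical thickness measurement.

Each nested tissue boundary (CSF/GM, GM/mGM, mGM/WM) is represented by a
signed Euclidean distance function φ, positive inside the enclosed
region and negative outside, in millimetres. Differences of levelsets
evaluated at the pial surface give the thickness metrics:

    G = φ_CSF/GM − φ_GM/mGM     (unmyelinated thickness)
    T = φ_CSF/GM − φ_mGM/WM     (total cortical thickness)
    M = T − G                   (myelinated thickness)
    P = M / T                   (proportional myelinated thickness)

The zero levelset is placed on the voxel faces between labeled and
unlabeled voxels (half-voxel convention): the distance transform
measures center-to-center distances, and half the smallest voxel size
is subtracted on each side so that boundary voxels sit half a voxel
from the zero crossing. This convention shifts absolute distances by up
to half a voxel but largely cancels in the levelset differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import MaskVolume, Volume3D, require_grid_compatible
from .segmentation import NestedLabels

__all__ = [
    "Levelset",
    "ThicknessMaps",
    "signed_distance",
    "thickness_at_pial",
    "thickness_from_labels",
    "sample_metric_on_surface",
]

logger = logging.getLogger(__name__)


@dataclass
class Levelset:
    """Signed distance volume (mm) for one nested tissue boundary."""

    phi: np.ndarray
    affine: np.ndarray
    region: str = ""

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def volume(self) -> Volume3D:
        return Volume3D(self.phi.astype(np.float32), affine=self.affine, unit="mm")


@dataclass
class ThicknessMaps:
    """T, G, M (mm) and P thickness volumes with a shared validity mask.

    Values are defined on the pial band and propagated to the cortex by
    nearest-pial-voxel assignment; voxels outside the defined region hold
    NaN in memory (written as 0 on disk next to the validity mask).
    """

    T: np.ndarray
    G: np.ndarray
    M: np.ndarray
    P: np.ndarray
    defined: np.ndarray          # boolean: where the metrics are valid
    pial: np.ndarray             # boolean: the pial-band voxels
    affine: np.ndarray
    negative_m_count: int = 0

    def as_volumes(self) -> dict[str, Volume3D]:
        """Export as volumes; the NaN sentinel becomes 0 (see ``defined``)."""
        return {k: Volume3D(np.nan_to_num(getattr(self, k), nan=0.0).astype(np.float32),
                            affine=self.affine, unit="mm" if k != "P" else "ratio")
                for k in ("T", "G", "M", "P")}

    def qc_summary(self) -> dict:
        d = self.defined
        stats = {}
        for k in ("T", "G", "M", "P"):
            v = getattr(self, k)[self.pial]
            stats[k] = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))
                        if v.size > 1 else 0.0}
        return {
            "pial_voxel_count": int(self.pial.sum()),
            "defined_voxel_count": int(d.sum()),
            "negative_m_count": int(self.negative_m_count),
            "pial_stats": stats,
        }


def signed_distance(region: MaskVolume | np.ndarray, spacing=None,
                    affine=None, name: str = "") -> Levelset:
    """Exact signed Euclidean distance to a region's boundary surface.

    Positive inside the region, negative outside, in mm, with the zero
    crossing on the voxel faces between inside and outside voxels.
    """
    if isinstance(region, MaskVolume):
        mask = region.bool_data
        affine = region.affine
        spacing = region.spacing
    else:
        mask = np.asarray(region, dtype=bool)
        if spacing is None and affine is not None:
            spacing = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
        spacing = np.ones(3) if spacing is None else np.asarray(spacing, dtype=float)
        affine = np.diag(list(spacing) + [1.0]) if affine is None else np.asarray(affine)
    if not mask.any():
        raise ValueError("region is empty; signed distance undefined")
    if mask.all():
        raise ValueError("region covers the whole grid; it has no boundary")
    half = 0.5 * float(np.min(spacing))
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    phi = np.where(mask, d_in - half, -(d_out - half))
    return Levelset(phi=phi.astype(np.float64), affine=np.asarray(affine, dtype=float),
                    region=name)


def _pial_band(phi_csf_gm: Levelset) -> np.ndarray:
    half_diag = 0.5 * float(np.linalg.norm(phi_csf_gm.spacing))
    return np.abs(phi_csf_gm.phi) < half_diag


def thickness_at_pial(phi_csf_gm: Levelset, phi_gm_mgm: Levelset,
                      phi_mgm_wm: Levelset,
                      negative_g_warn_fraction: float = 0.01) -> ThicknessMaps:
    """Evaluate T, G, M, P at the pial surface and propagate through the cortex.

    The pial band is the set of voxels within half a voxel diagonal of the
    CSF/GM zero crossing. On that band G = φ_CSF/GM − φ_GM/mGM,
    T = φ_CSF/GM − φ_mGM/WM, M = T − G and P = M/T (P = 0 where T = 0).
    Values are propagated to every cortex voxel (φ_CSF/GM > 0) by
    nearest-pial-voxel assignment; other voxels are NaN.
    """
    vols = [Levelset.volume(l) for l in (phi_csf_gm, phi_gm_mgm, phi_mgm_wm)]
    require_grid_compatible(*vols)
    pial = _pial_band(phi_csf_gm)
    if not pial.any():
        raise ValueError("no pial voxels found: CSF/GM levelset has no zero crossing")

    g_p = phi_csf_gm.phi - phi_gm_mgm.phi
    t_p = phi_csf_gm.phi - phi_mgm_wm.phi
    m_p = t_p - g_p
    with np.errstate(invalid="ignore", divide="ignore"):
        p_p = np.where(t_p != 0, m_p / t_p, 0.0)

    neg_g = int(np.count_nonzero(g_p[pial] < 0))
    if neg_g > negative_g_warn_fraction * pial.sum():
        logger.warning("non-nested regions: G < 0 on %d of %d pial voxels",
                       neg_g, int(pial.sum()))
    neg_m = int(np.count_nonzero(m_p[pial] < 0))
    if neg_m:
        logger.warning("M < 0 on %d pial voxels (segmentation pathology; "
                       "values retained, not clamped)", neg_m)

    # propagate by nearest pial voxel across the cortex (pial band included)
    spacing = phi_csf_gm.spacing
    defined = pial | (phi_csf_gm.phi > 0)
    _, idx = ndimage.distance_transform_edt(~pial, sampling=spacing,
                                            return_indices=True)
    maps = {}
    for key, src in (("T", t_p), ("G", g_p), ("M", m_p), ("P", p_p)):
        prop = src[tuple(idx)]
        out = np.full(src.shape, np.nan)
        out[defined] = prop[defined]
        maps[key] = out
    tm = ThicknessMaps(T=maps["T"], G=maps["G"], M=maps["M"], P=maps["P"],
                       defined=defined, pial=pial, affine=phi_csf_gm.affine,
                       negative_m_count=neg_m)
    return tm


def thickness_from_labels(labels: NestedLabels) -> tuple[ThicknessMaps, dict]:
    """Full thickness measurement from nested hard labels.

    Computes the three boundary levelsets and evaluates the metrics at
    the pial surface; returns the maps and the levelsets used.
    """
    spacing = np.linalg.norm(np.asarray(labels.affine)[:3, :3], axis=0)
    ls = {
        "csf_gm": signed_distance(labels.r_cortex, spacing=spacing,
                                  affine=labels.affine, name="CSF/GM"),
        "gm_mgm": signed_distance(labels.r_inner, spacing=spacing,
                                  affine=labels.affine, name="GM/mGM"),
        "mgm_wm": signed_distance(labels.r_wm, spacing=spacing,
                                  affine=labels.affine, name="mGM/WM"),
    }
    maps = thickness_at_pial(ls["csf_gm"], ls["gm_mgm"], ls["mgm_wm"])
    return maps, ls


def sample_metric_on_surface(maps: ThicknessMaps, metric: str,
                             surface_voxels: np.ndarray) -> pd.DataFrame:
    """Nearest-neighbor lookup of one metric at a set of surface voxels.

    ``surface_voxels`` is an (n, 3) integer array of voxel indices.
    Returns a table with columns i, j, k, value, defined; rows landing
    outside the defined-metric region are flagged (defined=False,
    value=NaN) rather than dropped.
    """
    if metric not in ("T", "G", "M", "P"):
        raise ValueError(f"unknown metric {metric!r}")
    vox = np.atleast_2d(np.asarray(surface_voxels, dtype=int))
    if vox.size == 0:
        return pd.DataFrame(columns=["i", "j", "k", "value", "defined"])
    if vox.shape[1] != 3:
        raise ValueError("surface voxels must be an (n, 3) index array")
    shape = maps.T.shape
    if (vox < 0).any() or (vox >= np.asarray(shape)).any():
        raise ValueError("surface voxel outside the image grid")
    field = getattr(maps, metric)
    vals = field[vox[:, 0], vox[:, 1], vox[:, 2]]
    ok = maps.defined[vox[:, 0], vox[:, 1], vox[:, 2]]
    return pd.DataFrame({"i": vox[:, 0], "j": vox[:, 1], "k": vox[:, 2],
                         "value": np.where(ok, vals, np.nan), "defined": ok})
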