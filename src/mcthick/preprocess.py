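"""Ratio-image construction.

Receive-field (B1-) intensity inhomogeneity multiplies both the
T1-weighted and the proton-density-weighted acquisitions by the same
smooth spatial field. Dividing the T1w image by a median-filtered PDw
image therefore cancels the field while keeping the T1w tissue contrast:
the median filter removes PDw tissue detail at scales below its kernel
but preserves the slowly varying bias, so the quotient is a "ratio"
image whose intensity tracks myelin-driven T1w contrast alone.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .volume_io import MaskVolume, Volume3D, require_grid_compatible

__all__ = ["median_filter_mm", "compute_ratio_image", "odd_window_voxels"]


def odd_window_voxels(kernel_mm: float, spacing_mm: float) -> int:
    """Nearest odd voxel window (>= 1) to ``kernel_mm / spacing_mm``.

    Exact ties between two odd candidates break toward the smaller window.
    """
    if kernel_mm <= 0:
        raise ValueError(f"kernel size must be positive, got {kernel_mm}")
    r = kernel_mm / spacing_mm
    lo = max(1, 2 * math.floor((r - 1) / 2) + 1)
    hi = lo + 2
    return lo if (r - lo) <= (hi - r) else hi


def median_filter_mm(v: Volume3D, kernel_mm) -> Volume3D:
    """3D median filter with a physical (mm) kernel size.

    ``kernel_mm`` is a scalar or per-axis triple; each axis uses the
    nearest odd voxel window to ``kernel_mm / spacing``. Edges are
    handled by reflecting the volume.
    """
    kernel_mm = np.broadcast_to(np.asarray(kernel_mm, dtype=float), (3,))
    if np.any(kernel_mm <= 0):
        raise ValueError(f"kernel size must be positive, got {kernel_mm}")
    size = tuple(odd_window_voxels(k, s) for k, s in zip(kernel_mm, v.spacing))
    filtered = ndimage.median_filter(np.asarray(v.data, dtype=np.float64),
                                     size=size, mode="reflect")
    return v.with_data(filtered.astype(v.data.dtype, copy=False))


def compute_ratio_image(t1w: Volume3D, pdw: Volume3D, mask: MaskVolume,
                        kernel_mm=5.0, eps_fraction: float = 1e-6) -> Volume3D:
    """T1w divided by median-filtered PDw, restricted to the cerebrum mask.

    Only the PDw image is filtered. The result is strictly positive on
    mask voxels and exactly 0 outside the mask (the unmasked ratio
    background is ill-behaved, so it is forced to zero before any
    segmentation).

    Raises
    ------
    ValueError
        If the filtered PDw falls at or below ``eps_fraction`` times its
        masked median on any mask voxel (division guard), reporting the
        number of offending voxels.
    """
    require_grid_compatible(t1w, pdw, mask)
    mask.require_nonempty()
    m = mask.bool_data
    pdw_f = median_filter_mm(pdw, kernel_mm).data.astype(np.float64)
    guard = eps_fraction * float(np.median(pdw_f[m]))
    bad = int(np.count_nonzero(pdw_f[m] <= guard))
    if bad:
        raise ValueError(
            f"filtered PDw is <= {guard:.3g} on {bad} mask voxel(s); "
            "cannot form a well-defined ratio image"
        )
    ratio = np.zeros(t1w.shape, dtype=np.float64)
    ratio[m] = np.asarray(t1w.data, dtype=np.float64)[m] / pdw_f[m]
    out = t1w.with_data(ratio.astype(np.float32), unit="ratio")
    return out
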