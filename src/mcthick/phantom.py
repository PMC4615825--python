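"""Synthetic laminar phantoms with known thickness ground truth.

The generator emulates a cerebrum-masked ratio image: three nested
tissue layers (lightly myelinated gray matter, heavily myelinated gray
matter, white matter) with piecewise-constant class intensities ordered
c_GM < c_mGM < c_WM, corrupted by additive Gaussian noise and a smooth
multiplicative bias field. Because every layer boundary is analytic
(spheres, perturbed spheres, or planes), the true total (T),
unmyelinated (G), myelinated (M) and proportional (P) thicknesses are
known exactly, which makes the full segmentation → levelset → thickness
pipeline testable without any scan data.

Defaults model the study conditions the method targets: a 1 mm
isotropic grid, 64³ voxels, a spherical shell with pial / GM-mGM /
mGM-WM radii of 24 / 20 / 17 mm (so T = 7, G = 4, M = 3 mm — cortical
layer proportions in the physiological range), unit class contrast and
additive noise at 5% of that contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .volume_io import MaskVolume, Volume3D

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom",
           "generate_paired_t1w_pdw", "make_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic laminar phantom.

    ``r_pial > r_gm_mgm > r_wm_inner`` are the radii (mm) of the CSF/GM,
    GM/mGM and mGM/WM boundaries for shell geometries; for the slab they
    are the z-positions (mm from the slab base) of the same boundaries.
    ``noise_sd`` is the additive Gaussian standard deviation in intensity
    units; ``bias_amplitude`` is the peak fractional deviation of a smooth
    (degree <= 2 polynomial) multiplicative field.
    """

    geometry: str = "spherical_shell"     # spherical_shell | folded_shell | slab
    r_pial: float = 24.0
    r_gm_mgm: float = 20.0
    r_wm_inner: float = 17.0
    intensities: tuple = (1.0, 2.0, 3.0)  # (c_GM, c_mGM, c_WM)
    noise_sd: float = 0.05
    bias_amplitude: float = 0.0
    spacing: tuple = (1.0, 1.0, 1.0)
    shape: tuple = (64, 64, 64)
    fold_amplitude: float = 1.5           # mm, folded_shell only
    fold_frequency: int = 4               # angular lobes, folded_shell only
    seed: int = 0

    def __post_init__(self):
        if not (self.r_pial > self.r_gm_mgm > self.r_wm_inner > 0):
            raise ValueError("radii must satisfy r_pial > r_gm_mgm > r_wm_inner > 0")
        c = self.intensities
        if not (c[0] < c[1] < c[2]):
            raise ValueError("class intensities must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")
        if self.geometry not in ("spherical_shell", "folded_shell", "slab"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def truth_thicknesses(self) -> dict:
        """Analytic ground-truth T, G, M, P (radial/through-plane distances)."""
        t = self.r_pial - self.r_wm_inner
        g = self.r_pial - self.r_gm_mgm
        m = t - g
        return {"T": t, "G": g, "M": m, "P": m / t}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    labels: np.ndarray            # {0 bg, 1 GM, 2 mGM, 3 WM}
    mask: MaskVolume              # cerebrum mask (all tissue)
    T: float
    G: float
    M: float
    P: float
    spec: PhantomSpec = None

    def __post_init__(self):
        assert abs(self.T - (self.G + self.M)) < 1e-12
        assert abs(self.P - self.M / self.T) < 1e-12


def _affine(spec: PhantomSpec) -> np.ndarray:
    a = np.diag(list(spec.spacing) + [1.0])
    return a


def _coords_mm(spec: PhantomSpec):
    """Voxel-center physical coordinates relative to the grid center."""
    axes = [ (np.arange(n) - (n - 1) / 2.0) * s
             for n, s in zip(spec.shape, spec.spacing) ]
    return np.meshgrid(*axes, indexing="ij")


def _layer_labels(spec: PhantomSpec) -> np.ndarray:
    """Hard ground-truth labels from the analytic geometry, by voxel center."""
    x, y, z = _coords_mm(spec)
    if spec.geometry == "slab":
        # layers stacked along z from the base plane at z = -r_pial/2
        depth = z - z.min()
        wm = depth < spec.r_wm_inner
        inner = depth < spec.r_gm_mgm
        cortex = depth < spec.r_pial
    else:
        r = np.sqrt(x**2 + y**2 + z**2)
        if spec.geometry == "folded_shell":
            # common additive sinusoidal perturbation of all radii, so the
            # radial layer separations (the ground truth) are unchanged
            with np.errstate(invalid="ignore"):
                theta = np.arctan2(np.sqrt(x**2 + y**2), z)
                phi_ang = np.arctan2(y, x)
            delta = spec.fold_amplitude * np.sin(spec.fold_frequency * theta) \
                * np.cos(spec.fold_frequency * phi_ang)
        else:
            delta = 0.0
        wm = r < spec.r_wm_inner + delta
        inner = r < spec.r_gm_mgm + delta
        cortex = r < spec.r_pial + delta
    labels = np.zeros(spec.shape, dtype=np.int8)
    labels[cortex] = 1
    labels[inner] = 2
    labels[wm] = 3
    return labels


def _check_fits(spec: PhantomSpec) -> None:
    margin = spec.r_pial + (spec.fold_amplitude if spec.geometry == "folded_shell" else 0)
    half_extent = np.array([(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)])
    if spec.geometry != "slab" and np.any(margin > half_extent - 2 * np.asarray(spec.spacing)):
        raise ValueError("phantom geometry exceeds the grid (need a >= 2-voxel margin)")
    min_layer = min(spec.r_pial - spec.r_gm_mgm, spec.r_gm_mgm - spec.r_wm_inner)
    if min_layer < max(spec.spacing):
        import warnings
        warnings.warn("a phantom layer is thinner than one voxel "
                      "(partial-volume stress test)", UserWarning)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: 1 + amplitude * normalized quadratic."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.shape)
    coords = [np.linspace(-1, 1, n) for n in spec.shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    coef = rng.uniform(-1, 1, size=9)
    p = (coef[0] * x + coef[1] * y + coef[2] * z
         + coef[3] * x * y + coef[4] * y * z + coef[5] * x * z
         + coef[6] * x**2 + coef[7] * y**2 + coef[8] * z**2)
    p = p / max(np.abs(p).max(), 1e-12)
    return 1.0 + spec.bias_amplitude * p


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Synthesize a cerebrum-masked ratio image and its ground truth.

    Voxel values inside the mask are the class intensity times the bias
    field plus Gaussian noise; background is 0. Deterministic given
    ``spec.seed``.
    """
    _check_fits(spec)
    rng = np.random.default_rng(spec.seed)
    labels = _layer_labels(spec)
    mask = labels > 0
    c = np.array((0.0,) + tuple(spec.intensities))
    img = c[labels]
    img *= _bias_field(spec, rng)
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(spec.shape)
    img[~mask] = 0.0
    affine = _affine(spec)
    truth = PhantomTruth(labels=labels,
                         mask=MaskVolume(mask.astype(np.uint8), affine=affine),
                         spec=spec, **spec.truth_thicknesses)
    return Volume3D(img.astype(np.float32), affine=affine, unit="ratio"), truth


def generate_paired_t1w_pdw(spec: PhantomSpec) -> tuple[Volume3D, Volume3D, MaskVolume]:
    """Synthesize a T1w / PDw pair sharing one bias field.

    T1w carries the tissue contrast times the bias; PDw is a constant
    tissue value times the same bias, so dividing T1w by (median-filtered)
    PDw cancels the bias up to noise and filter edge effects. Like a real
    whole-head proton-density acquisition, the PDw signal covers the whole
    grid (tissue surrounds the cerebrum), so the median filter sees no
    signal void at the mask rim.
    """
    _check_fits(spec)
    rng = np.random.default_rng(spec.seed)
    labels = _layer_labels(spec)
    mask = labels > 0
    bias = _bias_field(spec, rng)
    c = np.array((0.0,) + tuple(spec.intensities))
    t1w = c[labels] * bias
    pdw_level = 2.0 * max(spec.intensities)
    pdw = pdw_level * bias
    if spec.noise_sd > 0:
        t1w = t1w + spec.noise_sd * rng.standard_normal(spec.shape)
        pdw = pdw + spec.noise_sd * rng.standard_normal(spec.shape)
    t1w[~mask] = 0.0
    affine = _affine(spec)
    return (Volume3D(t1w.astype(np.float32), affine=affine, unit="intensity"),
            Volume3D(pdw.astype(np.float32), affine=affine, unit="intensity"),
            MaskVolume(mask.astype(np.uint8), affine=affine))


def make_cohort(template: PhantomSpec, n_subjects: int = 10,
                effect: dict | None = None, jitter_sd: float = 0.02,
                seed: int = 0) -> list[dict]:
    """Simulate a two-group cohort of phantoms on a shared grid.

    Controls get between-subject fractional jitter (sd ``jitter_sd``) on
    the layer thicknesses; cases additionally have the G and/or M layer
    scaled by (1 − effect[metric]). Layer radii are rebuilt from the
    jittered thicknesses on a fixed inner radius, so changing M leaves G
    untouched and vice versa.

    Returns a list of records: {subject, group, spec, ratio, truth}.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    effect = effect or {}
    for k, e in effect.items():
        if k not in ("G", "M"):
            raise ValueError(f"effect keys must be 'G' or 'M', got {k!r}")
        if abs(e) >= 1:
            raise ValueError("effect magnitudes must be < 1")
    rng = np.random.default_rng(seed)
    g0 = template.r_pial - template.r_gm_mgm
    m0 = template.r_gm_mgm - template.r_wm_inner
    records = []
    for group in ("control", "case"):
        for i in range(n_subjects):
            g = g0 * (1 + jitter_sd * rng.standard_normal())
            m = m0 * (1 + jitter_sd * rng.standard_normal())
            if group == "case":
                g *= 1 - effect.get("G", 0.0)
                m *= 1 - effect.get("M", 0.0)
            if min(g, m) < max(template.spacing):
                import warnings
                warnings.warn("cohort effect/jitter produced a sub-voxel layer",
                              UserWarning)
            spec = replace(template,
                           r_gm_mgm=template.r_wm_inner + m,
                           r_pial=template.r_wm_inner + m + g,
                           seed=int(rng.integers(0, 2**31 - 1)))
            ratio, truth = generate_phantom(spec)
            records.append({"subject": f"{group}{i:02d}", "group": group,
                            "spec": spec, "ratio": ratio, "truth": truth})
    return records
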