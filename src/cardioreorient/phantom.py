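"""Synthetic FDG myocardial-metabolism phantoms with known orientation.

The left ventricle is modeled as the region between two concentric,
co-oriented ellipsoids (outer semiaxes minus a constant wall thickness),
truncated by a plane normal to the long axis at the base so the ventricle
opens toward the valve plane; the apex is closed.  The long axis is the
canonical z-axis rotated by H2(beta) . H1(alpha) — the same two-angle
parameterization the reorientation stage inverts — so every phantom carries
exact ground truth for validation.

Three image classes are generated: clean ventricles, ventricles with a
reduced-uptake wedge defect, and ventricles with a right-ventricular
crescent of excess uptake abutting the septal wall.  Scanner appearance is
emulated by a Gaussian point-spread blur (default 5 mm FWHM, the typical
reconstruction filter) and Poisson count noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_volume import Volume3D
from .reorientation import rotation_matrices_from_degrees


@dataclass(frozen=True)
class DefectSpec:
    """Wedge-shaped reduced-uptake region of the myocardial shell.

    The wedge is defined in the ventricle's own frame: circumferential
    center angle and width (degrees, angle measured from +x toward +y), and
    an axial range as fractions of the long semi-axis (apex at +1).
    ``intensity_fraction`` multiplies the myocardial intensity inside.
    """

    center_angle_deg: float = 0.0
    width_deg: float = 60.0
    z_frac_range: tuple[float, float] = (-0.2, 0.6)
    intensity_fraction: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.intensity_fraction <= 1.0:
            raise ValueError("defect intensity fraction must be in [0, 1]")


@dataclass(frozen=True)
class RVUptakeSpec:
    """Right-ventricular crescent abutting the septal side of the LV shell."""

    offset_mm: float = 2.0
    thickness_mm: float = 8.0
    intensity_ratio: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.intensity_ratio <= 1.2:
            raise ValueError("rv intensity ratio must be in (0, 1.2]")


@dataclass(frozen=True)
class OrganBlob:
    """Spherical uptake blob (liver/spine stand-in): center mm relative to grid center."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    intensity: float


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    alpha_true: float = 0.0
    beta_true: float = 0.0
    lv_outer_semiaxes: tuple[float, float, float] = (35.0, 35.0, 50.0)
    wall_thickness: float = 10.0
    base_truncation_fraction: float = 0.3
    myocardium_intensity: float = 8.0
    background_intensity: float = 1.0
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    defect: DefectSpec | None = None
    rv_uptake: RVUptakeSpec | None = None
    extra_organs: tuple[OrganBlob, ...] = ()
    psf_fwhm_mm: float = 5.0
    noise_scale: float = 50.0
    seed: int = 0

    def __post_init__(self):
        rx, ry, rz = self.lv_outer_semiaxes
        if not (rz > rx and abs(rx - ry) < 1e-9):
            raise ValueError("need prolate semiaxes with rz > rx = ry")
        if self.wall_thickness >= rz:
            raise ValueError("wall thickness must be smaller than the long semi-axis")
        if not (-45.0 < self.alpha_true < 45.0 and -45.0 < self.beta_true < 45.0):
            raise ValueError("true angles must lie in (-45, 45) degrees")
        if not 0.0 <= self.base_truncation_fraction < 1.0:
            raise ValueError("base truncation fraction must be in [0, 1)")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    alpha_true: float
    beta_true: float
    lv_center_mm: tuple[float, float, float]
    shell_mask: np.ndarray
    class_label: str = "no_defect"

    def __post_init__(self):
        if not np.any(self.shell_mask):
            raise ValueError("shell mask is empty")


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / np.sqrt(8.0 * np.log(2.0))


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Voxelize a phantom from its analytic description.

    The rotation is applied to the analytic surfaces (voxel coordinates are
    pulled back into the ventricle frame), never to a voxelized shell, so the
    ground-truth orientation is exact.  Deterministic for a fixed seed.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    rx, ry, rz = spec.lv_outer_semiaxes
    R = rotation_matrices_from_degrees(spec.alpha_true, spec.beta_true).R
    axis = R @ np.array([0.0, 0.0, 1.0])

    grid_half = (np.asarray(shape) - 1) / 2.0 * spacing
    center = grid_half + np.asarray(spec.center_offset_mm)
    # bounding half-width of the rotated outer ellipsoid along each grid axis
    half_widths = np.sqrt((R * np.array([rx, ry, rz])) ** 2 @ np.ones(3))
    lo = center - half_widths
    hi = center + half_widths
    if np.any(lo < -1e-9) or np.any(hi > (np.asarray(shape) - 1) * spacing + 1e-9):
        raise ValueError("LV shell does not fit in the grid at the requested orientation")

    # voxel-center physical coordinates relative to LV center, in the ventricle frame
    ax = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1) - center
    Q = P @ R  # equivalent to R.T applied to each point

    inner = np.array([rx - spec.wall_thickness, ry - spec.wall_thickness, rz - spec.wall_thickness])
    inner = np.maximum(inner, 1e-6)
    outer_q = (Q / np.array([rx, ry, rz])) ** 2
    inner_q = (Q / inner) ** 2
    in_outer = outer_q.sum(axis=-1) <= 1.0
    in_inner = inner_q.sum(axis=-1) < 1.0
    # truncation removes the basal fraction of the -z semi-axis: cut at -(1-f) rz
    z_cut = -rz * (1.0 - spec.base_truncation_fraction)
    kept = Q[..., 2] >= z_cut  # base opens toward -z; apex closed at +z
    shell = in_outer & ~in_inner & kept

    img = np.full(shape, float(spec.background_intensity))
    img[shell] = spec.myocardium_intensity

    if spec.defect is not None:
        d = spec.defect
        theta = np.degrees(np.arctan2(Q[..., 1], Q[..., 0]))
        dtheta = (theta - d.center_angle_deg + 180.0) % 360.0 - 180.0
        zlo, zhi = (f * rz for f in d.z_frac_range)
        wedge = shell & (np.abs(dtheta) <= d.width_deg / 2.0) & (Q[..., 2] >= zlo) & (Q[..., 2] <= zhi)
        img[wedge] = d.intensity_fraction * spec.myocardium_intensity

    if spec.rv_uptake is not None:
        rv = spec.rv_uptake
        o = rv.offset_mm
        t = rv.thickness_mm
        rv_inner = np.array([rx + o, ry + o, rz])
        rv_outer = rv_inner + t
        in_rv_outer = ((Q / rv_outer) ** 2).sum(axis=-1) <= 1.0
        in_rv_inner = ((Q / rv_inner) ** 2).sum(axis=-1) < 1.0
        septal = Q[..., 0] <= -0.3 * rx  # crescent on the septal (-x) side
        crescent = in_rv_outer & ~in_rv_inner & septal & kept & ~shell
        img[crescent] = rv.intensity_ratio * spec.myocardium_intensity

    for organ in spec.extra_organs:
        oc = center - np.asarray(spec.center_offset_mm) + np.asarray(organ.center_mm)
        dist2 = ((np.stack([X, Y, Z], axis=-1) - oc) ** 2).sum(axis=-1)
        blob = dist2 <= organ.radius_mm**2
        img[blob & ~shell] = organ.intensity

    truth = PhantomTruth(
        alpha_true=float(spec.alpha_true),
        beta_true=float(spec.beta_true),
        lv_center_mm=tuple(float(c) for c in center),
        shell_mask=shell.copy(),
        class_label=_class_label(spec),
    )

    if spec.psf_fwhm_mm > 0:
        sigma_vox = _fwhm_to_sigma(spec.psf_fwhm_mm) / spacing
        img = ndimage.gaussian_filter(img, sigma_vox)
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        img = rng.poisson(np.clip(img, 0, None) * spec.noise_scale).astype(np.float64) / spec.noise_scale
    img = np.clip(img, 0.0, None)

    return Volume3D(img, tuple(spacing)), truth


def synthetic_shell_points(
    alpha_deg: float,
    beta_deg: float,
    semiaxes: tuple[float, float, float] = (35.0, 35.0, 50.0),
    truncation_fraction: float = 0.3,
    n: int = 600,
    radial_noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Surface points of a truncated, tilted ellipsoidal shell (analytic).

    Points are drawn quasi-uniformly on the outer ellipsoid surface, the
    basal cap below the truncation plane is discarded, optional multiplicative
    radial noise is applied, and the cloud is rotated by H2(beta) H1(alpha)
    and centered.  This is the point-cloud-level stand-in for a segmented
    myocardium, used for angle-recovery studies without voxelization effects.
    """
    rng = np.random.default_rng(seed)
    rx, ry, rz = semiaxes
    z_cut = -(1.0 - truncation_fraction) * rz
    pts = []
    while len(pts) < n:
        u = rng.normal(size=(2 * n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cand = u * np.array([rx, ry, rz])
        cand = cand[cand[:, 2] >= z_cut]
        pts.extend(cand.tolist())
    pts = np.asarray(pts[:n])
    if radial_noise > 0:
        pts = pts * (1.0 + radial_noise * rng.normal(size=(n, 1)))
    R = rotation_matrices_from_degrees(alpha_deg, beta_deg).R
    out = pts @ R.T
    return out - out.mean(axis=0)


def _class_label(spec: PhantomSpec) -> str:
    if spec.rv_uptake is not None:
        return "rv_uptake"
    if spec.defect is not None:
        return "defect"
    return "no_defect"


def phantom_batch(
    class_counts: tuple[int, int, int],
    angle_range_deg: float = 30.0,
    base_seed: int = 42,
    rv_intensity_ratio: float = 0.5,
    **spec_overrides,
) -> list[tuple[Volume3D, PhantomTruth]]:
    """Generate a batch over the three image classes with random orientations.

    ``class_counts`` is (no-defect, defect, rv-uptake).  Per-case seeds are
    ``base_seed + i`` so any case is individually reproducible; angles are
    drawn uniformly from ±``angle_range_deg``, defect geometry and a small
    in-plane center jitter are randomized per case.
    """
    n1, n2, n3 = (int(c) for c in class_counts)
    if min(n1, n2, n3) < 0:
        raise ValueError("class counts must be >= 0")
    labels = ["no_defect"] * n1 + ["defect"] * n2 + ["rv_uptake"] * n3
    out = []
    for i, label in enumerate(labels):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        alpha, beta = rng.uniform(-angle_range_deg, angle_range_deg, size=2)
        offset = tuple(rng.uniform(-8.0, 8.0, size=2)) + (float(rng.uniform(-4.0, 4.0)),)
        defect = None
        rv = None
        if label == "defect":
            defect = DefectSpec(
                center_angle_deg=float(rng.uniform(0.0, 360.0)),
                width_deg=60.0,
                intensity_fraction=float(rng.uniform(0.1, 0.4)),
            )
        elif label == "rv_uptake":
            rv = RVUptakeSpec(intensity_ratio=rv_intensity_ratio)
        spec = PhantomSpec(
            alpha_true=float(alpha),
            beta_true=float(beta),
            center_offset_mm=offset,
            defect=defect,
            rv_uptake=rv,
            seed=seed,
            **spec_overrides,
        )
        out.append(generate_phantom(spec))
    return out
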