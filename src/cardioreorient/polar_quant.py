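"""Polar-map quantification of the short-axis volume.

The left ventricle is sampled with the hemisphere-plus-cylinder model: the
apex is treated as a hemisphere and the mid-cavity and base as a cylinder
around the long axis (the z-axis of the short-axis stack).  Rays normal to
the axis (cylinder) or radiating from the hemisphere center (apex) sample
the maximal wall intensity into a fine polar map of 16 rings x 36 angular
bins = 576 sectors, which reduces to the standard AHA 17-segment bullseye
(6 basal, 6 mid, 4 apical, 1 apex) and to the three coronary territories:

    LAD: segments 1, 2, 7, 8, 13, 14, 17
    RCA: segments 3, 4, 9, 10, 15
    LCX: segments 5, 6, 11, 12, 16

Agreement between a method map and a reference map is scored per segment by

    m = | 1 - (p_r - p_o) / p_o | x 100%

(100% when they coincide; the formula as printed exceeds 100% when the
reference is smaller than the method value — a bounded variant is available
behind a flag).  Metabolic defects are graded by the summed metabolism
score: each segment, expressed as percent of the map maximum, scores 0-4 by
threshold bands and SMS is the sum over the 17 segments; SMS > 2 flags a
defect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_volume import Volume3D

N_RINGS = 16
N_ANGLES = 36
N_FINE = N_RINGS * N_ANGLES  # 576
RING_BANDS = {"basal": range(0, 6), "mid": range(6, 11), "apical": range(11, 15), "apex": range(15, 16)}

LAD_SEGMENTS = frozenset({1, 2, 7, 8, 13, 14, 17})
RCA_SEGMENTS = frozenset({3, 4, 9, 10, 15})
LCX_SEGMENTS = frozenset({5, 6, 11, 12, 16})
assert LAD_SEGMENTS | RCA_SEGMENTS | LCX_SEGMENTS == frozenset(range(1, 18))
assert (len(LAD_SEGMENTS), len(RCA_SEGMENTS), len(LCX_SEGMENTS)) == (7, 5, 5)

# default SMS threshold bands (% of maximum): >=70 -> 0, >=50 -> 1, >=30 -> 2, >=10 -> 3, else 4
SMS_THRESHOLDS = (70.0, 50.0, 30.0, 10.0)


@dataclass
class PolarMap:
    """Fine 16x36 sector map plus its 17-segment reduction."""

    fine: np.ndarray
    seg17: np.ndarray
    normalization: str = "raw"

    def __post_init__(self):
        self.fine = np.asarray(self.fine, dtype=np.float64)
        self.seg17 = np.asarray(self.seg17, dtype=np.float64)
        if self.fine.size != N_FINE:
            raise ValueError(f"fine map must have {N_FINE} sectors")
        self.fine = self.fine.reshape(N_RINGS, N_ANGLES)
        if self.seg17.shape != (17,):
            raise ValueError("seg17 must have 17 values")
        if self.normalization == "pct_of_max" and (self.seg17.min() < 0 or self.seg17.max() > 100 + 1e-9):
            raise ValueError("pct_of_max values must lie in [0, 100]")

    def as_pct_of_max(self) -> "PolarMap":
        peak = max(self.fine.max(), 1e-300)
        return PolarMap(self.fine / peak * 100.0, self.seg17 / peak * 100.0, "pct_of_max")

    def territory_means(self) -> dict[str, float]:
        s = self.seg17
        return {
            "LAD": float(np.mean([s[i - 1] for i in sorted(LAD_SEGMENTS)])),
            "RCA": float(np.mean([s[i - 1] for i in sorted(RCA_SEGMENTS)])),
            "LCX": float(np.mean([s[i - 1] for i in sorted(LCX_SEGMENTS)])),
        }


@dataclass(frozen=True)
class TerritoryMap:
    lad: float
    rca: float
    lcx: float
    lad_segments: frozenset = LAD_SEGMENTS
    rca_segments: frozenset = RCA_SEGMENTS
    lcx_segments: frozenset = LCX_SEGMENTS


@dataclass
class SimilarityReport:
    per_segment: np.ndarray  # % per segment, NaN where undefined
    territory_means: dict[str, float]
    total_mean: float
    n_undefined: int
    p_r: np.ndarray
    p_o: np.ndarray


@dataclass
class SMSScore:
    per_segment: np.ndarray
    sms: int
    defect_class: bool

    def __post_init__(self):
        if not 0 <= self.sms <= 68:
            raise ValueError("SMS must lie in [0, 68]")


def _segment_of(ring: int, abin: int) -> int:
    """AHA segment (1-17) owning fine sector (ring, angular bin).

    Angular convention: theta = bin center in degrees, measured from the
    anterior wall (theta = 0) increasing counterclockwise viewed from the
    apex; basal/mid segments span 60 degrees starting 30 degrees before
    anterior, apical segments span 90 degrees starting 45 degrees before.
    """
    theta = (abin + 0.5) * (360.0 / N_ANGLES)
    if ring in RING_BANDS["apex"]:
        return 17
    if ring in RING_BANDS["apical"]:
        return 13 + int(((theta + 45.0) % 360.0) // 90.0)
    base = 1 if ring in RING_BANDS["basal"] else 7
    return base + int(((theta + 30.0) % 360.0) // 60.0)


_SEG_LOOKUP = np.array([[_segment_of(r, a) for a in range(N_ANGLES)] for r in range(N_RINGS)])


def fine_to_17(fine: np.ndarray) -> np.ndarray:
    """Average the 576 fine sectors into the 17 AHA segments.

    Each fine sector contributes to exactly one segment, so the
    sector-count-weighted mean of the 17 values reproduces the fine-map
    mean.
    """
    fine = np.asarray(fine, dtype=np.float64).reshape(N_RINGS, N_ANGLES)
    out = np.empty(17)
    for s in range(1, 18):
        out[s - 1] = fine[_SEG_LOOKUP == s].mean()
    return out


def sample_polar(
    sa: Volume3D,
    mask: np.ndarray,
    radius_mult: float = 1.6,
    junction_frac: float = 0.8,
) -> PolarMap:
    """Sample a short-axis volume into the 576-sector polar map.

    The LV axis is the line through the mask centroid along z (apex toward
    high z).  Axial positions with in-plane mask radius at or above
    ``junction_frac`` of the median radius belong to the cylinder; beyond
    the junction the apex is sampled as a hemisphere centered on the
    junction point.  Each fine sector takes the maximum interpolated
    intensity along its ray, out to ``radius_mult`` times the median wall
    radius.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty myocardium mask")
    spacing = np.asarray(sa.spacing)
    coords = np.argwhere(mask).astype(np.float64)
    cx, cy = coords[:, 0].mean(), coords[:, 1].mean()

    zs = np.unique(coords[:, 2].astype(int))
    radii_by_z = {}
    for z in zs:
        sl = coords[coords[:, 2] == z]
        r = np.hypot((sl[:, 0] - cx) * spacing[0], (sl[:, 1] - cy) * spacing[1])
        radii_by_z[z] = float(np.median(r))
    if not radii_by_z:
        raise ValueError("axis undeterminable")
    med_radius = float(np.median(list(radii_by_z.values())))

    z_lo, z_hi = zs.min(), zs.max()
    # junction: last z (scanning toward the apex at high z) with full cylinder radius
    z_junc = z_lo
    for z in zs:
        if radii_by_z[z] >= junction_frac * med_radius:
            z_junc = z
    z_junc = max(z_junc, z_lo + 1)

    r_max = radius_mult * med_radius
    step = float(min(spacing)) / 2.0
    n_cyl = N_RINGS - len(RING_BANDS["apical"]) - len(RING_BANDS["apex"])  # 11 cylinder rings
    fine = np.zeros((N_RINGS, N_ANGLES))
    thetas = np.radians((np.arange(N_ANGLES) + 0.5) * (360.0 / N_ANGLES))
    radii = np.arange(0.0, r_max, step)

    def ray_max(origin_idx, direction_mm):
        d = direction_mm / np.linalg.norm(direction_mm)
        pts = origin_idx[None, :] + (radii[:, None] * d[None, :]) / spacing
        ok = np.all((pts >= 0) & (pts <= np.asarray(sa.shape) - 1), axis=1)
        if not ok.any():
            return 0.0
        vals = ndimage.map_coordinates(sa.data, pts[ok].T, order=1)
        return float(vals.max())

    # cylinder rings at band centers between the base cut and the junction
    # (the extreme positions sit on the open base cut and the junction itself)
    z_edges = np.linspace(z_lo, z_junc, n_cyl + 1)
    z_ring = (z_edges[:-1] + z_edges[1:]) / 2.0
    for ring in range(n_cyl):
        origin = np.array([cx, cy, z_ring[ring]])
        for a, th in enumerate(thetas):
            fine[ring, a] = ray_max(origin, np.array([np.cos(th), np.sin(th), 0.0]))

    # hemisphere: colatitude band centers from the junction toward the pole
    hemi_rings = list(RING_BANDS["apical"]) + list(RING_BANDS["apex"])
    origin = np.array([cx, cy, float(z_junc)])
    psi_edges = np.linspace(np.pi / 2, 0.0, len(hemi_rings) + 1)
    psis = (psi_edges[:-1] + psi_edges[1:]) / 2.0
    for j, ring in enumerate(hemi_rings):
        psi = psis[j]
        for a, th in enumerate(thetas):
            d = np.array([np.cos(th) * np.sin(psi), np.sin(th) * np.sin(psi), np.cos(psi)])
            fine[ring, a] = ray_max(origin, d)

    return PolarMap(fine, fine_to_17(fine), "raw")


def similarity(p_r: np.ndarray, p_o: np.ndarray, bounded: bool = False) -> SimilarityReport:
    """Per-segment similarity m = |1 - (p_r - p_o)/p_o| x 100%.

    ``p_r`` is the reference map's segment values, ``p_o`` the method's.
    Identical values give 100% everywhere; as printed the score exceeds
    100% when p_r < p_o.  ``bounded`` switches to 1 - |p_r - p_o|/p_o
    (never above 100%).  Segments with p_o = 0 are undefined, excluded from
    the means and counted.
    """
    p_r = np.asarray(p_r, dtype=np.float64)
    p_o = np.asarray(p_o, dtype=np.float64)
    if p_r.shape != p_o.shape:
        raise ValueError("reference and method maps must have the same shape")
    m = np.full(p_r.shape, np.nan)
    ok = p_o != 0
    if bounded:
        m[ok] = (1.0 - np.abs(p_r[ok] - p_o[ok]) / p_o[ok]) * 100.0
    else:
        m[ok] = np.abs(1.0 - (p_r[ok] - p_o[ok]) / p_o[ok]) * 100.0
    terr = {}
    if p_r.shape == (17,):
        for name, segs in (("LAD", LAD_SEGMENTS), ("RCA", RCA_SEGMENTS), ("LCX", LCX_SEGMENTS)):
            vals = [m[i - 1] for i in sorted(segs) if np.isfinite(m[i - 1])]
            terr[name] = float(np.mean(vals)) if vals else float("nan")
    total = float(np.nanmean(m)) if np.any(np.isfinite(m)) else float("nan")
    return SimilarityReport(m, terr, total, int(np.count_nonzero(~ok)), p_r, p_o)


def sms(seg17_pct: np.ndarray, thresholds: tuple[float, float, float, float] = SMS_THRESHOLDS) -> SMSScore:
    """Summed metabolism score from percent-of-maximum segment values.

    Scores 0-4 per segment by descending threshold bands; SMS is the sum
    over 17 segments (0-68) and SMS > 2 classifies the case as having a
    metabolic defect.
    """
    seg = np.asarray(seg17_pct, dtype=np.float64)
    if seg.shape != (17,):
        raise ValueError("need 17 segment values")
    if seg.min() < 0 or seg.max() > 100 + 1e-9:
        raise ValueError("segment values must be normalized to percent of maximum")
    t = np.asarray(thresholds, dtype=np.float64)
    if not np.all(np.diff(t) < 0):
        raise ValueError("thresholds must be strictly descending")
    scores = np.searchsorted(-t, -seg, side="left")
    total = int(scores.sum())
    return SMSScore(scores.astype(int), total, total > 2)
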