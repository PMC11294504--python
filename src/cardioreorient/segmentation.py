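"""Myocardial segmentation by unsupervised intensity clustering.

The divided cardiac volume is segmented by clustering its 1-D intensity
distribution into k classes (default k = 3: background, blood pool / soft
tissue, myocardium) with K-means or fuzzy c-means; particle-swarm
optimization can drive the centroid search (PSO-K-means, PSO-FCM) to avoid
poor local minima.  The myocardium is the class with the highest centroid
— the brightest structure once region division has removed hot
interference — cleaned up to a single connected component.  Maximum
radioactivity sampling (MRS) offers a clustering-free alternative: the wall
is located as the intensity maximum along rays cast from the cavity center.

The segmented voxels are converted to a centered point cloud in physical
millimeters, the input to ellipsoid fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .core_volume import Volume3D


@dataclass
class ClusterResult:
    """Outcome of a 1-D intensity clustering run.

    ``memberships`` rows sum to one (hard 0/1 for K-means, fuzzy for FCM);
    ``objective_trace`` records the within-cluster objective per iteration,
    which both algorithms keep non-increasing.
    """

    centroids: np.ndarray
    memberships: np.ndarray
    objective: float
    iterations: int
    seed: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        rowsum = self.memberships.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("memberships must sum to 1 per sample")


@dataclass
class SegmentationMask:
    mask: np.ndarray
    method: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


class SegmentationFailure(RuntimeError):
    """Raised when no myocardium class can be identified (e.g. constant input)."""


@dataclass
class PointCloud:
    """N points in voxel-center physical coordinates (mm), centroid at the origin."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if len(self.points) < 1:
            raise ValueError("point cloud is empty")

    def __len__(self) -> int:
        return len(self.points)


def _kpp_init(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding on a 1-D sample."""
    centroids = [values[rng.integers(len(values))]]
    for _ in range(k - 1):
        d2 = np.min((values[:, None] - np.asarray(centroids)[None, :]) ** 2, axis=1)
        tot = d2.sum()
        if tot <= 0:
            centroids.append(values[rng.integers(len(values))])
            continue
        centroids.append(values[rng.choice(len(values), p=d2 / tot)])
    return np.sort(np.asarray(centroids, dtype=np.float64))


def kmeans_objective(values: np.ndarray, centroids: np.ndarray) -> float:
    d2 = (values[:, None] - centroids[None, :]) ** 2
    return float(d2.min(axis=1).sum())


def kmeans_cluster(
    values: np.ndarray,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    init_centroids: np.ndarray | None = None,
) -> ClusterResult:
    """Lloyd's algorithm on a 1-D intensity sample with k-means++ seeding."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(values) < k:
        raise ValueError("sample smaller than k")
    if len(np.unique(values)) < k:
        raise ValueError("fewer distinct values than clusters")
    rng = np.random.default_rng(seed)
    c = np.sort(np.asarray(init_centroids, float)) if init_centroids is not None else _kpp_init(values, k, rng)
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        labels = np.argmin(np.abs(values[:, None] - c[None, :]), axis=1)
        new_c = c.copy()
        for j in range(k):
            sel = values[labels == j]
            if len(sel):
                new_c[j] = sel.mean()
        trace.append(kmeans_objective(values, new_c))
        shift = np.max(np.abs(new_c - c))
        c = new_c
        if shift < tol:
            break
    labels = np.argmin(np.abs(values[:, None] - c[None, :]), axis=1)
    memb = np.zeros((len(values), k))
    memb[np.arange(len(values)), labels] = 1.0
    order = np.argsort(c)
    return ClusterResult(c[order], memb[:, order], kmeans_objective(values, c), it, seed, np.asarray(trace))


def fcm_objective(values: np.ndarray, centroids: np.ndarray, m: float = 2.0) -> float:
    """Fuzzy within-cluster objective sum_i sum_j u_ij^m d_ij^2 at optimal memberships."""
    u = _fcm_memberships(values, centroids, m)
    d2 = (values[:, None] - centroids[None, :]) ** 2
    return float((u**m * d2).sum())


def _fcm_memberships(values: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d = np.abs(values[:, None] - centroids[None, :])
    coincident = d < 1e-300
    d = np.where(coincident, 1.0, d)
    expo = 2.0 / (m - 1.0)
    inv = d ** (-expo)
    u = inv / inv.sum(axis=1, keepdims=True)
    hit = coincident.any(axis=1)
    if np.any(hit):
        u[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
    return u


def fcm_cluster(
    values: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    init_centroids: np.ndarray | None = None,
) -> ClusterResult:
    """Standard fuzzy c-means: alternate membership and centroid updates.

    Memberships use the 2/(m-1) inverse-distance exponent; a sample
    coincident with a centroid receives full membership there.  Stops when
    the maximum membership change falls below ``tol``.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    c = np.sort(np.asarray(init_centroids, float)) if init_centroids is not None else _kpp_init(values, k, rng)
    u = _fcm_memberships(values, c, m)
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        c = (um * values[:, None]).sum(axis=0) / um.sum(axis=0)
        u_new = _fcm_memberships(values, c, m)
        d2 = (values[:, None] - c[None, :]) ** 2
        trace.append(float((u_new**m * d2).sum()))
        change = np.max(np.abs(u_new - u))
        u = u_new
        if change < tol:
            break
    order = np.argsort(c)
    return ClusterResult(c[order], u[:, order], fcm_objective(values, c, m), it, seed, np.asarray(trace))


def pso_optimize(
    objective,
    k: int,
    bounds: tuple[float, float],
    swarm_size: int = 20,
    iters: int = 100,
    inertia: tuple[float, float] = (0.9, 0.4),
    c1: float = 2.0,
    c2: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Canonical particle-swarm minimization of a centroid-vector objective.

    Particles are k-vectors inside ``bounds``; velocities are clamped to 20%
    of the bound width; inertia decays linearly across iterations.  Returns
    the global-best centroid vector; deterministic for a fixed seed, and the
    global-best objective is non-increasing by construction.
    """
    lo, hi = (float(bounds[0]), float(bounds[1]))
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("bounds must be finite with hi > lo")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(lo, hi, size=(swarm_size, k))
    vmax = 0.2 * (hi - lo)
    vel = rng.uniform(-vmax, vmax, size=(swarm_size, k))
    pbest = pos.copy()
    pbest_f = np.array([objective(np.sort(p)) for p in pos])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    w0, w1 = inertia
    for t in range(iters):
        w = w0 + (w1 - w0) * (t / max(iters - 1, 1))
        r1 = rng.uniform(size=(swarm_size, k))
        r2 = rng.uniform(size=(swarm_size, k))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest[None, :] - pos)
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        f = np.array([objective(np.sort(p)) for p in pos])
        improved = f < pbest_f
        pbest[improved] = pos[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    return np.sort(gbest)


def _cleanup(mask: np.ndarray, hole_area: int = 16) -> np.ndarray:
    """Largest 26-connected component, then small-hole filling per axial slice.

    Only holes below ``hole_area`` pixels are filled so the blood-pool
    cavity (a large in-slice hole wherever the wall closes into a ring)
    survives while speckle holes are removed.
    """
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = lab == (1 + int(np.argmax(sizes)))
    out = keep.copy()
    for z in range(out.shape[2]):
        sl = out[:, :, z]
        if sl.any():
            out[:, :, z] = morphology.remove_small_holes(sl, max_size=hole_area)
    return out


def _cluster_segment(
    vol: Volume3D,
    method: str,
    k: int,
    m: float,
    seed: int,
    pso_kwargs: dict | None,
    subsample: int = 20000,
) -> SegmentationMask:
    values = vol.data.ravel()
    if np.ptp(values) <= 0:
        raise SegmentationFailure("constant volume: no intensity structure to cluster")
    lo, hi = float(values.min()), float(values.max())
    pso_kwargs = dict(pso_kwargs or {})
    pso_seed = pso_kwargs.pop("seed", seed)
    rng = np.random.default_rng(seed)
    # centroids are estimated on an intensity subsample (the 1-D distribution
    # is heavily oversampled by 80*80*64 voxels); all voxels are then labeled
    # by the final centroids, which equals the argmax-membership assignment
    fit_sample = values if len(values) <= 5 * subsample else rng.choice(values, size=5 * subsample, replace=False)
    init = None
    if method in ("pso-kmeans", "pso-fcm"):
        sample = fit_sample if len(fit_sample) <= subsample else rng.choice(fit_sample, size=subsample, replace=False)
        if method == "pso-fcm":
            obj = lambda c: fcm_objective(sample, c, m)
        else:
            obj = lambda c: kmeans_objective(sample, c)
        init = pso_optimize(obj, k, (lo, hi), seed=pso_seed, **pso_kwargs)
    if method in ("fcm", "pso-fcm"):
        res = fcm_cluster(fit_sample, k=k, m=m, seed=seed, init_centroids=init)
    else:
        res = kmeans_cluster(fit_sample, k=k, seed=seed, init_centroids=init)
    # nearest final centroid == maximal membership for both hard and fuzzy memberships
    labels = np.argmin(np.abs(values[:, None] - res.centroids[None, :]), axis=1)
    myo = labels == (k - 1)  # centroids sorted ascending: brightest class
    if not np.any(myo):
        raise SegmentationFailure("empty myocardium class")
    mask = _cleanup(myo.reshape(vol.shape))
    if not np.any(mask):
        raise SegmentationFailure("myocardium mask empty after cleanup")
    return SegmentationMask(mask, method)


def pso_fcm_segment(
    vol: Volume3D,
    k: int = 3,
    m: float = 2.0,
    seed: int = 0,
    pso_kwargs: dict | None = None,
) -> SegmentationMask:
    """PSO-seeded fuzzy c-means segmentation of the myocardium.

    PSO minimizes the FCM objective over centroid vectors (on an intensity
    subsample for speed), FCM then refines from the PSO global best on the
    full volume; the myocardium is the brightest class, cleaned to a single
    26-connected component.
    """
    return _cluster_segment(vol, "pso-fcm", k, m, seed, pso_kwargs)


def segment(vol: Volume3D, method: str = "pso-fcm", k: int = 3, m: float = 2.0, seed: int = 0, **kw) -> SegmentationMask:
    """Dispatch across the implemented segmentation methods."""
    if method in ("kmeans", "fcm", "pso-kmeans", "pso-fcm"):
        return _cluster_segment(vol, method, k, m, seed, kw.get("pso_kwargs"))
    if method == "mrs":
        pc = mrs_sample(vol, center=kw.get("center"), n_directions=kw.get("n_directions", 200))
        mask = np.zeros(vol.shape, dtype=bool)
        idx = np.round(pc.points / np.asarray(vol.spacing) + (np.asarray(vol.shape) - 1) / 2.0).astype(int)
        idx = np.clip(idx, 0, np.asarray(vol.shape) - 1)
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return SegmentationMask(mask, "mrs")
    raise ValueError(f"unknown segmentation method {method!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])


def mrs_sample(
    vol: Volume3D,
    center: tuple[float, float, float] | None = None,
    n_directions: int = 200,
    step_mm: float = 1.0,
    directions: np.ndarray | None = None,
) -> PointCloud:
    """Maximum radioactivity sampling of the myocardial wall.

    Rays are cast from ``center`` (mm from the grid center; default the
    intensity centroid) along quasi-uniform sphere directions (or explicit
    unit ``directions``); each ray contributes the point of maximal
    interpolated intensity.  On a low-contrast volume the maxima are
    meaningless; a warning is issued.
    """
    import warnings

    spacing = np.asarray(vol.spacing)
    half = (np.asarray(vol.shape) - 1) / 2.0 * spacing
    if center is None:
        tot = vol.data.sum()
        if tot > 0:
            idx = np.indices(vol.shape).reshape(3, -1)
            center = tuple((idx * vol.data.reshape(1, -1)).sum(axis=1) / tot * spacing - half)
        else:
            center = (0.0, 0.0, 0.0)
    c = np.asarray(center, dtype=np.float64)
    if np.any(np.abs(c) > half):
        raise ValueError("ray center outside the grid")
    if np.ptp(vol.data) <= 1e-12 * max(1.0, abs(float(vol.data.max()))):
        warnings.warn("low-contrast volume: maximum radioactivity sampling is unreliable")
    dirs = _fibonacci_sphere(n_directions) if directions is None else np.asarray(directions, dtype=np.float64)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    max_r = float(np.linalg.norm(half - np.abs(c)) + np.max(spacing))
    radii = np.arange(0.0, max_r, step_mm)
    pts = []
    for d in dirs:
        ray = c[None, :] + radii[:, None] * d[None, :]
        idx = (ray + half) / spacing
        inside = np.all((idx >= 0) & (idx <= np.asarray(vol.shape) - 1), axis=1)
        if not inside.any():
            continue
        vals = ndimage.map_coordinates(vol.data, idx[inside].T, order=1, mode="constant", cval=-1.0)
        pts.append(ray[inside][int(np.argmax(vals))])
    pts = np.asarray(pts)
    return PointCloud(pts - pts.mean(axis=0))


def mask_to_points(mask: SegmentationMask | np.ndarray, spacing: tuple[float, float, float]) -> PointCloud:
    """Physical voxel-center coordinates of mask voxels, centroid at the origin."""
    arr = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, dtype=bool)
    if not np.any(arr):
        raise ValueError("empty mask")
    pts = np.argwhere(arr).astype(np.float64) * np.asarray(spacing)
    return PointCloud(pts - pts.mean(axis=0))
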