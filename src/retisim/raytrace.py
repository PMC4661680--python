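"""Monte-Carlo sequential ray tracing through the schematic eye.

Rays start on the chart plane, are aimed at the pupil disc (importance
sampling), refract at the four eye surfaces, optionally interact with a
hole-array opacity at the lens anterior surface, and land on the retina
plane where they are binned into an irradiance map.  All failure modes
are statuses, never exceptions: a ray ends ``landed``, ``vignetted``
(blocked by an aperture or missing a surface) or ``absorbed`` (total
internal reflection, opacity blocking, or reversed propagation).

Power bookkeeping is exact: every ray carries the same power, and
``landed + vignetted + absorbed == launched`` by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chart import Chart, SourceSampleSet, region_bbox
from .eye import EyeModel, OpticalSurface, paraxial_image_height
from .microstructure import (
    MicrostructureGeometry,
    MicrostructureSpec,
    build_hole_array,
    interact,
)

__all__ = [
    "ALIVE",
    "LANDED",
    "VIGNETTED",
    "ABSORBED",
    "Ray",
    "IrradianceMap",
    "MapSpec",
    "RetinalROI",
    "TotalInternalReflectionError",
    "refract",
    "intersect",
    "trace",
    "trace_batch",
    "simulate_image",
    "total_flux",
    "magnification",
    "roi_from_region",
]

ALIVE, LANDED, VIGNETTED, ABSORBED = 0, 1, 2, 3
_STATUS_NAMES = {ALIVE: "alive", LANDED: "landed", VIGNETTED: "vignetted", ABSORBED: "absorbed"}
_EPS = 1e-9


class TotalInternalReflectionError(ValueError):
    pass


@dataclass
class Ray:
    """A single ray; ``status`` is one of alive|landed|vignetted|absorbed."""

    origin: np.ndarray
    direction: np.ndarray
    power: float = 1.0
    status: str = "alive"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            self.direction = self.direction / norm
        if self.power < 0:
            raise ValueError("ray power must be >= 0")


def refract(
    direction: np.ndarray, normal: np.ndarray, n1: float, n2: float
) -> np.ndarray:
    """Vector Snell refraction of a unit ``direction`` at a unit ``normal``.

    The normal may point either way; it is flipped internally to oppose
    the incoming ray.  Raises :class:`TotalInternalReflectionError` when
    ``n1 sin(theta1) > n2``.
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos1 = -float(np.dot(d, n))
    if cos1 < 0:
        n = -n
        cos1 = -cos1
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cos1 * cos1)
    if k < 0:
        raise TotalInternalReflectionError(
            f"total internal reflection: n1={n1}, n2={n2}, cos(theta1)={cos1}"
        )
    t = eta * d + (eta * cos1 - math.sqrt(k)) * n
    return t / np.linalg.norm(t)


def _refract_batch(d, normals, n1, n2):
    """Vectorized Snell refraction; returns (new_directions, tir_mask)."""
    cos1 = -np.einsum("ij,ij->i", d, normals)
    flip = cos1 < 0
    normals = np.where(flip[:, None], -normals, normals)
    cos1 = np.abs(cos1)
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cos1 * cos1)
    tir = k < 0
    k = np.clip(k, 0.0, None)
    t = eta * d + (eta * cos1 - np.sqrt(k))[:, None] * normals
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return t, tir


def _intersect_sphere_batch(pos, d, surface: OpticalSurface):
    """Nearest forward hit with the surface cap.

    Returns (hit, ok): ``ok`` False where the ray misses the sphere (or
    plane) entirely.  Aperture clipping is the caller's job.
    """
    if surface.is_flat:
        dz = d[:, 2]
        ok = dz > _EPS
        t = np.where(ok, (surface.vertex_z - pos[:, 2]) / np.where(ok, dz, 1.0), np.nan)
        ok &= t > _EPS
        hit = pos + t[:, None] * d
        return hit, ok
    R = surface.radius
    cz = surface.vertex_z + R
    oc = pos - np.array([0.0, 0.0, cz])
    b = np.einsum("ij,ij->i", d, oc)
    c2 = np.einsum("ij,ij->i", oc, oc) - R * R
    disc = b * b - c2
    ok = disc >= 0
    sq = np.sqrt(np.clip(disc, 0.0, None))
    t1 = -b - sq
    t2 = -b + sq
    # hemisphere condition: hit on the vertex-side cap
    z1 = pos[:, 2] + t1 * d[:, 2]
    z2 = pos[:, 2] + t2 * d[:, 2]
    if R > 0:
        v1 = (t1 > _EPS) & (z1 <= cz)
        v2 = (t2 > _EPS) & (z2 <= cz)
    else:
        v1 = (t1 > _EPS) & (z1 >= cz)
        v2 = (t2 > _EPS) & (z2 >= cz)
    t = np.where(v1, t1, np.where(v2, t2, np.nan))
    ok &= v1 | v2
    hit = pos + t[:, None] * d
    return hit, ok


def intersect(ray: Ray, surface: OpticalSurface) -> np.ndarray | None:
    """Nearest forward intersection of a single ray with a surface cap.

    Returns the hit point (mm) or ``None`` on a miss or when the hit lies
    beyond the surface semi-aperture.
    """
    hit, ok = _intersect_sphere_batch(
        ray.origin[None, :], ray.direction[None, :], surface
    )
    if not ok[0]:
        return None
    r = math.hypot(hit[0, 0], hit[0, 1])
    if r > surface.semi_aperture:
        return None
    return hit[0]


def _surface_normals(hit, surface: OpticalSurface):
    if surface.is_flat:
        n = np.zeros_like(hit)
        n[:, 2] = -1.0
        return n
    cz = surface.vertex_z + surface.radius
    return (hit - np.array([0.0, 0.0, cz])) / surface.radius


def trace_batch(
    eye: EyeModel,
    origins: np.ndarray,
    directions: np.ndarray,
    microstructure: MicrostructureGeometry | MicrostructureSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trace ray bundles through the eye.

    Returns ``(status, landing)`` where ``status`` is per-ray
    LANDED/VIGNETTED/ABSORBED and ``landing`` the (n, 2) retina-plane
    coordinates (NaN where the ray did not land).
    """
    geometry = _as_geometry(eye, microstructure)
    if geometry is not None and rng is None:
        rng = np.random.default_rng(0)

    pos = np.array(origins, dtype=float, copy=True)
    d = np.array(directions, dtype=float, copy=True)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    n_rays = len(pos)
    status = np.full(n_rays, ALIVE, dtype=np.uint8)

    n_before = 1.0
    lens_anterior_index = 2
    for i, surface in enumerate(eye.surfaces):
        alive = status == ALIVE
        if not alive.any():
            break
        # pupil stop: a plane aperture crossed before the lens anterior
        if i == lens_anterior_index:
            _apply_stop(eye, pos, d, status)
            alive = status == ALIVE
            if not alive.any():
                break
        hit, ok = _intersect_sphere_batch(pos[alive], d[alive], surface)
        idx = np.flatnonzero(alive)
        status[idx[~ok]] = VIGNETTED
        idx = idx[ok]
        hit = hit[ok]
        r2 = hit[:, 0] ** 2 + hit[:, 1] ** 2
        inside = r2 <= surface.semi_aperture**2
        status[idx[~inside]] = VIGNETTED
        idx = idx[inside]
        hit = hit[inside]
        dirs = d[idx]
        if i == lens_anterior_index and geometry is not None and len(idx):
            absorbed, dirs = interact(hit[:, :2], dirs, geometry, rng)
            status[idx[absorbed]] = ABSORBED
            keep = ~absorbed
            idx = idx[keep]
            hit = hit[keep]
            dirs = dirs[keep]
        normals = _surface_normals(hit, surface)
        new_d, tir = _refract_batch(dirs, normals, n_before, surface.n_after)
        status[idx[tir]] = ABSORBED
        idx = idx[~tir]
        pos[idx] = hit[~tir]
        d[idx] = new_d[~tir]
        n_before = surface.n_after

    # propagate to the retina
    landing = np.full((n_rays, 2), np.nan)
    alive = status == ALIVE
    if alive.any():
        dz = d[alive, 2]
        fwd = dz > _EPS
        idx = np.flatnonzero(alive)
        status[idx[~fwd]] = ABSORBED
        idx = idx[fwd]
        if eye.retina_radius is None:
            t = (eye.retina_z - pos[idx, 2]) / d[idx, 2]
            land = pos[idx] + t[:, None] * d[idx]
            landing[idx] = land[:, :2]
            status[idx] = LANDED
        else:
            retina = OpticalSurface(
                vertex_z=eye.retina_z,
                radius=-abs(eye.retina_radius),
                semi_aperture=min(abs(eye.retina_radius), 12.0),
                n_after=eye.n_image,
            )
            hit, ok = _intersect_sphere_batch(pos[idx], d[idx], retina)
            status[idx[~ok]] = ABSORBED
            idx = idx[ok]
            landing[idx] = hit[ok][:, :2]
            status[idx] = LANDED
    return status, landing


def _apply_stop(eye: EyeModel, pos, d, status) -> None:
    alive = status == ALIVE
    idx = np.flatnonzero(alive)
    dz = d[idx, 2]
    fwd = dz > _EPS
    status[idx[~fwd]] = ABSORBED
    idx = idx[fwd]
    t = (eye.stop_z - pos[idx, 2]) / d[idx, 2]
    p = pos[idx] + t[:, None] * d[idx]
    r2 = p[:, 0] ** 2 + p[:, 1] ** 2
    blocked = r2 > eye.stop_semi**2
    status[idx[blocked]] = VIGNETTED
    keep = idx[~blocked]
    pos[keep] = p[~blocked]


def _as_geometry(eye, microstructure):
    if microstructure is None:
        return None
    if isinstance(microstructure, MicrostructureSpec):
        lens_aperture = 2.0 * eye.surfaces[2].semi_aperture
        return build_hole_array(microstructure, lens_aperture_mm=lens_aperture)
    return microstructure


def trace(
    eye: EyeModel,
    ray: Ray,
    microstructure: MicrostructureGeometry | MicrostructureSpec | None = None,
    rng: np.random.Generator | None = None,
) -> Ray:
    """Trace a single ray; returns a terminal Ray (landed at the retina
    plane, or vignetted/absorbed at its failure point)."""
    status, landing = trace_batch(
        eye, ray.origin[None, :], ray.direction[None, :], microstructure, rng
    )
    out = Ray(
        origin=ray.origin.copy(),
        direction=ray.direction.copy(),
        power=ray.power,
        status=_STATUS_NAMES[int(status[0])],
    )
    if status[0] == LANDED:
        out.origin = np.array([landing[0, 0], landing[0, 1], eye.retina_z])
    return out


@dataclass(frozen=True)
class MapSpec:
    """Binning of the retinal irradiance map.

    ``window=None`` sizes the window to the paraxial image of the whole
    chart extent plus ``margin`` relative slack per side.
    """

    n_bins: int = 256
    window: tuple[float, float, float, float] | None = None
    margin: float = 0.2


@dataclass
class IrradianceMap:
    """Binned retinal flux plus exact power accounting.

    ``bins[iy, ix]`` covers the window row-major with y increasing along
    axis 0; ``sum(bins)`` equals the power landed inside the window
    (rays may land outside the window and still count as landed).
    """

    bins: np.ndarray
    window: tuple[float, float, float, float]
    bin_size: tuple[float, float]
    launched: float
    landed: float
    vignetted: float
    absorbed: float
    n_rays: int
    metadata: dict = field(default_factory=dict)

    @property
    def landed_in_window(self) -> float:
        return float(self.bins.sum())

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, y0, y1 = self.window
        ny, nx = self.bins.shape
        xs = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
        ys = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
        return xs, ys


@dataclass(frozen=True)
class RetinalROI:
    """Union of rectangles (xmin, xmax, ymin, ymax) in retinal mm."""

    rects: tuple[tuple[float, float, float, float], ...]
    name: str = ""


def magnification(eye: EyeModel, object_distance_mm: float) -> float:
    """Transverse paraxial magnification chart -> retina (negative: inverted)."""
    return paraxial_image_height(eye, 1.0, -object_distance_mm)


def _image_window(eye: EyeModel, source: SourceSampleSet, margin: float):
    m = magnification(eye, source.distance_mm)
    x0, x1, y0, y1 = source.chart_extent
    xs = sorted((m * x0, m * x1))
    ys = sorted((m * y0, m * y1))
    dx = (xs[1] - xs[0]) * margin / 2.0
    dy = (ys[1] - ys[0]) * margin / 2.0
    return (xs[0] - dx, xs[1] + dx, ys[0] - dy, ys[1] + dy)


def _sample_pupil(eye: EyeModel, n: int, rng: np.random.Generator) -> np.ndarray:
    r = eye.stop_semi * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack(
        [r * np.cos(phi), r * np.sin(phi), np.full(n, eye.stop_z)]
    )


def simulate_image(
    eye: EyeModel,
    source: SourceSampleSet,
    map_spec: MapSpec | None = None,
    seed: int = 0,
    microstructure: MicrostructureGeometry | MicrostructureSpec | None = None,
) -> IrradianceMap:
    """Trace every source sample to the retina and bin the landed flux.

    Deterministic for a fixed ``seed``: the pupil-sampling and scatter
    random streams are independent substreams of ``seed``, so adding a
    microstructure does not perturb the primary rays (common random
    numbers across opacity configurations).
    """
    if map_spec is None:
        map_spec = MapSpec()
    ss = np.random.SeedSequence(seed)
    pupil_rng, scatter_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    n = source.n
    origins = np.column_stack([source.points, np.full(n, source.z)])
    targets = _sample_pupil(eye, n, pupil_rng)
    directions = targets - origins
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    geometry = _as_geometry(eye, microstructure)
    status, landing = trace_batch(eye, origins, directions, geometry, scatter_rng)

    window = map_spec.window or _image_window(eye, source, map_spec.margin)
    x0, x1, y0, y1 = window
    nb = map_spec.n_bins
    landed_mask = status == LANDED
    w = source.power_per_point
    hist, _, _ = np.histogram2d(
        landing[landed_mask, 1],
        landing[landed_mask, 0],
        bins=nb,
        range=[[y0, y1], [x0, x1]],
    )
    return IrradianceMap(
        bins=hist * w,
        window=window,
        bin_size=((x1 - x0) / nb, (y1 - y0) / nb),
        launched=n * w,
        landed=float(landed_mask.sum()) * w,
        vignetted=float((status == VIGNETTED).sum()) * w,
        absorbed=float((status == ABSORBED).sum()) * w,
        n_rays=n,
        metadata={
            "seed": seed,
            "eye": eye.name,
            "myopia": eye.myopia,
            "microstructure": geometry.spec.__dict__.copy() if geometry else None,
        },
    )


def roi_from_region(
    eye: EyeModel, chart: Chart, region: str, padding_frac: float | None = None
) -> RetinalROI:
    """Retinal ROI: paraxial image of a chart region's bounding box."""
    reg = region_bbox(chart, region, padding_frac)
    m = magnification(eye, chart.distance_mm)
    x0, x1, y0, y1 = reg.bbox
    xs = sorted((m * x0, m * x1))
    ys = sorted((m * y0, m * y1))
    return RetinalROI(rects=((xs[0], xs[1], ys[0], ys[1]),), name=reg.name)


def total_flux(imap: IrradianceMap, roi: RetinalROI) -> float:
    """Sum of map bins whose centers fall inside the ROI rectangles."""
    xs, ys = imap.bin_centers()
    xx, yy = np.meshgrid(xs, ys)
    mask = np.zeros_like(xx, dtype=bool)
    for x0, x1, y0, y1 in roi.rects:
        mask |= (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
    return float(imap.bins[mask].sum())
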