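"""Hole-array opacities on the anterior lens surface.

An opacity configuration is an N x N array of ~10 um holes with
center-to-center period P (mm), optionally stacked in L layers.  Its
distribution area is ``(N * P)**2 * L`` (footprint area times layers).

Three ray-interaction models are provided:

``block``
    A ray hitting a hole is absorbed.
``cone``
    A ray hitting a hole is deflected: polar angle drawn from a folded
    Gaussian with the configured half-angle (degrees), azimuth uniform.
``diffractive``
    Like ``cone`` but the half-angle is the first grating-lobe angle of
    the periodic array, ``asin(wavelength / period)`` — a geometric
    surrogate that makes tighter-packed arrays scatter light further from
    the image (no wave amplitudes are computed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MicrostructureSpec",
    "MicrostructureGeometry",
    "FootprintError",
    "build_hole_array",
    "array_area",
    "interact",
    "scatter_sigma_rad",
    "in_hole",
]

SCATTER_MODELS = ("block", "cone", "diffractive")


class FootprintError(ValueError):
    """Hole-array footprint exceeds the lens aperture."""


@dataclass(frozen=True)
class MicrostructureSpec:
    """Parameters of a hole-array opacity.

    ``period_mm`` is the center-to-center spacing (the 0.02-0.07 mm
    column of the reference parameter table); ``hole_diameter_mm``
    defaults to the ~10 um feature size.
    """

    array_count: int  # N: holes per side
    period_mm: float  # P: center-to-center spacing
    hole_diameter_mm: float = 0.01
    layers: int = 1
    placement: str = "periodic"  # "periodic" | "random"
    placement_seed: int = 0
    scatter_model: str = "block"  # "block" | "cone" | "diffractive"
    cone_half_angle_deg: float = 5.0
    wavelength_um: float = 0.55

    def __post_init__(self) -> None:
        if self.array_count < 1:
            raise ValueError("array_count must be >= 1")
        if self.period_mm <= 0:
            raise ValueError("period must be positive")
        if self.hole_diameter_mm > self.period_mm:
            raise ValueError("hole diameter must not exceed the period")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.placement not in ("periodic", "random"):
            raise ValueError(f"placement must be periodic|random, got {self.placement!r}")
        if self.scatter_model not in SCATTER_MODELS:
            raise ValueError(
                f"scatter_model must be one of {SCATTER_MODELS}, got {self.scatter_model!r}"
            )

    @property
    def footprint_side_mm(self) -> float:
        return self.array_count * self.period_mm

    @property
    def area_mm2(self) -> float:
        return array_area(self.array_count, self.period_mm, self.layers)

    @property
    def coverage_fraction(self) -> float:
        """Hole area fraction within the footprint (single layer)."""
        n = self.array_count
        return (
            n**2 * (math.pi / 4.0) * self.hole_diameter_mm**2
            / (n * self.period_mm) ** 2
        )


def array_area(n: int, period_mm: float, layers: int) -> float:
    """Distribution area of the hole array: (N * P)^2 * L, in mm^2."""
    if n < 1 or layers < 1:
        raise ValueError("array count and layers must be >= 1")
    if period_mm <= 0:
        raise ValueError("period must be positive")
    return (n * period_mm) ** 2 * layers


def scatter_sigma_rad(spec: MicrostructureSpec) -> float:
    """Half-angle (radians) of the deflection cone for the spec's model."""
    if spec.scatter_model == "cone":
        return math.radians(spec.cone_half_angle_deg)
    if spec.scatter_model == "diffractive":
        s = spec.wavelength_um * 1e-3 / spec.period_mm
        return math.asin(min(s, 1.0))
    raise ValueError(f"no scatter angle for model {spec.scatter_model!r}")


@dataclass(frozen=True)
class MicrostructureGeometry:
    """Realized hole centers, one (N^2, 2) array per layer, lens-surface mm."""

    spec: MicrostructureSpec
    layer_centers: tuple[np.ndarray, ...]
    footprint_side_mm: float
    _trees: tuple = field(default=None, repr=False, compare=False)

    @property
    def n_holes(self) -> int:
        return sum(len(c) for c in self.layer_centers)

    def trees(self) -> tuple[cKDTree, ...]:
        """KD-trees over each layer's centers (built lazily, cached)."""
        if self._trees is None:
            object.__setattr__(
                self, "_trees", tuple(cKDTree(c) for c in self.layer_centers)
            )
        return self._trees


def build_hole_array(
    spec: MicrostructureSpec, lens_aperture_mm: float | None = None
) -> MicrostructureGeometry:
    """Realize the hole centers of ``spec``.

    Periodic placement puts the N x N lattice centered on the optical
    axis (identical in every layer); random placement draws N^2 centers
    uniformly inside the footprint, fresh per layer, from
    ``spec.placement_seed``.
    """
    side = spec.footprint_side_mm
    if lens_aperture_mm is not None and side > lens_aperture_mm:
        raise FootprintError(
            f"footprint side {side:.3f} mm exceeds lens aperture {lens_aperture_mm:.3f} mm"
        )
    n = spec.array_count
    if spec.placement == "periodic":
        coords = (np.arange(n) - (n - 1) / 2.0) * spec.period_mm
        xx, yy = np.meshgrid(coords, coords)
        lattice = np.column_stack([xx.ravel(), yy.ravel()])
        layers = tuple(lattice for _ in range(spec.layers))
    else:
        rng = np.random.default_rng(spec.placement_seed)
        half = side / 2.0
        layers = tuple(
            rng.uniform(-half, half, size=(n * n, 2)) for _ in range(spec.layers)
        )
    return MicrostructureGeometry(
        spec=spec, layer_centers=layers, footprint_side_mm=side
    )


def in_hole(geometry: MicrostructureGeometry, xy: np.ndarray) -> np.ndarray:
    """(n_points, layers) bool: is each point inside a hole of each layer?

    Periodic layers use exact lattice arithmetic; random layers query a
    KD-tree of centers.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    spec = geometry.spec
    r = spec.hole_diameter_mm / 2.0
    out = np.empty((len(xy), spec.layers), dtype=bool)
    if spec.placement == "periodic":
        n, p = spec.array_count, spec.period_mm
        # nearest lattice index along each axis, clipped to the array
        idx = np.clip(np.rint(xy / p + (n - 1) / 2.0), 0, n - 1)
        nearest = (idx - (n - 1) / 2.0) * p
        d2 = ((xy - nearest) ** 2).sum(axis=1)
        hit = d2 <= r * r
        out[:] = hit[:, None]
    else:
        for k, tree in enumerate(geometry.trees()):
            d, _ = tree.query(xy, k=1)
            out[:, k] = d <= r
    return out


def interact(
    xy: np.ndarray,
    directions: np.ndarray,
    geometry: MicrostructureGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the hole-array interaction to rays crossing the lens surface.

    Parameters
    ----------
    xy:
        (n, 2) transverse hit points on the lens anterior surface, mm.
    directions:
        (n, 3) unit propagation vectors (modified in a copy, not in place).
    geometry, rng:
        Realized hole array and the random stream for scatter draws.

    Returns
    -------
    absorbed:
        (n,) bool — rays absorbed (block model only).
    directions:
        (n, 3) possibly deflected unit vectors.

    A ray outside every hole passes unchanged.  In ``block`` mode a hit in
    any layer absorbs the ray.  In the cone models each layer hit deflects
    the ray by an independent folded-Gaussian polar angle (uniform
    azimuth), so L coincident layers compound the spread.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    directions = np.array(directions, dtype=float, copy=True)
    spec = geometry.spec
    hits = in_hole(geometry, xy)  # (n, L)
    absorbed = np.zeros(len(xy), dtype=bool)
    if spec.scatter_model == "block":
        absorbed = hits.any(axis=1)
        return absorbed, directions
    sigma = scatter_sigma_rad(spec)
    for layer in range(spec.layers):
        sel = hits[:, layer]
        if not sel.any():
            continue
        directions[sel] = _deflect(directions[sel], sigma, rng)
    return absorbed, directions


def _deflect(d: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Tilt each unit vector by |N(0, sigma)| polar angle, uniform azimuth."""
    n = len(d)
    theta = np.abs(rng.normal(0.0, sigma, size=n))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    # orthonormal frame (e1, e2) perpendicular to each d
    helper = np.where(
        np.abs(d[:, 2:3]) < 0.9, np.array([[0.0, 0.0, 1.0]]), np.array([[1.0, 0.0, 0.0]])
    )
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    out = ct * d + st * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out
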