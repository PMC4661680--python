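"""Schematic eye geometry and paraxial optics.

Conventions (used throughout the package):

* Right-handed coordinates, optical axis = +z, pointing from the cornea
  toward the retina.  Transverse coordinates (x, y) in mm.
* Axial positions and radii are in mm; powers and vergences in diopters
  (1 D = 1/m, so ``P = 1000 * (n2 - n1) / R_mm``).
* A surface radius is positive when its center of curvature lies toward
  the retina; ``radius == 0`` denotes a flat surface.
* Object vergence at the corneal vertex is ``1000 * n / l`` with ``l`` the
  (signed, mm) object distance; a real object in front of the eye has
  negative vergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from scipy.optimize import brentq

from .presets import EYE_PRESETS

__all__ = [
    "OpticalSurface",
    "EyeModel",
    "ParaxialState",
    "InvalidGeometryError",
    "MyopiaRangeError",
    "build_schematic_eye",
    "paraxial_trace",
    "paraxial_trace_ray",
    "paraxial_image_z",
    "paraxial_image_height",
    "far_point_diopters",
    "induce_myopia",
    "total_power",
]


class InvalidGeometryError(ValueError):
    """Surfaces out of order, retina inside the lens, or similar."""


class MyopiaRangeError(ValueError):
    """Requested refractive error outside the supported [0, 15] D range."""


@dataclass(frozen=True)
class OpticalSurface:
    """A single spherical (or flat) refracting surface.

    Parameters
    ----------
    vertex_z:
        Axial position of the surface vertex (mm, increasing toward retina).
    radius:
        Signed radius of curvature in mm; positive when the center of
        curvature lies toward the retina, 0 for a flat surface.
    semi_aperture:
        Half-diameter of the clear aperture (mm).
    n_after:
        Refractive index of the medium *following* the surface.
    """

    vertex_z: float
    radius: float
    semi_aperture: float
    n_after: float

    def __post_init__(self) -> None:
        if self.semi_aperture <= 0:
            raise InvalidGeometryError("semi_aperture must be positive")
        if self.n_after < 1.0:
            raise InvalidGeometryError("n_after must be >= 1")
        if self.radius != 0.0 and abs(self.radius) < self.semi_aperture:
            raise InvalidGeometryError(
                "surface cap undefined: |radius| smaller than semi_aperture"
            )

    @property
    def is_flat(self) -> bool:
        return self.radius == 0.0

    def power_diopters(self, n_before: float) -> float:
        """Paraxial power (n2 - n1)/R in diopters; 0 for a flat surface."""
        if self.is_flat:
            return 0.0
        return 1000.0 * (self.n_after - n_before) / self.radius


@dataclass(frozen=True)
class EyeModel:
    """Four-surface schematic eye with a pupil stop and a detector retina.

    ``surfaces`` are ordered cornea anterior, cornea posterior, lens
    anterior, lens posterior.  The stop (iris/pupil) lies between the
    cornea posterior and lens anterior vertices.  The retina is a flat
    detector plane at ``retina_z`` unless ``retina_radius`` is given.
    """

    surfaces: tuple[OpticalSurface, ...]
    stop_z: float
    stop_semi: float
    retina_z: float
    retina_radius: float | None = None
    myopia: float = 0.0
    corneal_thickness: float = field(default=0.55)
    corneal_diameter: float = field(default=11.5)
    name: str = "custom"

    def __post_init__(self) -> None:
        zs = [s.vertex_z for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise InvalidGeometryError("surface vertices must be strictly increasing in z")
        if self.retina_z <= zs[-1]:
            raise InvalidGeometryError("retina must lie behind the last surface")
        if len(self.surfaces) >= 3 and not (zs[1] < self.stop_z < zs[2]):
            raise InvalidGeometryError(
                "pupil stop must lie between the cornea posterior and lens anterior"
            )
        if self.stop_semi <= 0:
            raise InvalidGeometryError("pupil semi-diameter must be positive")
        if self.myopia < 0:
            raise InvalidGeometryError("myopia must be >= 0")

    @property
    def n_image(self) -> float:
        """Refractive index of the image space (vitreous)."""
        return self.surfaces[-1].n_after


@dataclass(frozen=True)
class ParaxialState:
    """Paraxial ray state at a plane: height, reduced angle n*u, vergence."""

    height: float
    angle: float  # reduced angle n * u (dimensionless)
    vergence: float  # diopters


def build_schematic_eye(
    config: dict | str | None = None,
    *,
    preset: str = "legrand_relaxed",
    focus: str = "chart",
    chart_distance_mm: float = 6096.0,
    stop_semi: float | None = None,
    overrides: dict | None = None,
) -> EyeModel:
    """Build a schematic eye from a named preset, solved to emmetropia.

    The retina is placed at the paraxial image of an axial object at
    ``chart_distance_mm`` (``focus="chart"``, default) or at infinity
    (``focus="infinity"``), so the returned eye has zero residual defocus
    for that object by construction.

    ``config`` may be a preset name or a dict with keys ``preset``,
    ``focus``, ``chart_distance_mm``, ``stop_semi``.
    """
    if isinstance(config, str):
        preset = config
    elif isinstance(config, dict):
        preset = config.get("preset", preset)
        focus = config.get("focus", focus)
        chart_distance_mm = config.get("chart_distance_mm", chart_distance_mm)
        stop_semi = config.get("stop_semi", stop_semi)

    if preset not in EYE_PRESETS:
        raise KeyError(f"unknown eye preset {preset!r}; have {sorted(EYE_PRESETS)}")
    p = dict(EYE_PRESETS[preset])
    if overrides:
        p.update(overrides)

    surfaces = tuple(OpticalSurface(*row) for row in p["surfaces"])
    if focus == "infinity":
        v_obj = 0.0
    elif focus == "chart":
        if chart_distance_mm <= 0:
            raise InvalidGeometryError("chart distance must be positive")
        v_obj = -1000.0 / chart_distance_mm
    else:
        raise ValueError(f"focus must be 'chart' or 'infinity', got {focus!r}")

    retina_z = paraxial_image_z(surfaces, v_obj)
    eye = EyeModel(
        surfaces=surfaces,
        stop_z=p["stop_z"],
        stop_semi=stop_semi if stop_semi is not None else p["stop_semi"],
        retina_z=retina_z,
        corneal_thickness=surfaces[1].vertex_z - surfaces[0].vertex_z,
        corneal_diameter=2.0 * surfaces[0].semi_aperture,
        name=preset,
    )
    return eye


def paraxial_trace_ray(
    surfaces: Sequence[OpticalSurface],
    y: float,
    u: float,
    z_start: float = 0.0,
    n_start: float = 1.0,
) -> tuple[float, float]:
    """Trace a paraxial ray (height y mm, real slope u) through ``surfaces``.

    The ray starts at axial position ``z_start`` in a medium of index
    ``n_start``.  Returns ``(y, u)`` immediately after the last surface.
    """
    z, n = z_start, n_start
    for s in surfaces:
        y = y + u * (s.vertex_z - z)
        z = s.vertex_z
        p_mm = 0.0 if s.is_flat else (s.n_after - n) / s.radius
        u = (n * u - y * p_mm) / s.n_after
        n = s.n_after
    return y, u


def paraxial_image_z(surfaces: Sequence[OpticalSurface], object_vergence: float) -> float:
    """Axial position (mm) of the paraxial image of an axial object.

    ``object_vergence`` is the vergence (D) of the object wavefront at the
    first vertex; 0 means an object at infinity.
    """
    z0 = surfaces[0].vertex_z
    # A ray from the axial object point with unit height at the first vertex:
    # slope u = -y * V / (1000 * n); for V=0 the ray is parallel.
    y0 = 1.0
    u0 = -y0 * object_vergence / 1000.0
    y, u = paraxial_trace_ray(surfaces, y0, u0, z_start=z0, n_start=1.0)
    if u == 0.0:
        raise InvalidGeometryError("afocal system: no finite paraxial image")
    return surfaces[-1].vertex_z + (-y / u)


def paraxial_trace(eye: EyeModel, object_vergence: float) -> tuple[ParaxialState, float]:
    """Paraxially trace an axial pencil through the eye.

    Returns the ray state at the retina plane together with the axial
    position of the paraxial image (mm, absolute z).
    """
    if not math.isfinite(object_vergence):
        raise ValueError("object_vergence must be finite")
    z0 = eye.surfaces[0].vertex_z
    y0 = 1.0
    u0 = -y0 * object_vergence / 1000.0
    y, u = paraxial_trace_ray(eye.surfaces, y0, u0, z_start=z0, n_start=1.0)
    image_z = eye.surfaces[-1].vertex_z + (-y / u) if u != 0.0 else math.inf
    y_ret = y + u * (eye.retina_z - eye.surfaces[-1].vertex_z)
    n_img = eye.n_image
    if image_z == eye.retina_z:
        vergence = math.inf
    else:
        vergence = 1000.0 * n_img / (image_z - eye.retina_z)
    return ParaxialState(height=y_ret, angle=n_img * u, vergence=vergence), image_z


def paraxial_image_height(eye: EyeModel, y_obj: float, z_obj: float) -> float:
    """Paraxial image height at the retina of an off-axis object point.

    The object point sits at transverse height ``y_obj`` (mm) and axial
    position ``z_obj`` (mm, negative in front of the cornea).  Exact when
    the object is in focus on the retina; otherwise this is the height of
    the vertex-aimed ray, a good proxy for the blur-patch center at small
    field angles.
    """
    z0 = eye.surfaces[0].vertex_z
    if z_obj >= z0:
        raise ValueError("object must lie in front of the first surface")
    u0 = (0.0 - y_obj) / (z0 - z_obj)
    y, u = paraxial_trace_ray(eye.surfaces, 0.0, u0, z_start=z0, n_start=1.0)
    return y + u * (eye.retina_z - eye.surfaces[-1].vertex_z)


def far_point_diopters(eye: EyeModel) -> float:
    """Refractive error of the eye: -(vergence of the object conjugate to the retina).

    Returns the myopia magnitude in diopters (positive = myopic, i.e. the
    far point lies at 1000/result mm in front of the cornea).  An eye
    focused at infinity returns 0.
    """

    def resid(v: float) -> float:
        return paraxial_image_z(eye.surfaces, v) - eye.retina_z

    # image_z is increasing in object vergence (closer object -> image
    # further back), so bracket the root in [-25, +10] D.
    return -brentq(resid, -25.0, 10.0, xtol=1e-12)


def induce_myopia(eye: EyeModel, diopters: float) -> EyeModel:
    """Return a myopic copy of ``eye`` produced by axial elongation.

    The retina is moved back so the eye's far point lies ``1/diopters``
    meters in front of the cornea; all refracting surfaces are unchanged.
    ``diopters == 0`` returns the eye unchanged.
    """
    if not 0.0 <= diopters <= 15.0:
        raise MyopiaRangeError(f"myopia must be within [0, 15] D, got {diopters}")
    if diopters == 0.0:
        return eye
    new_retina = paraxial_image_z(eye.surfaces, -diopters)
    if new_retina < eye.retina_z:
        raise InvalidGeometryError(
            "requested myopia is below the eye's baseline refractive state"
        )
    return replace(eye, retina_z=new_retina, myopia=diopters)


def total_power(eye: EyeModel) -> float:
    """Equivalent paraxial power of the whole eye in diopters.

    Computed from a parallel unit-height ray: P = -n' u' / y_in (scaled to
    diopters), independent of the stop and retina.
    """
    z0 = eye.surfaces[0].vertex_z
    y, u = paraxial_trace_ray(eye.surfaces, 1.0, 0.0, z_start=z0, n_start=1.0)
    return -1000.0 * eye.n_image * u
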