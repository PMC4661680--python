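"""Flux-vs-diopter calibration and equivalent-myopia prediction.

The calibration curve is the region-of-interest retinal flux of the
chart, swept over induced myopia (axial elongation) on a 0..10 D grid and
normalized to 1 at plano.  For the whole-chart region the curve is
strictly decreasing and is inverted (monotone piecewise-linear) to map a
measured normalized flux back to diopters.  An opacity configuration is
assigned its "equivalent myopia" by simulating the plano eye with the
microstructure, normalizing its ROI flux against the same plano baseline,
and inverting.

By default every sweep point reuses the same source and pupil samples
(common random numbers): with axial elongation only, each ray's landing
point drifts monotonically outward as the retina recedes, so the
whole-chart curve decreases deterministically instead of drowning the
small low-diopter signal in Monte-Carlo noise.  Set
``common_random=False`` for independent substreams per grid point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .chart import Chart, ChartSpec, build_chart, sample_source, select_region
from .eye import EyeModel, induce_myopia
from .microstructure import MicrostructureSpec
from .raytrace import (
    MapSpec,
    _image_window,
    roi_from_region,
    simulate_image,
    total_flux,
)

__all__ = [
    "CalibrationCurve",
    "PredictionReport",
    "CalibrationError",
    "NonMonotoneWarning",
    "NotInvertibleError",
    "FluxOutOfRangeError",
    "build_calibration",
    "equivalent_myopia",
    "predict",
]

DEFAULT_GRID = tuple(float(d) for d in range(11))
DEFAULT_N_RAYS = 200_000


class CalibrationError(RuntimeError):
    """Whole-chart calibration curve failed its monotonicity check."""


class NonMonotoneWarning(UserWarning):
    """A sub-region curve is non-monotone (stray-light behavior); it is
    flagged non-invertible instead of being inverted."""


class NotInvertibleError(RuntimeError):
    pass


class FluxOutOfRangeError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    diopters: np.ndarray
    flux: np.ndarray
    normalized_flux: np.ndarray
    region: str
    invertible: bool
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.diopters, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("diopter grid must be strictly increasing")
        if self.normalized_flux[0] != 1.0:
            raise ValueError("normalized flux must be exactly 1 at the first node")


def build_calibration(
    eye: EyeModel,
    chart: Chart | ChartSpec,
    region: str = "whole",
    grid: tuple[float, ...] = DEFAULT_GRID,
    n_rays: int = DEFAULT_N_RAYS,
    seed: int = 0,
    map_spec: MapSpec | None = None,
    common_random: bool = True,
) -> CalibrationCurve:
    """Sweep induced myopia over ``grid`` and record normalized ROI flux.

    One simulation + flux integration per grid point.  The ROI is the
    paraxial image of the region bounding box in the *base* eye, held
    fixed across the sweep.  The grid must start at 0 (the normalization
    anchor).
    """
    if grid[0] != 0.0:
        raise ValueError("diopter grid must start at 0 (plano anchor)")
    if n_rays < 10_000:
        raise ValueError("calibration needs at least 1e4 rays per point")
    if isinstance(chart, ChartSpec):
        chart = build_chart(chart)
    chart_sel = select_region(chart, region)
    roi = roi_from_region(eye, chart, region)
    if map_spec is None:
        map_spec = MapSpec()
    # keep the binning window fixed across the sweep (plano geometry)
    if map_spec.window is None:
        probe = sample_source(chart_sel, 1, seed=0)
        map_spec = MapSpec(
            n_bins=map_spec.n_bins,
            window=_image_window(eye, probe, map_spec.margin),
            margin=map_spec.margin,
        )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(grid))
    sim_seed0 = int(children[1].generate_state(1)[0])
    shared_source = None
    if common_random:
        shared_source = sample_source(
            chart_sel, n_rays, seed=np.random.default_rng(children[0])
        )

    flux = np.empty(len(grid))
    for i, d in enumerate(grid):
        if common_random:
            source = shared_source
            sim_seed = sim_seed0
        else:
            source = sample_source(
                chart_sel, n_rays, seed=np.random.default_rng(children[2 * i])
            )
            sim_seed = int(children[2 * i + 1].generate_state(1)[0])
        eye_d = induce_myopia(eye, d)
        imap = simulate_image(eye_d, source, map_spec=map_spec, seed=sim_seed)
        flux[i] = total_flux(imap, roi)

    normalized = flux / flux[0]
    normalized[0] = 1.0
    decreasing = bool(np.all(np.diff(normalized) < 0))
    if not decreasing:
        if region == "whole":
            raise CalibrationError(
                "whole-chart calibration curve is not strictly decreasing at "
                f"{n_rays} rays; increase the budget"
            )
        warnings.warn(
            f"calibration curve for region {region!r} is non-monotone "
            "(stray light); curve flagged non-invertible",
            NonMonotoneWarning,
            stacklevel=2,
        )
    return CalibrationCurve(
        diopters=np.asarray(grid, dtype=float),
        flux=flux,
        normalized_flux=normalized,
        region=region,
        invertible=decreasing,
        metadata={
            "seed": seed,
            "n_rays": n_rays,
            "eye": eye.name,
            "common_random": common_random,
            "n_bins": map_spec.n_bins,
            "window": map_spec.window,
        },
    )


def equivalent_myopia(curve: CalibrationCurve, flux_normalized: float) -> float:
    """Invert the calibration curve by monotone piecewise-linear interpolation.

    Exact at grid nodes.  Raises :class:`FluxOutOfRangeError` outside
    [flux(max D), flux(0)] and :class:`NotInvertibleError` for flagged
    (non-monotone) curves.
    """
    if not curve.invertible:
        raise NotInvertibleError(
            f"curve for region {curve.region!r} is non-monotone; cannot invert"
        )
    f = curve.normalized_flux
    if flux_normalized > f[0] or flux_normalized < f[-1]:
        raise FluxOutOfRangeError(
            f"normalized flux {flux_normalized} outside curve range [{f[-1]}, {f[0]}]"
        )
    # np.interp wants increasing x; the curve is decreasing in flux
    return float(np.interp(flux_normalized, f[::-1], curve.diopters[::-1]))


@dataclass(frozen=True)
class PredictionReport:
    """Equivalent-myopia assignment for one opacity configuration.

    ``equivalent_myopia_centi`` follows the clinical "degree" convention
    (100 per diopter, as in the reference parameter table).
    """

    spec: MicrostructureSpec
    measured_flux_normalized: float
    equivalent_myopia: float | None
    equivalent_myopia_centi: float | None
    status: str  # ok | indistinguishable | out-of-range
    detection_threshold: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = asdict(self.spec)
        return d


def predict(
    eye: EyeModel,
    chart: Chart | ChartSpec,
    curve: CalibrationCurve,
    spec: MicrostructureSpec | None,
    n_rays: int = DEFAULT_N_RAYS,
    seed: int = 0,
    threshold_sigma: float = 3.0,
    map_spec: MapSpec | None = None,
) -> PredictionReport:
    """Assign an equivalent myopia to an opacity configuration.

    Simulates the plano eye with and without the microstructure using the
    same primary rays (the scatter stream is independent), normalizes the
    opacified ROI flux by the clean plano flux, and inverts the
    calibration curve.  A flux deficit smaller than ``threshold_sigma``
    Monte-Carlo standard errors of the plano flux is reported as
    ``indistinguishable`` (the "cannot be distinguished" case).
    """
    if curve.region != "whole":
        raise ValueError("prediction requires a whole-chart calibration curve")
    if isinstance(chart, ChartSpec):
        chart = build_chart(chart)
    roi = roi_from_region(eye, chart, "whole")
    if map_spec is None:
        map_spec = MapSpec()
    ss = np.random.SeedSequence(seed)
    src_child, sim_child = ss.spawn(2)
    source = sample_source(chart, n_rays, seed=np.random.default_rng(src_child))
    sim_seed = int(sim_child.generate_state(1)[0])

    base = simulate_image(eye, source, map_spec=map_spec, seed=sim_seed)
    f0 = total_flux(base, roi)
    if f0 <= 0:
        raise RuntimeError("plano baseline flux is zero; check the configuration")

    if spec is None:
        f1 = f0
    else:
        opaque = simulate_image(
            eye, source, map_spec=map_spec, seed=sim_seed, microstructure=spec
        )
        f1 = total_flux(opaque, roi)

    measured = f1 / f0
    # binomial standard error of the plano in-ROI flux
    w = source.power_per_point
    p_hit = f0 / base.launched
    se = w * math.sqrt(n_rays * p_hit * (1.0 - p_hit))
    threshold = threshold_sigma * se / f0

    deficit = 1.0 - measured
    if deficit <= threshold:
        status = "indistinguishable"
        eq = 0.0 if measured > 1.0 else _invert_clipped(curve, measured)
    else:
        try:
            eq = equivalent_myopia(curve, measured)
            status = "ok"
        except FluxOutOfRangeError:
            status = "out-of-range"
            eq = None
    return PredictionReport(
        spec=spec,
        measured_flux_normalized=measured,
        equivalent_myopia=eq,
        equivalent_myopia_centi=None if eq is None else 100.0 * eq,
        status=status,
        detection_threshold=threshold,
        metadata={
            "seed": seed,
            "n_rays": n_rays,
            "eye": eye.name,
            "scatter_model": spec.scatter_model if spec else None,
            "curve_seed": curve.metadata.get("seed"),
        },
    )


def _invert_clipped(curve: CalibrationCurve, measured: float) -> float:
    try:
        return equivalent_myopia(curve, min(measured, 1.0))
    except (FluxOutOfRangeError, NotInvertibleError):
        return 0.0
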