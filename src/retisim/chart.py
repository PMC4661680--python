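"""Snellen chart as an emissive extended source.

The chart is a set of block optotypes built on the 5x5 stroke grid
(:mod:`retisim.glyphs`).  Letter sizes follow the acuity definition: the
20/20 row subtends 5 arc minutes at the 20 ft reference distance, and a
20/X row is X/20 times taller.  Chart coordinates are mm in the chart
plane, centered on the optical axis, +y up; the plane sits at
``z = -distance_mm``.

Lit areas are exact by construction: every glyph cell has area
``(h/5)**2``, so the lit area of a letter of height ``h`` is
``lit_cells * (h/5)**2`` (17/25 h**2 for the block "E").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .glyphs import GLYPHS

__all__ = [
    "ARCMIN",
    "REFERENCE_DISTANCE_MM",
    "ChartSpec",
    "ChartRegion",
    "Chart",
    "Letter",
    "SourceSampleSet",
    "REGION_NAMES",
    "UnknownRegionError",
    "EmptyRegionError",
    "build_chart",
    "render_chart",
    "rasterize",
    "region_bbox",
    "select_region",
    "sample_source",
]

ARCMIN = math.pi / 10800.0  # radians per arc minute
REFERENCE_DISTANCE_MM = 6096.0  # 20 ft
#: Physical height of a 20/20 letter: 5 arc min at the 20 ft reference.
LETTER_HEIGHT_2020_MM = REFERENCE_DISTANCE_MM * 5.0 * ARCMIN

DEFAULT_ROWS: tuple[tuple[str, str], ...] = (
    ("20/200", "E"),
    ("20/100", "FP"),
    ("20/70", "TOZ"),
    ("20/50", "LPED"),
    ("20/40", "PEDFZ"),
    ("20/30", "ELOPZD"),
    ("20/25", "FELOPZD"),
    ("20/20", "DEFPOTEL"),
)


class UnknownRegionError(KeyError):
    pass


class EmptyRegionError(ValueError):
    pass


@dataclass(frozen=True)
class ChartSpec:
    """Chart layout and photometry.

    ``luminance`` is emitted power per unit lit area (arbitrary units per
    mm^2).  ``letter_gap_factor`` and ``row_gap_factor`` are gaps in units
    of the local letter height.
    """

    distance_mm: float = REFERENCE_DISTANCE_MM
    rows: tuple[tuple[str, str], ...] = DEFAULT_ROWS
    luminance: float = 1.0
    letter_gap_factor: float = 1.0
    row_gap_factor: float = 1.0
    region_padding: float = 0.1  # fraction of letter height, sub-regions only

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError("chart distance must be positive")
        if self.luminance <= 0:
            raise ValueError("luminance must be positive")
        for label, letters in self.rows:
            self._acuity_denominator(label)
            for c in letters:
                if c not in GLYPHS:
                    raise KeyError(f"no glyph for letter {c!r}")

    @staticmethod
    def _acuity_denominator(label: str) -> float:
        num, _, den = label.partition("/")
        if num != "20" or not den:
            raise ValueError(f"acuity label must look like '20/40', got {label!r}")
        return float(den)

    def row_height(self, row_index: int) -> float:
        """Physical letter height (mm) of a row."""
        den = self._acuity_denominator(self.rows[row_index][0])
        return den / 20.0 * LETTER_HEIGHT_2020_MM


@dataclass(frozen=True)
class Letter:
    """One placed optotype: lower-left corner (x0, y0), height h, 5x5 mask."""

    char: str
    x0: float
    y0: float
    h: float
    mask: np.ndarray  # (5, 5) bool, mask[0] = top stroke row
    row: int

    @property
    def cell(self) -> float:
        return self.h / 5.0

    @property
    def lit_area(self) -> float:
        return float(self.mask.sum()) * self.cell**2

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.x0, self.x0 + self.h, self.y0, self.y0 + self.h)

    def cell_centers(self) -> np.ndarray:
        """(k, 2) centers of the lit cells, chart coordinates."""
        ii, jj = np.nonzero(self.mask)
        c = self.cell
        x = self.x0 + (jj + 0.5) * c
        y = self.y0 + (4 - ii + 0.5) * c
        return np.column_stack([x, y])


@dataclass(frozen=True)
class ChartRegion:
    """A named rectangular selection in chart coordinates."""

    name: str
    bbox: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


@dataclass(frozen=True)
class Chart:
    """A built chart: placed letters plus the originating spec."""

    spec: ChartSpec
    letters: tuple[Letter, ...]
    region: str = "whole"

    @property
    def extent(self) -> tuple[float, float, float, float]:
        xs0 = min(l.x0 for l in self.letters)
        xs1 = max(l.x0 + l.h for l in self.letters)
        ys0 = min(l.y0 for l in self.letters)
        ys1 = max(l.y0 + l.h for l in self.letters)
        return (xs0, xs1, ys0, ys1)

    @property
    def lit_area(self) -> float:
        return float(sum(l.lit_area for l in self.letters))

    @property
    def distance_mm(self) -> float:
        return self.spec.distance_mm


def build_chart(spec: ChartSpec) -> Chart:
    """Place every letter of ``spec`` on the chart plane, centered on axis."""
    heights = [spec.row_height(r) for r in range(len(spec.rows))]
    gaps = [spec.row_gap_factor * heights[r + 1] for r in range(len(heights) - 1)]
    total_h = sum(heights) + sum(gaps)
    y_top = total_h / 2.0

    letters: list[Letter] = []
    for r, (_, chars) in enumerate(spec.rows):
        h = heights[r]
        gap = spec.letter_gap_factor * h
        width = len(chars) * h + (len(chars) - 1) * gap
        x = -width / 2.0
        y0 = y_top - h
        for c in chars:
            mask = np.array(
                [[ch == "#" for ch in row] for row in GLYPHS[c]], dtype=bool
            )
            letters.append(Letter(char=c, x0=x, y0=y0, h=h, mask=mask, row=r))
            x += h + gap
        y_top = y0 - (gaps[r] if r < len(gaps) else 0.0)
    return Chart(spec=spec, letters=tuple(letters))


def rasterize(chart: Chart, pixel_size: float = 0.5) -> tuple[np.ndarray, tuple]:
    """Binary bitmap of the chart (rows top-to-bottom) plus its extent.

    The bitmap is a rendering aid; area bookkeeping uses the exact cell
    counts, not pixels.
    """
    x0, x1, y0, y1 = chart.extent
    nx = max(1, int(math.ceil((x1 - x0) / pixel_size)))
    ny = max(1, int(math.ceil((y1 - y0) / pixel_size)))
    img = np.zeros((ny, nx), dtype=np.uint8)
    xc = x0 + (np.arange(nx) + 0.5) * pixel_size
    yc = y1 - (np.arange(ny) + 0.5) * pixel_size
    for letter in chart.letters:
        c = letter.cell
        jj = np.floor((xc - letter.x0) / c).astype(int)
        ii = np.floor((letter.y0 + letter.h - yc) / c).astype(int)
        okx = (jj >= 0) & (jj < 5)
        oky = (ii >= 0) & (ii < 5)
        sub = np.zeros((ny, nx), dtype=bool)
        sub[np.ix_(oky, okx)] = letter.mask[np.ix_(ii[oky], jj[okx])]
        img |= sub.astype(np.uint8)
    return img, (x0, x1, y0, y1)


def render_chart(
    spec: ChartSpec, pixel_size: float = 0.5
) -> tuple[np.ndarray, float]:
    """Render the chart; returns (binary bitmap, exact lit area in mm^2)."""
    chart = build_chart(spec)
    img, _ = rasterize(chart, pixel_size=pixel_size)
    return img, chart.lit_area


REGION_NAMES = ("whole", "E", "EFP", "EFPTOZ", "rows2to4", "rows5to8")
_REGION_ROWS: dict[str, tuple[int, ...]] = {
    "E": (0,),
    "EFP": (0, 1),
    "EFPTOZ": (0, 1, 2),
    "rows2to4": (1, 2, 3),
    "rows5to8": (4, 5, 6, 7),
}


def region_bbox(
    chart: Chart, name: str, padding_frac: float | None = None
) -> ChartRegion:
    """Bounding box of a named selection region.

    ``whole`` is the exact chart extent.  Sub-regions are the union bbox
    of their rows' letters padded by ``padding_frac`` of the tallest
    letter in the region, then clipped to the chart extent (so whole
    always contains every sub-region).
    """
    if name == "whole":
        return ChartRegion(name="whole", bbox=chart.extent)
    if name not in _REGION_ROWS:
        raise UnknownRegionError(
            f"unknown region {name!r}; known: {REGION_NAMES}"
        )
    if padding_frac is None:
        padding_frac = chart.spec.region_padding
    rows = _REGION_ROWS[name]
    sel = [l for l in chart.letters if l.row in rows]
    if not sel:
        raise UnknownRegionError(f"region {name!r} selects no letters on this chart")
    x0 = min(l.x0 for l in sel)
    x1 = max(l.x0 + l.h for l in sel)
    y0 = min(l.y0 for l in sel)
    y1 = max(l.y0 + l.h for l in sel)
    pad = padding_frac * max(l.h for l in sel)
    ex0, ex1, ey0, ey1 = chart.extent
    bbox = (
        max(x0 - pad, ex0),
        min(x1 + pad, ex1),
        max(y0 - pad, ey0),
        min(y1 + pad, ey1),
    )
    return ChartRegion(name=name, bbox=bbox)


def select_region(chart: Chart, region: str | ChartRegion) -> Chart:
    """Mask the chart to a region: cells whose centers fall outside go dark."""
    reg = region_bbox(chart, region) if isinstance(region, str) else region
    if reg.name == "whole":
        return replace(chart, region="whole")
    x0, x1, y0, y1 = reg.bbox
    kept: list[Letter] = []
    for letter in chart.letters:
        ii, jj = np.nonzero(letter.mask)
        c = letter.cell
        cx = letter.x0 + (jj + 0.5) * c
        cy = letter.y0 + (4 - ii + 0.5) * c
        inside = (cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1)
        if inside.any():
            new_mask = np.zeros_like(letter.mask)
            new_mask[ii[inside], jj[inside]] = True
            kept.append(replace(letter, mask=new_mask))
    if not kept:
        raise EmptyRegionError(f"region {reg.name!r} contains no lit cells")
    return Chart(spec=chart.spec, letters=tuple(kept), region=reg.name)


@dataclass(frozen=True)
class SourceSampleSet:
    """Monte-Carlo point samples of the lit chart strokes.

    Each point emits toward the pupil disc (importance sampling); per-point
    power is ``total_power / n``, so the sum of sample powers equals
    ``luminance * lit_area`` exactly.
    """

    points: np.ndarray  # (n, 2) chart-plane positions, mm
    z: float  # chart plane axial position (mm, negative)
    power_per_point: float
    total_power: float
    chart_extent: tuple[float, float, float, float]
    distance_mm: float

    @property
    def n(self) -> int:
        return len(self.points)


def sample_source(
    chart: Chart, n_samples: int, seed: int | np.random.Generator = 0
) -> SourceSampleSet:
    """Sample ``n_samples`` points uniformly over the lit area of ``chart``."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    centers = []
    sizes = []
    for letter in chart.letters:
        cc = letter.cell_centers()
        if len(cc):
            centers.append(cc)
            sizes.append(np.full(len(cc), letter.cell))
    if not centers:
        raise EmptyRegionError("chart has no lit cells to sample")
    centers = np.concatenate(centers)
    sizes = np.concatenate(sizes)
    areas = sizes**2
    lit_area = float(areas.sum())
    probs = areas / lit_area

    idx = rng.choice(len(centers), size=n_samples, p=probs)
    offsets = (rng.random((n_samples, 2)) - 0.5) * sizes[idx, None]
    points = centers[idx] + offsets

    total_power = chart.spec.luminance * lit_area
    return SourceSampleSet(
        points=points,
        z=-chart.distance_mm,
        power_per_point=total_power / n_samples,
        total_power=total_power,
        chart_extent=chart.extent,
        distance_mm=chart.distance_mm,
    )
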