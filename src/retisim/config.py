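"""Run configuration: YAML loading, validation, and fixture generation.

A run config fully resolves to concrete values and is serialized verbatim
into every output's metadata, so any run can be reproduced bit-for-bit
from its own sidecar given the same seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chart import ChartSpec, DEFAULT_ROWS, build_chart, rasterize
from .eye import EyeModel, MyopiaRangeError, build_schematic_eye
from .microstructure import MicrostructureSpec, build_hole_array

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "resolve_eye",
    "resolve_chart_spec",
    "resolve_microstructure",
    "make_fixtures",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved simulation configuration (all defaults applied)."""

    eye: dict = field(
        default_factory=lambda: {
            "preset": "legrand_relaxed",
            "focus": "chart",
            "stop_semi": 2.0,
        }
    )
    chart: dict = field(
        default_factory=lambda: {
            "distance_mm": 6096.0,
            "luminance": 1.0,
            "letter_gap_factor": 1.0,
            "row_gap_factor": 1.0,
            "region_padding": 0.1,
        }
    )
    region: str = "whole"
    myopia_grid: tuple[float, ...] = tuple(float(d) for d in range(11))
    microstructure: dict | None = None
    n_rays: int = 200_000
    n_bins: int = 256
    seed: int = 0
    outdir: str = "runs"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["myopia_grid"] = list(self.myopia_grid)
        return d


_SECTION_KEYS = {
    "eye": {"preset", "focus", "chart_distance_mm", "stop_semi"},
    "chart": {
        "distance_mm",
        "luminance",
        "letter_gap_factor",
        "row_gap_factor",
        "region_padding",
        "rows",
    },
    "microstructure": {
        "array_count",
        "period_mm",
        "hole_diameter_mm",
        "layers",
        "placement",
        "placement_seed",
        "scatter_model",
        "cone_half_angle_deg",
        "wavelength_um",
    },
}
_TOP_KEYS = {
    "eye",
    "chart",
    "region",
    "myopia_grid",
    "microstructure",
    "n_rays",
    "n_bins",
    "seed",
    "outdir",
}


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; an empty file means all defaults.

    Unknown keys are rejected.  Myopia grid entries must lie in the
    calibration domain [0, 10] D (a :class:`MyopiaRangeError` otherwise).
    """
    if data is None:
        if path is None:
            data = {}
        else:
            try:
                with open(path) as fh:
                    data = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        sub = data.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {section!r}: {sorted(bad)}")

    defaults = RunConfig()
    merged_eye = {**defaults.eye, **data.get("eye", {})}
    merged_chart = {**defaults.chart, **data.get("chart", {})}
    if "rows" in merged_chart:
        merged_chart["rows"] = [tuple(r) for r in merged_chart["rows"]]
    grid = tuple(float(d) for d in data.get("myopia_grid", defaults.myopia_grid))
    for d in grid:
        if not 0.0 <= d <= 10.0:
            raise MyopiaRangeError(
                f"myopia grid value {d} outside the calibration domain [0, 10] D"
            )
    cfg = RunConfig(
        eye=merged_eye,
        chart=merged_chart,
        region=data.get("region", defaults.region),
        myopia_grid=grid,
        microstructure=data.get("microstructure"),
        n_rays=int(data.get("n_rays", defaults.n_rays)),
        n_bins=int(data.get("n_bins", defaults.n_bins)),
        seed=int(data.get("seed", defaults.seed)),
        outdir=str(data.get("outdir", defaults.outdir)),
    )
    # fail fast on invalid nested specs
    resolve_chart_spec(cfg)
    resolve_microstructure(cfg)
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """YAML serialization; ``load_config(data=yaml.safe_load(...))`` round-trips."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def resolve_eye(cfg: RunConfig) -> EyeModel:
    eye_cfg = dict(cfg.eye)
    eye_cfg.setdefault("chart_distance_mm", cfg.chart["distance_mm"])
    return build_schematic_eye(eye_cfg)


def resolve_chart_spec(cfg: RunConfig) -> ChartSpec:
    c = dict(cfg.chart)
    rows = c.pop("rows", None)
    spec = ChartSpec(rows=tuple(tuple(r) for r in rows) if rows else DEFAULT_ROWS, **c)
    return spec


def resolve_microstructure(cfg: RunConfig) -> MicrostructureSpec | None:
    if cfg.microstructure is None:
        return None
    return MicrostructureSpec(**cfg.microstructure)


def run_metadata(cfg: RunConfig) -> dict:
    return {"version": __version__, "config": cfg.to_dict()}


def make_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write a tiny deterministic test scene (sub-second to simulate).

    Emits a one-letter chart config with a 3-point diopter grid and a
    2x2 microstructure, the realized hole centers as CSV, and a small
    ASCII-PGM chart bitmap.  Identical seeds give byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    placement_seed = int(rng.integers(0, 2**31 - 1))

    cfg_data = {
        "chart": {"rows": [["20/200", "E"]]},
        "myopia_grid": [0.0, 2.0, 4.0],
        "microstructure": {
            "array_count": 2,
            "period_mm": 1.0,
            "hole_diameter_mm": 0.01,
            "layers": 1,
            "placement": "periodic",
            "placement_seed": placement_seed,
        },
        "n_rays": 20_000,
        "n_bins": 64,
        "seed": int(seed),
    }
    cfg = load_config(data=cfg_data)
    written = []

    cfg_path = out / "fixture_config.yaml"
    cfg_path.write_text(dump_config(cfg))
    written.append(cfg_path)

    geom = build_hole_array(resolve_microstructure(cfg))
    lines = ["layer,x_mm,y_mm"]
    for k, centers in enumerate(geom.layer_centers):
        for x, y in centers:
            lines.append(f"{k},{x:.6f},{y:.6f}")
    holes_path = out / "fixture_holes.csv"
    holes_path.write_text("\n".join(lines) + "\n")
    written.append(holes_path)

    chart = build_chart(resolve_chart_spec(cfg))
    img, _ = rasterize(chart, pixel_size=chart.letters[0].cell / 2.0)
    pgm_path = out / "fixture_chart.pgm"
    pgm_path.write_text(_to_pgm(img))
    written.append(pgm_path)
    return written


def _to_pgm(img: np.ndarray) -> str:
    h, w = img.shape
    rows = [" ".join("1" if v else "0" for v in row) for row in img]
    return f"P2\n{w} {h}\n1\n" + "\n".join(rows) + "\n"
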