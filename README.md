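# retisim

Monte-Carlo retinal imaging with a schematic eye.

`retisim` simulates a Snellen chart viewed through a four-surface schematic
human eye and quantifies image degradation by total retinal flux. Vision can
be degraded two ways:

* **Myopia** — axial elongation moving the retina behind the paraxial focus
  (0–10 D sweeps), or
* **Lens opacities** — periodic (or randomized) arrays of ~10 µm holes on
  the anterior lens surface, interacting with rays by blocking or
  cone/grating-like scattering.

Sweeping myopia yields a **calibration curve** of normalized whole-chart
retinal flux versus diopters (1 at plano, strictly decreasing). Inverting
this curve assigns any opacity configuration an **equivalent myopia**: the
defocus whose flux loss matches the opacity's — a severity score for the
opacity (also reported in centi-diopter clinical "degrees").

## Package layout

| module | contents |
| --- | --- |
| `retisim.eye` | `OpticalSurface`, `EyeModel`, paraxial solver, emmetropia construction, `induce_myopia` (axial elongation to a prescribed far point) |
| `retisim.chart` | 5×5-grid block optotypes, chart layout, six selection regions, uniform source sampling with exact power bookkeeping |
| `retisim.raytrace` | vector-Snell sequential tracer (vectorized over ray bundles), pupil importance sampling, `IrradianceMap` binning, ROI flux integration |
| `retisim.microstructure` | hole-array specs/geometry, the distribution-area formula `(N·P)²·L`, block / cone / diffractive interaction models |
| `retisim.calibrate` | calibration curve build + monotonicity checks, piecewise-linear inversion, `predict` with an indistinguishability threshold |
| `retisim.config`, `retisim.cli` | YAML run configs, deterministic fixtures, `retisim` CLI |

Every geometric/numeric kernel is cross-checked in the tests against an
independent oracle: a 2×2 ray-transfer-matrix product (paraxial trace),
`np.roots` (sphere intersection), the scalar Snell law (vector refraction),
the folded-normal closed form (cone scatter), and a paraxial blur-disc
prediction (Monte-Carlo spot size).

## CLI

```bash
retisim area --n 100 --period 0.05 --layers 1      # hole-array area, mm^2
retisim render-chart --out runs/chart              # chart bitmap + lit area
retisim simulate --myopia 5 --out runs/sim         # irradiance map + totals
retisim calibrate --out runs/cal                   # flux-vs-diopter curve CSV
retisim predict --config cfg.yaml --out runs/pred  # equivalent-myopia report
retisim fixtures --out runs/fixtures               # tiny deterministic scene
```

All commands accept `--config` (YAML; unknown keys rejected; empty file =
defaults) and write a `metadata.json` sidecar embedding the fully resolved
config and package version, so any run is reproducible from its own outputs.
Example config:

```yaml
eye: {preset: legrand_relaxed, focus: chart}
chart: {distance_mm: 6096.0, luminance: 1.0}
region: whole
myopia_grid: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
microstructure:
  array_count: 50
  period_mm: 0.05
  layers: 2
  scatter_model: diffractive   # block | cone | diffractive
n_rays: 200000
seed: 1
```

## Notes

* Geometric optics only: no diffraction amplitudes, polarization, chromatic
  dispersion, or accommodation. The `diffractive` scatter model is a ray
  surrogate (deflection cone with half-angle `asin(wavelength/period)`).
* The eye preset is data (`retisim/presets.py`); results that matter are
  properties (emmetropia, far-point round trips, monotonicity, rank
  ordering), not preset-specific values.
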