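"""Named parameter sets: eye geometries and chart layouts.

These are data, not code: substitute your own preset by passing
``overrides`` to :func:`retisim.eye.build_schematic_eye` or by adding an
entry here.  Surface rows are ``(vertex_z, radius, semi_aperture,
n_after)`` in mm / refractive index, ordered cornea anterior, cornea
posterior, lens anterior, lens posterior.
"""

# Four-surface relaxed schematic eye (uniform-index lens), after the
# classic full theoretical eye tabulations.  Corneal center thickness
# 0.55 mm, corneal diameter 11.5 mm, lens diameter 10 mm.
EYE_PRESETS: dict[str, dict] = {
    "legrand_relaxed": {
        "surfaces": [
            (0.00, 7.80, 5.75, 1.3771),   # cornea anterior -> cornea
            (0.55, 6.50, 5.75, 1.3374),   # cornea posterior -> aqueous
            (3.60, 10.20, 5.00, 1.4200),  # lens anterior -> lens
            (7.60, -6.00, 5.00, 1.3360),  # lens posterior -> vitreous
        ],
        "stop_z": 3.0,
        "stop_semi": 2.0,  # 4 mm pupil diameter (fixed photopic default)
    },
}

# Chart distances (mm).  The acuity definition references 20 ft; a 6 ft
# viewing preset is provided as a named alternative.
CHART_DISTANCES_MM: dict[str, float] = {
    "20ft": 6096.0,
    "6ft": 1828.8,
}
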