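"""Published derived rows of the bundled immersion dataset (2 d.p.).

The bundled CSV carries only the measured quantities (mass, geometry,
velocity); these are the independently published derived rows the package
must reproduce from them: bulk density (g/cm^3), wet-basis mass moisture and
volumetric moisture (fractions), 15 timepoints x 3 samples each.
"""

DENSITY = {
    "cyl6": [0.60, 0.63, 0.68, 0.69, 0.71, 0.74, 0.78, 0.79, 0.85, 0.85, 0.88, 0.88, 0.91, 1.00, 1.02],
    "cyl7": [0.41, 0.46, 0.47, 0.47, 0.48, 0.49, 0.53, 0.53, 0.58, 0.59, 0.61, 0.62, 0.64, 0.71, 0.73],
    "cyl10": [0.37, 0.40, 0.41, 0.42, 0.42, 0.43, 0.47, 0.48, 0.52, 0.53, 0.54, 0.55, 0.57, 0.63, 0.65],
}

MASS_MOISTURE = {
    "cyl6": [0.00, 0.04, 0.11, 0.12, 0.15, 0.19, 0.22, 0.23, 0.29, 0.29, 0.31, 0.32, 0.34, 0.40, 0.41],
    "cyl7": [0.00, 0.09, 0.12, 0.13, 0.14, 0.16, 0.22, 0.23, 0.29, 0.31, 0.33, 0.33, 0.35, 0.42, 0.43],
    "cyl10": [0.00, 0.05, 0.08, 0.11, 0.11, 0.13, 0.20, 0.21, 0.28, 0.29, 0.31, 0.32, 0.34, 0.40, 0.42],
}

VOLUMETRIC_MOISTURE = {
    "cyl6": [0.00, 0.02, 0.08, 0.09, 0.11, 0.14, 0.17, 0.18, 0.25, 0.25, 0.27, 0.28, 0.31, 0.40, 0.42],
    "cyl7": [0.00, 0.04, 0.05, 0.06, 0.07, 0.08, 0.11, 0.12, 0.17, 0.18, 0.20, 0.20, 0.23, 0.30, 0.32],
    "cyl10": [0.00, 0.02, 0.03, 0.04, 0.05, 0.06, 0.09, 0.10, 0.15, 0.15, 0.17, 0.17, 0.20, 0.25, 0.27],
}


def round_half_up_2dp(x: float) -> float:
    """Round to 2 decimals with ties away from zero (table printing rule)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
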