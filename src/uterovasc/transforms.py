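"""Variable transformations used throughout the association analysis.

Volumetric markers are analysed on the cube-root scale, count/length/
thickness markers on the square-root scale, and branching densities on the
natural-log scale; serum PlGF and sFlt-1 and both biomarker ratios enter the
models log-transformed while sEng enters untransformed.  These are the scales
on which the association coefficients are defined, and the synthetic cohort
generator injects its true coefficients on the same scales so fitted and true
values are directly comparable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "transform_marker",
    "inverse_transform",
    "MARKER_TRANSFORMS",
    "BIOMARKER_TRANSFORMS",
    "MARKER_NAMES",
    "BIOMARKER_NAMES",
]

_FAMILIES = {
    "sqrt": (np.sqrt, np.square),
    "cbrt": (np.cbrt, lambda y: np.power(y, 3.0)),
    "ln": (np.log, np.exp),
    "identity": (lambda x: np.asarray(x, dtype=float), lambda y: np.asarray(y, dtype=float)),
}

#: Imaging marker -> transform family (volumes cbrt, counts/lengths sqrt,
#: densities ln).
MARKER_TRANSFORMS = {
    "pv_cm3": "cbrt",
    "upvv_cm3": "cbrt",
    "end_points": "sqrt",
    "bifurcation_points": "sqrt",
    "crossing_points": "sqrt",
    "vessel_points": "sqrt",
    "total_length_mm": "sqrt",
    "avg_thickness_mm": "sqrt",
    "density_end": "ln",
    "density_bifurcation": "ln",
    "density_crossing": "ln",
}

#: Serum biomarker -> transform family.  sEng enters the models on its
#: natural scale; PlGF, sFlt-1 and the ratios are log-transformed.
BIOMARKER_TRANSFORMS = {
    "plgf": "ln",
    "sflt1": "ln",
    "seng": "identity",
    "sflt1_plgf_ratio": "ln",
    "seng_plgf_ratio": "ln",
}

MARKER_NAMES = list(MARKER_TRANSFORMS)
BIOMARKER_NAMES = list(BIOMARKER_TRANSFORMS)


def transform_marker(x, family: str):
    """Apply an elementary transform (sqrt / cbrt / ln / identity).

    sqrt and cbrt require x >= 0; ln requires x > 0.  A zero under ln usually
    means a zero branching count; offset such values first (see
    :func:`uterovasc.association.transformed_frame`).
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown transform family {family!r}")
    x = np.asarray(x, dtype=float)
    if family in ("sqrt", "cbrt") and (x < 0).any():
        raise ValueError(f"{family} transform requires nonnegative input")
    if family == "ln" and (x <= 0).any():
        raise ValueError(
            "ln transform requires positive input; zero counts must be offset "
            "by half the smallest positive observed value first"
        )
    return _FAMILIES[family][0](x)


def inverse_transform(y, family: str):
    """Invert :func:`transform_marker`; exact round-trip on positive inputs."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown transform family {family!r}")
    return _FAMILIES[family][1](np.asarray(y, dtype=float))
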