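"""Anterior–posterior axis conventions shared across modules.

An AP axis is written ``"x+"``, ``"x-"``, ``"y+"`` or ``"y-"``: the named image
axis, signed by the direction in which *posterior* position increases.  With
``"x+"`` the posterior edge of the image is the right-hand (max-x) edge and the
anterior edge is the left-hand one.  Images are indexed ``[y, x]`` (numpy row,
column), origin top-left.
"""

from __future__ import annotations

import numpy as np

AP_AXES = ("x+", "x-", "y+", "y-")


def validate_ap_axis(ap_axis: str) -> str:
    if ap_axis not in AP_AXES:
        raise ValueError(f"ap_axis must be one of {AP_AXES}, got {ap_axis!r}")
    return ap_axis


def posterior_coord(shape: tuple[int, int], ap_axis: str) -> np.ndarray:
    """Per-pixel coordinate that increases toward the posterior edge.

    Returns an integer (Y, X) map in pixel units; the minimum value (0) sits on
    the anterior edge of the frame.
    """
    validate_ap_axis(ap_axis)
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    if ap_axis == "x+":
        return xs
    if ap_axis == "x-":
        return (w - 1) - xs
    if ap_axis == "y+":
        return ys
    return (h - 1) - ys


def distance_from_posterior_px(shape: tuple[int, int], ap_axis: str) -> np.ndarray:
    """Per-pixel distance (in pixels) from the posterior edge of the frame."""
    pc = posterior_coord(shape, ap_axis)
    return pc.max() - pc


def axis_extent_px(shape: tuple[int, int], ap_axis: str) -> int:
    """Number of pixels the frame spans along the AP axis."""
    validate_ap_axis(ap_axis)
    h, w = shape
    return w if ap_axis[0] == "x" else h
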