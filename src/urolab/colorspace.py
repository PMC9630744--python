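"""RGB ↔ CIE L*a*b* conversion for urine-color analysis.

The hydration index used throughout this package is the CIELAB b* value
(blue → yellow axis), because urine yellowness tracks solute concentration.
Colors travel RGB → XYZ → L*a*b*:

* RGB → XYZ is a fixed 3×3 linear map applied to channel fractions in
  [0, 1], scaled by 100 so the white point sits at Y ≈ 100.
* XYZ → Lab uses the D65 reference white (Xn, Yn, Zn) =
  (95.047, 100.0, 108.883) and the standard piecewise cube-root
  companding function ``f(t)``.

By default the linear map is applied directly to camera channel
fractions, with no sRGB gamma decoding: the device acquires images under
a fixed LED light source and the grading scale was established on that
raw path. Pass ``srgb_gamma=True`` to decode standard sRGB-encoded
images first.

All functions accept either a single ``(3,)`` triple or an ``(..., 3)``
array and are vectorized over leading axes. Math is double precision;
conversion to 8-bit counts rounds half away from zero.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "XYZ_TO_RGB_MATRIX",
    "WHITE_POINT",
    "ChannelRangeError",
    "DomainError",
    "f_lab",
    "f_lab_inv",
    "rgb_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "rgb_to_lab",
    "lab_to_rgb",
    "lab_to_rgb_float",
]

#: Fixed RGB→XYZ matrix (rows map channel fractions to X, Y, Z / 100).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124, 0.3575, 0.1804],
        [0.2126, 0.7151, 0.0721],
        [0.0193, 0.1191, 0.9502],
    ]
)

XYZ_TO_RGB_MATRIX = np.linalg.inv(RGB_TO_XYZ_MATRIX)

#: D65 reference white on the 0–100 tristimulus scale.
WHITE_POINT = np.array([95.047, 100.0, 108.883])

#: XYZ is reported on the 0–100 scale so ratios X/Xn etc. are ≈1 for white.
XYZ_SCALE = 100.0

_DELTA = 6.0 / 29.0
_CHANNELS = ("r", "g", "b")


class ChannelRangeError(ValueError):
    """A color channel is outside its valid range; names the channel."""


class DomainError(ValueError):
    """Input outside the mathematical domain of the companding function."""


def _as_triples(c, name: str) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1:] != (3,):
        raise ValueError(f"{name} must have a trailing axis of length 3, got shape {arr.shape}")
    return arr


def _check_range(arr: np.ndarray, lo: float, hi: float, what: str) -> None:
    for i, ch in enumerate(_CHANNELS):
        v = arr[..., i]
        if np.any(v < lo) or np.any(v > hi):
            bad = v[(v < lo) | (v > hi)].ravel()[0]
            raise ChannelRangeError(
                f"channel '{ch}' of {what} out of range [{lo:g}, {hi:g}]: {bad!r}"
            )


def round_half_away(x):
    """Round to nearest integer with ties going away from zero."""
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x))


def f_lab(t):
    """CIELAB companding function.

    ``t**(1/3)`` for ``t > (6/29)**3``, else the linear continuation
    ``(1/3)(29/6)**2 t + 4/29``. Both branches meet at the breakpoint.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("f_lab requires t >= 0")
    out = np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)
    return out if out.ndim else float(out)


def f_lab_inv(u):
    """Inverse of :func:`f_lab`: ``u**3`` for ``u > 6/29``, else ``3(6/29)²(u − 4/29)``."""
    u = np.asarray(u, dtype=float)
    out = np.where(u > _DELTA, u**3, 3.0 * _DELTA**2 * (u - 4.0 / 29.0))
    return out if out.ndim else float(out)


def _srgb_linearize(c):
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_encode(c):
    c = np.asarray(c, dtype=float)
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def rgb_to_xyz(rgb):
    """Map normalized RGB (channel fractions in [0, 1]) to XYZ on the 0–100 scale."""
    arr = _as_triples(rgb, "normalized RGB")
    _check_range(arr, 0.0, 1.0, "normalized RGB")
    return arr @ RGB_TO_XYZ_MATRIX.T * XYZ_SCALE


def xyz_to_lab(xyz):
    """Map XYZ (0–100 scale) to L*a*b* relative to the D65 white point."""
    arr = _as_triples(xyz, "XYZ")
    if np.any(arr < 0):
        raise DomainError("XYZ tristimulus values must be nonnegative")
    fxyz = f_lab(arr / WHITE_POINT)
    fx, fy, fz = fxyz[..., 0], fxyz[..., 1], fxyz[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab):
    """Inverse of :func:`xyz_to_lab`."""
    arr = _as_triples(lab, "Lab")
    L, a, b = arr[..., 0], arr[..., 1], arr[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    return f_lab_inv(np.stack([fx, fy, fz], axis=-1)) * WHITE_POINT


def rgb_to_lab(rgb8, *, srgb_gamma: bool = False):
    """Full conversion of 8-bit RGB counts to L*a*b*.

    Parameters
    ----------
    rgb8 : array-like, (..., 3)
        Integer channel counts in [0, 255].
    srgb_gamma : bool
        Apply standard sRGB decoding before the linear RGB→XYZ map.
        Off by default (the device path applies the map to raw counts).
    """
    arr = _as_triples(rgb8, "RGB8")
    _check_range(arr, 0, 255, "RGB8")
    frac = arr / 255.0
    if srgb_gamma:
        frac = _srgb_linearize(frac)
    return xyz_to_lab(rgb_to_xyz(frac))


def lab_to_rgb_float(lab, *, srgb_gamma: bool = False):
    """Exact algebraic inverse of :func:`rgb_to_lab`, before rounding/clipping.

    Returns float channel values on the 0–255 scale; values outside
    [0, 255] indicate an out-of-gamut Lab input.
    """
    xyz = lab_to_xyz(lab)
    frac = xyz / XYZ_SCALE @ XYZ_TO_RGB_MATRIX.T
    if srgb_gamma:
        frac = _srgb_encode(frac)
    return frac * 255.0


def lab_to_rgb(lab, *, srgb_gamma: bool = False, return_flag: bool = False):
    """Convert L*a*b* back to 8-bit RGB counts.

    Out-of-gamut channels are clipped to [0, 255]. With
    ``return_flag=True`` also returns ``in_gamut``: True where every
    pre-rounding channel lies within half a count of the representable
    range (so clipping changed nothing beyond ordinary rounding).
    """
    scaled = lab_to_rgb_float(lab, srgb_gamma=srgb_gamma)
    in_gamut = np.all((scaled > -0.5) & (scaled < 255.5), axis=-1)
    rgb8 = np.clip(round_half_away(scaled), 0, 255).astype(np.int64)
    if return_flag:
        if in_gamut.ndim == 0:
            in_gamut = bool(in_gamut)
        return rgb8, in_gamut
    return rgb8
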