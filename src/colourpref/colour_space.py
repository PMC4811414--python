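"""Colour-space conversions used throughout the analysis.

Participants' final colour choices arrive either as device RGB triplets or as
measured CIE xyY (luminance + chromaticity).  All statistics run on CIE LCh,
the cylindrical form of CIE 1976 L*a*b*: lightness L in [0, 100], chroma
C >= 0, hue angle h in degrees [0, 360).  The Lab transform is always taken
relative to an explicit reference white -- in the original experiment the
white background the patches were shown on -- so no illuminant is assumed
implicitly here.

Device RGB cannot be converted exactly without measuring the monitor; the
:class:`DisplayModel` replaces that measurement with a parameterised model
(primaries' chromaticities, white point, transfer function), defaulting to
sRGB/D65.  Measured xyY, when available, is always preferred over RGB.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CIExyY",
    "CIEXYZ",
    "CIELab",
    "CIELCh",
    "RGBTriplet",
    "DisplayModel",
    "UndefinedChromaticityError",
    "xyY_to_XYZ",
    "XYZ_to_Lab",
    "Lab_to_XYZ",
    "Lab_to_LCh",
    "LCh_to_Lab",
    "rgb_to_XYZ",
    "XYZ_to_rgb",
    "convert_choice",
    "SRGB_D65",
]

# CIE 1976 constants, exact rational forms.
_DELTA = 6.0 / 29.0
_T0 = _DELTA ** 3               # (6/29)^3 ~ 0.008856: linear-branch threshold
_M = (29.0 / 6.0) ** 2 / 3.0    # 841/108 ~ 7.787: linear-branch slope
_C0 = 4.0 / 29.0


class UndefinedChromaticityError(ValueError):
    """xyY with y = 0 but Y > 0 has no finite tristimulus representation."""


@dataclass(frozen=True)
class CIExyY:
    """Chromaticity (x, y) plus luminance Y (cd/m^2)."""

    x: float
    y: float
    Y: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.Y)):
            raise ValueError("non-finite xyY component")
        if self.x < 0 or self.y < 0 or self.x + self.y > 1 + 1e-12:
            raise ValueError(f"invalid chromaticity (x={self.x}, y={self.y})")
        if self.Y < 0:
            raise ValueError("luminance Y must be >= 0")


@dataclass(frozen=True)
class CIEXYZ:
    """Tristimulus values, all >= 0.  Also used for reference whites (Y > 0)."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.X, self.Y, self.Z)):
            raise ValueError("non-finite XYZ component")
        if min(self.X, self.Y, self.Z) < -1e-9:
            raise ValueError("tristimulus values must be >= 0")


# A reference white is simply an XYZ triple whose Y is positive.
ReferenceWhite = CIEXYZ


@dataclass(frozen=True)
class CIELab:
    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.L, self.a, self.b)):
            raise ValueError("non-finite Lab component")


@dataclass(frozen=True)
class CIELCh:
    """L in [0, 100], C >= 0, hue angle h in degrees [0, 360)."""

    L: float
    C: float
    h: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.L, self.C, self.h)):
            raise ValueError("non-finite LCh component")
        if self.C < 0:
            raise ValueError("chroma must be >= 0")
        if not 0 <= self.h < 360:
            raise ValueError("hue angle must lie in [0, 360)")


@dataclass(frozen=True)
class RGBTriplet:
    """Device RGB, integer channels 0-255."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not 0 <= v <= 255:
                raise ValueError(f"channel {name}={v} outside [0, 255]")


def xyY_to_XYZ(c: CIExyY) -> CIEXYZ:
    """X = x*Y/y, Z = (1-x-y)*Y/y; Y preserved.

    y = 0 with Y = 0 is defined as black; y = 0 with Y > 0 is rejected.
    """
    if c.y == 0:
        if c.Y == 0:
            return CIEXYZ(0.0, 0.0, 0.0)
        raise UndefinedChromaticityError("y = 0 with Y > 0")
    return CIEXYZ(c.x * c.Y / c.y, c.Y, (1.0 - c.x - c.y) * c.Y / c.y)


def _f(t: float) -> float:
    # CIE 1976 compressive nonlinearity with the linear branch below (6/29)^3.
    if t > _T0:
        return t ** (1.0 / 3.0)
    return _M * t + _C0


def _f_inv(u: float) -> float:
    if u > _DELTA:
        return u ** 3
    return (u - _C0) / _M


def XYZ_to_Lab(c: CIEXYZ, white: ReferenceWhite) -> CIELab:
    """CIE 1976 L*a*b* relative to the given reference white (white.Y > 0)."""
    if white.Y <= 0:
        raise ValueError("reference white must have Y > 0")
    if white.X <= 0 or white.Z <= 0:
        raise ValueError("reference white must have positive X and Z")
    fx = _f(c.X / white.X)
    fy = _f(c.Y / white.Y)
    fz = _f(c.Z / white.Z)
    return CIELab(116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def Lab_to_XYZ(c: CIELab, white: ReferenceWhite) -> CIEXYZ:
    """Inverse of :func:`XYZ_to_Lab`."""
    if white.Y <= 0:
        raise ValueError("reference white must have Y > 0")
    fy = (c.L + 16.0) / 116.0
    fx = fy + c.a / 500.0
    fz = fy - c.b / 200.0
    return CIEXYZ(
        max(_f_inv(fx) * white.X, 0.0),
        max(_f_inv(fy) * white.Y, 0.0),
        max(_f_inv(fz) * white.Z, 0.0),
    )


def Lab_to_LCh(c: CIELab) -> CIELCh:
    """C = hypot(a, b); h = atan2(b, a) in degrees mapped to [0, 360).

    Achromatic colours (a = b = 0) get h = 0 by convention; downstream hue
    categorisation never consults h when C is at or below the achromatic
    cut-off, so the convention is inert.
    """
    C = math.hypot(c.a, c.b)
    if C == 0:
        return CIELCh(c.L, 0.0, 0.0)
    h = math.degrees(math.atan2(c.b, c.a)) % 360.0
    if h >= 360.0:  # guard against 359.9999... % artefacts
        h = 0.0
    return CIELCh(c.L, C, h)


def LCh_to_Lab(c: CIELCh) -> CIELab:
    hr = math.radians(c.h)
    return CIELab(c.L, c.C * math.cos(hr), c.C * math.sin(hr))


@dataclass(frozen=True)
class DisplayModel:
    """RGB -> XYZ model: primaries' chromaticities, white point, transfer.

    ``transfer`` is either the string ``"srgb"`` (IEC 61966-2-1 piecewise
    curve) or a float gamma exponent.  The 3x3 matrix is derived from the
    primaries so that (255, 255, 255) maps exactly to the white point
    (scaled to ``white_Y``).
    """

    red_xy: tuple[float, float] = (0.64, 0.33)
    green_xy: tuple[float, float] = (0.30, 0.60)
    blue_xy: tuple[float, float] = (0.15, 0.06)
    white_xy: tuple[float, float] = (0.3127, 0.3290)
    white_Y: float = 100.0
    transfer: str | float = "srgb"

    def __post_init__(self) -> None:
        if self.white_Y <= 0:
            raise ValueError("white_Y must be > 0")
        if isinstance(self.transfer, str) and self.transfer != "srgb":
            raise ValueError("transfer must be 'srgb' or a gamma exponent")
        if isinstance(self.transfer, (int, float)) and self.transfer <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def white_point(self) -> CIEXYZ:
        x, y = self.white_xy
        return xyY_to_XYZ(CIExyY(x, y, self.white_Y))

    def matrix(self) -> np.ndarray:
        """3x3 matrix mapping linear RGB in [0, 1] to XYZ (white-scaled)."""
        prim = np.empty((3, 3))
        for col, (x, y) in enumerate((self.red_xy, self.green_xy, self.blue_xy)):
            prim[:, col] = (x / y, 1.0, (1.0 - x - y) / y)
        w = self.white_point
        scale = np.linalg.solve(prim, np.array([w.X, w.Y, w.Z]))
        return prim * scale

    def linearise(self, channel: float) -> float:
        """Map one encoded channel in [0, 1] to linear-light in [0, 1]."""
        if self.transfer == "srgb":
            if channel <= 0.04045:
                return channel / 12.92
            return ((channel + 0.055) / 1.055) ** 2.4
        return channel ** float(self.transfer)

    def delinearise(self, linear: float) -> float:
        if self.transfer == "srgb":
            if linear <= 0.04045 / 12.92:
                return linear * 12.92
            return 1.055 * linear ** (1.0 / 2.4) - 0.055
        return linear ** (1.0 / float(self.transfer))

    def to_dict(self) -> dict:
        return {
            "red_xy": list(self.red_xy),
            "green_xy": list(self.green_xy),
            "blue_xy": list(self.blue_xy),
            "white_xy": list(self.white_xy),
            "white_Y": self.white_Y,
            "transfer": self.transfer,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DisplayModel":
        return cls(
            red_xy=tuple(d["red_xy"]),
            green_xy=tuple(d["green_xy"]),
            blue_xy=tuple(d["blue_xy"]),
            white_xy=tuple(d["white_xy"]),
            white_Y=float(d["white_Y"]),
            transfer=d["transfer"],
        )

    @classmethod
    def from_json(cls, path) -> "DisplayModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


SRGB_D65 = DisplayModel()


def rgb_to_XYZ(c: RGBTriplet, model: DisplayModel = SRGB_D65) -> CIEXYZ:
    """Deterministic display-model mapping; (255,255,255) hits the white point."""
    lin = np.array([model.linearise(v / 255.0) for v in (c.r, c.g, c.b)])
    X, Y, Z = model.matrix() @ lin
    return CIEXYZ(max(X, 0.0), max(Y, 0.0), max(Z, 0.0))


def XYZ_to_rgb(c: CIEXYZ, model: DisplayModel = SRGB_D65) -> RGBTriplet:
    """Inverse display-model mapping, clipped to the 0-255 cube.

    Out-of-gamut tristimulus values are clipped channel-wise; this is only
    used to attach an approximate device RGB to synthetic records, never in
    the analysis path.
    """
    lin = np.linalg.solve(model.matrix(), np.array([c.X, c.Y, c.Z]))
    lin = np.clip(lin, 0.0, 1.0)
    enc = [model.delinearise(float(v)) for v in lin]
    return RGBTriplet(*(int(round(np.clip(v, 0.0, 1.0) * 255)) for v in enc))


def convert_choice(
    colour: RGBTriplet | CIExyY,
    white: ReferenceWhite,
    model: DisplayModel = SRGB_D65,
) -> CIELCh:
    """Full conversion of one recorded colour choice to CIE LCh.

    Measured xyY is converted directly; device RGB goes through the display
    model first.  The reference white is explicit and required.
    """
    if isinstance(colour, CIExyY):
        xyz = xyY_to_XYZ(colour)
    elif isinstance(colour, RGBTriplet):
        xyz = rgb_to_XYZ(colour, model)
    else:
        raise TypeError(f"unsupported colour representation: {type(colour)!r}")
    return Lab_to_LCh(XYZ_to_Lab(xyz, white))
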