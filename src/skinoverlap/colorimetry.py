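"""CIELAB colorimetry: spectra → XYZ → L*a*b*, chroma, and ΔE*ab.

Skin colour statistics in this package all live in the CIE 1976 L*a*b*
space, whose axes track perceived lightness (L*), redness (a*) and
yellowness (b*).  This module provides the conversions into that space
and the two derived quantities everything downstream depends on:

* chroma C* = sqrt(a*² + b*²), the distance from the neutral axis, and
* the colour difference ΔE*ab, the Euclidean distance between two
  CIELAB points — the classic perceptual difference measure.

Spectral input is supported through a standard tristimulus integration.
Colour-matching functions are evaluated from the analytic multi-lobe
Gaussian / lognormal fits published by Wyman, Sloan & Shirley (accurate
to roughly 1% of peak, ample for reflectance plumbing); illuminant D65
is the standard 10 nm relative-power table bundled with the package and
illuminant A is computed from its defining Planck formula.  The study
pipeline itself starts at XYZ, so the spectral path is a convenience
for archives that store raw reflectance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np

__all__ = [
    "LabColour",
    "ReflectanceSpectrum",
    "WhitePoint",
    "STANDARD_WHITES",
    "spectrum_to_xyz",
    "white_point",
    "xyz_to_lab",
    "lab_to_xyz",
    "chroma",
    "delta_e_ab",
]

# Cube-root / linear split point of the L*a*b* transform.
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear segment

#: Published white points on the Y=100 scale, keyed by (illuminant, observer).
STANDARD_WHITES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("D65", "1931_2deg"): (95.047, 100.0, 108.883),
    ("D65", "1964_10deg"): (94.811, 100.0, 107.304),
    ("D50", "1931_2deg"): (96.422, 100.0, 82.521),
    ("A", "1931_2deg"): (109.850, 100.0, 35.585),
    ("E", "1931_2deg"): (100.0, 100.0, 100.0),
    ("E", "1964_10deg"): (100.0, 100.0, 100.0),
}


class LabColour(NamedTuple):
    """A CIELAB point. L* is nominally 0–100; a*, b* are unbounded."""

    L: float
    a: float
    b: float


@dataclass(frozen=True)
class WhitePoint:
    """Reference white on the scale where Yn = 100."""

    Xn: float
    Yn: float
    Zn: float
    illuminant: str = "D65"
    observer: str = "1964_10deg"

    def __post_init__(self) -> None:
        if not (self.Xn > 0 and self.Yn > 0 and self.Zn > 0):
            raise ValueError("white point components must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn])


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Spectral reflectance on a strictly increasing uniform nm grid.

    Reflectance is a unitless fraction; values marginally above 1 (up to
    1.2) are tolerated because fluorescent edges of real skin
    measurements occasionally exceed unity.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rv = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", rv)
        if wl.ndim != 1 or wl.size < 2 or wl.shape != rv.shape:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        steps = np.diff(wl)
        if not np.all(steps > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength grid must have a uniform step")
        if not np.all(np.isfinite(rv)):
            raise ValueError("reflectance values must be finite")
        if np.any(rv < 0) or np.any(rv > 1.2):
            raise ValueError("reflectance must lie in [0, 1.2]")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


def _bimodal_gaussian(x: np.ndarray, mu: float, s_left: float, s_right: float) -> np.ndarray:
    s = np.where(x < mu, s_left, s_right)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cmf_1931_2deg(wavelengths: np.ndarray) -> np.ndarray:
    """CIE 1931 2° colour-matching functions (analytic fit), shape (n, 3)."""
    wl = np.asarray(wavelengths, dtype=float)
    x = (
        1.056 * _bimodal_gaussian(wl, 599.8, 37.9, 31.0)
        + 0.362 * _bimodal_gaussian(wl, 442.0, 16.0, 26.7)
        - 0.065 * _bimodal_gaussian(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _bimodal_gaussian(wl, 568.8, 46.9, 40.5) + 0.286 * _bimodal_gaussian(
        wl, 530.9, 16.3, 31.1
    )
    z = 1.217 * _bimodal_gaussian(wl, 437.0, 11.8, 36.0) + 0.681 * _bimodal_gaussian(
        wl, 459.0, 26.0, 13.8
    )
    return np.stack([x, y, z], axis=-1)


def cmf_1964_10deg(wavelengths: np.ndarray) -> np.ndarray:
    """CIE 1964 10° colour-matching functions (analytic fit), shape (n, 3)."""
    wl = np.asarray(wavelengths, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = 0.398 * np.exp(-1250.0 * np.log((wl + 570.1) / 1014.0) ** 2) + 1.132 * np.exp(
            -234.0 * np.log((1338.0 - wl) / 743.5) ** 2
        )
        y = 1.011 * np.exp(-0.5 * ((wl - 556.1) / 46.14) ** 2)
        z = 2.060 * np.exp(-32.0 * np.log((wl - 265.8) / 180.4) ** 2)
    return np.stack([x, y, z], axis=-1)


_CMFS = {"1931_2deg": cmf_1931_2deg, "1964_10deg": cmf_1964_10deg}


def _load_d65_table() -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("skinoverlap.data") / "cie_illuminant_d65_10nm.csv"
    raw = np.loadtxt(str(path), delimiter=",", skiprows=1)
    return raw[:, 0], raw[:, 1]


_D65_WL, _D65_SPD = _load_d65_table()


def illuminant_spd(name: str, wavelengths: np.ndarray) -> np.ndarray:
    """Relative spectral power of a standard illuminant on a given nm grid.

    D65 is linearly interpolated from the bundled 10 nm table; A uses the
    Planck radiator formula (T = 2848 K with c2 = 1.435e-2 m·K, the
    definition of the illuminant); E is the equal-energy spectrum.
    """
    wl = np.asarray(wavelengths, dtype=float)
    name = name.upper()
    if name == "D65":
        if wl.min() < _D65_WL.min() or wl.max() > _D65_WL.max():
            raise ValueError("requested grid outside the bundled D65 table (380–780 nm)")
        return np.interp(wl, _D65_WL, _D65_SPD)
    if name == "A":
        c2 = 1.435e-2  # m·K
        t = 2848.0
        lam = wl * 1e-9
        ref = 560e-9
        planck = lambda l: l ** -5 / np.expm1(c2 / (l * t))  # noqa: E731
        return 100.0 * planck(lam) / planck(ref)
    if name == "E":
        return np.full(wl.shape, 100.0)
    raise ValueError(f"unknown illuminant {name!r}; supported: D65, A, E")


def spectrum_to_xyz(
    spectrum: ReflectanceSpectrum,
    illuminant: str = "D65",
    observer: str = "1964_10deg",
) -> np.ndarray:
    """Integrate a reflectance spectrum to tristimulus XYZ (Yn = 100 scale).

    Rectangular-rule weighting with renormalization so that the perfect
    (unit) reflector maps to the illuminant white with Y = 100.  The
    spectrum must cover at least 400–700 nm; contributions outside the
    spectrum's own grid are not extrapolated.
    """
    if observer not in _CMFS:
        raise ValueError(f"unknown observer {observer!r}; supported: {sorted(_CMFS)}")
    wl = spectrum.wavelengths
    if wl.min() > 400.0 or wl.max() < 700.0:
        raise ValueError(
            "spectrum must cover 400–700 nm; "
            f"got {wl.min():g}–{wl.max():g} nm (missing "
            f"{'below 400' if wl.min() > 400 else 'above 700'} nm)"
        )
    cmf = _CMFS[observer](wl)
    spd = illuminant_spd(illuminant, wl)
    k = 100.0 / np.sum(spd * cmf[:, 1])
    xyz = k * np.einsum("i,ij,i->j", spd, cmf, spectrum.values)
    return xyz


def white_point(illuminant: str = "D65", observer: str = "1964_10deg") -> WhitePoint:
    """White point of an illuminant/observer pair, derived from the same
    tables/fits used by :func:`spectrum_to_xyz` (so spectra and their
    Lab conversions are mutually consistent)."""
    grid = np.arange(400.0, 701.0, 10.0)
    flat = ReflectanceSpectrum(grid, np.ones_like(grid))
    x, y, z = spectrum_to_xyz(flat, illuminant=illuminant, observer=observer)
    return WhitePoint(x, y, z, illuminant=illuminant, observer=observer)


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > 6.0 / 29.0, u ** 3, (u - 4.0 / 29.0) / _KAPPA)


def _default_white() -> WhitePoint:
    x, y, z = STANDARD_WHITES[("D65", "1964_10deg")]
    return WhitePoint(x, y, z)


def xyz_to_lab(xyz, white: WhitePoint | None = None) -> np.ndarray:
    """CIE 1976 L*a*b* transform. `xyz` has shape (..., 3) on the Yn=100 scale.

    L* is not clamped; results outside [0, 100] trigger a warning so
    implausible records surface instead of being silently truncated.
    """
    if white is None:
        white = _default_white()
    arr = np.asarray(xyz, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("xyz must have shape (..., 3)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("tristimulus values must be finite")
    if np.any(arr < 0):
        raise ValueError("tristimulus values must be non-negative")
    ratios = arr / white.as_array()
    fx, fy, fz = _f(ratios[..., 0]), _f(ratios[..., 1]), _f(ratios[..., 2])
    lab = np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)
    l_star = lab[..., 0]
    if np.any((l_star < 0) | (l_star > 100)):
        bad = np.flatnonzero((np.atleast_1d(l_star) < 0) | (np.atleast_1d(l_star) > 100))
        warnings.warn(
            f"L* outside [0, 100] for {bad.size} record(s) (first indices {bad[:5].tolist()})",
            stacklevel=2,
        )
    return lab


def lab_to_xyz(lab, white: WhitePoint | None = None) -> np.ndarray:
    """Inverse L*a*b* transform (used for round-trip checks and previews)."""
    if white is None:
        white = _default_white()
    arr = np.asarray(lab, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("lab must have shape (..., 3)")
    fy = (arr[..., 0] + 16.0) / 116.0
    fx = fy + arr[..., 1] / 500.0
    fz = fy - arr[..., 2] / 200.0
    ratios = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1)
    return ratios * white.as_array()


def chroma(lab) -> np.ndarray | float:
    """Chroma C* = sqrt(a*² + b*²): distance from the neutral axis."""
    arr = np.asarray(lab, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("lab must have shape (..., 3)")
    out = np.hypot(arr[..., 1], arr[..., 2])
    return float(out) if out.ndim == 0 else out


def delta_e_ab(lab1, lab2) -> np.ndarray | float:
    """Perceptual colour difference ΔE*ab: Euclidean distance in CIELAB."""
    a1 = np.asarray(lab1, dtype=float)
    a2 = np.asarray(lab2, dtype=float)
    if a1.shape[-1] != 3 or a2.shape[-1] != 3:
        raise ValueError("colours must have shape (..., 3)")
    out = np.sqrt(np.sum((a1 - a2) ** 2, axis=-1))
    return float(out) if out.ndim == 0 else out
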