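"""Device-independent color math.

Transmittance spectra of the color-chart patches are turned into CIEXYZ
tristimulus values under illuminant D65 with the CIE 1931 2-degree observer,
then into linear RGB with sRGB primaries.  Color differences are measured as
CIE76 dE* — the Euclidean distance in CIELAB.

The color-matching functions are evaluated from the multi-lobe piecewise
Gaussian analytic fit of Wyman, Sloan & Shirley (2013), and the daylight
illuminant is a 6504 K Planckian spectrum with a small correction (in the span
of the CMFs) solved so that a fully transmissive sample integrates exactly to
the sRGB D65 white point.  This keeps the clear-glass background of a chart
mapping exactly to linear RGB (1, 1, 1), which the calibration protocol
assumes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GridMismatchError, IhccalError, LayoutError

# The chart calibration data grid: 340-830 nm at 5 nm steps, 99 samples.
WAVELENGTH_GRID = np.arange(340.0, 831.0, 5.0)

#: Canonical patch order: 12 color patches then the background glass.
PATCH_IDS = (
    "A1", "A2", "A3", "A4",
    "B1", "B2", "B3", "B4",
    "C1", "C2", "C3", "C4",
    "BG",
)

#: Neutral patches used for gamma estimation (three grays plus background).
GRAYSCALE_IDS = ("A1", "B1", "C1", "BG")

# sRGB primary / D65 white chromaticities (x, y).
_PRIMARIES = {"r": (0.64, 0.33), "g": (0.30, 0.60), "b": (0.15, 0.06)}
_WHITE_XY = (0.3127, 0.3290)


def _xy_to_xyz(x: float, y: float) -> np.ndarray:
    return np.array([x / y, 1.0, (1.0 - x - y) / y])


#: D65 white point, normalized to Y = 1.
D65_WHITE_XYZ = _xy_to_xyz(*_WHITE_XY)


@dataclass(frozen=True)
class SpectralCurve:
    """Per-patch spectral transmittance T(lambda) on the standard grid."""

    wavelengths_nm: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "transmittance", t)
        if w.shape != t.shape or w.ndim != 1:
            raise GridMismatchError("wavelengths and transmittance must be 1-D and equal length")
        if w.size != WAVELENGTH_GRID.size or not np.allclose(w, WAVELENGTH_GRID):
            raise GridMismatchError("spectral grid must be 340..830 nm at 5 nm steps")
        if np.any(~np.isfinite(t)) or np.any(t < 0) or np.any(t > 1):
            raise IhccalError("transmittance must lie in [0, 1]")


@dataclass(frozen=True)
class Illuminant:
    """Relative spectral power distribution S(lambda) of the light source."""

    wavelengths_nm: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "power", p)
        if w.shape != p.shape or np.any(p < 0):
            raise GridMismatchError("illuminant power must be nonnegative on the grid")


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """CIE 1931 2-degree standard observer xbar, ybar, zbar."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray


@dataclass(frozen=True)
class XYZColor:
    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class LinearRGB:
    R: float
    G: float
    B: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.G, self.B])


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


@dataclass(frozen=True)
class ConversionMatrix:
    """3x3 matrix C with XYZ = C . RGB (sRGB primaries, D65 white)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", c)
        if c.shape != (3, 3):
            raise IhccalError("conversion matrix must be 3x3")
        if abs(np.linalg.det(c)) < 1e-12:
            raise IhccalError("conversion matrix must be invertible")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.C)


@dataclass(frozen=True)
class ChartColors:
    """3x13 matrix of linear RGB chart colors (columns A1..C4, BG)."""

    values: np.ndarray
    role: str = "reference"
    ids: Sequence[str] = field(default=PATCH_IDS)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (3, len(self.ids)) or len(self.ids) != 13:
            raise LayoutError("chart colors must be a 3x13 matrix (12 patches + background)")
        if self.role not in ("reference", "scanned"):
            raise IhccalError("role must be 'reference' or 'scanned'")

    def column(self, patch_id: str) -> np.ndarray:
        try:
            j = list(self.ids).index(patch_id)
        except ValueError as exc:
            raise LayoutError(f"unknown patch id {patch_id!r}") from exc
        return self.values[:, j]


# ---------------------------------------------------------------------------
# Embedded standard-observer / illuminant tabulations
# ---------------------------------------------------------------------------

def _lobe(w: np.ndarray, amp: float, mu: float, s_lo: float, s_hi: float) -> np.ndarray:
    sigma = np.where(w < mu, s_lo, s_hi)
    return amp * np.exp(-0.5 * ((w - mu) / sigma) ** 2)


def cie_1931_cmf(wavelengths_nm: np.ndarray | None = None) -> ColorMatchingFunctions:
    """CIE 1931 2-degree observer on the chart grid (analytic multi-lobe fit)."""
    w = WAVELENGTH_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    xbar = (
        _lobe(w, 1.056, 599.8, 37.9, 31.0)
        + _lobe(w, 0.362, 442.0, 16.0, 26.7)
        - _lobe(w, 0.065, 501.1, 20.4, 26.2)
    )
    ybar = _lobe(w, 0.821, 568.8, 46.9, 40.5) + _lobe(w, 0.286, 530.9, 16.3, 31.1)
    zbar = _lobe(w, 1.217, 437.0, 11.8, 36.0) + _lobe(w, 0.681, 459.0, 26.0, 13.8)
    return ColorMatchingFunctions(w, np.clip(xbar, 0, None), np.clip(ybar, 0, None), np.clip(zbar, 0, None))


def _planck(w_nm: np.ndarray, temperature_k: float) -> np.ndarray:
    # Relative spectral radiance; constants folded out by normalization at 560 nm.
    lam = w_nm * 1e-9
    c2 = 1.4388e-2  # m.K, second radiation constant
    rad = lam ** -5 / np.expm1(c2 / (lam * temperature_k))
    return rad / rad[np.argmin(np.abs(w_nm - 560.0))]


def d65_illuminant(wavelengths_nm: np.ndarray | None = None) -> Illuminant:
    """Daylight illuminant whose white integrates exactly to the D65 white point.

    A 6504 K Planckian base is corrected by a small component in the span of
    xbar/zbar so that ``spectral_to_xyz`` of a unit transmittance yields the
    sRGB D65 white exactly (not merely approximately).
    """
    w = WAVELENGTH_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    cmf = cie_1931_cmf(w)
    s = _planck(w, 6504.0)
    x, y, z = cmf.xbar, cmf.ybar, cmf.zbar
    xw, _, zw = D65_WHITE_XYZ
    # Solve S' = S + a*xbar + c*zbar with sum(S'x) = Xw*sum(S'y), sum(S'z) = Zw*sum(S'y).
    a_mat = np.array(
        [
            [np.sum(x * x) - xw * np.sum(x * y), np.sum(x * z) - xw * np.sum(y * z)],
            [np.sum(x * z) - zw * np.sum(x * y), np.sum(z * z) - zw * np.sum(y * z)],
        ]
    )
    b_vec = np.array(
        [xw * np.sum(s * y) - np.sum(s * x), zw * np.sum(s * y) - np.sum(s * z)]
    )
    a, c = np.linalg.solve(a_mat, b_vec)
    power = s + a * x + c * z
    power = np.clip(power, 0.0, None)
    return Illuminant(w, power)


def srgb_matrix() -> ConversionMatrix:
    """The XYZ-from-linear-RGB matrix for sRGB primaries and D65 white."""
    prim = np.column_stack(
        [_xy_to_xyz(*_PRIMARIES[k]) for k in ("r", "g", "b")]
    )
    scale = np.linalg.solve(prim, D65_WHITE_XYZ)
    return ConversionMatrix(prim * scale)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def _check_grids(*tables) -> None:
    ref = tables[0].wavelengths_nm
    for t in tables[1:]:
        if t.wavelengths_nm.shape != ref.shape or not np.allclose(t.wavelengths_nm, ref):
            raise GridMismatchError("spectral tables must share the wavelength grid")


def spectral_to_xyz(
    curve: SpectralCurve, illum: Illuminant, cmf: ColorMatchingFunctions
) -> XYZColor:
    """Tristimulus values of a transmissive sample under the given illuminant.

    Uses the summation form with normalization k = 1 / sum(S * ybar), so a
    unit transmittance yields Y = 1 exactly.
    """
    _check_grids(curve, illum, cmf)
    s, t = illum.power, curve.transmittance
    k = 1.0 / np.sum(s * cmf.ybar)
    return XYZColor(
        k * float(np.sum(s * t * cmf.xbar)),
        k * float(np.sum(s * t * cmf.ybar)),
        k * float(np.sum(s * t * cmf.zbar)),
    )


def xyz_to_linear_rgb(xyz: XYZColor, C: ConversionMatrix) -> LinearRGB:
    """Invert XYZ = C.RGB; values are not clipped to [0, 1]."""
    rgb = C.inverse @ xyz.as_array()
    return LinearRGB(*rgb)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta ** 3, np.cbrt(t), t / (3 * delta ** 2) + 4.0 / 29.0)


def xyz_array_to_lab(xyz: np.ndarray, white: XYZColor) -> np.ndarray:
    """Vectorized CIE 1976 L*a*b*; ``xyz`` has shape (..., 3)."""
    w = white.as_array()
    if w[1] <= 0:
        raise IhccalError("white point must have positive luminance")
    f = _lab_f(np.asarray(xyz, float) / w)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def linear_rgb_to_lab(
    rgb: LinearRGB, C: ConversionMatrix, white: XYZColor | None = None
) -> LabColor:
    """Standard CIELAB coordinates of a linear RGB color (D65 white reference)."""
    white = white if white is not None else XYZColor(*(C.C @ np.ones(3)))
    xyz = C.C @ rgb.as_array()
    return LabColor(*xyz_array_to_lab(xyz, white))


def delta_e(lab1: LabColor, lab2: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in L*a*b*."""
    return float(np.linalg.norm(lab1.as_array() - lab2.as_array()))


def describe_delta_e(value: float) -> str:
    """Perceptual interpretation: <1 invisible, 1-2 visible to experts only."""
    if value < 1.0:
        return "imperceptible"
    if value <= 2.0:
        return "expert-perceptible"
    return "perceptible"


def compute_reference_chart(
    curves: Mapping[str, SpectralCurve] | Sequence[SpectralCurve],
    illum: Illuminant,
    cmf: ColorMatchingFunctions,
    C: ConversionMatrix,
) -> ChartColors:
    """Reference chart matrix Gr: per-patch spectra -> linear RGB columns."""
    if isinstance(curves, Mapping):
        missing = [p for p in PATCH_IDS if p not in curves]
        if missing:
            raise LayoutError(f"missing patch spectra: {missing}")
        ordered = [curves[p] for p in PATCH_IDS]
    else:
        ordered = list(curves)
    if len(ordered) != 13:
        raise LayoutError("a chart needs exactly 13 spectra (A1..C4 + BG)")
    cols = [
        xyz_to_linear_rgb(spectral_to_xyz(c, illum, cmf), C).as_array()
        for c in ordered
    ]
    return ChartColors(np.column_stack(cols), role="reference")
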