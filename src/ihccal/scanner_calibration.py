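"""Scanner (device) color calibration from a color chart slide.

The device model is: incident light -> per-channel scaling, a device color
mixing stage, and a display gamma encoding.  Calibration inverts it in three
steps, in this fixed order:

1. normalize by the incident light measured on the clear glass background,
2. linearize with an estimated display gamma (power law, fitted on the
   luminance of the neutral patches by least squares),
3. apply a white-point-preserving polynomial color correction (WPPLS) fitted
   on the 13 chart patches with the 5-term basis (R, G, B, R*G*B, 1).

Pixelwise CIE76 dE* maps against a reference image quantify residual error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .colorimetry import (
    ChartColors,
    ConversionMatrix,
    GRAYSCALE_IDS,
    PATCH_IDS,
    XYZColor,
    xyz_array_to_lab,
)
from .errors import (
    CalibrationError,
    EncodingError,
    IhccalError,
    InsufficientDataError,
    LayoutError,
)

ENCODINGS = ("device_gamma", "device_linear", "standard_linear")

#: Ordered polynomial basis of the color-correction map.
POLY_BASIS = ("R", "G", "B", "RGB", "1")


@dataclass(frozen=True)
class ImagePatch:
    """An H x W x 3 image patch with an explicit encoding tag.

    ``encoding`` records where the pixels live in the calibration chain:
    ``device_gamma`` (raw scanner output), ``device_linear`` (after gamma
    linearization) or ``standard_linear`` (after color correction; the
    device-independent working space).
    """

    pixels: np.ndarray
    encoding: str = "device_gamma"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise IhccalError("image must be H x W x 3 with H, W >= 1")
        if not np.all(np.isfinite(px)):
            raise IhccalError("image contains non-finite values")
        if self.encoding not in ENCODINGS:
            raise EncodingError(f"unknown encoding {self.encoding!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class IncidentLight:
    """Per-channel incident (glass-level) intensity I0."""

    I0: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.I0, dtype=float).reshape(3)
        object.__setattr__(self, "I0", v)
        if np.any(v <= 0):
            raise IhccalError("incident light components must be positive")


@dataclass(frozen=True)
class GammaEstimate:
    gamma: float
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if not 0.2 <= self.gamma <= 5.0:
            raise CalibrationError("gamma outside the plausible range [0.2, 5.0]")


@dataclass(frozen=True)
class PolynomialColorMap:
    """Per-channel polynomial map with basis (R, G, B, R*G*B, 1)."""

    coeffs: np.ndarray
    basis: Sequence[str] = field(default=POLY_BASIS)
    white_preserving: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        object.__setattr__(self, "coeffs", c)
        if c.shape != (3, 5):
            raise IhccalError("polynomial map coefficients must be 3 x 5")
        if self.white_preserving:
            dev = np.abs(self(np.ones(3)) - 1.0)
            if np.any(dev > 1e-9):
                raise CalibrationError("map does not preserve the white point")

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        """Evaluate on an (..., 3) array of linear device colors."""
        rgb = np.asarray(rgb, dtype=float)
        terms = np.stack(
            [
                rgb[..., 0],
                rgb[..., 1],
                rgb[..., 2],
                rgb[..., 0] * rgb[..., 1] * rgb[..., 2],
                np.ones(rgb.shape[:-1]),
            ],
            axis=-1,
        )
        return terms @ self.coeffs.T

    @classmethod
    def identity(cls) -> "PolynomialColorMap":
        co = np.zeros((3, 5))
        co[:, :3] = np.eye(3)
        return cls(co)


@dataclass(frozen=True)
class ScannerCalibration:
    """Complete device calibration: normalize -> linearize -> color map."""

    gamma: GammaEstimate
    color_map: PolynomialColorMap
    incident: IncidentLight

    def apply(self, img: ImagePatch) -> ImagePatch:
        out = normalize_by_incident(img, self.incident)
        out = linearize(out, self.gamma)
        return apply_color_map(out, self.color_map)


@dataclass(frozen=True)
class DeltaEMap:
    """Pixelwise dE* between two aligned images plus masked summaries."""

    values: np.ndarray
    mask: np.ndarray
    mean: float
    sd: float
    histogram: np.ndarray
    bin_edges: np.ndarray


# ---------------------------------------------------------------------------
# Layout handling and patch extraction
# ---------------------------------------------------------------------------

def _central_region(rect: Sequence[int], fraction: float) -> tuple[slice, slice]:
    r0, c0, h, w = rect
    dh, dw = int(round(h * (1 - fraction) / 2)), int(round(w * (1 - fraction) / 2))
    return slice(r0 + dh, r0 + h - dh), slice(c0 + dw, c0 + w - dw)


def extract_patch_colors(
    chart_img: ImagePatch,
    layout: Mapping[str, Sequence[int]],
    central_fraction: float = 0.5,
) -> ChartColors:
    """Mean color over the central area of each chart patch.

    ``layout`` maps patch id to a (row0, col0, height, width) rectangle,
    0-based and half-open.  Only the central ``central_fraction`` of the
    rectangle per side is averaged, avoiding patch-edge blur.
    """
    H, W = chart_img.shape
    cols = []
    for pid in PATCH_IDS:
        if pid not in layout:
            raise LayoutError(f"layout is missing patch {pid!r}")
        r0, c0, h, w = layout[pid]
        if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W or h < 1 or w < 1:
            raise LayoutError(f"rectangle for {pid!r} out of image bounds")
        rs, cs = _central_region((r0, c0, h, w), central_fraction)
        region = chart_img.pixels[rs, cs]
        if region.size == 0:
            raise LayoutError(f"central region for {pid!r} is empty")
        cols.append(region.reshape(-1, 3).mean(axis=0))
    return ChartColors(np.column_stack(cols), role="scanned")


def estimate_incident(img: ImagePatch, quantile: float = 99.0) -> IncidentLight:
    """Incident light from the brightest (glass) pixels of an image.

    Per-channel mean over pixels whose channel-sum is at or above the given
    percentile; a robust stand-in when no explicit glass region is given.
    """
    s = img.pixels.sum(axis=2)
    thr = np.percentile(s, quantile)
    sel = img.pixels[s >= thr]
    return IncidentLight(sel.mean(axis=0))


def normalize_by_incident(img: ImagePatch, incident: IncidentLight) -> ImagePatch:
    """Hadamard division of every pixel by the incident light I0."""
    return replace(img, pixels=img.pixels / incident.I0)


# ---------------------------------------------------------------------------
# Gamma estimation and linearization
# ---------------------------------------------------------------------------

def estimate_gamma(
    scanned: ChartColors,
    reference: ChartColors,
    C: ConversionMatrix,
    bounds: tuple[float, float] = (0.2, 5.0),
) -> GammaEstimate:
    """Display gamma from the luminance of the neutral patches.

    Minimizes sum over neutral patches of (Y_scanned^gamma - Y_reference)^2
    by bounded scalar least squares.  Patches whose scanned luminance is
    saturated (Y <= 0 or Y >= 1) are excluded; the glass background always is,
    since its normalized luminance is exactly 1 and 1^gamma carries no
    information.
    """
    y_row = C.C[1]
    ys, yr = [], []
    for pid in GRAYSCALE_IDS:
        y_s = float(y_row @ scanned.column(pid))
        y_r = float(y_row @ reference.column(pid))
        if 1e-6 < y_s < 1.0 - 1e-6:
            ys.append(y_s)
            yr.append(y_r)
    if len(ys) < 2:
        raise InsufficientDataError("need at least two unsaturated neutral patches")
    ys_a, yr_a = np.array(ys), np.array(yr)

    def loss(g: float) -> float:
        return float(np.sum((ys_a ** g - yr_a) ** 2))

    res = minimize_scalar(loss, bounds=bounds, method="bounded",
                          options={"xatol": 1e-7})
    return GammaEstimate(float(res.x), float(res.fun))


def linearize(img: ImagePatch, gamma: GammaEstimate) -> ImagePatch:
    """Undo the display encoding: value -> value ** gamma, per channel."""
    if img.encoding != "device_gamma":
        raise EncodingError("linearize expects a device_gamma image")
    if np.any(img.pixels < 0):
        raise IhccalError("negative pixel values; clip before linearizing")
    return ImagePatch(img.pixels ** gamma.gamma, "device_linear", img.pixel_size_um)


# ---------------------------------------------------------------------------
# White-point-preserving polynomial color correction
# ---------------------------------------------------------------------------

def _design(colors: np.ndarray) -> np.ndarray:
    """5 x N design matrix of the polynomial basis on chart columns."""
    r, g, b = colors
    return np.vstack([r, g, b, r * g * b, np.ones_like(r)])


def fit_wppls(reference: ChartColors, scanned_linear: ChartColors) -> PolynomialColorMap:
    """White-point-preserved least squares fit of the polynomial color map.

    Solves, for each output channel, min ||Gr_row - m.Phi||^2 subject to
    m.phi(1,1,1) = 1 via the KKT (Lagrange multiplier) system, so the
    constraint holds to machine precision.
    """
    phi = _design(scanned_linear.values)  # 5 x 13
    gram = phi @ phi.T
    if np.linalg.matrix_rank(gram, tol=1e-10) < 5:
        raise CalibrationError("degenerate chart: polynomial design is rank-deficient")
    phi_u = _design(np.ones((3, 1)))[:, 0]  # basis at the white point
    kkt = np.zeros((6, 6))
    kkt[:5, :5] = 2.0 * gram
    kkt[:5, 5] = phi_u
    kkt[5, :5] = phi_u
    coeffs = np.empty((3, 5))
    for ch in range(3):
        rhs = np.concatenate([2.0 * phi @ reference.values[ch], [1.0]])
        sol = np.linalg.solve(kkt, rhs)
        coeffs[ch] = sol[:5]
    return PolynomialColorMap(coeffs)


def apply_color_map(img: ImagePatch, cmap: PolynomialColorMap) -> ImagePatch:
    """Map a linearized device image into the standard linear RGB space."""
    if img.encoding != "device_linear":
        raise EncodingError("apply_color_map expects a device_linear image")
    return ImagePatch(cmap(img.pixels), "standard_linear", img.pixel_size_um)


def calibrate_scanner(
    chart_img: ImagePatch,
    layout: Mapping[str, Sequence[int]],
    reference: ChartColors,
    C: ConversionMatrix,
    incident: IncidentLight | None = None,
    central_fraction: float = 0.5,
) -> ScannerCalibration:
    """Fit the full device calibration from a scanned chart image.

    The incident light defaults to the mean of the chart's background (glass)
    region.  Order of operations is fixed: incident normalization, gamma
    linearization on neutral-patch luminances, then the WPPLS color map on
    the linearized patch colors.
    """
    if chart_img.encoding != "device_gamma":
        raise EncodingError("calibration expects the raw device_gamma chart image")
    if incident is None:
        raw = extract_patch_colors(chart_img, layout, central_fraction)
        incident = IncidentLight(raw.column("BG"))
    norm = normalize_by_incident(chart_img, incident)
    gs = extract_patch_colors(norm, layout, central_fraction)
    gamma = estimate_gamma(gs, reference, C)
    gs_lin = ChartColors(gs.values ** gamma.gamma, role="scanned")
    cmap = fit_wppls(reference, gs_lin)
    return ScannerCalibration(gamma, cmap, incident)


# ---------------------------------------------------------------------------
# dE* evaluation maps
# ---------------------------------------------------------------------------

def compute_de_map(
    imgA: ImagePatch,
    imgB: ImagePatch,
    C: ConversionMatrix,
    white: XYZColor | None = None,
    mask: np.ndarray | None = None,
    bins: int = 64,
) -> DeltaEMap:
    """Pixelwise CIE76 dE* between two aligned standard-linear images.

    Images must already be registered; no alignment is attempted here.  The
    mean/sd and the 64-bin histogram are computed over the mask only.
    """
    if imgA.shape != imgB.shape:
        raise IhccalError("images must have identical dimensions (register upstream)")
    if imgA.encoding != "standard_linear" or imgB.encoding != "standard_linear":
        raise EncodingError("dE* maps require standard_linear images")
    white = white if white is not None else XYZColor(*(C.C @ np.ones(3)))
    labA = xyz_array_to_lab(imgA.pixels @ C.C.T, white)
    labB = xyz_array_to_lab(imgB.pixels @ C.C.T, white)
    values = np.linalg.norm(labA - labB, axis=-1)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise IhccalError("mask shape must match the images")
    sel = values[mask]
    if sel.size == 0:
        warnings.warn("empty dE* mask; summaries are NaN")
        mean = sd = float("nan")
        hist, edges = np.zeros(bins), np.linspace(0, 1, bins + 1)
    else:
        mean, sd = float(sel.mean()), float(sel.std())
        hi = float(sel.max())
        hist, edges = np.histogram(sel, bins=bins, range=(0.0, hi if hi > 0 else 1.0))
    return DeltaEMap(values, mask, mean, sd, hist, edges)


def mean_patch_delta_e(
    a: ChartColors, b: ChartColors, C: ConversionMatrix
) -> float:
    """Mean CIE76 dE* over the 13 chart columns of two color sets."""
    white = XYZColor(*(C.C @ np.ones(3)))
    labA = xyz_array_to_lab(a.values.T @ C.C.T, white)
    labB = xyz_array_to_lab(b.values.T @ C.C.T, white)
    return float(np.linalg.norm(labA - labB, axis=-1).mean())
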