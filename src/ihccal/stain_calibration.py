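"""DAB staining color and intensity calibration from a microbead calibrator.

The calibrator slide carries microbeads coated with ten graded peptide
concentrations; after IHC staining alongside the tissue, their DAB optical
densities characterize the staining batch.  Two correction routes follow:

* method 1 adjusts the immunoscore thresholds to the target batch's scale;
* method 2 corrects the image intensities onto the reference batch's scale.

Optical density follows the Beer-Lambert convention OD = -log10(I / I0).
DAB stain direction is estimated from the lightly stained bead levels only,
since heavily stained DAB scatters and departs from Beer-Lambert behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.isotonic import IsotonicRegression

from .errors import (
    CalibrationError,
    EncodingError,
    IhccalError,
    MissingLevelError,
)
from .scanner_calibration import ImagePatch, IncidentLight

#: Floor applied before taking logs (one 16-bit step).
OD_EPS = 1.0 / 65536.0

#: Ruifrok-Johnston stain OD directions (unit-normalized on construction).
RUIFROK_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
RUIFROK_DAB = np.array([0.268, 0.570, 0.776])


@dataclass(frozen=True)
class BeadPanel:
    """Per-level mean colors and optical densities of a calibrator slide."""

    mean_rgb: np.ndarray  # (10, 3) linear RGB
    mean_od: np.ndarray  # (10, 3) optical density
    n_pixels: np.ndarray  # (10,) pixel counts

    def __post_init__(self) -> None:
        rgb = np.asarray(self.mean_rgb, float)
        od = np.asarray(self.mean_od, float)
        n = np.asarray(self.n_pixels, int)
        object.__setattr__(self, "mean_rgb", rgb)
        object.__setattr__(self, "mean_od", od)
        object.__setattr__(self, "n_pixels", n)
        if rgb.shape != (10, 3) or od.shape != (10, 3) or n.shape != (10,):
            raise IhccalError("a bead panel has exactly 10 levels")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, 11)

    def dab_od(self, dab_vector: np.ndarray) -> np.ndarray:
        """Per-level scalar DAB OD: projection of mean OD onto the DAB direction."""
        v = np.asarray(dab_vector, float)
        return self.mean_od @ (v / np.linalg.norm(v))


@dataclass(frozen=True)
class StainModel:
    """Orthonormal-ish stain basis: DAB, hematoxylin and a residual direction."""

    dab_vector: np.ndarray
    hematoxylin_vector: np.ndarray
    residual_vector: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dab_vector", "hematoxylin_vector", "residual_vector"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            n = np.linalg.norm(v)
            if n == 0:
                raise IhccalError(f"{name} must be nonzero")
            object.__setattr__(self, name, v / n)
        if np.any(self.dab_vector < 0) or np.any(self.hematoxylin_vector < 0):
            raise IhccalError("stain vectors must have nonnegative components")
        m = self.matrix
        if np.linalg.cond(m) > 1e6:
            raise CalibrationError("stain vectors are nearly collinear")

    @property
    def matrix(self) -> np.ndarray:
        """Columns: DAB, hematoxylin, residual."""
        return np.column_stack(
            [self.dab_vector, self.hematoxylin_vector, self.residual_vector]
        )


def make_stain_model(
    dab_vector: np.ndarray, hematoxylin_vector: np.ndarray | None = None
) -> StainModel:
    """Build a stain model; the residual completes the basis by cross product."""
    hem = RUIFROK_HEMATOXYLIN if hematoxylin_vector is None else np.asarray(hematoxylin_vector, float)
    dab = np.asarray(dab_vector, float)
    res = np.cross(dab, hem)
    n = np.linalg.norm(res)
    if n < 1e-12:
        raise CalibrationError("DAB and hematoxylin vectors are collinear")
    return StainModel(dab, hem, res / n)


@dataclass(frozen=True)
class IntensityTransferMap:
    """Monotone piecewise-linear map from target-batch DAB OD to reference OD.

    Knots pair matched bead levels, with (0, 0) prepended; beyond the last
    knot the final segment's slope is continued (the dark regime is unreliable
    anyway, and the working thresholds sit well inside the knot range).
    """

    x: np.ndarray  # target-scale knot abscissae, strictly increasing, x[0] = 0
    y: np.ndarray  # reference-scale ordinates, nondecreasing, y[0] = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise IhccalError("transfer map needs matched 1-D knot arrays")
        if x[0] != 0 or y[0] != 0:
            raise IhccalError("transfer map must be anchored at (0, 0)")
        if np.any(np.diff(x) <= 0):
            raise IhccalError("knot abscissae must be strictly increasing")
        if np.any(np.diff(y) < 0):
            raise IhccalError("transfer map must be monotone nondecreasing")

    def __call__(self, od: np.ndarray | float) -> np.ndarray | float:
        od = np.asarray(od, dtype=float)
        out = np.interp(od, self.x, self.y)
        # linear extrapolation past the last knot
        slope = (self.y[-1] - self.y[-2]) / (self.x[-1] - self.x[-2])
        high = od > self.x[-1]
        out = np.where(high, self.y[-1] + slope * (od - self.x[-1]), out)
        return out if out.ndim else float(out)

    def inverse(self, ref_od: float) -> float:
        """Target-scale OD mapping to the given reference-scale OD.

        On a flat segment the preimage is an interval; its midpoint is
        returned with a warning.
        """
        x, y = self.x, self.y
        if ref_od <= 0.0:
            return 0.0
        if ref_od >= y[-1]:
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            if slope <= 0:
                warnings.warn("flat terminal segment; inverse ill-defined, using last knot")
                return float(x[-1])
            return float(x[-1] + (ref_od - y[-1]) / slope)
        lo = int(np.searchsorted(y, ref_od, side="left"))
        hi = int(np.searchsorted(y, ref_od, side="right"))
        if lo < hi:  # ref_od ties with one or more knot ordinates
            if hi - lo > 1:
                warnings.warn("threshold falls on a flat segment; using its midpoint")
                return float(0.5 * (x[lo] + x[hi - 1]))
            return float(x[lo])
        # strictly inside the (lo-1, lo) segment, which is strictly increasing
        x0, x1, y0, y1 = x[lo - 1], x[lo], y[lo - 1], y[lo]
        return float(x0 + (ref_od - y0) * (x1 - x0) / (y1 - y0))

    @classmethod
    def identity(cls, max_od: float = 3.0) -> "IntensityTransferMap":
        return cls(np.array([0.0, max_od]), np.array([0.0, max_od]))


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing DAB OD thresholds separating immunoscores 0..3."""

    t1: float
    t2: float
    t3: float

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 < self.t3):
            raise IhccalError("thresholds must be positive and strictly increasing")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.t1, self.t2, self.t3)


# ---------------------------------------------------------------------------
# Optical density conversions
# ---------------------------------------------------------------------------

def rgb_to_od(img: ImagePatch, incident: IncidentLight) -> np.ndarray:
    """Beer-Lambert optical density: OD = -log10(I / I0), floored at OD_EPS."""
    if img.encoding != "standard_linear":
        raise EncodingError("optical density expects a standard_linear image")
    ratio = np.maximum(img.pixels / incident.I0, OD_EPS)
    return -np.log10(ratio)


def od_to_rgb(od: np.ndarray, incident: IncidentLight) -> ImagePatch:
    """Inverse of :func:`rgb_to_od`."""
    return ImagePatch(10.0 ** (-np.asarray(od, float)) * incident.I0, "standard_linear")


# ---------------------------------------------------------------------------
# Bead panel measurement
# ---------------------------------------------------------------------------

def measure_bead_panel(
    calib_img: ImagePatch,
    incident: IncidentLight,
    bead_layout: Sequence[tuple[float, float, float]] | None = None,
    od_threshold: float = 0.05,
    erode_px: int = 2,
) -> BeadPanel:
    """Per-level mean OD over bead-interior pixels of a calibrator image.

    With an explicit ``bead_layout`` (10 disks as (row, col, radius), in level
    order), pixels within each slightly eroded disk are averaged.  Without
    one, beads are auto-detected: total OD above ``od_threshold``, connected
    components, interiors eroded, and the 10 largest components ordered by
    position (row band, then column).
    """
    od = rgb_to_od(calib_img, incident)
    H, W = od.shape[:2]
    rows, cols = np.mgrid[0:H, 0:W]
    regions: list[np.ndarray] = []
    if bead_layout is not None:
        if len(bead_layout) != 10:
            raise MissingLevelError("bead layout must describe exactly 10 levels")
        for r, c, rad in bead_layout:
            mask = (rows - r) ** 2 + (cols - c) ** 2 <= (rad - erode_px) ** 2
            regions.append(mask)
    else:
        fg = od.sum(axis=2) > od_threshold
        labels, n = ndimage.label(fg)
        if n < 10:
            raise MissingLevelError(f"found only {n} bead candidates; need 10")
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[-10:] + 1
        centroids = ndimage.center_of_mass(fg, labels, index=keep)
        # order: top row band left-to-right, then bottom band
        cy = np.array([c[0] for c in centroids])
        cx = np.array([c[1] for c in centroids])
        band = (cy > np.median(cy)).astype(int)
        order = np.lexsort((cx, band))
        for idx in order:
            mask = labels == keep[idx]
            mask = ndimage.binary_erosion(mask, iterations=erode_px)
            regions.append(mask)
    mean_rgb = np.empty((10, 3))
    mean_od = np.empty((10, 3))
    n_pixels = np.empty(10, dtype=int)
    for k, mask in enumerate(regions):
        if not np.any(mask):
            raise MissingLevelError(f"level {k + 1}: no interior pixels detected")
        mean_rgb[k] = calib_img.pixels[mask].mean(axis=0)
        mean_od[k] = od[mask].mean(axis=0)
        n_pixels[k] = int(mask.sum())
    return BeadPanel(mean_rgb, mean_od, n_pixels)


def estimate_dab_vector(
    panel: BeadPanel, od_window: tuple[float, float] = (0.02, 0.6)
) -> np.ndarray:
    """Unit DAB OD direction from the lightly stained bead levels.

    Levels whose OD norm falls in ``od_window`` qualify; the unit-normalized
    mean of their per-level OD directions is returned.  Darkly stained levels
    are excluded because scattering bends the DAB color off the Beer-Lambert
    line.
    """
    norms = np.linalg.norm(panel.mean_od, axis=1)
    sel = (norms > od_window[0]) & (norms < od_window[1])
    if sel.sum() < 2:
        raise CalibrationError("fewer than 2 lightly stained levels; cannot estimate DAB vector")
    dirs = panel.mean_od[sel] / norms[sel, None]
    v = dirs.mean(axis=0)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Color unmixing
# ---------------------------------------------------------------------------

def unmix(od_img: np.ndarray, stains: StainModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel stain concentrations (DAB OD, hematoxylin OD).

    Solves [dab | hem | residual] . c = OD per pixel, clips the two stain
    channels at zero and discards the residual channel.
    """
    od = np.asarray(od_img, float)
    inv = np.linalg.inv(stains.matrix)
    conc = od @ inv.T
    dab = np.clip(conc[..., 0], 0.0, None)
    hem = np.clip(conc[..., 1], 0.0, None)
    return dab, hem


def unmix_full(od_img: np.ndarray, stains: StainModel) -> np.ndarray:
    """As :func:`unmix` but returns all three raw channels unclipped."""
    return np.asarray(od_img, float) @ np.linalg.inv(stains.matrix).T


def compose(dab: np.ndarray, hem: np.ndarray, stains: StainModel) -> np.ndarray:
    """Forward model: stain concentrations -> OD image."""
    return (
        np.asarray(dab, float)[..., None] * stains.dab_vector
        + np.asarray(hem, float)[..., None] * stains.hematoxylin_vector
    )


# ---------------------------------------------------------------------------
# Intensity transfer and the two calibration methods
# ---------------------------------------------------------------------------

def build_intensity_transfer(
    target: BeadPanel,
    reference: BeadPanel,
    stains_target: StainModel,
    stains_reference: StainModel,
) -> IntensityTransferMap:
    """Monotone map from target-batch DAB OD scale to the reference scale.

    Level k's target DAB OD is paired with level k's reference DAB OD (each
    panel projected onto its own DAB direction).  Non-monotone noisy ladders
    are repaired by isotonic regression before knot construction; ties are
    merged; (0, 0) is prepended.
    """
    tx = target.dab_od(stains_target.dab_vector)
    ty = reference.dab_od(stains_reference.dab_vector)
    levels = np.arange(10, dtype=float)
    iso = IsotonicRegression(increasing=True)
    tx = iso.fit_transform(levels, tx)
    ty = IsotonicRegression(increasing=True).fit_transform(levels, ty)
    # merge knots with tied abscissae (flat after isotonic repair)
    xs, ys = [0.0], [0.0]
    for xv, yv in zip(tx, ty):
        if xv <= xs[-1] + 1e-12:
            ys[-1] = max(ys[-1], float(yv))
            continue
        xs.append(float(xv))
        ys.append(max(float(yv), ys[-1]))
    if len(xs) < 2:
        raise CalibrationError("degenerate bead panels: no usable transfer knots")
    return IntensityTransferMap(np.array(xs), np.array(ys))


def calibrate_thresholds_method1(
    ref_thresholds: ThresholdSet, transfer: IntensityTransferMap
) -> ThresholdSet:
    """Method 1: move the reference thresholds onto the target batch's scale.

    Each reference threshold t becomes transfer^{-1}(t): the target-scale OD
    whose calibrated value equals t.
    """
    t = [transfer.inverse(v) for v in ref_thresholds.as_tuple()]
    if not t[0] < t[1] < t[2]:
        raise CalibrationError("transfer map collapsed the threshold ordering")
    return ThresholdSet(*t)


def correct_image_method2(
    img: ImagePatch,
    transfer: IntensityTransferMap,
    stains_target: StainModel,
    stains_reference: StainModel,
    incident: IncidentLight,
) -> ImagePatch:
    """Method 2: correct a tissue image onto the reference staining scale.

    The image is unmixed with the target stain model; the DAB channel is
    passed through the transfer map; the OD image is recomposed with the
    reference stain vectors (hematoxylin is never rescaled; the residual
    channel is carried over untouched) and converted back to linear RGB.
    """
    od = rgb_to_od(img, incident)
    conc = unmix_full(od, stains_target)
    dab = np.clip(conc[..., 0], 0.0, None)
    hem = np.clip(conc[..., 1], 0.0, None)
    res = conc[..., 2]
    od_new = (
        np.asarray(transfer(dab))[..., None] * stains_reference.dab_vector
        + hem[..., None] * stains_reference.hematoxylin_vector
        + res[..., None] * stains_target.residual_vector
    )
    out = od_to_rgb(od_new, incident)
    return ImagePatch(out.pixels, "standard_linear", img.pixel_size_um)
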