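"""File formats: images, spectral tables, layouts, calibrations and reports.

Images are 8/16-bit PNG or TIFF; integer codes map to [0, 1] by division
with the dtype maximum.  Spectral calibration data is CSV with a
``wavelength_nm`` column plus one transmittance column per patch id.
Calibrations and reports serialize to deterministic JSON (sorted keys, fixed
float precision) so identical runs produce identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .colorimetry import PATCH_IDS, SpectralCurve, WAVELENGTH_GRID
from .errors import IhccalError
from .scanner_calibration import (
    GammaEstimate,
    ImagePatch,
    IncidentLight,
    PolynomialColorMap,
    ScannerCalibration,
)
from .stain_calibration import (
    BeadPanel,
    IntensityTransferMap,
    StainModel,
    ThresholdSet,
)

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path, encoding: str = "device_gamma") -> ImagePatch:
    """Read a PNG/TIFF patch; integer codes are scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] > 3:
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return ImagePatch(arr, encoding)


def write_image(img: ImagePatch, path, bits: int = 16) -> None:
    """Write a patch as 8/16-bit PNG or TIFF, clipping to [0, 1] on export."""
    path = Path(path)
    if bits not in (8, 16):
        raise IhccalError("bit depth must be 8 or 16")
    if bits == 16 and path.suffix.lower() not in (".tif", ".tiff"):
        raise IhccalError("16-bit export is only supported for TIFF")
    scale = 2 ** bits - 1
    arr = np.clip(img.pixels, 0.0, 1.0)
    arr = np.round(arr * scale).astype(np.uint16 if bits == 16 else np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# Spectral tables and layouts
# ---------------------------------------------------------------------------

def load_spectral_table(path) -> dict[str, SpectralCurve]:
    """Load the 13 patch transmittance spectra from CSV.

    Requires a header row, a ``wavelength_nm`` column covering 340..830 nm at
    5 nm steps (99 rows) and one column per patch id A1..C4 plus BG.
    """
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise IhccalError("spectral CSV needs a 'wavelength_nm' column")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    if w.size != WAVELENGTH_GRID.size or not np.allclose(np.sort(w), WAVELENGTH_GRID):
        raise IhccalError("spectral grid must be 340..830 nm at 5 nm steps (99 rows)")
    order = np.argsort(w)
    missing = [p for p in PATCH_IDS if p not in df.columns]
    if missing:
        raise IhccalError(f"spectral CSV missing patch columns: {missing}")
    out = {}
    for pid in PATCH_IDS:
        t = df[pid].to_numpy(dtype=float)[order]
        if np.any(t < 0) or np.any(t > 1) or np.any(~np.isfinite(t)):
            raise IhccalError(f"patch {pid!r}: transmittance outside [0, 1]")
        out[pid] = SpectralCurve(WAVELENGTH_GRID, t)
    return out


def write_spectral_table(spectra: Mapping[str, SpectralCurve], path) -> None:
    data = {"wavelength_nm": WAVELENGTH_GRID}
    for pid in PATCH_IDS:
        data[pid] = spectra[pid].transmittance
    pd.DataFrame(data).to_csv(path, index=False)


def load_layout(path) -> dict:
    """Chart layout mapping patch id -> (row0, col0, height, width)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return {k: tuple(int(x) for x in v) for k, v in raw.items()}


def save_layout(layout: Mapping, path) -> None:
    Path(path).write_text(
        json.dumps({k: list(v) for k, v in layout.items()}, sort_keys=True, indent=1)
    )


# ---------------------------------------------------------------------------
# Calibration serialization
# ---------------------------------------------------------------------------

def scanner_calibration_to_dict(cal: ScannerCalibration) -> dict:
    return {
        "kind": "scanner_calibration",
        "gamma": cal.gamma.gamma,
        "gamma_fit_residual": cal.gamma.fit_residual,
        "color_map_coeffs": cal.color_map.coeffs.tolist(),
        "color_map_basis": list(cal.color_map.basis),
        "incident": cal.incident.I0.tolist(),
    }


def scanner_calibration_from_dict(d: dict) -> ScannerCalibration:
    return ScannerCalibration(
        GammaEstimate(float(d["gamma"]), float(d.get("gamma_fit_residual", 0.0))),
        PolynomialColorMap(np.asarray(d["color_map_coeffs"], float)),
        IncidentLight(np.asarray(d["incident"], float)),
    )


def stain_calibration_to_dict(
    panel: BeadPanel, stains: StainModel, transfer: IntensityTransferMap | None = None
) -> dict:
    d = {
        "kind": "stain_calibration",
        "panel_mean_od": panel.mean_od.tolist(),
        "panel_mean_rgb": panel.mean_rgb.tolist(),
        "panel_n_pixels": panel.n_pixels.tolist(),
        "dab_vector": stains.dab_vector.tolist(),
        "hematoxylin_vector": stains.hematoxylin_vector.tolist(),
        "residual_vector": stains.residual_vector.tolist(),
    }
    if transfer is not None:
        d["transfer_knots_x"] = transfer.x.tolist()
        d["transfer_knots_y"] = transfer.y.tolist()
    return d


def stain_calibration_from_dict(d: dict):
    panel = BeadPanel(
        np.asarray(d["panel_mean_rgb"], float),
        np.asarray(d["panel_mean_od"], float),
        np.asarray(d["panel_n_pixels"], int),
    )
    stains = StainModel(
        np.asarray(d["dab_vector"], float),
        np.asarray(d["hematoxylin_vector"], float),
        np.asarray(d["residual_vector"], float),
    )
    transfer = None
    if "transfer_knots_x" in d:
        transfer = IntensityTransferMap(
            np.asarray(d["transfer_knots_x"], float),
            np.asarray(d["transfer_knots_y"], float),
        )
    return panel, stains, transfer


def thresholds_to_dict(t: ThresholdSet) -> dict:
    return {"t1": t.t1, "t2": t.t2, "t3": t.t3}


def thresholds_from_dict(d: dict) -> ThresholdSet:
    return ThresholdSet(float(d["t1"]), float(d["t2"]), float(d["t3"]))


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_round_floats(obj), sort_keys=True, indent=1))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 4):
    """Fixed float formatting for deterministic report bytes."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_report(result: dict, diagnostics: dict | None, path) -> None:
    """Deterministic JSON report: sorted keys, 4-decimal floats, versioned."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "result": result}
    if diagnostics:
        doc["diagnostics"] = diagnostics
    Path(path).write_text(json.dumps(_round_floats(doc), sort_keys=True, indent=1))


def read_report(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise IhccalError("unsupported report schema version")
    return doc
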