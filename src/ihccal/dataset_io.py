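"""Serialization of rendered experiment datasets to a directory tree.

The ``simulate`` CLI writes, and ``run`` reads, this layout::

    <root>/
      spectra.csv           chart patch transmittances
      manifest.json
      reference/            one directory per dataset
        chart.tiff  chart_layout.json
        calibrator.tiff  bead_layout.json  truth_panel.json
        tissue_<status>.tiff  cells_<status>.csv
      target_00_.../ ...

Images are 16-bit TIFF; ground truth (per-cell true membrane OD and intended
score, per-level bead ODs) rides along for evaluation but is never consumed
by the calibration pipeline itself.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    load_spectral_table,
    read_image,
    save_layout,
    load_layout,
    write_image,
    write_spectral_table,
)
from .stain_calibration import BeadPanel
from .synthetic import (
    Dataset,
    ExperimentBundle,
    PhantomCell,
    StainBatchConfig,
    TissuePhantomSpec,
    demo_chart_spectra,
    reference_chart_colors,
    scanner_preset,
    STATUS_COMPOSITIONS,
)

_STATUS_SLUG = {"0": "0", "1+": "1p", "2+": "2p", "3+": "3p"}
_SLUG_STATUS = {v: k for k, v in _STATUS_SLUG.items()}


def save_dataset(ds: Dataset, root: Path) -> None:
    root.mkdir(parents=True, exist_ok=True)
    write_image(ds.chart, root / "chart.tiff")
    save_layout(ds.chart_layout, root / "chart_layout.json")
    write_image(ds.calibrator, root / "calibrator.tiff")
    (root / "bead_layout.json").write_text(
        json.dumps([list(map(float, g)) for g in ds.bead_geometry])
    )
    (root / "truth_panel.json").write_text(
        json.dumps(
            {
                "mean_rgb": ds.truth_panel.mean_rgb.tolist(),
                "mean_od": ds.truth_panel.mean_od.tolist(),
                "n_pixels": ds.truth_panel.n_pixels.tolist(),
            }
        )
    )
    for status, (img, cells) in ds.tissues.items():
        slug = _STATUS_SLUG[status]
        write_image(img, root / f"tissue_{slug}.tiff")
        pd.DataFrame(
            [
                {
                    "row": c.row,
                    "col": c.col,
                    "membrane_od": c.membrane_od,
                    "intended_score": c.intended_score,
                }
                for c in cells
            ]
        ).to_csv(root / f"cells_{slug}.csv", index=False)


def load_dataset(root: Path, name: str) -> Dataset:
    chart = read_image(root / "chart.tiff")
    layout = load_layout(root / "chart_layout.json")
    calibrator = read_image(root / "calibrator.tiff")
    geometry = [tuple(g) for g in json.loads((root / "bead_layout.json").read_text())]
    tp = json.loads((root / "truth_panel.json").read_text())
    panel = BeadPanel(
        np.asarray(tp["mean_rgb"], float),
        np.asarray(tp["mean_od"], float),
        np.asarray(tp["n_pixels"], int),
    )
    tissues = {}
    for slug, status in _SLUG_STATUS.items():
        img = read_image(root / f"tissue_{slug}.tiff")
        df = pd.read_csv(root / f"cells_{slug}.csv")
        cells = [
            PhantomCell(r.row, r.col, r.membrane_od, int(r.intended_score))
            for r in df.itertuples()
        ]
        tissues[status] = (img, cells)
    # placeholder forward-model configs: unknown for externally loaded data
    return Dataset(
        name,
        scanner_preset("A"),
        StainBatchConfig(),
        chart,
        layout,
        calibrator,
        geometry,
        panel,
        tissues,
    )


def save_experiment(bundle: ExperimentBundle, root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_spectral_table(demo_chart_spectra(), root / "spectra.csv")
    (root / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    save_dataset(bundle.reference, root / "reference")
    for ds in bundle.targets:
        save_dataset(ds, root / ds.name)


def load_experiment(root) -> ExperimentBundle:
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    from .colorimetry import cie_1931_cmf, compute_reference_chart, d65_illuminant, srgb_matrix

    spectra = load_spectral_table(root / "spectra.csv")
    chart_reference = compute_reference_chart(
        spectra, d65_illuminant(), cie_1931_cmf(), srgb_matrix()
    )
    reference = load_dataset(root / "reference", "reference")
    targets = [
        load_dataset(root / d["name"], d["name"]) for d in manifest["datasets"]
    ]
    specs = {s: TissuePhantomSpec(intended_status=s) for s in STATUS_COMPOSITIONS}
    return ExperimentBundle(reference, targets, chart_reference, specs, manifest)
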