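"""End-to-end calibration and scoring pipeline.

The six method selectors combine the two calibration stages:

    "<ccs>-<ihc>"  with  ccs in {0, 1}  and  ihc in {0, 1, 2}

* ccs = 1: scanner color calibration from the dataset's chart image
  (incident normalization, gamma linearization, WPPLS color map).
* ihc = 1: staining calibration by threshold adjustment (method 1);
  ihc = 2: staining calibration by image intensity correction (method 2);
  ihc = 0: reference thresholds applied as-is.

Preparation fits the reference standard once: scanner calibration of the
reference dataset, its bead panel and stain model, and the immunoscore
thresholds derived from the score-known reference cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .colorimetry import ChartColors, ConversionMatrix, srgb_matrix
from .errors import ConfigError
from .her2_scoring import (
    CellRecord,
    DetectorParams,
    HER2Result,
    StatusRule,
    DEFAULT_STATUS_RULE,
    detect_cells,
    derive_reference_thresholds,
    evaluate_cells,
)
from .scanner_calibration import (
    ImagePatch,
    IncidentLight,
    ScannerCalibration,
    calibrate_scanner,
    estimate_incident,
    mean_patch_delta_e,
    extract_patch_colors,
    normalize_by_incident,
)
from .stain_calibration import (
    BeadPanel,
    IntensityTransferMap,
    StainModel,
    ThresholdSet,
    build_intensity_transfer,
    calibrate_thresholds_method1,
    correct_image_method2,
    estimate_dab_vector,
    make_stain_model,
    measure_bead_panel,
)
from .synthetic import Dataset, ExperimentBundle

log = logging.getLogger(__name__)

SELECTORS = ("0-0", "0-1", "0-2", "1-0", "1-1", "1-2")

_UNIT_INCIDENT = IncidentLight(np.ones(3))


def _parse_selector(selector: str) -> tuple[int, int]:
    if selector not in SELECTORS:
        raise ConfigError(f"selector must be one of {SELECTORS}, got {selector!r}")
    ccs, ihc = selector.split("-")
    return int(ccs), int(ihc)


def _assume_standard(img: ImagePatch) -> ImagePatch:
    """Uncalibrated route: trust the scanner, normalize by estimated incident."""
    inc = estimate_incident(img)
    out = normalize_by_incident(img, inc)
    return ImagePatch(out.pixels, "standard_linear", img.pixel_size_um)


@dataclass(frozen=True)
class PreparedReference:
    """The reference standard fitted in the preparation stage."""

    chart_reference: ChartColors
    scanner_cal: ScannerCalibration
    panel: BeadPanel
    stains: StainModel
    thresholds: ThresholdSet
    rule: StatusRule = field(default_factory=StatusRule)


def prepare_reference(
    dataset: Dataset,
    chart_reference: ChartColors,
    C: ConversionMatrix | None = None,
    rule: StatusRule = DEFAULT_STATUS_RULE,
    detector: DetectorParams = DetectorParams(),
) -> PreparedReference:
    """Fit the reference standard from the fully calibrated reference dataset."""
    C = C if C is not None else srgb_matrix()
    cal = calibrate_scanner(dataset.chart, dataset.chart_layout, chart_reference, C)
    log.info("reference scanner gamma=%.4f", cal.gamma.gamma)
    calib_img = cal.apply(dataset.calibrator)
    panel = measure_bead_panel(calib_img, _UNIT_INCIDENT, bead_layout=dataset.bead_geometry)
    stains = make_stain_model(estimate_dab_vector(panel))
    log.info("reference DAB vector=%s", np.round(stains.dab_vector, 4))
    cases = []
    for status, (img, _truth) in dataset.tissues.items():
        cells = detect_cells(cal.apply(img), stains, _UNIT_INCIDENT, detector)
        cases.append((cells, status))
    thresholds = derive_reference_thresholds(cases, rule=rule)
    log.info("reference thresholds=%s", thresholds.as_tuple())
    return PreparedReference(chart_reference, cal, panel, stains, thresholds, rule)


@dataclass(frozen=True)
class DatasetResult:
    """Scored tissues of one target dataset plus the fitted stage parameters."""

    selector: str
    results: dict  # status -> HER2Result
    cells: dict  # status -> list[CellRecord]
    scanner_cal: ScannerCalibration | None
    transfer: IntensityTransferMap | None
    thresholds: ThresholdSet
    chart_delta_e: float | None = None


def process_dataset(
    dataset: Dataset,
    prep: PreparedReference,
    selector: str,
    C: ConversionMatrix | None = None,
    detector: DetectorParams = DetectorParams(),
) -> DatasetResult:
    """Run one target dataset through the selected calibration combination."""
    C = C if C is not None else srgb_matrix()
    ccs, ihc = _parse_selector(selector)

    chart_de = None
    if ccs == 1:
        cal = calibrate_scanner(dataset.chart, dataset.chart_layout, prep.chart_reference, C)
        log.info("%s: target gamma=%.4f", dataset.name, cal.gamma.gamma)
        transform = cal.apply
        calibrated_chart = ChartColors(
            cal.color_map(
                extract_patch_colors(
                    normalize_by_incident(dataset.chart, cal.incident),
                    dataset.chart_layout,
                ).values.T
                ** cal.gamma.gamma
            ).T,
            role="scanned",
        )
        chart_de = mean_patch_delta_e(calibrated_chart, prep.chart_reference, C)
    else:
        cal = None
        transform = _assume_standard

    transfer = None
    if ihc == 0:
        stains_t = prep.stains
        thresholds = prep.thresholds
    else:
        calib_img = transform(dataset.calibrator)
        panel_t = measure_bead_panel(
            calib_img, _UNIT_INCIDENT, bead_layout=dataset.bead_geometry
        )
        stains_t = make_stain_model(estimate_dab_vector(panel_t))
        transfer = build_intensity_transfer(panel_t, prep.panel, stains_t, prep.stains)
        if ihc == 1:
            thresholds = calibrate_thresholds_method1(prep.thresholds, transfer)
            log.info("%s: method-1 thresholds=%s", dataset.name, thresholds.as_tuple())
        else:
            thresholds = prep.thresholds

    results: dict[str, HER2Result] = {}
    cells_out: dict[str, list[CellRecord]] = {}
    for status, (img, _truth) in dataset.tissues.items():
        work = transform(img)
        if ihc == 2:
            assert transfer is not None
            work = correct_image_method2(
                work, transfer, stains_t, prep.stains, _UNIT_INCIDENT
            )
            cells = detect_cells(work, prep.stains, _UNIT_INCIDENT, detector)
        else:
            cells = detect_cells(work, stains_t, _UNIT_INCIDENT, detector)
        results[status] = evaluate_cells(cells, thresholds, prep.rule)
        cells_out[status] = cells
    return DatasetResult(selector, results, cells_out, cal, transfer, thresholds, chart_de)


def evaluate_experiment(
    bundle: ExperimentBundle,
    selectors: Sequence[str] = ("0-0", "1-1", "1-2"),
    rule: StatusRule = DEFAULT_STATUS_RULE,
    detector: DetectorParams = DetectorParams(),
) -> dict:
    """Score every target dataset under each selector.

    Returns a nested mapping selector -> dataset name -> status ->
    HER2Result, plus the prepared reference under key ``"_reference"``.
    """
    prep = prepare_reference(
        bundle.reference, bundle.chart_reference, rule=rule, detector=detector
    )
    out: dict = {"_reference": prep}
    for selector in selectors:
        per_ds = {}
        for ds in bundle.targets:
            per_ds[ds.name] = process_dataset(ds, prep, selector, detector=detector)
        out[selector] = per_ds
    return out


def concordance(
    results: Mapping[str, "DatasetResult"],
) -> tuple[int, int]:
    """(matching, total) of assessed vs intended HER2 status over a selector."""
    match = total = 0
    for res in results.values():
        for status, r in res.results.items():
            total += 1
            match += int(r.status == status)
    return match, total


def h_score_sd(results: Mapping[str, "DatasetResult"]) -> dict[str, float]:
    """Across-dataset SD of the H-score per intended case."""
    per_case: dict[str, list[float]] = {}
    for res in results.values():
        for status, r in res.results.items():
            per_case.setdefault(status, []).append(r.h_score)
    return {
        s: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        for s, v in per_case.items()
    }


def result_to_dict(res: DatasetResult) -> dict:
    d = {
        "selector": res.selector,
        "thresholds": list(res.thresholds.as_tuple()),
        "tissues": {
            s: {
                "distribution": r.distribution.as_array().tolist(),
                "h_score": r.h_score,
                "status": r.status,
                "n_cells": len(res.cells[s]),
            }
            for s, r in res.results.items()
        },
    }
    if res.scanner_cal is not None:
        d["scanner"] = {
            "gamma": res.scanner_cal.gamma.gamma,
            "incident": res.scanner_cal.incident.I0.tolist(),
        }
        if res.chart_delta_e is not None:
            d["chart_mean_delta_e"] = res.chart_delta_e
    if res.transfer is not None:
        d["transfer_knots"] = [res.transfer.x.tolist(), res.transfer.y.tolist()]
    return d
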