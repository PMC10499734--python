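"""Per-cell immunoscoring, H-score and HER2 status.

Each cell's mean membrane DAB optical density is classified into an
immunoscore m in {0, 1, 2, 3} (no / weak / moderate / strong staining) by
three thresholds; the percentages P0..P3 yield the H-score

    H-score = sum_m Pm * m        (0 .. 300)

and a configurable percentage rule maps the distribution to the clinical
HER2 status 0 / 1+ / 2+ / 3+.  Threshold boundaries are lower-inclusive for
the higher score.  Reference thresholds can be derived from score-known
reference cases by exhaustive grid search.

Also included: a simplified nucleus-blob / membrane-ring cell detector
sufficient for the disk-shaped tissue phantoms (full membrane-completeness
morphology as done by interactive pathology software is out of scope), and a
CSV path for externally measured per-cell tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import IhccalError, InsufficientDataError
from .scanner_calibration import ImagePatch, IncidentLight
from .stain_calibration import StainModel, ThresholdSet, rgb_to_od, unmix

HER2_STATUSES = ("0", "1+", "2+", "3+")


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    membrane_dab_od: float
    nucleus_detected: bool = True
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.membrane_dab_od < 0:
            raise IhccalError("membrane DAB OD must be nonnegative")


@dataclass(frozen=True)
class ScoreDistribution:
    """Percentages of cells at immunoscore 0..3; sums to 100."""

    P0: float
    P1: float
    P2: float
    P3: float

    def __post_init__(self) -> None:
        ps = self.as_array()
        if np.any(ps < 0) or np.any(ps > 100) or abs(ps.sum() - 100.0) > 1e-9:
            raise IhccalError("percentages must lie in [0, 100] and sum to 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.P0, self.P1, self.P2, self.P3])


@dataclass(frozen=True)
class HER2Result:
    distribution: ScoreDistribution
    h_score: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in HER2_STATUSES:
            raise IhccalError(f"invalid HER2 status {self.status!r}")


@dataclass(frozen=True)
class StatusRule:
    """Percentage cutoffs of the cells-above-score rule (strict '>').

    Default mirrors the ASCO/CAP-style reduction to percentages: 3+ when
    P3 > 10; else 2+ when P2 + P3 > 10; else 1+ when P1 + P2 + P3 > 10;
    else 0.  Membrane-completeness criteria are not computable from mean OD
    alone, hence the rule is intentionally configurable.
    """

    p3_cut: float = 10.0
    p2_cut: float = 10.0
    p1_cut: float = 10.0

    def __call__(self, dist: ScoreDistribution) -> str:
        if dist.P3 > self.p3_cut:
            return "3+"
        if dist.P2 + dist.P3 > self.p2_cut:
            return "2+"
        if dist.P1 + dist.P2 + dist.P3 > self.p1_cut:
            return "1+"
        return "0"


DEFAULT_STATUS_RULE = StatusRule()


def classify_cells(
    cells: Sequence[CellRecord], thresholds: ThresholdSet
) -> np.ndarray:
    """Immunoscore per cell: 0 below t1, then 1, 2, 3 (lower-inclusive)."""
    od = np.array([c.membrane_dab_od for c in cells], dtype=float)
    if np.any(od < 0):
        raise IhccalError("negative membrane OD")
    t1, t2, t3 = thresholds.as_tuple()
    return np.digitize(od, [t1, t2, t3], right=False)


def score_distribution(immunoscores: Iterable[int]) -> ScoreDistribution:
    scores = np.asarray(list(immunoscores), dtype=int)
    if scores.size == 0:
        raise InsufficientDataError("no cells to score")
    counts = np.bincount(scores, minlength=4)[:4]
    return ScoreDistribution(*(100.0 * counts / scores.size))


def h_score(dist: ScoreDistribution) -> float:
    """H-score = sum over immunoscores m of Pm * m; range 0-300."""
    return float(np.dot(dist.as_array(), np.arange(4)))


def her2_status(dist: ScoreDistribution, rule: StatusRule = DEFAULT_STATUS_RULE) -> str:
    return rule(dist)


def evaluate_cells(
    cells: Sequence[CellRecord],
    thresholds: ThresholdSet,
    rule: StatusRule = DEFAULT_STATUS_RULE,
) -> HER2Result:
    """Full per-image assessment: classification, distribution, H-score, status."""
    dist = score_distribution(classify_cells(cells, thresholds))
    return HER2Result(dist, h_score(dist), her2_status(dist, rule))


# ---------------------------------------------------------------------------
# Reference threshold derivation
# ---------------------------------------------------------------------------

def derive_reference_thresholds(
    reference_cases: Sequence[tuple[Sequence[CellRecord], str]],
    search_grid: np.ndarray | None = None,
    rule: StatusRule = DEFAULT_STATUS_RULE,
) -> ThresholdSet:
    """Threshold triple maximizing status concordance on score-known cases.

    Exhaustive search over ordered triples (t1 < t2 < t3) of the OD grid
    (default 0.01..0.60 step 0.01); ties are broken by the lexicographically
    smallest triple.  If no triple reproduces every known score, the best one
    is returned with a warning.
    """
    statuses = {s for _, s in reference_cases}
    if not statuses >= set(HER2_STATUSES):
        raise InsufficientDataError(
            "reference set must contain at least one case per status 0, 1+, 2+, 3+"
        )
    grid = (
        np.round(np.arange(0.01, 0.6001, 0.01), 4)
        if search_grid is None
        else np.asarray(search_grid, float)
    )
    # per case: count of cells below each grid value (half-open convention)
    case_counts = []
    for cells, known in reference_cases:
        od = np.sort([c.membrane_dab_od for c in cells])
        below = np.searchsorted(od, grid, side="left")
        case_counts.append((below, od.size, known))

    best: tuple[float, float, float] | None = None
    best_hits = -1
    for i, j, k in itertools.combinations(range(grid.size), 3):
        hits = 0
        for below, n, known in case_counts:
            n0 = below[i]
            n1 = below[j] - below[i]
            n2 = below[k] - below[j]
            n3 = n - below[k]
            dist = ScoreDistribution(*(100.0 * np.array([n0, n1, n2, n3]) / n))
            if rule(dist) == known:
                hits += 1
        if hits > best_hits:
            best_hits = hits
            best = (float(grid[i]), float(grid[j]), float(grid[k]))
    assert best is not None
    if best_hits < len(reference_cases):
        import warnings

        warnings.warn(
            f"no threshold triple reproduces all reference scores; best matches "
            f"{best_hits}/{len(reference_cases)}"
        )
    return ThresholdSet(*best)


# ---------------------------------------------------------------------------
# Phantom cell detection and tabular I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorParams:
    """Nucleus-blob / membrane-ring detector tuned to the disk phantoms.

    Nuclei are thresholded on the hematoxylin OD channel; the membrane is
    sampled on a fixed-radius annulus around each nucleus centroid, matching
    the phantom geometry (cell radius 10 px, membrane annulus 8-10 px).  The
    ring is kept strictly interior to the rendered membrane so the mean is
    unbiased against background dilution.
    """

    hem_threshold: float = 0.2
    min_nucleus_area: int = 20
    ring_radii: tuple[float, float] = (8.4, 9.6)


def detect_cells(
    img: ImagePatch,
    stains: StainModel,
    incident: IncidentLight,
    params: DetectorParams = DetectorParams(),
) -> list[CellRecord]:
    """Detect phantom cells and measure mean membrane DAB OD per cell."""
    od = rgb_to_od(img, incident)
    dab, hem = unmix(od, stains)
    return measure_membrane_at_nuclei(dab, hem, params)


def measure_membrane_at_nuclei(
    dab: np.ndarray, hem: np.ndarray, params: DetectorParams = DetectorParams()
) -> list[CellRecord]:
    """Nucleus detection on hematoxylin; ring measurement on a DAB image."""
    mask = hem > params.hem_threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= params.min_nucleus_area) + 1
    centroids = ndimage.center_of_mass(mask, labels, index=keep)
    H, W = dab.shape
    rows, cols = np.mgrid[0:H, 0:W]
    r_in, r_out = params.ring_radii
    cells = []
    for cid, (cy, cx) in enumerate(centroids):
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        ring = (d2 >= r_in ** 2) & (d2 <= r_out ** 2)
        if not np.any(ring):
            continue
        cells.append(
            CellRecord(
                cell_id=cid,
                membrane_dab_od=float(max(dab[ring].mean(), 0.0)),
                nucleus_detected=True,
                centroid=(float(cy), float(cx)),
            )
        )
    return cells


def measure_membrane_at(
    dab: np.ndarray,
    centroids: Sequence[tuple[float, float]],
    params: DetectorParams = DetectorParams(),
) -> list[CellRecord]:
    """Ring measurement at externally supplied centroids (tabular path)."""
    H, W = dab.shape
    rows, cols = np.mgrid[0:H, 0:W]
    r_in, r_out = params.ring_radii
    cells = []
    for cid, (cy, cx) in enumerate(centroids):
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        ring = (d2 >= r_in ** 2) & (d2 <= r_out ** 2)
        cells.append(
            CellRecord(cid, float(max(dab[ring].mean(), 0.0)), True, (float(cy), float(cx)))
        )
    return cells


CELL_CSV_COLUMNS = ("cell_id", "membrane_dab_od", "nucleus_detected", "row", "col")


def write_cell_table(cells: Sequence[CellRecord], path) -> None:
    rows = [
        {
            "cell_id": c.cell_id,
            "membrane_dab_od": c.membrane_dab_od,
            "nucleus_detected": c.nucleus_detected,
            "row": c.centroid[0] if c.centroid else np.nan,
            "col": c.centroid[1] if c.centroid else np.nan,
        }
        for c in cells
    ]
    pd.DataFrame(rows, columns=list(CELL_CSV_COLUMNS)).to_csv(path, index=False)


def read_cell_table(path) -> list[CellRecord]:
    df = pd.read_csv(path)
    missing = set(CELL_CSV_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise IhccalError(f"cell table missing columns: {sorted(missing)}")
    cells = []
    for _, row in df.iterrows():
        centroid = None
        if "row" in df.columns and np.isfinite(row.get("row", np.nan)):
            centroid = (float(row["row"]), float(row["col"]))
        cells.append(
            CellRecord(
                int(row["cell_id"]),
                float(row["membrane_dab_od"]),
                bool(row["nucleus_detected"]),
                centroid,
            )
        )
    return cells
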