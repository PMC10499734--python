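"""Forward models rendering the three slide types under a simulated scanner.

Ground truth for every inverse operation in the package: a color chart, a
microbead calibrator and disk-phantom tissue images are rendered in the
standard linear RGB space and pushed through a parameterized scanner model

    device = clip(matrix . (rgb) * incident + noise) ** (1 / gamma)

with a white-preserving 3x3 device mixing matrix (rows sum to 1), a
per-channel incident light, additive Gaussian device-space noise and a
display gamma.  Staining-batch variation is a multiplicative scale on the
DAB optical density.  All renderers are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .colorimetry import (
    ChartColors,
    PATCH_IDS,
    SpectralCurve,
    WAVELENGTH_GRID,
    cie_1931_cmf,
    compute_reference_chart,
    d65_illuminant,
    srgb_matrix,
)
from .errors import IhccalError, LayoutError
from .scanner_calibration import ImagePatch, IncidentLight
from .stain_calibration import (
    BeadPanel,
    RUIFROK_DAB,
    RUIFROK_HEMATOXYLIN,
)

# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScannerSimConfig:
    """Forward scanner model parameters."""

    device_matrix: np.ndarray
    gamma: float = 1.0
    incident: IncidentLight = field(default_factory=lambda: IncidentLight(np.ones(3)))
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.device_matrix, float)
        object.__setattr__(self, "device_matrix", m)
        if m.shape != (3, 3):
            raise IhccalError("device matrix must be 3x3")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise IhccalError("device matrix rows must sum to 1 (white-preserving)")
        if self.gamma <= 0 or self.noise_sd < 0:
            raise IhccalError("gamma must be positive and noise_sd nonnegative")


#: Default bead ladder: a geometric ramp spanning the usable OD range.
DEFAULT_BEAD_ODS = np.geomspace(0.02, 1.2, 10)


@dataclass(frozen=True)
class StainBatchConfig:
    """Staining-batch characteristics: stain directions and intensity scale."""

    dab_scale: float = 1.0
    dab_vector: np.ndarray = field(default_factory=lambda: RUIFROK_DAB.copy())
    hematoxylin_vector: np.ndarray = field(
        default_factory=lambda: RUIFROK_HEMATOXYLIN.copy()
    )
    bead_level_ods: np.ndarray = field(default_factory=lambda: DEFAULT_BEAD_ODS.copy())

    def __post_init__(self) -> None:
        if self.dab_scale <= 0:
            raise IhccalError("dab_scale must be positive")
        for name in ("dab_vector", "hematoxylin_vector"):
            v = np.asarray(getattr(self, name), float)
            object.__setattr__(self, name, v / np.linalg.norm(v))
        ods = np.asarray(self.bead_level_ods, float)
        object.__setattr__(self, "bead_level_ods", ods)
        if ods.size != 10 or np.any(np.diff(ods) <= 0):
            raise IhccalError("bead ladder needs 10 strictly increasing ODs")


#: Membrane-OD bands (reference-batch scale) for each intended immunoscore.
SCORE_BANDS: dict[int, tuple[float, float]] = {
    0: (0.000, 0.015),
    1: (0.090, 0.130),
    2: (0.190, 0.250),
    3: (0.400, 0.550),
}

#: Cell-score composition per intended slide-level HER2 status.
STATUS_COMPOSITIONS: dict[str, dict[int, float]] = {
    "0": {0: 1.0},
    "1+": {1: 0.9, 0: 0.1},
    "2+": {2: 0.9, 0: 0.1},
    "3+": {3: 0.9, 0: 0.1},
}


@dataclass(frozen=True)
class TissuePhantomSpec:
    """Geometry and staining statistics of a disk-phantom tissue image."""

    intended_status: str = "2+"
    shape: tuple[int, int] = (256, 256)
    n_cells: int = 40
    cell_radius: float = 10.0
    membrane_radii: tuple[float, float] = (8.0, 10.0)
    nucleus_radius: float = 4.5
    nucleus_od: float = 0.7
    score_bands: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(SCORE_BANDS)
    )
    composition: Mapping[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise IhccalError("need at least one cell")
        if self.intended_status not in STATUS_COMPOSITIONS:
            raise IhccalError(f"unknown status {self.intended_status!r}")


@dataclass(frozen=True)
class PhantomCell:
    """Ground-truth cell: position plus reference-scale membrane DAB OD."""

    row: float
    col: float
    membrane_od: float
    intended_score: int


# ---------------------------------------------------------------------------
# Scanner forward model
# ---------------------------------------------------------------------------


def simulate_scan(linear_img: ImagePatch, cfg: ScannerSimConfig) -> ImagePatch:
    """Push a standard-linear image through the scanner forward model."""
    if linear_img.encoding != "standard_linear":
        raise IhccalError("simulate_scan expects a standard_linear image")
    rng = np.random.default_rng(cfg.seed)
    dev = linear_img.pixels @ cfg.device_matrix.T
    dev = dev * cfg.incident.I0
    if cfg.noise_sd > 0:
        dev = dev + rng.normal(0.0, cfg.noise_sd, size=dev.shape)
    dev = np.clip(dev, 0.0, 1.0)
    dev = dev ** (1.0 / cfg.gamma)
    return ImagePatch(dev, "device_gamma", linear_img.pixel_size_um)


def random_device_matrix(
    rng: np.random.Generator, strength: float = 0.08, max_cond: float = 10.0
) -> np.ndarray:
    """Random white-preserving mixing matrix with bounded condition number.

    Rows are nonnegative and sum to 1 (row-stochastic): channel crosstalk in a
    real sensor is nonnegative, and a convex combination of in-range channel
    values can never exceed the sensor range, so the simulated device does not
    saturate on in-gamut input.
    """
    for _ in range(1000):
        m = np.eye(3) + strength * rng.normal(size=(3, 3))
        m = np.clip(m, 0.0, None)
        m /= m.sum(axis=1, keepdims=True)
        if np.linalg.cond(m) < max_cond:
            return m
    raise IhccalError("failed to draw a well-conditioned device matrix")


#: Two fixed scanner personalities so the full experiment design is
#: reproducible by name.
SCANNER_PRESETS: dict[str, dict] = {
    "A": {
        "device_matrix": np.array(
            [[0.92, 0.05, 0.03], [0.04, 0.93, 0.03], [0.02, 0.06, 0.92]]
        ),
        "incident": np.array([0.96, 0.99, 0.93]),
    },
    "B": {
        "device_matrix": np.array(
            [[0.88, 0.09, 0.03], [0.06, 0.90, 0.04], [0.05, 0.03, 0.92]]
        ),
        "incident": np.array([0.99, 0.95, 0.97]),
    },
}


def scanner_preset(
    name: str, gamma: float = 1.0, noise_sd: float = 0.003, seed: int = 0
) -> ScannerSimConfig:
    if name not in SCANNER_PRESETS:
        raise IhccalError(f"unknown scanner preset {name!r}")
    p = SCANNER_PRESETS[name]
    return ScannerSimConfig(
        p["device_matrix"].copy(), gamma, IncidentLight(p["incident"]), noise_sd, seed
    )


# ---------------------------------------------------------------------------
# Chart rendering
# ---------------------------------------------------------------------------


def demo_chart_spectra() -> dict[str, SpectralCurve]:
    """Synthetic transmittance spectra for a 12-patch chart plus background.

    Broad smooth bands chosen so that every reference color stays inside the
    sRGB gamut: three neutral grays (A1, B1, C1), primaries/secondaries of
    moderate saturation, and warm tissue-like tones.  The background is clear
    glass (unit transmittance).
    """
    w = WAVELENGTH_GRID

    def sigmoid(center: float, width: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(w - center) / width))

    def band(center: float, width: float) -> np.ndarray:
        return np.exp(-(((w - center) / width) ** 2))

    curves = {
        "A1": np.full_like(w, 0.80),
        "B1": np.full_like(w, 0.50),
        "C1": np.full_like(w, 0.20),
        "A2": 0.06 + 0.80 * sigmoid(605, 18),            # red
        "A3": 0.08 + 0.70 * band(545, 60),               # green
        "A4": 0.14 + 0.62 * band(468, 58),               # blue
        "B2": 0.08 + 0.80 * sigmoid(520, 25),            # yellow
        "B3": 0.08 + 0.80 * (1 - sigmoid(575, 22)),      # cyan
        "B4": np.clip(0.90 - 0.70 * band(545, 55), 0, 1),  # magenta
        "C2": 0.10 + 0.72 * sigmoid(575, 20),            # orange
        "C3": 0.18 + 0.45 * sigmoid(580, 35),            # brown / tissue tone
        "C4": np.clip(0.15 + 0.55 * band(455, 50) + 0.35 * sigmoid(640, 20), 0, 1),  # purple
        "BG": np.ones_like(w),
    }
    return {k: SpectralCurve(w, v) for k, v in curves.items()}


def reference_chart_colors(
    spectra: Mapping[str, SpectralCurve] | None = None,
) -> ChartColors:
    """Reference matrix Gr for the demo chart under D65 / CIE 1931 / sRGB."""
    spectra = spectra if spectra is not None else demo_chart_spectra()
    return compute_reference_chart(
        spectra, d65_illuminant(), cie_1931_cmf(), srgb_matrix()
    )


def default_chart_layout() -> dict[str, tuple[int, int, int, int]]:
    """Patch rectangles of the rendered chart: 3 rows x 4 columns + BG strip."""
    layout: dict[str, tuple[int, int, int, int]] = {}
    for i, letter in enumerate("ABC"):
        for j in range(4):
            layout[f"{letter}{j + 1}"] = (10 + 50 * i, 10 + 50 * j, 40, 40)
    layout["BG"] = (160, 10, 30, 190)
    return layout


CHART_SHAPE = (200, 210)


def render_color_chart(
    reference: ChartColors,
    cfg: ScannerSimConfig,
    layout: Mapping[str, tuple[int, int, int, int]] | None = None,
    shape: tuple[int, int] = CHART_SHAPE,
) -> tuple[ImagePatch, dict[str, tuple[int, int, int, int]]]:
    """Render a chart slide: patch rectangles on glass, then simulate the scan."""
    layout = dict(layout) if layout is not None else default_chart_layout()
    H, W = shape
    if H < 1 or W < 1:
        raise IhccalError("chart image must be at least 1x1")
    img = np.ones((H, W, 3)) * reference.column("BG")
    occupied = np.zeros((H, W), dtype=bool)
    for pid in PATCH_IDS:
        if pid == "BG":
            continue
        if pid not in layout:
            raise LayoutError(f"layout is missing patch {pid!r}")
        r0, c0, h, w = layout[pid]
        if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
            raise LayoutError(f"patch {pid!r} exceeds the image bounds")
        if occupied[r0 : r0 + h, c0 : c0 + w].any():
            raise LayoutError(f"patch {pid!r} overlaps another patch")
        occupied[r0 : r0 + h, c0 : c0 + w] = True
        img[r0 : r0 + h, c0 : c0 + w] = reference.column(pid)
    scan = simulate_scan(ImagePatch(img, "standard_linear"), cfg)
    return scan, layout


# ---------------------------------------------------------------------------
# Calibrator rendering
# ---------------------------------------------------------------------------

CALIBRATOR_SHAPE = (140, 320)


def default_bead_geometry(
    shape: tuple[int, int] = CALIBRATOR_SHAPE, radius: float = 12.0
) -> list[tuple[float, float, float]]:
    """Disk centers for 10 levels: 1-5 across the top row, 6-10 below."""
    H, W = shape
    rows = [H / 4.0, 3.0 * H / 4.0]
    cols = [W * (2 * j + 1) / 10.0 for j in range(5)]
    return [(r, c, radius) for r in rows for c in cols]


def render_calibrator(
    batch: StainBatchConfig,
    cfg: ScannerSimConfig,
    geometry: Sequence[tuple[float, float, float]] | None = None,
    shape: tuple[int, int] = CALIBRATOR_SHAPE,
) -> tuple[ImagePatch, list[tuple[float, float, float]], BeadPanel]:
    """Render the microbead calibrator and return its ground-truth panel."""
    geometry = list(geometry) if geometry is not None else default_bead_geometry(shape)
    if len(geometry) != 10:
        raise LayoutError("calibrator geometry must place 10 bead levels")
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W]
    od = np.zeros((H, W, 3))
    mean_rgb = np.empty((10, 3))
    mean_od = np.empty((10, 3))
    n_pixels = np.empty(10, dtype=int)
    for k, (r, c, rad) in enumerate(geometry):
        if not (0 <= r < H and 0 <= c < W and rad > 0):
            raise LayoutError(f"bead {k + 1} outside the image")
        disk = (rows - r) ** 2 + (cols - c) ** 2 <= rad ** 2
        level_od = batch.dab_scale * batch.bead_level_ods[k] * batch.dab_vector
        od[disk] = level_od
        mean_od[k] = level_od
        mean_rgb[k] = 10.0 ** (-level_od)
        n_pixels[k] = int(disk.sum())
    linear = ImagePatch(10.0 ** (-od), "standard_linear")
    scan = simulate_scan(linear, cfg)
    return scan, geometry, BeadPanel(mean_rgb, mean_od, n_pixels)


# ---------------------------------------------------------------------------
# Tissue phantom rendering
# ---------------------------------------------------------------------------


def sample_phantom_cells(spec: TissuePhantomSpec) -> list[PhantomCell]:
    """Dart-throw non-overlapping cells and sample their membrane ODs."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    R = spec.cell_radius
    margin = R + 2.0
    min_d2 = (2 * R + 2.0) ** 2
    comp = (
        dict(spec.composition)
        if spec.composition is not None
        else STATUS_COMPOSITIONS[spec.intended_status]
    )
    scores = rng.choice(
        list(comp.keys()), size=spec.n_cells, p=np.array(list(comp.values()))
    )
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < spec.n_cells:
        tries += 1
        if tries > 200 * spec.n_cells:
            raise IhccalError("could not place the requested number of cells")
        r = rng.uniform(margin, H - margin)
        c = rng.uniform(margin, W - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_d2 for pr, pc in positions):
            positions.append((r, c))
    cells = []
    for (r, c), s in zip(positions, scores):
        lo, hi = spec.score_bands[int(s)]
        cells.append(PhantomCell(r, c, float(rng.uniform(lo, hi)), int(s)))
    return cells


def render_phantom(
    cells: Sequence[PhantomCell],
    spec: TissuePhantomSpec,
    batch: StainBatchConfig,
    cfg: ScannerSimConfig,
) -> ImagePatch:
    """Render pre-sampled cells under a given batch and scanner."""
    H, W = spec.shape
    rows, cols = np.mgrid[0:H, 0:W]
    dab = np.zeros((H, W))
    hem = np.zeros((H, W))
    m_in, m_out = spec.membrane_radii
    for cell in cells:
        d2 = (rows - cell.row) ** 2 + (cols - cell.col) ** 2
        hem[d2 <= spec.nucleus_radius ** 2] = spec.nucleus_od
        ring = (d2 >= m_in ** 2) & (d2 <= m_out ** 2)
        dab[ring] = cell.membrane_od * batch.dab_scale
    od = (
        dab[..., None] * batch.dab_vector
        + hem[..., None] * batch.hematoxylin_vector
    )
    linear = ImagePatch(10.0 ** (-od), "standard_linear")
    return simulate_scan(linear, cfg)


def render_tissue(
    spec: TissuePhantomSpec, batch: StainBatchConfig, cfg: ScannerSimConfig
) -> tuple[ImagePatch, list[PhantomCell]]:
    """Sample and render a tissue phantom; returns image and ground truth."""
    cells = sample_phantom_cells(spec)
    return render_phantom(cells, spec, batch, cfg), cells


# ---------------------------------------------------------------------------
# Full experiment bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetDesign:
    scanner: str
    gamma: float
    dab_scale: float | None = None


def table_design() -> list[DatasetDesign]:
    """The 10-dataset design: two scanners crossed with gammas 1.0/1.8/2.2."""
    rows = [
        ("A", 1.0), ("A", 1.0), ("A", 1.8), ("A", 1.8), ("A", 2.2),
        ("B", 1.0), ("B", 1.0), ("B", 1.8), ("B", 2.2), ("B", 2.2),
    ]
    return [DatasetDesign(s, g) for s, g in rows]


@dataclass(frozen=True)
class Dataset:
    """One rendered dataset: chart + calibrator + four tissue phantoms."""

    name: str
    scanner_cfg: ScannerSimConfig
    batch: StainBatchConfig
    chart: ImagePatch
    chart_layout: dict
    calibrator: ImagePatch
    bead_geometry: list
    truth_panel: BeadPanel
    tissues: dict  # status -> (ImagePatch, list[PhantomCell])


@dataclass(frozen=True)
class ExperimentBundle:
    reference: Dataset
    targets: list[Dataset]
    chart_reference: ChartColors
    tissue_spec: dict  # status -> TissuePhantomSpec
    manifest: dict


def _render_dataset(
    name: str,
    cfg: ScannerSimConfig,
    batch: StainBatchConfig,
    chart_reference: ChartColors,
    case_cells: Mapping[str, Sequence[PhantomCell]],
    specs: Mapping[str, TissuePhantomSpec],
    rng: np.random.Generator,
) -> Dataset:
    def sub(c: ScannerSimConfig) -> ScannerSimConfig:
        return replace(c, seed=int(rng.integers(2 ** 31)))

    chart, layout = render_color_chart(chart_reference, sub(cfg))
    calib, geom, panel = render_calibrator(batch, sub(cfg))
    tissues = {
        status: (render_phantom(case_cells[status], specs[status], batch, sub(cfg)), list(case_cells[status]))
        for status in STATUS_COMPOSITIONS
    }
    return Dataset(name, cfg, batch, chart, layout, calib, geom, panel, tissues)


def make_experiment(
    design: Sequence[DatasetDesign] | None = None,
    seed: int = 0,
    noise_sd: float = 0.003,
    scale_range: tuple[float, float] = (0.7, 1.3),
    n_cells: int = 40,
) -> ExperimentBundle:
    """Render the reference dataset plus one target dataset per design row.

    The four tissue cases (intended HER2 0, 1+, 2+, 3+) are sampled once and
    re-rendered in every dataset — the synthetic analog of serial sections of
    the same case stained in different batches and scanned on different
    devices.  Batch DAB scales not given in the design are drawn uniformly
    from ``scale_range``.
    """
    design = list(design) if design is not None else table_design()
    if not design:
        raise IhccalError("experiment design must be nonempty")
    rng = np.random.default_rng(seed)
    chart_reference = reference_chart_colors()
    specs = {
        status: TissuePhantomSpec(
            intended_status=status, n_cells=n_cells, seed=int(rng.integers(2 ** 31))
        )
        for status in STATUS_COMPOSITIONS
    }
    case_cells = {s: sample_phantom_cells(spec) for s, spec in specs.items()}
    ref_batch = StainBatchConfig(dab_scale=1.0)
    ref_cfg = scanner_preset("A", gamma=1.0, noise_sd=noise_sd)
    reference = _render_dataset(
        "reference", ref_cfg, ref_batch, chart_reference, case_cells, specs, rng
    )
    targets = []
    for i, row in enumerate(design):
        scale = (
            row.dab_scale
            if row.dab_scale is not None
            else float(rng.uniform(*scale_range))
        )
        cfg = scanner_preset(row.scanner, gamma=row.gamma, noise_sd=noise_sd)
        batch = StainBatchConfig(dab_scale=scale)
        targets.append(
            _render_dataset(
                f"target_{i:02d}_{row.scanner}_g{row.gamma}",
                cfg,
                batch,
                chart_reference,
                case_cells,
                specs,
                rng,
            )
        )
    manifest = {
        "seed": seed,
        "n_targets": len(targets),
        "datasets": [
            {
                "name": t.name,
                "scanner": design[i].scanner,
                "gamma": design[i].gamma,
                "dab_scale": t.batch.dab_scale,
                "tissues": list(STATUS_COMPOSITIONS),
            }
            for i, t in enumerate(targets)
        ],
    }
    return ExperimentBundle(reference, targets, chart_reference, specs, manifest)
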