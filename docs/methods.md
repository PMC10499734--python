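# Methods

## Scope and assumptions

`ihccal` calibrates exported WSI *patches*, not pyramidal whole-slide files.
Images enter as H×W×3 arrays in [0, 1] with an explicit encoding tag
(`device_gamma` → `device_linear` → `standard_linear`) so that every
operation can assert where in the chain its input lives.  The working
device-independent space is linear RGB with sRGB primaries and D65 white.
Registration between scanners is out of scope: dE* maps require the caller
to supply pixel-aligned images (synthetic fixtures are aligned by
construction).

## Colorimetry

Reference chart colors are computed by discrete summation over the
340–830 nm / 5 nm grid (99 samples) that chart calibration data uses, with
normalization k = 1/Σ S·ȳ so that a fully transmissive sample has Y = 1
exactly.  Conversions return unclipped values; clipping to [0, 1] happens
only at image export, because the fitting steps need unclipped residuals.

Two tabulation choices are the package's own:

* The CIE 1931 2° color-matching functions are evaluated from the published
  multi-lobe piecewise-Gaussian analytic fit (Wyman, Sloan & Shirley 2013),
  clipped at zero.  Accuracy is ~1% of peak per lobe, which is immaterial
  here because reference and scanned chart colors are produced by the same
  functions — the calibration problem is self-consistent.
* The D65 illuminant is a 6504 K Planckian base plus a small correction in
  the span of the CMFs, solved in closed form so that unit transmittance
  integrates *exactly* to the sRGB D65 white point.  This guarantees the
  clear-glass background column of a reference chart is exactly (1, 1, 1),
  which the white-preserving regression and the incident-light normalization
  both assume.  The correction stays nonnegative on the grid.

The sRGB matrix is derived from the primary/white chromaticities rather than
copied, and agrees with the published 4-decimal matrix to 5e-4.  dE* is
CIE76 (plain Euclidean distance in L\*a\*b\*), not CIEDE2000.

## Scanner calibration

Order of operations is fixed: incident normalization → gamma linearization →
polynomial color correction.

* **Incident light** defaults to the mean of the chart's background (glass)
  region; for images without a designated glass region a robust estimate
  (mean of the brightest-percentile pixels) is provided.
* **Gamma** is fitted jointly on the luminances of the neutral patches
  (A1, B1, C1, background) by bounded scalar minimization of
  Σ (Y_s^γ − Y_r)² on γ ∈ [0.2, 5.0] (initializer irrelevant for a bounded
  scalar method; the residual is recorded).  Patches with saturated scanned
  luminance (Y ≤ 0 or ≥ 1, with 1e-6 tolerance) are excluded — this always
  removes the background, whose normalized luminance is identically 1 and
  carries no gamma information.
* **WPPLS** uses the 5-term basis (R, G, B, R·G·B, 1) — the basis the
  5th-order polynomial transform enumerates — and enforces M{u} = u through
  the KKT system of the equality-constrained least-squares problem, so white
  preservation holds to machine precision regardless of noise, not merely as
  a penalty.  Tests cross-check the solution against an independent
  null-space-elimination solver.
* **Patch sampling** averages the central 50% (per side) of each layout
  rectangle, configurable.

## Staining calibration

Optical density uses log base 10 with values floored at 1/65536 (one 16-bit
step) before the logarithm.  The DAB direction is the unit mean of per-level
OD directions over the *lightly stained* bead levels (OD norm in (0.02, 0.6),
configurable): darkly stained DAB scatters and departs from Beer–Lambert, so
the dark levels are deliberately ignored.  The hematoxylin direction cannot
be observed on a DAB-only calibrator; the Ruifrok–Johnston direction
(0.650, 0.704, 0.286) is the default and is overridable.  The third
(residual) basis vector is the normalized cross product of the two stains.

The intensity transfer map pairs level k of the target panel with level k of
the reference panel (each projected on its own DAB direction), prepends
(0, 0), repairs non-monotone noisy ladders by isotonic regression, and
interpolates piecewise-linearly with the last segment's slope continued
beyond the final knot — the dark regime is unreliable anyway, and working
thresholds sit around 0.03–0.29 OD, well inside the knot range.  Method 1
inverts this map at the reference thresholds (flat segments: midpoint of the
preimage, with a warning); method 2 maps the unmixed DAB channel per pixel
and recomposes with the reference stain vectors.  Hematoxylin is never
rescaled by method 2, matching the protocol's behavior when only the
calibrator is available.

## Scoring

Thresholds are lower-inclusive for the higher score (a cell exactly at t2
scores 2).  Cells without detected nuclei would still be scored; the phantom
detector always finds nuclei, but the CSV input path carries the flag.  The
status rule is the percentage reduction of the ASCO/CAP logic with strict
">" cutoffs (3+ if P3 > 10, else 2+ if P2+P3 > 10, else 1+ if P1+P2+P3 > 10,
else 0) and is configurable, because membrane-completeness criteria are not
computable from mean OD alone.  Reference thresholds are derived by
exhaustive search over ordered triples of a 0.01–0.60 / 0.01 OD grid
(≤ C(60,3) ≈ 34k triples — deterministic and fast), maximizing case-level
status concordance, ties broken by the lexicographically smallest triple.

## Synthetic data: what it emulates, and what it does not

The forward model is: white-preserving device mixing matrix → per-channel
incident scaling → additive Gaussian noise (sd 0.003 by default) → clip →
display-gamma encoding.  Device matrices are *row-stochastic* (nonnegative
entries, rows summing to 1): sensor crosstalk is nonnegative, and a convex
combination of in-range values cannot saturate, keeping the simulation
inside the regime the linear correction can invert.  Two fixed scanner
personalities (A, B) plus gammas {1.0, 1.8, 2.2} reproduce the 10-dataset
two-scanner experiment design by name; staining batches vary by a
multiplicative DAB OD scale drawn from [0.7, 1.3].

Tissue phantoms are non-overlapping disk cells (radius 10 px, hematoxylin
nucleus of radius 4.5 px at OD 0.7, DAB membrane annulus 8–10 px) placed by
dart throwing on 256×256 patches with 40 cells.  Membrane ODs are drawn from
per-score bands (0: 0–0.015, 1: 0.09–0.13, 2: 0.19–0.25, 3: 0.40–0.55 OD)
and each intended slide-level status mixes 90% cells of the matching score
with 10% negative cells.  The bead ladder is a geometric ramp over
0.02–1.2 OD.  The same sampled cells are re-rendered in every target dataset
— the analog of serial sections of one case — so across-dataset H-score
spread measures calibration, not phantom resampling.  Problem sizes (chart
200×210, calibrator 140×320, tissue 256×256, 10 datasets) were chosen so the
whole experiment renders and scores in seconds while every region still
contains hundreds of pixels.

Not modeled: optical blur / focus differences between bead sizes, spatial
illumination gradients, Beer–Lambert violation of dark DAB, chromatic
adaptation to non-D65 sources, and inter-scanner geometric distortion.
Passing tests therefore demonstrate correctness of the *calibration
mathematics* under the stated forward model, not robustness to these
real-slide effects.

The cell detector is a nucleus-blob + fixed-radius membrane-ring measurement
matched to the phantom geometry (ring radii 8.4–9.6 px, strictly interior to
the rendered membrane so the mean is unbiased).  It replaces interactive
pathology software, whose segmentation internals are out of scope; real
per-cell measurements can be supplied as CSV instead.

## Numerical conventions

* Gamma fit: bounded Brent minimization, xatol 1e-7.
* WPPLS: rank check on the 5×5 Gram matrix (tol 1e-10) before solving;
  degenerate charts raise.
* Unmixing: per-pixel 3×3 solve via the stain-matrix inverse; stain
  channels clipped at 0; condition number > 1e6 raises.
* Transfer map: tied knot abscissae after isotonic repair are merged;
  map(0) = 0 always.
* dE* histograms use 64 bins over the masked value range.
* All renderers accept a seed and are bitwise reproducible; reports are
  written with sorted keys and 4-decimal floats so identical runs produce
  identical bytes.
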