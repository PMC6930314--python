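"""Pre-processing chain for multi-scan Raman spectra.

Implements the standard serum-Raman conditioning sequence: wavenumber
calibration against a toluene reference, background (water/cuvette)
subtraction, cosmic-ray rejection, variance-based scan culling, scan and
measurement averaging, cubic-spline baseline correction through fixed anchor
wavenumbers, and vector normalization.

The processing state of every :class:`Spectrum` is tracked with flags
(calibrated / background-corrected / baseline-corrected / normalized) and the
chain order is enforced: calling a step out of order raises
:class:`ChainOrderError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, peak_prominences

__all__ = [
    "ChainOrderError",
    "ScanBlock",
    "Spectrum",
    "CalibrationModel",
    "BaselineSpec",
    "detect_reference_peaks",
    "fit_calibration",
    "apply_calibration",
    "remove_cosmic_rays",
    "cull_scans",
    "average_scans",
    "average_measurements",
    "subtract_background",
    "correct_baseline",
    "normalize",
]

N_BASELINE_ANCHORS = 12


class ChainOrderError(ValueError):
    """A pre-processing step was invoked out of chain order."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ScanBlock:
    """Repeated scans of one acquisition on a common axis.

    Parameters
    ----------
    axis
        Strictly increasing pixel indices or wavenumbers (cm^-1).
    intensities
        Array of shape ``(n_points, n_scans)``.
    axis_kind
        ``"pixel"`` before calibration, ``"wavenumber"`` after.
    """

    axis: np.ndarray
    intensities: np.ndarray
    axis_kind: str = "pixel"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1:
            raise ValueError("axis must be one-dimensional")
        if self.intensities.ndim == 1:
            self.intensities = self.intensities[:, None]
        if self.intensities.ndim != 2:
            raise ValueError("intensities must have shape (n_points, n_scans)")
        if self.intensities.shape[0] != self.axis.size:
            raise ValueError(
                f"axis has {self.axis.size} points but intensities have "
                f"{self.intensities.shape[0]} rows"
            )
        if self.intensities.shape[1] < 1:
            raise ValueError("a ScanBlock needs at least one scan")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.axis_kind not in ("pixel", "wavenumber"):
            raise ValueError("axis_kind must be 'pixel' or 'wavenumber'")

    @property
    def n_points(self) -> int:
        return self.axis.size

    @property
    def n_scans(self) -> int:
        return self.intensities.shape[1]


@dataclass
class Spectrum:
    """A single intensity vector on an explicit wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    calibrated: bool = False
    background_corrected: bool = False
    baseline_corrected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError("wavenumbers and intensities differ in length")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def state(self) -> dict:
        return {
            "calibrated": self.calibrated,
            "background_corrected": self.background_corrected,
            "baseline_corrected": self.baseline_corrected,
            "normalized": self.normalized,
        }


@dataclass
class CalibrationModel:
    """Polynomial pixel -> wavenumber (cm^-1) map fit to reference bands."""

    coefficients: np.ndarray  # ascending powers
    degree: int
    residuals: np.ndarray  # cm^-1, one per reference band

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)

    def __call__(self, pixels) -> np.ndarray:
        return npoly.polyval(np.asarray(pixels, dtype=float), self.coefficients)


@dataclass(frozen=True)
class BaselineSpec:
    """The fixed set of 12 anchor wavenumbers used for every spline baseline.

    Using one identical anchor set for every sample in a run keeps the
    baseline estimate objective (no per-sample anchor tuning).
    """

    anchor_wavenumbers: tuple

    def __post_init__(self) -> None:
        anchors = tuple(float(a) for a in self.anchor_wavenumbers)
        object.__setattr__(self, "anchor_wavenumbers", anchors)
        if len(anchors) != N_BASELINE_ANCHORS:
            raise ValueError(
                f"exactly {N_BASELINE_ANCHORS} anchor wavenumbers are required, "
                f"got {len(anchors)}"
            )
        if not all(b > a for a, b in zip(anchors, anchors[1:])):
            raise ValueError("anchor wavenumbers must be strictly increasing")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def detect_reference_peaks(block: ScanBlock, n_expected: int) -> np.ndarray:
    """Locate the ``n_expected`` most prominent peaks of a reference spectrum.

    The scans are averaged, local maxima are ranked by prominence, and each
    apex is refined to sub-pixel precision with a three-point parabolic fit.

    Returns
    -------
    numpy.ndarray
        Apex positions in axis units, ascending.
    """
    if block.axis_kind != "pixel":
        raise ChainOrderError("reference peak detection expects a pixel-axis block")
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    profile = block.intensities.mean(axis=1)
    idx, _ = find_peaks(profile)
    if idx.size < n_expected:
        raise ValueError(
            f"found {idx.size} local maxima but {n_expected} were expected"
        )
    prom = peak_prominences(profile, idx)[0]
    top = idx[np.argsort(prom)[::-1][:n_expected]]
    top.sort()
    step = float(np.median(np.diff(block.axis)))
    apexes = []
    for i in top:
        y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
        denom = y0 - 2.0 * y1 + y2
        offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        apexes.append(block.axis[i] + offset * step)
    return np.asarray(apexes)


def fit_calibration(apex_pixels, reference_bands, degree: int = 2) -> CalibrationModel:
    """Fit a least-squares polynomial pixel -> cm^-1 map to reference bands."""
    pixels = np.asarray(apex_pixels, dtype=float)
    bands = np.asarray(reference_bands, dtype=float)
    if pixels.size != bands.size:
        raise ValueError(
            f"{pixels.size} apex pixels but {bands.size} reference bands"
        )
    if pixels.size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} points for a degree-{degree} fit, "
            f"got {pixels.size}"
        )
    if not np.all(np.diff(pixels) > 0) or not np.all(np.diff(bands) > 0):
        raise ValueError("apex pixels and reference bands must both be ascending")
    coeffs = npoly.polyfit(pixels, bands, degree)
    fitted = npoly.polyval(pixels, coeffs)
    residuals = bands - fitted
    dense = np.linspace(pixels[0], pixels[-1], 2048)
    if not np.all(np.diff(npoly.polyval(dense, coeffs)) > 0):
        raise ValueError("fitted calibration map is not strictly increasing")
    return CalibrationModel(coefficients=coeffs, degree=degree, residuals=residuals)


def apply_calibration(
    block: ScanBlock,
    model: CalibrationModel,
    grid_start: float,
    grid_stop: float,
    grid_step: float = 1.0,
) -> ScanBlock:
    """Map a pixel-axis block onto a common uniform wavenumber grid.

    Each scan is linearly interpolated onto ``grid_start..grid_stop`` with
    spacing ``grid_step`` (cm^-1).
    """
    if block.axis_kind != "pixel":
        raise ChainOrderError("block is already on a wavenumber axis")
    mapped = model(block.axis)
    if not np.all(np.diff(mapped) > 0):
        raise ValueError("calibration map is not strictly increasing on this block")
    grid = np.arange(grid_start, grid_stop + 0.5 * grid_step, grid_step)
    tol = 1e-9 * (mapped[-1] - mapped[0])  # absorb float residue of the fit
    if grid[0] < mapped[0] - tol or grid[-1] > mapped[-1] + tol:
        raise ValueError(
            f"target grid [{grid[0]:.1f}, {grid[-1]:.1f}] cm^-1 exceeds the "
            f"mapped span [{mapped[0]:.1f}, {mapped[-1]:.1f}] cm^-1"
        )
    out = np.empty((grid.size, block.n_scans))
    for j in range(block.n_scans):
        out[:, j] = np.interp(grid, mapped, block.intensities[:, j])
    return ScanBlock(axis=grid, intensities=out, axis_kind="wavenumber")


# ---------------------------------------------------------------------------
# Scan-level artifact handling and averaging
# ---------------------------------------------------------------------------

def remove_cosmic_rays(block: ScanBlock, threshold_mads: float = 8.0):
    """Flag and repair cosmic-ray spikes by cross-scan median/MAD comparison.

    For each grid point the median and the median absolute deviation (MAD)
    are computed across scans; a value deviating from the median by more than
    ``threshold_mads`` robust standard deviations (1.4826 x MAD, the
    normal-consistent scale estimate) is replaced by the cross-scan median.
    At 14 scans and threshold 8 this keeps the false-positive rate on clean
    Gaussian data below 0.1% while spikes tens of times the signal are
    detected essentially always.

    A spike hitting the same point in every scan contaminates the median and
    is not detected — a documented limitation of cross-scan despiking.

    Returns
    -------
    (ScanBlock, numpy.ndarray)
        The repaired block and a boolean flag array of shape
        ``(n_points, n_scans)``.
    """
    if block.n_scans < 3:
        raise ValueError(
            "cross-scan despiking needs at least 3 scans; "
            "single-scan despiking is unsupported"
        )
    data = block.intensities
    med = np.median(data, axis=1, keepdims=True)
    dev = np.abs(data - med)
    mad = np.median(dev, axis=1, keepdims=True)
    flags = dev > threshold_mads * 1.4826 * mad
    repaired = np.where(flags, med, data)
    return (
        ScanBlock(axis=block.axis.copy(), intensities=repaired, axis_kind=block.axis_kind),
        flags,
    )


def cull_scans(block: ScanBlock, keep: int = 10) -> ScanBlock:
    """Drop the highest-variance scans, keeping ``keep`` of them.

    Each scan is scored by its summed squared deviation from the cross-scan
    mean spectrum; the highest-scoring scans are removed. Ties are broken by
    keeping the earlier scan. Kept scans are returned unmodified, in their
    original order.
    """
    if keep < 1:
        raise ValueError("keep must be >= 1")
    if keep > block.n_scans:
        raise ValueError(f"cannot keep {keep} of {block.n_scans} scans")
    mean = block.intensities.mean(axis=1, keepdims=True)
    scores = ((block.intensities - mean) ** 2).sum(axis=0)
    # remove highest scores first; among equal scores remove the later scan
    order = sorted(range(block.n_scans), key=lambda i: (-scores[i], -i))
    dropped = set(order[: block.n_scans - keep])
    kept = [i for i in range(block.n_scans) if i not in dropped]
    return ScanBlock(
        axis=block.axis.copy(),
        intensities=block.intensities[:, kept],
        axis_kind=block.axis_kind,
    )


def average_scans(block: ScanBlock) -> Spectrum:
    """Pointwise mean across scans; yields one spectrum per measurement."""
    if block.axis_kind != "wavenumber":
        raise ChainOrderError("average_scans expects a calibrated (wavenumber) block")
    return Spectrum(
        wavenumbers=block.axis.copy(),
        intensities=block.intensities.mean(axis=1),
        calibrated=True,
    )


def average_measurements(spectra) -> Spectrum:
    """Pointwise mean of same-subject measurement spectra.

    All spectra must share the grid and the processing state.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavenumbers, ref.wavenumbers):
            raise ValueError("spectra are on different wavenumber grids")
        if s.state != ref.state:
            raise ValueError(f"processing states differ: {s.state} vs {ref.state}")
    stack = np.stack([s.intensities for s in spectra], axis=1)
    return replace(ref, wavenumbers=ref.wavenumbers.copy(), intensities=stack.mean(axis=1))


# ---------------------------------------------------------------------------
# Spectrum-level corrections
# ---------------------------------------------------------------------------

def subtract_background(serum: Spectrum, water_mean: Spectrum) -> Spectrum:
    """Subtract the averaged water/cuvette spectrum from a serum spectrum.

    Negative values are permitted in the result; the BG flag is set.
    """
    if not (serum.calibrated and water_mean.calibrated):
        raise ChainOrderError("both spectra must be calibrated before BG subtraction")
    if serum.background_corrected:
        raise ChainOrderError("spectrum is already background-corrected")
    if not np.array_equal(serum.wavenumbers, water_mean.wavenumbers):
        raise ValueError("serum and water spectra are on different grids")
    return replace(
        serum,
        wavenumbers=serum.wavenumbers.copy(),
        intensities=serum.intensities - water_mean.intensities,
        background_corrected=True,
    )


def correct_baseline(spectrum: Spectrum, anchors: BaselineSpec):
    """Remove autofluorescence with a cubic-spline baseline.

    A not-a-knot cubic spline is interpolated through the spectrum's values
    at the 12 anchor wavenumbers, evaluated on the full grid and subtracted.
    Because a not-a-knot spline reproduces cubic polynomials exactly, a
    spectrum that *is* a cubic is flattened to zero.

    Returns
    -------
    (Spectrum, Spectrum)
        The baseline-corrected spectrum and the estimated baseline.
    """
    if not spectrum.background_corrected:
        raise ChainOrderError("baseline correction requires a BG-corrected spectrum")
    if spectrum.baseline_corrected:
        raise ChainOrderError("spectrum is already baseline-corrected")
    w = spectrum.wavenumbers
    pts = np.asarray(anchors.anchor_wavenumbers)
    if pts[0] < w[0] or pts[-1] > w[-1]:
        raise ValueError(
            f"anchor wavenumbers must lie inside the spectrum span "
            f"[{w[0]:.1f}, {w[-1]:.1f}] cm^-1"
        )
    values = np.interp(pts, w, spectrum.intensities)
    spline = CubicSpline(pts, values, bc_type="not-a-knot")
    baseline_vals = spline(w)
    corrected = replace(
        spectrum,
        wavenumbers=w.copy(),
        intensities=spectrum.intensities - baseline_vals,
        baseline_corrected=True,
    )
    baseline = Spectrum(
        wavenumbers=w.copy(),
        intensities=baseline_vals,
        calibrated=spectrum.calibrated,
        background_corrected=spectrum.background_corrected,
    )
    return corrected, baseline


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale the intensity vector to unit Euclidean norm (idempotent)."""
    if not spectrum.baseline_corrected:
        raise ChainOrderError("vector normalization requires a BC spectrum")
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise ValueError("cannot normalize a zero spectrum")
    return replace(
        spectrum,
        wavenumbers=spectrum.wavenumbers.copy(),
        intensities=spectrum.intensities / norm,
        normalized=True,
    )
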