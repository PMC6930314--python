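"""Synthetic Raman measurement sessions with known ground truth.

Emulates a serum-diagnostics measurement campaign on a dispersive Raman
instrument: a toluene acquisition for wavenumber calibration, a distilled
water acquisition (broad ~1640 cm^-1 band plus a smooth cuvette
contribution) for background subtraction, and per-subject serum sessions
(two measurements of 14 scans each by default). Serum spectra are sums of
Lorentzian bands at 1005, 1156, 1239, 1450, 1520 and 1650 cm^-1, a smooth
4th-order fluorescence baseline, the water/cuvette background, Gaussian
detector noise and Poisson-distributed cosmic-ray spikes. The disease
effect is an attenuation of the carotenoid (beta-carotene) bands at
1156 and 1520 cm^-1 in the patient group.

Everything injected — calibration map, spike coordinates, contaminated
scans, per-subject band amplitudes, the fluorescence baseline — is recorded
in a :class:`GroundTruth` so each downstream stage has a parameter-recovery
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .preprocess import ScanBlock

__all__ = [
    "DEFAULT_TOLUENE_BANDS",
    "InstrumentSpec",
    "SerumModel",
    "SpikeRecord",
    "GroundTruth",
    "lorentzian",
    "simulate_toluene",
    "simulate_water",
    "simulate_cohort",
]

#: Literature positions of strong toluene reference bands (cm^-1).
DEFAULT_TOLUENE_BANDS = (521.7, 785.5, 1003.6, 1030.6, 1211.4, 1605.1)


def lorentzian(x, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Lorentzian line with apex ``amplitude`` at ``center`` and the given FWHM."""
    hw = 0.5 * fwhm
    x = np.asarray(x, dtype=float)
    return amplitude * hw * hw / ((x - center) ** 2 + hw * hw)


@dataclass(frozen=True)
class InstrumentSpec:
    """Idealized CCD spectrometer: a polynomial pixel->cm^-1 map plus noise.

    Parameters
    ----------
    n_pixels
        Detector width.
    true_calib_coeffs
        Ascending-power polynomial coefficients of the true pixel->cm^-1 map;
        must be strictly increasing over the pixel range.
    noise_sd
        Per-point Gaussian noise standard deviation (intensity units).
    cosmic_ray_rate
        Expected spike count per scan (Poisson mean).
    cosmic_ray_amplitude
        Spike amplitude as a multiple of the tallest serum band.
    """

    n_pixels: int = 1024
    true_calib_coeffs: tuple = (400.0, 1.45, -5.0e-5)
    noise_sd: float = 0.01
    cosmic_ray_rate: float = 0.1
    cosmic_ray_amplitude: float = 30.0

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cosmic_ray_rate < 0:
            raise ValueError("cosmic_ray_rate must be >= 0")
        if not np.all(np.diff(self.wavenumbers()) > 0):
            raise ValueError(
                "true pixel->wavenumber map must be strictly increasing "
                "over the pixel range"
            )

    def pixel_grid(self) -> np.ndarray:
        return np.arange(self.n_pixels, dtype=float)

    def wavenumbers(self) -> np.ndarray:
        """True wavenumber of each pixel center."""
        return npoly.polyval(self.pixel_grid(), np.asarray(self.true_calib_coeffs))

    def span(self):
        w = self.wavenumbers()
        return float(w[0]), float(w[-1])


@dataclass(frozen=True)
class SerumModel:
    """Parametric serum spectrum: Lorentzian bands over a fluorescence baseline.

    ``patient_attenuation`` scales the carotenoid-band amplitudes by
    ``(1 - patient_attenuation)`` in the patient group, emulating reduced
    beta-carotene. ``subject_sd`` is the sigma of a log-normal multiplicative
    factor drawn per subject and band, giving realistic between-subject
    amplitude variability. The baseline is a 4th-order polynomial in the
    scaled coordinate ``t = (w - w_lo) / (w_hi - w_lo)``; the default is
    positive and slowly decaying across the span, smooth enough for a
    12-anchor cubic spline to capture.
    """

    band_centers: tuple = (1005.0, 1156.0, 1239.0, 1450.0, 1520.0, 1650.0)
    band_fwhm: float = 10.0
    band_amplitudes: tuple = (1.0, 0.7, 0.5, 0.8, 0.6, 0.9)
    carotenoid_bands: tuple = (1156.0, 1520.0)
    patient_attenuation: float = 0.3
    baseline_coeffs: tuple = (5.0, -4.0, 1.5, -0.8, 0.3)
    subject_sd: float = 0.15

    def __post_init__(self) -> None:
        if len(self.band_centers) != len(self.band_amplitudes):
            raise ValueError("band_centers and band_amplitudes differ in length")
        if self.band_fwhm <= 0:
            raise ValueError("band widths must be > 0")
        if not 0.0 <= self.patient_attenuation <= 1.0:
            raise ValueError("patient_attenuation must lie in [0, 1]")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        missing = set(self.carotenoid_bands) - set(self.band_centers)
        if missing:
            raise ValueError(f"carotenoid bands {sorted(missing)} not in band_centers")

    def carotenoid_mask(self) -> np.ndarray:
        return np.asarray(
            [c in self.carotenoid_bands for c in self.band_centers], dtype=bool
        )

    def baseline(self, wavenumbers, span) -> np.ndarray:
        lo, hi = span
        t = (np.asarray(wavenumbers, dtype=float) - lo) / (hi - lo)
        return npoly.polyval(t, np.asarray(self.baseline_coeffs))

    def bands(self, wavenumbers, amplitudes=None) -> np.ndarray:
        amps = self.band_amplitudes if amplitudes is None else amplitudes
        w = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(w)
        for center, amp in zip(self.band_centers, amps):
            out += lorentzian(w, center, self.band_fwhm, amp)
        return out


@dataclass(frozen=True)
class SpikeRecord:
    """Apex coordinate of one injected cosmic-ray spike."""

    subject_id: str
    measurement: int
    scan: int
    pixel: int
    amplitude: float


@dataclass
class GroundTruth:
    """Everything injected by the simulator, for parameter-recovery tests."""

    labels: dict
    true_calib_coeffs: tuple
    spikes: list
    contaminated_scans: dict  # (subject_id, measurement) -> tuple of scan indices
    band_amplitude_factors: dict  # subject_id -> per-band multiplicative factor
    fluorescence_baseline: np.ndarray  # on the instrument pixel grid
    n_pixels: int = 0
    scans_per_measurement: int = 0

    def __post_init__(self) -> None:
        bad = set(self.labels.values()) - {"patient", "control"}
        if bad:
            raise ValueError(f"labels must be 'patient' or 'control', got {sorted(bad)}")
        for s in self.spikes:
            if not (0 <= s.pixel < self.n_pixels):
                raise ValueError(f"spike pixel {s.pixel} outside the detector")
            if not (0 <= s.scan < self.scans_per_measurement):
                raise ValueError(f"spike scan {s.scan} outside the scan grid")

    def to_json_dict(self) -> dict:
        return {
            "labels": dict(self.labels),
            "true_calib_coeffs": list(self.true_calib_coeffs),
            "spikes": [
                {
                    "subject_id": s.subject_id,
                    "measurement": s.measurement,
                    "scan": s.scan,
                    "pixel": s.pixel,
                    "amplitude": s.amplitude,
                }
                for s in self.spikes
            ],
            "contaminated_scans": {
                f"{sid}/{m}": list(scans)
                for (sid, m), scans in self.contaminated_scans.items()
            },
            "band_amplitude_factors": {
                sid: list(map(float, f)) for sid, f in self.band_amplitude_factors.items()
            },
            "fluorescence_baseline": list(map(float, self.fluorescence_baseline)),
            "n_pixels": self.n_pixels,
            "scans_per_measurement": self.scans_per_measurement,
        }


# ---------------------------------------------------------------------------
# Reference acquisitions
# ---------------------------------------------------------------------------

def _check_bands_in_span(bands, span) -> None:
    lo, hi = span
    for b in bands:
        if not lo <= b <= hi:
            raise ValueError(
                f"reference band {b:.1f} cm^-1 lies outside the instrument "
                f"span [{lo:.1f}, {hi:.1f}] cm^-1"
            )


def simulate_toluene(
    instrument: InstrumentSpec,
    reference_bands=DEFAULT_TOLUENE_BANDS,
    n_scans: int = 1,
    seed: int = 0,
) -> ScanBlock:
    """Short-exposure toluene acquisition for wavenumber calibration.

    Lorentzian peaks (10 cm^-1 FWHM, unit amplitude) are placed at the
    reference bands; the true calibration maps them onto the pixel grid.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    _check_bands_in_span(reference_bands, instrument.span())
    w = instrument.wavenumbers()
    template = np.zeros_like(w)
    for b in reference_bands:
        template += lorentzian(w, b, 10.0, 1.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, instrument.noise_sd, size=(instrument.n_pixels, n_scans))
    return ScanBlock(
        axis=instrument.pixel_grid(),
        intensities=template[:, None] + noise,
        axis_kind="pixel",
    )


def water_template(instrument: InstrumentSpec) -> np.ndarray:
    """Noiseless water/cuvette background on the instrument pixel grid."""
    w = instrument.wavenumbers()
    lo, hi = instrument.span()
    t = (w - lo) / (hi - lo)
    return lorentzian(w, 1640.0, 200.0, 0.5) + 0.2 + 0.05 * t


def simulate_water(instrument: InstrumentSpec, n_scans: int = 14, seed: int = 0) -> ScanBlock:
    """Distilled-water acquisition: broad featureless background, no serum bands."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    template = water_template(instrument)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, instrument.noise_sd, size=(instrument.n_pixels, n_scans))
    return ScanBlock(
        axis=instrument.pixel_grid(),
        intensities=template[:, None] + noise,
        axis_kind="pixel",
    )


# ---------------------------------------------------------------------------
# Cohort sessions
# ---------------------------------------------------------------------------

def simulate_cohort(
    instrument: InstrumentSpec,
    serum: SerumModel,
    n_patients: int,
    n_controls: int,
    scans_per_measurement: int = 14,
    measurements_per_subject: int = 2,
    noisy_scans_per_block: int = 0,
    noisy_scan_factor: float = 10.0,
    seed: int = 0,
):
    """Generate per-subject serum measurement sessions plus ground truth.

    Each subject receives ``measurements_per_subject`` ScanBlocks of
    ``scans_per_measurement`` scans. Patients' carotenoid bands are scaled by
    ``(1 - patient_attenuation)``. Per scan, a Poisson(``cosmic_ray_rate``)
    number of cosmic-ray spikes is injected (width 1-2 pixels, amplitude
    ``cosmic_ray_amplitude`` x tallest band, jittered +-20%) and the apex
    coordinates are recorded. Optionally ``noisy_scans_per_block`` scans per
    block carry ``noisy_scan_factor`` x the nominal noise, emulating the
    high-variance scans that the culling step should discard.

    Returns
    -------
    (dict, GroundTruth)
        ``sessions[subject_id]`` is the list of measurement ScanBlocks.
    """
    if n_patients + n_controls < 1:
        raise ValueError("the cohort must contain at least one subject")
    if min(n_patients, n_controls) < 0:
        raise ValueError("subject counts must be >= 0")
    if scans_per_measurement < 1 or measurements_per_subject < 1:
        raise ValueError("scan and measurement counts must be >= 1")
    if noisy_scans_per_block > scans_per_measurement:
        raise ValueError("noisy_scans_per_block exceeds scans_per_measurement")
    lo, hi = instrument.span()
    for c in serum.band_centers:
        if not lo <= c <= hi:
            raise ValueError(
                f"serum band {c:.1f} cm^-1 outside instrument span "
                f"[{lo:.1f}, {hi:.1f}] cm^-1"
            )

    rng = np.random.default_rng(seed)
    w = instrument.wavenumbers()
    baseline = serum.baseline(w, (lo, hi))
    water = water_template(instrument)
    caro = serum.carotenoid_mask()
    base_amps = np.asarray(serum.band_amplitudes, dtype=float)
    max_band = float(base_amps.max())

    subjects = [("P%03d" % (i + 1), "patient") for i in range(n_patients)]
    subjects += [("C%03d" % (i + 1), "control") for i in range(n_controls)]

    sessions = {}
    labels = {}
    spikes = []
    contaminated = {}
    factors = {}

    for sid, label in subjects:
        labels[sid] = label
        f = rng.lognormal(mean=0.0, sigma=serum.subject_sd, size=base_amps.size)
        factors[sid] = f
        amps = base_amps * f
        if label == "patient":
            amps = np.where(caro, amps * (1.0 - serum.patient_attenuation), amps)
        clean = serum.bands(w, amps) + baseline + water
        blocks = []
        for m in range(measurements_per_subject):
            scan_sd = np.full(scans_per_measurement, instrument.noise_sd)
            if noisy_scans_per_block > 0:
                noisy = rng.choice(
                    scans_per_measurement, size=noisy_scans_per_block, replace=False
                )
                noisy = tuple(sorted(int(i) for i in noisy))
                scan_sd[list(noisy)] *= noisy_scan_factor
                contaminated[(sid, m)] = noisy
            else:
                contaminated[(sid, m)] = ()
            data = clean[:, None] + rng.normal(
                0.0, 1.0, size=(instrument.n_pixels, scans_per_measurement)
            ) * scan_sd[None, :]
            for scan in range(scans_per_measurement):
                for _ in range(rng.poisson(instrument.cosmic_ray_rate)):
                    pixel = int(rng.integers(0, instrument.n_pixels))
                    amp = (
                        instrument.cosmic_ray_amplitude
                        * max_band
                        * rng.uniform(0.8, 1.2)
                    )
                    data[pixel, scan] += amp
                    if rng.random() < 0.5 and pixel + 1 < instrument.n_pixels:
                        data[pixel + 1, scan] += 0.5 * amp
                    spikes.append(
                        SpikeRecord(
                            subject_id=sid,
                            measurement=m,
                            scan=scan,
                            pixel=pixel,
                            amplitude=amp,
                        )
                    )
            blocks.append(
                ScanBlock(axis=instrument.pixel_grid(), intensities=data, axis_kind="pixel")
            )
        sessions[sid] = blocks

    truth = GroundTruth(
        labels=labels,
        true_calib_coeffs=tuple(instrument.true_calib_coeffs),
        spikes=spikes,
        contaminated_scans=contaminated,
        band_amplitude_factors=factors,
        fluorescence_baseline=baseline,
        n_pixels=instrument.n_pixels,
        scans_per_measurement=scans_per_measurement,
    )
    return sessions, truth
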