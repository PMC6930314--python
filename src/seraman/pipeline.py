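"""Configuration, file I/O and end-to-end orchestration.

``run_pipeline`` executes the whole chain — session simulation (or loading),
toluene calibration, water-background preparation, per-subject
pre-processing, cross-validated region selection, the 85/15 split, PCA
feature extraction and classifier evaluation — and returns a
machine-readable :class:`RunReport`.

All file formats are plain text: CSV for spectra, labels and tables, JSON
for the report and ground truth, YAML or JSON for configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify, features, preprocess, simulate
from .classify import FAMILIES, MetricsReport, ModelSpec
from .features import CohortDataset, Region
from .preprocess import BaselineSpec, ScanBlock, Spectrum

__all__ = [
    "DEFAULT_ANCHORS",
    "RunConfig",
    "RunReport",
    "read_scans",
    "write_scans",
    "read_spectrum",
    "write_spectrum",
    "read_labels",
    "write_labels",
    "simulate_session_dir",
    "load_session_dir",
    "build_cohort_dataset",
    "run_pipeline",
]

logger = logging.getLogger("seraman")

#: Default spline anchors (cm^-1): 12 points in the band-free zones of the
#: simulated serum model, spanning the 450-1729 cm^-1 processing grid.
DEFAULT_ANCHORS = (
    455.0, 600.0, 700.0, 800.0, 900.0, 960.0,
    1080.0, 1310.0, 1400.0, 1580.0, 1700.0, 1725.0,
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full run configuration; round-trips losslessly through YAML/JSON."""

    # cohort simulation (ignored when input_dir is set)
    n_patients: int = 49
    n_controls: int = 45
    scans_per_measurement: int = 14
    measurements_per_subject: int = 2
    patient_attenuation: float = 0.3
    subject_sd: float = 0.15
    noise_sd: float = 0.01
    cosmic_ray_rate: float = 0.1
    cosmic_ray_amplitude: float = 30.0
    noisy_scans_per_block: int = 0
    noisy_scan_factor: float = 10.0
    # calibration
    toluene_bands: list = field(default_factory=lambda: list(simulate.DEFAULT_TOLUENE_BANDS))
    calibration_degree: int = 2
    grid_start: float = 450.0
    grid_stop: float = 1729.0
    grid_step: float = 1.0
    # pre-processing
    cosmic_threshold_mads: float = 8.0
    scans_kept: int = 10
    anchor_wavenumbers: list = field(default_factory=lambda: list(DEFAULT_ANCHORS))
    # features / classification
    candidate_regions: list = field(
        default_factory=lambda: [[r.low, r.high] for r in features.DEFAULT_REGIONS]
    )
    tve_threshold: float = 95.0
    families: list = field(default_factory=lambda: list(FAMILIES))
    cv_folds: int = 5
    repetitions: int = 10
    train_fraction: float = 0.85
    split_target_counts: dict | None = None
    # input
    input_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def instrument(self) -> simulate.InstrumentSpec:
        return simulate.InstrumentSpec(
            noise_sd=self.noise_sd,
            cosmic_ray_rate=self.cosmic_ray_rate,
            cosmic_ray_amplitude=self.cosmic_ray_amplitude,
        )

    def serum_model(self) -> simulate.SerumModel:
        return simulate.SerumModel(
            patient_attenuation=self.patient_attenuation,
            subject_sd=self.subject_sd,
        )

    def regions(self):
        return [Region(low, high) for low, high in self.candidate_regions]

    def baseline_spec(self) -> BaselineSpec:
        return BaselineSpec(tuple(self.anchor_wavenumbers))


def _derive_seeds(master_seed: int, n: int):
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return df

def _check_finite_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values))[0]
    if bad.size:
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(f"{path}: malformed value in column '{col}' at line {bad[0] + 2}")
    return values


def read_scans(path) -> ScanBlock:
    """Read a multi-scan CSV: column 1 axis (pixel/wavenumber), columns 2..n scans."""
    df = _read_csv(path)
    axis_name = df.columns[0]
    if axis_name not in ("pixel", "wavenumber"):
        raise ValueError(
            f"{path}: first column must be 'pixel' or 'wavenumber', got {axis_name!r}"
        )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: no scan columns found")
    axis = _check_finite_column(df, axis_name, path)
    steps = np.diff(axis)
    if not np.all(steps > 0):
        line = int(np.nonzero(steps <= 0)[0][0]) + 3
        raise ValueError(f"{path}: axis not strictly increasing at line {line}")
    scans = np.column_stack(
        [_check_finite_column(df, c, path) for c in df.columns[1:]]
    )
    return ScanBlock(axis=axis, intensities=scans, axis_kind=axis_name)


def write_scans(block: ScanBlock, path) -> None:
    cols = {block.axis_kind: block.axis}
    for j in range(block.n_scans):
        cols[f"scan_{j + 1}"] = block.intensities[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber": spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum(path, **state_flags) -> Spectrum:
    df = _read_csv(path)
    if list(df.columns[:2]) != ["wavenumber", "intensity"]:
        raise ValueError(f"{path}: expected columns 'wavenumber,intensity'")
    return Spectrum(
        wavenumbers=_check_finite_column(df, "wavenumber", path),
        intensities=_check_finite_column(df, "intensity", path),
        **state_flags,
    )


def read_labels(path) -> dict:
    """Read subject labels as ``{subject_id: 'patient'|'control'}``."""
    df = _read_csv(path)
    if list(df.columns[:2]) != ["subject_id", "label"]:
        raise ValueError(f"{path}: expected columns 'subject_id,label'")
    labels = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sid, label = str(row.subject_id), str(row.label)
        if label not in ("patient", "control"):
            raise ValueError(f"{path}: invalid label {label!r} at line {i + 2}")
        if sid in labels:
            raise ValueError(f"{path}: duplicate subject id {sid!r} at line {i + 2}")
        labels[sid] = label
    return labels


def write_labels(labels: dict, path) -> None:
    pd.DataFrame(
        {"subject_id": list(labels.keys()), "label": list(labels.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Session directories
# ---------------------------------------------------------------------------

def simulate_session_dir(config: RunConfig, out_dir) -> None:
    """Simulate a full measurement session and write it as CSV + JSON files."""
    os.makedirs(os.path.join(out_dir, "measurements"), exist_ok=True)
    toluene_seed, water_seed, cohort_seed = _derive_seeds(config.seed, 3)
    instrument = config.instrument()
    toluene = simulate.simulate_toluene(
        instrument, config.toluene_bands, seed=toluene_seed
    )
    water = simulate.simulate_water(
        instrument, n_scans=config.scans_per_measurement, seed=water_seed
    )
    sessions, truth = simulate.simulate_cohort(
        instrument,
        config.serum_model(),
        n_patients=config.n_patients,
        n_controls=config.n_controls,
        scans_per_measurement=config.scans_per_measurement,
        measurements_per_subject=config.measurements_per_subject,
        noisy_scans_per_block=config.noisy_scans_per_block,
        noisy_scan_factor=config.noisy_scan_factor,
        seed=cohort_seed,
    )
    write_scans(toluene, os.path.join(out_dir, "toluene.csv"))
    write_scans(water, os.path.join(out_dir, "water.csv"))
    for sid, blocks in sessions.items():
        for m, block in enumerate(blocks):
            write_scans(
                block, os.path.join(out_dir, "measurements", f"{sid}_m{m + 1}.csv")
            )
    write_labels(truth.labels, os.path.join(out_dir, "labels.csv"))
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh)
    logger.info("simulated session written to %s (%d subjects)", out_dir, len(sessions))


def load_session_dir(in_dir):
    """Load a session directory -> (toluene, water, sessions dict, labels dict)."""
    toluene = read_scans(os.path.join(in_dir, "toluene.csv"))
    water = read_scans(os.path.join(in_dir, "water.csv"))
    labels = read_labels(os.path.join(in_dir, "labels.csv"))
    meas_dir = os.path.join(in_dir, "measurements")
    sessions: dict = {}
    for name in sorted(os.listdir(meas_dir)):
        if not name.endswith(".csv"):
            continue
        sid = name.rsplit("_m", 1)[0]
        sessions.setdefault(sid, []).append(read_scans(os.path.join(meas_dir, name)))
    missing = sorted(set(sessions) - set(labels))
    if missing:
        raise ValueError(f"no label found for subject ids: {missing}")
    unmeasured = sorted(set(labels) - set(sessions))
    if unmeasured:
        raise ValueError(f"no measurements found for labelled subjects: {unmeasured}")
    return toluene, water, sessions, labels


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _preprocess_block(block, model, config: RunConfig) -> Spectrum:
    calibrated = preprocess.apply_calibration(
        block, model, config.grid_start, config.grid_stop, config.grid_step
    )
    despiked, _ = preprocess.remove_cosmic_rays(
        calibrated, threshold_mads=config.cosmic_threshold_mads
    )
    keep = min(config.scans_kept, despiked.n_scans)
    culled = preprocess.cull_scans(despiked, keep=keep)
    return preprocess.average_scans(culled)


def build_cohort_dataset(config: RunConfig, toluene, water, sessions, labels):
    """Run the pre-processing chain on raw sessions -> CohortDataset.

    Returns ``(dataset, calibration_model)``.
    """
    apexes = preprocess.detect_reference_peaks(toluene, len(config.toluene_bands))
    model = preprocess.fit_calibration(
        apexes, config.toluene_bands, degree=config.calibration_degree
    )
    logger.info(
        "calibration fit: degree %d, max |residual| %.3g cm^-1",
        model.degree,
        float(np.max(np.abs(model.residuals))),
    )
    water_mean = _preprocess_block(water, model, config)
    anchors = config.baseline_spec()
    rows, row_labels, ids = [], [], []
    for sid in sorted(sessions):
        spectra = [_preprocess_block(b, model, config) for b in sessions[sid]]
        subject_mean = preprocess.average_measurements(spectra)
        bg = preprocess.subtract_background(subject_mean, water_mean)
        bc, _ = preprocess.correct_baseline(bg, anchors)
        final = preprocess.normalize(bc)
        rows.append(final.intensities)
        row_labels.append(labels[sid])
        ids.append(sid)
    grid = np.arange(
        config.grid_start, config.grid_stop + 0.5 * config.grid_step, config.grid_step
    )
    dataset = CohortDataset(
        X=np.vstack(rows),
        labels=np.asarray(row_labels),
        subject_ids=np.asarray(ids),
        grid=grid,
    )
    logger.info("pre-processing done: %d subjects on %d grid points",
                dataset.n_subjects, grid.size)
    return dataset, model


@dataclass
class RunReport:
    """Machine-readable end-to-end run summary.

    Every reported percentage is recomputable from the stored confusion
    counts; provenance records the seed and a hash of the exact
    configuration used.
    """

    chosen_region: list
    accuracy_table: list
    n_components: int
    tve_retained: list
    training_metrics: dict
    test_metrics: dict
    split_counts: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None):
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _metrics_dict(report: MetricsReport) -> dict:
    c = report.counts
    return {
        "counts": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
        "metrics": {
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "ppv": report.ppv,
            "npv": report.npv,
            "accuracy": report.accuracy,
        },
    }


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the full analysis chain and return the run report.

    When ``out_dir`` is given, the report, accuracy table, processed
    spectra, labels, PCA scores/loadings and test predictions are written
    there as JSON/CSV.
    """
    seeds = _derive_seeds(config.seed, 6)
    toluene_seed, water_seed, cohort_seed, selection_seed, split_seed, cv_seed = seeds

    if config.input_dir is not None:
        logger.info("stage: load sessions from %s", config.input_dir)
        toluene, water, sessions, labels = load_session_dir(config.input_dir)
    else:
        logger.info(
            "stage: simulate sessions (%d patients, %d controls, seed %d)",
            config.n_patients, config.n_controls, config.seed,
        )
        instrument = config.instrument()
        toluene = simulate.simulate_toluene(
            instrument, config.toluene_bands, seed=toluene_seed
        )
        water = simulate.simulate_water(
            instrument, n_scans=config.scans_per_measurement, seed=water_seed
        )
        sessions, truth = simulate.simulate_cohort(
            instrument,
            config.serum_model(),
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            scans_per_measurement=config.scans_per_measurement,
            measurements_per_subject=config.measurements_per_subject,
            noisy_scans_per_block=config.noisy_scans_per_block,
            noisy_scan_factor=config.noisy_scan_factor,
            seed=cohort_seed,
        )
        labels = truth.labels

    logger.info("stage: pre-processing")
    dataset, _calibration = build_cohort_dataset(config, toluene, water, sessions, labels)

    logger.info(
        "stage: region selection (%d regions x %d families, %d repetitions)",
        len(config.candidate_regions), len(config.families), config.repetitions,
    )
    selection = classify.select_region(
        dataset,
        config.regions(),
        families=config.families,
        repetitions=config.repetitions,
        folds=config.cv_folds,
        seed=selection_seed,
        tve_threshold=config.tve_threshold,
    )
    chosen = selection.chosen_region
    logger.info("chosen region: %s cm^-1", chosen)

    region_data = features.truncate(dataset, chosen)
    train, test = classify.split_train_test(
        region_data,
        train_fraction=config.train_fraction,
        seed=split_seed,
        target_counts=config.split_target_counts,
    )
    pca = features.fit_pca(train, tve_threshold=config.tve_threshold)
    logger.info(
        "PCA: %d components retained (cumulative TVE %.1f%%)",
        pca.n_components, float(np.sum(pca.tve[: pca.n_components])),
    )
    train_scores = features.transform(pca, train)
    test_scores = features.transform(pca, test)

    training_metrics, test_metrics, test_predictions = {}, {}, {}
    for family in config.families:
        spec = ModelSpec(family=family)
        cv_preds, cv_labels = classify.cross_validate_predictions(
            spec, train, folds=config.cv_folds, seed=cv_seed,
            tve_threshold=config.tve_threshold,
        )
        training_metrics[family] = _metrics_dict(classify.evaluate(cv_preds, cv_labels))
        preds = classify.fit_predict(spec, train_scores, train.labels, test_scores)
        test_metrics[family] = _metrics_dict(classify.evaluate(preds, test.labels))
        test_predictions[family] = preds

    split_counts = {
        "train_patients": int(np.sum(train.labels == classify.POSITIVE_LABEL)),
        "train_controls": int(np.sum(train.labels == classify.NEGATIVE_LABEL)),
        "test_patients": int(np.sum(test.labels == classify.POSITIVE_LABEL)),
        "test_controls": int(np.sum(test.labels == classify.NEGATIVE_LABEL)),
    }
    from . import __version__

    report = RunReport(
        chosen_region=[chosen.low, chosen.high],
        accuracy_table=selection.as_records(),
        n_components=pca.n_components,
        tve_retained=[float(v) for v in pca.tve[: pca.n_components]],
        training_metrics=training_metrics,
        test_metrics=test_metrics,
        split_counts=split_counts,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "package_version": __version__,
        },
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        report.to_json(os.path.join(out_dir, "report.json"))
        pd.DataFrame(selection.as_records()).to_csv(
            os.path.join(out_dir, "accuracy_table.csv"), index=False
        )
        spec_cols = {"wavenumber": dataset.grid}
        for i, sid in enumerate(dataset.subject_ids):
            spec_cols[str(sid)] = dataset.X[i]
        pd.DataFrame(spec_cols).to_csv(
            os.path.join(out_dir, "processed_spectra.csv"), index=False
        )
        write_labels(labels, os.path.join(out_dir, "labels.csv"))
        features.export_scores_loadings(
            pca, train_scores, train.labels, train.subject_ids, out_dir
        )
        pred_cols = {"subject_id": test.subject_ids, "label": test.labels}
        for family, preds in test_predictions.items():
            pred_cols[f"predicted_{family}"] = preds
        pd.DataFrame(pred_cols).to_csv(
            os.path.join(out_dir, "test_predictions.csv"), index=False
        )
        logger.info("outputs written to %s", out_dir)

    return report
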