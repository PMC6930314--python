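"""Spectral-region truncation and PCA feature extraction.

PCA is fit on training rows only (mean-centering, no per-column scaling —
the rows are already vector-normalized spectra) and the number of retained
components is the smallest number whose cumulative total variance explained
(TVE) reaches the threshold (default 95%). Loading signs are fixed so each
loading's largest-magnitude element is positive, making scores and loadings
reproducible across runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "CohortDataset",
    "PCAModel",
    "truncate",
    "n_components_for_tve",
    "fit_pca",
    "transform",
    "export_scores_loadings",
    "DEFAULT_REGIONS",
]


@dataclass(frozen=True)
class Region:
    """Inclusive wavenumber interval [low, high] in cm^-1."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"region low ({self.low}) must be < high ({self.high})")

    @property
    def width(self) -> float:
        return self.high - self.low

    def __str__(self) -> str:
        return f"{self.low:g}-{self.high:g}"


#: Candidate regions scanned during region selection (cm^-1).
DEFAULT_REGIONS = (
    Region(450.0, 1729.0),
    Region(790.0, 1729.0),
    Region(1140.0, 1729.0),
    Region(1368.0, 1729.0),
)


@dataclass
class CohortDataset:
    """Processed per-subject spectra with binary labels.

    ``X`` has one row per subject on the shared wavenumber ``grid``;
    ``labels`` are ``"patient"`` / ``"control"``.
    """

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x grid points)")
        n = self.X.shape[0]
        if not (self.labels.size == n and self.subject_ids.size == n):
            raise ValueError("rows, labels and subject ids must align")
        if self.X.shape[1] != self.grid.size:
            raise ValueError("X columns must match the wavenumber grid")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "CohortDataset":
        idx = np.asarray(idx)
        return CohortDataset(
            X=self.X[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            grid=self.grid.copy(),
        )


@dataclass
class PCAModel:
    """Mean-centered PCA fit with the TVE retention rule applied.

    ``tve`` holds the per-component percentage of total variance explained
    for *all* components (sums to 100); ``loadings`` holds only the retained
    components, orthonormal, one per row.
    """

    loadings: np.ndarray
    component_variances: np.ndarray
    tve: np.ndarray
    n_components: int
    mean: np.ndarray
    grid: np.ndarray


def truncate(dataset: CohortDataset, region: Region) -> CohortDataset:
    """Keep the columns with ``region.low <= wavenumber <= region.high``."""
    mask = (dataset.grid >= region.low) & (dataset.grid <= region.high)
    if not mask.any():
        raise ValueError(
            f"region {region} selects no grid points in "
            f"[{dataset.grid[0]:g}, {dataset.grid[-1]:g}] cm^-1"
        )
    return CohortDataset(
        X=dataset.X[:, mask],
        labels=dataset.labels.copy(),
        subject_ids=dataset.subject_ids.copy(),
        grid=dataset.grid[mask],
    )


def n_components_for_tve(tve, threshold: float) -> int:
    """Smallest n with cumulative TVE >= threshold (both in percent)."""
    cum = np.cumsum(np.asarray(tve, dtype=float))
    reached = np.nonzero(cum >= threshold - 1e-9)[0]
    if reached.size == 0:
        return len(cum)
    return int(reached[0]) + 1


def fit_pca(train: CohortDataset, tve_threshold: float = 95.0) -> PCAModel:
    """Fit mean-centered PCA on training rows; retain components by TVE."""
    if train.n_subjects < 2:
        raise ValueError("PCA needs at least 2 training subjects")
    if not 0.0 < tve_threshold <= 100.0:
        raise ValueError("tve_threshold must lie in (0, 100]")
    mean = train.X.mean(axis=0)
    centered = train.X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / (train.n_subjects - 1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("training data have zero variance")
    tve = 100.0 * variances / total
    n_comp = n_components_for_tve(tve, tve_threshold)
    loadings = vt[:n_comp].copy()
    for row in loadings:  # sign convention: largest-|.| element positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        loadings=loadings,
        component_variances=variances,
        tve=tve,
        n_components=n_comp,
        mean=mean,
        grid=train.grid.copy(),
    )


def transform(model: PCAModel, data: CohortDataset) -> np.ndarray:
    """Project rows onto the retained loadings using the training mean."""
    if not np.array_equal(data.grid, model.grid):
        raise ValueError("data grid does not match the PCA training grid")
    return (data.X - model.mean) @ model.loadings.T


def export_scores_loadings(model: PCAModel, scores, labels, subject_ids, out_dir):
    """Write scores (with labels) and loadings (vs wavenumber) as CSV.

    Returns the two file paths ``(scores_csv, loadings_csv)``.
    """
    scores = np.asarray(scores, dtype=float)
    os.makedirs(out_dir, exist_ok=True)
    score_cols = {f"PC{i + 1}": scores[:, i] for i in range(scores.shape[1])}
    scores_df = pd.DataFrame(
        {"subject_id": np.asarray(subject_ids), "label": np.asarray(labels), **score_cols}
    )
    scores_path = os.path.join(out_dir, "scores.csv")
    scores_df.to_csv(scores_path, index=False)
    loading_cols = {
        f"loading_{i + 1}": model.loadings[i] for i in range(model.n_components)
    }
    loadings_df = pd.DataFrame({"wavenumber": model.grid, **loading_cols})
    loadings_path = os.path.join(out_dir, "loadings.csv")
    loadings_df.to_csv(loadings_path, index=False)
    return scores_path, loadings_path
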