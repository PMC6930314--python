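"""Classification models, cross-validation, region selection and metrics.

Four classifier variants are supported, mirroring the common chemometrics
presets: ``knn_fine`` (1-nearest-neighbor, Euclidean), ``knn_weighted``
(k=10 with squared-inverse-distance votes), and polynomial-kernel SVMs of
degree 2 (``svm_quadratic``) and 3 (``svm_cubic``) with box constraint 1 and
training-set standardization. All models consume PCA scores.

Cross-validation is stratified and refits the PCA inside every training
fold, so held-out folds never leak into the feature extraction. Region
selection repeats the full CV several times per (region, family) cell with
fresh fold randomization and picks the region with the highest mean
accuracy (ties go to the wider region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import CohortDataset, Region, fit_pca, transform, truncate

__all__ = [
    "FAMILIES",
    "POSITIVE_LABEL",
    "NEGATIVE_LABEL",
    "ModelSpec",
    "ConfusionCounts",
    "MetricsReport",
    "RegionSelectionResult",
    "split_train_test",
    "fit_predict",
    "cross_validate",
    "cross_validate_predictions",
    "select_region",
    "evaluate",
]

FAMILIES = ("knn_fine", "knn_weighted", "svm_quadratic", "svm_cubic")
POSITIVE_LABEL = "patient"
NEGATIVE_LABEL = "control"

_FAMILY_DEFAULTS = {
    "knn_fine": {"k": 1},
    "knn_weighted": {"k": 10},
    "svm_quadratic": {"degree": 2},
    "svm_cubic": {"degree": 3},
}


@dataclass
class ModelSpec:
    """One of the four classifier presets with resolved hyperparameters.

    ``k`` applies to the kNN families, ``degree``/``box_constraint``/
    ``standardize`` to the SVMs; unset fields are filled with the preset
    defaults for the family.
    """

    family: str
    k: int | None = None
    degree: int | None = None
    box_constraint: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        defaults = _FAMILY_DEFAULTS[self.family]
        if self.k is None:
            self.k = defaults.get("k")
        if self.degree is None:
            self.degree = defaults.get("degree")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.degree is not None and self.degree not in (2, 3):
            raise ValueError("kernel degree must be 2 or 3")


def _squared_inverse_distance(distances: np.ndarray) -> np.ndarray:
    # distance floor avoids inf weights when a query coincides with a
    # training point; the coincident point then dominates the vote anyway
    return 1.0 / np.maximum(distances, 1e-12) ** 2


def _build_estimator(spec: ModelSpec):
    if spec.family == "knn_fine":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    if spec.family == "knn_weighted":
        return KNeighborsClassifier(
            n_neighbors=spec.k,
            metric="euclidean",
            weights=_squared_inverse_distance,
        )
    svc = SVC(
        kernel="poly",
        degree=spec.degree,
        C=spec.box_constraint,
        gamma="scale",
        coef0=1.0,
    )
    if spec.standardize:
        return make_pipeline(StandardScaler(), svc)
    return svc


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_test(
    dataset: CohortDataset,
    train_fraction: float = 0.85,
    seed: int = 0,
    target_counts: dict | None = None,
):
    """Stratified random train/test split of a cohort.

    ``target_counts``, when given, must be a mapping with keys
    ``train_patients``, ``train_controls``, ``test_patients``,
    ``test_controls`` that exactly partitions each class; it allows
    reproducing a reported split (e.g. 41/39 train vs 8/6 test) that is not
    an exact proportional stratification. Without it, each class is split by
    proportional rounding of ``train_fraction``.
    """
    labels = dataset.labels
    pat_idx = np.nonzero(labels == POSITIVE_LABEL)[0]
    ctl_idx = np.nonzero(labels == NEGATIVE_LABEL)[0]
    if pat_idx.size == 0 or ctl_idx.size == 0:
        raise ValueError("both classes must be present for a stratified split")
    if target_counts is not None:
        tp, tc = target_counts["train_patients"], target_counts["train_controls"]
        sp, sc = target_counts["test_patients"], target_counts["test_controls"]
        if tp + sp != pat_idx.size:
            raise ValueError(
                f"patient counts {tp}+{sp} do not partition the {pat_idx.size} patients"
            )
        if tc + sc != ctl_idx.size:
            raise ValueError(
                f"control counts {tc}+{sc} do not partition the {ctl_idx.size} controls"
            )
        n_train_pat, n_train_ctl = tp, tc
    else:
        n_train_pat = int(round(train_fraction * pat_idx.size))
        n_train_ctl = int(round(train_fraction * ctl_idx.size))
    if not (1 <= n_train_pat < pat_idx.size and 1 <= n_train_ctl < ctl_idx.size):
        raise ValueError(
            "split would leave an empty training or test set in one class"
        )
    rng = np.random.default_rng(seed)
    train_idx = np.concatenate(
        [
            rng.permutation(pat_idx)[:n_train_pat],
            rng.permutation(ctl_idx)[:n_train_ctl],
        ]
    )
    train_mask = np.zeros(dataset.n_subjects, dtype=bool)
    train_mask[train_idx] = True
    return dataset.subset(np.nonzero(train_mask)[0]), dataset.subset(
        np.nonzero(~train_mask)[0]
    )


# ---------------------------------------------------------------------------
# Fitting and cross-validation
# ---------------------------------------------------------------------------

def fit_predict(spec: ModelSpec, train_scores, train_labels, query_scores) -> np.ndarray:
    """Fit the given model on PCA scores and predict labels for queries.

    Residual vote ties resolve to the negative class ("control"), which is
    first in label sort order.
    """
    train_scores = np.asarray(train_scores, dtype=float)
    query_scores = np.asarray(query_scores, dtype=float)
    train_labels = np.asarray(train_labels)
    if np.unique(train_labels).size > 2:
        raise ValueError("labels must be binary")
    if spec.k is not None and spec.k > train_scores.shape[0]:
        raise ValueError(
            f"k={spec.k} exceeds the {train_scores.shape[0]} training samples"
        )
    est = _build_estimator(spec)
    est.fit(train_scores, train_labels)
    return est.predict(query_scores)


def _check_cv_feasible(labels: np.ndarray, folds: int) -> None:
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than {folds} folds"
        )


def cross_validate_predictions(
    spec: ModelSpec,
    dataset: CohortDataset,
    folds: int = 5,
    seed: int = 0,
    tve_threshold: float = 95.0,
):
    """Stratified k-fold CV with per-fold PCA refits; pooled predictions.

    Returns ``(predictions, labels)`` aligned over all held-out folds.
    """
    _check_cv_feasible(dataset.labels, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    preds = np.empty(dataset.n_subjects, dtype=dataset.labels.dtype)
    for train_idx, test_idx in skf.split(dataset.X, dataset.labels):
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        pca = fit_pca(train, tve_threshold=tve_threshold)
        preds[test_idx] = fit_predict(
            spec, transform(pca, train), train.labels, transform(pca, test)
        )
    return preds, dataset.labels.copy()


def cross_validate(
    spec: ModelSpec,
    dataset: CohortDataset,
    folds: int = 5,
    seed: int = 0,
    tve_threshold: float = 95.0,
) -> float:
    """Pooled held-out accuracy (%) of a stratified k-fold CV."""
    preds, labels = cross_validate_predictions(
        spec, dataset, folds=folds, seed=seed, tve_threshold=tve_threshold
    )
    return 100.0 * float(np.mean(preds == labels))


# ---------------------------------------------------------------------------
# Region selection
# ---------------------------------------------------------------------------

@dataclass
class RegionSelectionResult:
    """Mean +- SD CV accuracy per (region, family) and the chosen region."""

    results: dict  # (Region, family) -> (mean accuracy %, SD)
    chosen_region: Region
    repetitions: int

    def as_records(self):
        return [
            {
                "region": str(region),
                "family": family,
                "mean_accuracy": mean,
                "sd": sd,
            }
            for (region, family), (mean, sd) in self.results.items()
        ]


def select_region(
    dataset: CohortDataset,
    regions,
    families=FAMILIES,
    repetitions: int = 10,
    folds: int = 5,
    seed: int = 0,
    tve_threshold: float = 95.0,
) -> RegionSelectionResult:
    """Cross-validated spectral-region selection.

    For every region x family cell, ``repetitions`` independent stratified
    CVs (fresh fold randomization each time) are run on the truncated
    dataset; the region of the cell with the highest mean accuracy is
    chosen, ties resolving to the wider region.
    """
    regions = list(regions)
    families = list(families)
    if not regions or not families:
        raise ValueError("need at least one region and one family")
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(
        0, 2**31 - 1, size=(len(regions), len(families), repetitions)
    )
    results = {}
    for i, region in enumerate(regions):
        sub = truncate(dataset, region)
        for j, family in enumerate(families):
            spec = ModelSpec(family=family)
            accs = [
                cross_validate(
                    spec,
                    sub,
                    folds=folds,
                    seed=int(fold_seeds[i, j, r]),
                    tve_threshold=tve_threshold,
                )
                for r in range(repetitions)
            ]
            results[(region, family)] = (
                float(np.mean(accs)),
                float(np.std(accs)),
            )
    chosen = max(
        results,
        key=lambda key: (results[key][0], key[0].width),
    )[0]
    return RegionSelectionResult(
        results=results, chosen_region=chosen, repetitions=repetitions
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with "patient" as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _pct(num: int, den: int):
    return None if den == 0 else 100.0 * num / den


@dataclass(frozen=True)
class MetricsReport:
    """Diagnostic performance metrics in percent.

    A metric whose denominator is zero is flagged undefined (``None``)
    rather than reported as 0 or 100.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def rounded(self, ndigits: int = 1) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        return out

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "MetricsReport":
        return cls(
            counts=counts,
            sensitivity=_pct(counts.tp, counts.tp + counts.fn),
            specificity=_pct(counts.tn, counts.tn + counts.fp),
            ppv=_pct(counts.tp, counts.tp + counts.fp),
            npv=_pct(counts.tn, counts.tn + counts.fn),
            accuracy=_pct(counts.tp + counts.tn, counts.total),
        )


def evaluate(predictions, truth_labels) -> MetricsReport:
    """Tally a confusion matrix (patient = positive) and derive the metrics."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth_labels)
    if predictions.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if predictions.shape != truth.shape:
        raise ValueError("predictions and labels differ in length")
    allowed = {POSITIVE_LABEL, NEGATIVE_LABEL}
    seen = set(np.unique(predictions)) | set(np.unique(truth))
    if not seen <= allowed:
        raise ValueError(f"labels must be in {sorted(allowed)}, got {sorted(seen)}")
    pos_pred = predictions == POSITIVE_LABEL
    pos_true = truth == POSITIVE_LABEL
    counts = ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )
    return MetricsReport.from_counts(counts)
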