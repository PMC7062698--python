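"""RBF-kernel support vector machine baseline under the same LOOS protocol.

Hyperparameters are chosen per split by grid search on the validation
subjects: C in {0.01, 0.1, 1, 10, 100} and gamma in
{0.1, ..., 0.9, 1, 2, ..., 10}. The input representation — flattened,
decimated single-trial epochs standardized with training-set statistics —
is a repository choice; the comparison protocol (splits, thresholds,
summaries) is identical to the network's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import EpochSet, concatenate_epochs
from .evaluation import (
    CohortSummary,
    SubjectResult,
    _summarize,
    chance_threshold,
    confusion_matrix,
    loos_splits,
)

__all__ = ["SVMGrid", "featurize", "run_svm_loos"]


def _default_gammas() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.1, 1.0, 0.1), 10)) + tuple(
        float(g) for g in range(1, 11)
    )


@dataclass(frozen=True)
class SVMGrid:
    """Hyperparameter grid for the RBF kernel."""

    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gammas)

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if min(self.C_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValueError("grid values must be positive")


def featurize(epochs: EpochSet, decimation: int = 5) -> np.ndarray:
    """Flatten channels x decimated timepoints into one vector per trial."""
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    x = epochs.data[:, :, ::decimation]
    return x.reshape(x.shape[0], -1)


def run_svm_loos(
    dataset: dict[str, EpochSet],
    grid: SVMGrid | None = None,
    *,
    n_val: int = 4,
    decimation: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    n_classes: int = 4,
) -> tuple[list[SubjectResult], CohortSummary]:
    """Leave-one-subject-out evaluation of the RBF SVM.

    Splits are generated from the same seed as the network evaluation so
    both classifiers consume identical partitions. For each split every
    (C, gamma) pair is fitted on the training subjects and scored on the
    validation subjects; the best pair (ties -> smallest C, then smallest
    gamma) is refitted on the training subjects and applied to the test
    subject. Multi-class handling is one-vs-one.
    """
    grid = grid or SVMGrid()
    usable = {sid: es for sid, es in dataset.items() if es.n_trials > 0}
    splits = loos_splits(sorted(usable), n_val=n_val, seed=seed)

    results: list[SubjectResult] = []
    for split in splits:
        train_set = concatenate_epochs([usable[s] for s in split.train_subjects])
        val_set = concatenate_epochs([usable[s] for s in split.val_subjects])
        test_set = usable[split.test_subject]
        if len(set(train_set.labels)) < 2:
            raise ValueError("training set is single-class; SVM undefined")

        scaler = StandardScaler()
        xtr = scaler.fit_transform(featurize(train_set, decimation))
        xval = scaler.transform(featurize(val_set, decimation))
        xte = scaler.transform(featurize(test_set, decimation))

        best = None  # (val_acc, -C, -gamma) maximized
        for c in sorted(grid.C_grid):
            for g in sorted(grid.gamma_grid):
                clf = SVC(kernel="rbf", C=c, gamma=g)
                clf.fit(xtr, train_set.labels)
                acc = float(
                    (clf.predict(xval) == val_set.labels).mean()
                )
                key = (acc, -c, -g)
                if best is None or key > best[0]:
                    best = (key, c, g)
        _, c_best, g_best = best
        clf = SVC(kernel="rbf", C=c_best, gamma=g_best)
        clf.fit(xtr, train_set.labels)
        pred = clf.predict(xte)
        conf = confusion_matrix(test_set.labels, pred, n_classes=n_classes)
        n_test = test_set.n_trials
        results.append(
            SubjectResult(
                subject=split.test_subject,
                n_test=n_test,
                accuracy=float(100.0 * np.trace(conf) / n_test),
                chance_threshold=chance_threshold(n_test, n_classes, alpha),
                confusion=conf,
            )
        )
    return results, _summarize(results, n_classes)
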