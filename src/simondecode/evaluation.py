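"""Leave-one-subject-out evaluation with binomial chance thresholds.

Each subject serves once as the test set while a few randomly drawn
subjects form the validation set used for best-checkpoint early
stopping; the rest train the network. Per-subject significance uses the
binomial inverse-CDF chance level: with n test trials and c classes the
threshold is the smallest accuracy whose exceedance is improbable
(p < alpha) under guessing, binoinv(1 - alpha, n, 1/c) * 100 / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import EpochSet, concatenate_epochs
from .nn import NetConfig, build_model, predict, train

__all__ = [
    "LOOSplit",
    "SubjectResult",
    "CohortSummary",
    "loos_splits",
    "chance_threshold",
    "run_loos",
    "confusion_matrix",
    "accuracy_trial_correlation",
    "data_point_count",
]


@dataclass(frozen=True)
class LOOSplit:
    """One left-out test subject with its validation and training subjects."""

    test_subject: str
    val_subjects: tuple[str, ...]
    train_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [{self.test_subject}, set(self.val_subjects),
                  set(self.train_subjects)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("test/val/train subjects must be disjoint")


def loos_splits(
    subject_ids: list[str], n_val: int = 4, seed: int = 0
) -> list[LOOSplit]:
    """One split per subject; validation subjects drawn uniformly, seeded.

    Validation subjects are redrawn independently for every split from a
    per-split generator derived from ``seed``, so the same seed always
    yields the same splits regardless of evaluation order.
    """
    subject_ids = list(subject_ids)
    if len(subject_ids) < n_val + 2:
        raise ValueError(
            f"cohort of {len(subject_ids)} too small for n_val={n_val} "
            "(need at least n_val + 2 subjects)"
        )
    children = np.random.SeedSequence(seed).spawn(len(subject_ids))
    splits = []
    for i, test in enumerate(subject_ids):
        rest = [s for s in subject_ids if s != test]
        rng = np.random.default_rng(children[i])
        val = tuple(sorted(rng.choice(rest, size=n_val, replace=False)))
        train = tuple(s for s in rest if s not in val)
        splits.append(LOOSplit(test_subject=test, val_subjects=val,
                               train_subjects=train))
    return splits


def chance_threshold(n: int, c: int = 4, alpha: float = 0.05) -> float:
    """Binomial chance-level threshold in percent correct.

    Returns 100/n times the smallest k whose Binomial(n, 1/c) CDF
    reaches 1 - alpha; accuracies strictly above it are significantly
    better than guessing at level alpha. Converges to 100/c for large n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if c < 1:
        raise ValueError("c must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k = stats.binom.ppf(1.0 - alpha, n, 1.0 / c)
    return float(k * 100.0 / n)


def data_point_count(
    n_subjects: int,
    n_channels: int,
    sfreq: float,
    interval_s: float,
    n_epochs: int,
) -> int:
    """Dataset-size bookkeeping: subjects x channels x samples-per-epoch
    x epochs, with samples-per-epoch = sfreq x analyzed interval length."""
    return int(n_subjects * n_channels * round(sfreq * interval_s) * n_epochs)


@dataclass
class SubjectResult:
    """Test-set outcome for one left-out subject."""

    subject: str
    n_test: int
    accuracy: float  # percent
    chance_threshold: float  # percent
    confusion: np.ndarray  # (c, c) counts, rows = true class

    @property
    def above_chance(self) -> bool:
        return self.accuracy > self.chance_threshold

    @property
    def margin(self) -> float:
        return self.accuracy - self.chance_threshold


@dataclass
class CohortSummary:
    """Cohort roll-up of the per-subject leave-one-out results."""

    mean_accuracy: float  # percent, all evaluated subjects
    n_above: int
    frac_above: float  # percent of subjects
    mean_margin: float  # percent, above-chance subjects only
    margin_t: float  # one-sample t of (accuracy - threshold) vs 0
    margin_p: float
    pooled_confusion: np.ndarray  # row-normalized (c, c)


def _summarize(results: list[SubjectResult], c: int) -> CohortSummary:
    accs = np.array([r.accuracy for r in results])
    margins = np.array([r.margin for r in results])
    above = np.array([r.above_chance for r in results])
    pooled = np.sum([r.confusion for r in results], axis=0).astype(float)
    row_sums = pooled.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        pooled_norm = np.where(row_sums > 0, pooled / row_sums, 0.0)
    sel = margins[above] if above.any() else np.array([])
    if len(sel) >= 2 and np.std(sel) > 0:
        t, p = stats.ttest_1samp(sel, 0.0)
    else:
        t, p = np.nan, np.nan
    return CohortSummary(
        mean_accuracy=float(accs.mean()),
        n_above=int(above.sum()),
        frac_above=float(100.0 * above.mean()),
        mean_margin=float(sel.mean()) if len(sel) else np.nan,
        margin_t=float(t),
        margin_p=float(p),
        pooled_confusion=pooled_norm,
    )


def run_loos(
    dataset: dict[str, EpochSet],
    net_config: NetConfig | None = None,
    *,
    n_val: int = 4,
    max_epochs: int = 500,
    batch_size: int = 32,
    lr: float = 1e-3,
    alpha: float = 0.05,
    seed: int = 0,
    return_models: bool = False,
):
    """Full leave-one-subject-out evaluation of the network.

    ``dataset`` maps subject id to that subject's preprocessed epochs.
    Subjects with zero surviving epochs are excluded with a warning.
    Returns (per-subject results, cohort summary) and, with
    ``return_models``, also the per-split trained models.
    """
    net_config = net_config or NetConfig()
    usable = {}
    for sid, es in dataset.items():
        if es.n_trials == 0:
            warnings.warn(f"subject {sid} has no surviving epochs; excluded")
            continue
        usable[sid] = es
    splits = loos_splits(sorted(usable), n_val=n_val, seed=seed)
    split_seeds = np.random.SeedSequence(seed).spawn(len(splits))

    results: list[SubjectResult] = []
    models = {}
    for split, ss in zip(splits, split_seeds):
        train_set = concatenate_epochs([usable[s] for s in split.train_subjects])
        val_set = concatenate_epochs([usable[s] for s in split.val_subjects])
        test_set = usable[split.test_subject]
        fit_seed = int(ss.generate_state(1)[0] % (2**31))
        model = build_model(net_config, test_set.n_channels,
                            test_set.n_times, seed=fit_seed)
        trained = train(model, train_set, val_set, max_epochs=max_epochs,
                        batch_size=batch_size, lr=lr, seed=fit_seed)
        probs, _ = predict(trained, test_set)
        pred = probs.argmax(axis=1)
        conf = confusion_matrix(test_set.labels, pred,
                                n_classes=net_config.n_classes)
        n_test = test_set.n_trials
        results.append(
            SubjectResult(
                subject=split.test_subject,
                n_test=n_test,
                accuracy=float(100.0 * np.trace(conf) / n_test),
                chance_threshold=chance_threshold(
                    n_test, net_config.n_classes, alpha
                ),
                confusion=conf,
            )
        )
        if return_models:
            models[split.test_subject] = trained
    summary = _summarize(results, net_config.n_classes)
    if return_models:
        return results, summary, models
    return results, summary


def confusion_matrix(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    normalize: str = "none",
    n_classes: int = 4,
) -> np.ndarray:
    """Confusion counts (rows = true class) or row-normalized frequencies."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if len(t) and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels outside the 0..{n_classes - 1} enumeration")
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (t, p), 1)
    if normalize == "none":
        return conf
    if normalize == "by-true-row":
        sums = conf.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(sums > 0, conf / sums, 0.0)
    raise ValueError("normalize must be 'none' or 'by-true-row'")


def accuracy_trial_correlation(
    results: list[SubjectResult],
) -> tuple[float, float, float]:
    """Pearson correlation between test-set size and accuracy, with R^2."""
    if len(results) < 3:
        raise ValueError("need at least 3 subjects")
    n = np.array([r.n_test for r in results], dtype=float)
    acc = np.array([r.accuracy for r in results], dtype=float)
    if np.ptp(n) == 0 or np.ptp(acc) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(n, acc)
    return float(r), float(p), float(r**2)
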