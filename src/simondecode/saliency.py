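"""Gradient saliency maps: which channels and timepoints drive the classifier.

For each trial the gradient of the pre-softmax score of the trial's own
class is taken with respect to the input, rectified (absolute value),
averaged over all trials of the class, and min-max normalized to [0, 1].
Values near 1 mark channel x time cells that most influence the
classification decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CLASS_ORDER, EpochSet, TrialClass, class_index
from .nn import TrainedModel, input_gradient

__all__ = [
    "SaliencyMap",
    "trial_saliency",
    "class_average_saliency",
    "cohort_average_saliency",
    "feature_ranking",
]


@dataclass
class SaliencyMap:
    """Class-averaged, min-max normalized saliency (channels x timepoints)."""

    class_label: TrialClass
    map: np.ndarray
    n_trials_averaged: int

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if self.map.ndim != 2:
            raise ValueError("saliency map must be channels x timepoints")


def trial_saliency(
    trained: TrainedModel, trial: np.ndarray, class_idx: int
) -> np.ndarray:
    """Elementwise |d score_class / d input| for a single trial."""
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValueError("trial must be channels x timepoints")
    if not 0 <= class_idx < trained.config.n_classes:
        raise ValueError(f"class index {class_idx} out of range")
    grad = input_gradient(trained, trial[None], np.array([class_idx]))
    return np.abs(grad[0]).astype(np.float64)


def _normalize(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise ValueError(
            "degenerate saliency map: averaged gradients are constant"
        )
    return (raw - lo) / (hi - lo)


def class_average_saliency(
    trained: TrainedModel,
    epochs: EpochSet,
    class_label: TrialClass | int,
    rectify: bool = True,
) -> SaliencyMap:
    """Average the per-trial true-class saliency over one class, normalized.

    With ``rectify`` (default) absolute gradients are averaged; otherwise
    signed gradients are averaged and the magnitude of the average is
    normalized.
    """
    idx = (class_label if isinstance(class_label, int)
           else class_index(class_label))
    sel = epochs.labels == idx
    if not sel.any():
        raise ValueError(f"no trials with class {CLASS_ORDER[idx].name}")
    x = epochs.data[sel]
    grads = input_gradient(trained, x, np.full(int(sel.sum()), idx))
    raw = (np.abs(grads).mean(axis=0) if rectify
           else np.abs(grads.mean(axis=0)))
    return SaliencyMap(
        class_label=CLASS_ORDER[idx],
        map=_normalize(raw.astype(np.float64)),
        n_trials_averaged=int(sel.sum()),
    )


def cohort_average_saliency(maps: list[SaliencyMap]) -> SaliencyMap:
    """Equal-weight average of per-subject maps of one class, renormalized."""
    if not maps:
        raise ValueError("need at least one map")
    label = maps[0].class_label
    if any(m.class_label != label for m in maps):
        raise ValueError("maps belong to different classes")
    raw = np.mean([m.map for m in maps], axis=0)
    return SaliencyMap(
        class_label=label,
        map=_normalize(raw),
        n_trials_averaged=sum(m.n_trials_averaged for m in maps),
    )


def top_mass_cells(smap: SaliencyMap | np.ndarray,
                   mass_fraction: float = 0.05) -> np.ndarray:
    """Smallest cell set holding ``mass_fraction`` of total saliency mass.

    Returns a boolean mask over the strongest cells whose cumulative
    saliency reaches the requested share of the map's total; this is the
    peak set a reader of the map would call its hot spots.
    """
    m = smap.map if isinstance(smap, SaliencyMap) else np.asarray(smap)
    if not 0.0 < mass_fraction <= 1.0:
        raise ValueError("mass_fraction must lie in (0, 1]")
    order = np.sort(m.ravel())[::-1]
    cum = np.cumsum(order)
    k = int(np.searchsorted(cum, mass_fraction * cum[-1])) + 1
    return m >= order[min(k, m.size) - 1]


def feature_ranking(
    smap: SaliencyMap, top_fraction: float
) -> list[dict]:
    """Contiguous high-saliency clusters ranked by summed saliency mass.

    Cells above the (1 - top_fraction) quantile are grouped into
    4-connected channel x time clusters; each cluster reports its
    channel and time extents and total mass.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    m = smap.map
    if m.size == 0:
        raise ValueError("empty saliency map")
    if top_fraction == 1.0:
        thresh = m.min() - 1.0  # include everything
    else:
        thresh = np.quantile(m, 1.0 - top_fraction)
    mask = m > thresh if top_fraction < 1.0 else np.ones_like(m, bool)
    labeled, n_clusters = ndimage.label(mask)
    clusters = []
    for lab in range(1, n_clusters + 1):
        cells = labeled == lab
        chans, times = np.nonzero(cells)
        clusters.append(
            {
                "channels": (int(chans.min()), int(chans.max())),
                "time_indices": (int(times.min()), int(times.max())),
                "n_cells": int(cells.sum()),
                "mass": float(m[cells].sum()),
            }
        )
    clusters.sort(key=lambda c: c["mass"], reverse=True)
    return clusters
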