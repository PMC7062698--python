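"""Core domain types for Simon-task EEG decoding.

The Simon task is a two-choice reaction paradigm: a letter cue determines
the responding hand while the irrelevant screen side of the letter either
matches the responding hand (non-conflict) or mismatches it (conflict).
Crossing responding hand with conflict gives the four trial classes that
the decoder must separate from single-trial EEG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .montage import Montage

__all__ = [
    "TrialClass",
    "CLASS_ORDER",
    "CLASS_NAMES",
    "class_index",
    "Event",
    "ContinuousRecording",
    "EpochSet",
]


@dataclass(frozen=True)
class TrialClass:
    """One of the four hand x conflict trial classes.

    ``stimulus_side`` is derived: the stimulus appears on the side of the
    responding hand on non-conflict trials and on the opposite side on
    conflict trials.
    """

    hand: str  # "left" | "right"
    conflict: bool

    def __post_init__(self) -> None:
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")

    @property
    def stimulus_side(self) -> str:
        if not self.conflict:
            return self.hand
        return "right" if self.hand == "left" else "left"

    @property
    def name(self) -> str:
        return f"{self.hand}_{'conflict' if self.conflict else 'nonconflict'}"


#: Fixed class enumeration used for labels, confusion matrices and softmax
#: outputs: (i) left/non-conflict, (ii) left/conflict, (iii) right/non-conflict,
#: (iv) right/conflict.
CLASS_ORDER: tuple[TrialClass, ...] = (
    TrialClass("left", False),
    TrialClass("left", True),
    TrialClass("right", False),
    TrialClass("right", True),
)

CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in CLASS_ORDER)

_CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}


def class_index(trial_class: TrialClass) -> int:
    """Integer code of a trial class in the fixed four-class enumeration."""
    try:
        return _CLASS_TO_INDEX[trial_class]
    except KeyError:
        raise ValueError(f"unknown trial class {trial_class!r}") from None


@dataclass(frozen=True)
class Event:
    """Stimulus event with its behavioral outcome."""

    onset_sample: int
    trial_class: TrialClass
    correct: bool
    rt_ms: float

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


@dataclass
class ContinuousRecording:
    """Continuous multi-channel EEG of one subject with event markers.

    data is channels x samples in microvolts.
    """

    subject_id: str
    sfreq: float
    data: np.ndarray
    events: list[Event]
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{len(self.montage)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Stimulus-locked single-trial epochs of one subject.

    data is trials x channels x timepoints; ``time_ms`` is aligned to
    stimulus onset (0 ms). Values are microvolts, or current source
    density units after the surface-Laplacian transform
    (``csd_applied``).
    """

    subject_id: str
    data: np.ndarray
    time_ms: np.ndarray
    labels: np.ndarray  # int codes into CLASS_ORDER
    montage: Montage
    sfreq: float
    csd_applied: bool = False
    rt_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n, c, t = self.data.shape
        if len(self.time_ms) != t:
            raise ValueError("time axis length mismatch")
        if len(self.labels) != n:
            raise ValueError("labels length mismatch")
        if c != len(self.montage):
            raise ValueError("channel count does not match montage")
        if t > 1:
            steps = np.diff(self.time_ms)
            if not np.allclose(steps, 1000.0 / self.sfreq, atol=1e-6):
                raise ValueError("time axis must be uniform at 1000/sfreq ms")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def trial_classes(self) -> list[TrialClass]:
        return [CLASS_ORDER[i] for i in self.labels]

    def select(self, mask: np.ndarray | Sequence[int]) -> "EpochSet":
        """Subset of trials (boolean mask or index array)."""
        idx = np.asarray(mask)
        return EpochSet(
            subject_id=self.subject_id,
            data=self.data[idx],
            time_ms=self.time_ms.copy(),
            labels=self.labels[idx],
            montage=self.montage,
            sfreq=self.sfreq,
            csd_applied=self.csd_applied,
            rt_ms=None if self.rt_ms is None else self.rt_ms[idx],
        )


def concatenate_epochs(epoch_sets: Sequence[EpochSet]) -> EpochSet:
    """Stack several subjects' epochs into one set (subject_id joined)."""
    if not epoch_sets:
        raise ValueError("need at least one EpochSet")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.data.shape[1:] != first.data.shape[1:]:
            raise ValueError("epoch shapes differ between sets")
        if es.csd_applied != first.csd_applied:
            raise ValueError("cannot mix CSD and non-CSD epochs")
    return EpochSet(
        subject_id="+".join(es.subject_id for es in epoch_sets),
        data=np.concatenate([es.data for es in epoch_sets], axis=0),
        time_ms=first.time_ms.copy(),
        labels=np.concatenate([es.labels for es in epoch_sets]),
        montage=first.montage,
        sfreq=first.sfreq,
        csd_applied=first.csd_applied,
    )
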