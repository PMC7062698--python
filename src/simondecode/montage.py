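"""EEG montages on the unit sphere.

Electrode layouts follow the extended 10-10 system. Idealized head
positions are taken from MNE's standard montage, re-centered by a
least-squares sphere fit, and projected to the unit sphere. The unit
sphere is the geometric substrate for the spherical-spline surface
Laplacian and for the spatial mixing of simulated background noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["Montage", "make_montage", "SUPPORTED_SIZES"]

#: Channels that downstream analyses rely on (lateral parieto-occipital,
#: fronto-central / lateral-frontal, and central motor sites).
REQUIRED_CHANNELS = ("PO9", "PO10", "F8", "FC1", "C3", "C4", "Cz")

_LAYOUT_64 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO9 PO7 PO3 POz PO4 PO8 PO10 "
    "O1 Oz O2 Iz"
).split()

# 60-channel cap: the 64-channel layout without midline sites that are
# commonly used as reference/ground or left unplaced (Fpz serves as the
# recording reference in the emulated setup).
_LAYOUT_60 = tuple(ch for ch in _LAYOUT_64 if ch not in ("Fpz", "AFz", "FCz", "Iz"))

_LAYOUT_32 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 "
    "T7 C3 Cz C4 T8 CP5 CP1 CP2 CP6 "
    "P7 P3 Pz P4 P8 PO9 PO3 POz PO4 PO10 O1 O2"
).split()

_LAYOUT_16 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC1 FC2 C3 Cz C4 PO9 PO3 PO4 PO10"
).split()

_LAYOUT_8 = "F3 F4 C3 Cz C4 Pz PO9 PO10".split()

_LAYOUTS = {
    8: tuple(_LAYOUT_8),
    16: tuple(_LAYOUT_16),
    32: tuple(_LAYOUT_32),
    60: tuple(_LAYOUT_60),
    64: tuple(_LAYOUT_64),
}

SUPPORTED_SIZES = tuple(sorted(_LAYOUTS))


@dataclass(frozen=True)
class Montage:
    """Named electrodes with unit-sphere positions (channels x 3)."""

    names: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=np.intp)

    def cosine_angles(self) -> np.ndarray:
        """Pairwise cosines of inter-electrode angles (channels x channels)."""
        cos = self.positions @ self.positions.T
        return np.clip(cos, -1.0, 1.0)


@lru_cache(maxsize=None)
def _standard_positions() -> dict[str, np.ndarray]:
    """10-10 electrode positions projected onto the unit sphere.

    A sphere is fitted to MNE's idealized head positions by linear least
    squares; positions are re-centered and normalized.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            std = mne.channels.make_standard_montage("colin27_1005")
        except ValueError:  # older montage naming
            std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    pts = np.array([ch_pos[ch] for ch in _LAYOUT_64])
    # least-squares sphere fit: |p - c|^2 = r^2  <=>  2 p.c + k = |p|^2
    a = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    unit = pts - center
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    return {ch: unit[i] for i, ch in enumerate(_LAYOUT_64)}


def make_montage(n_channels: int) -> Montage:
    """Build a standard cap layout of the given size.

    Supported sizes are 8, 16, 32, 60 and 64 channels; layouts of 16
    channels or more contain all channels downstream analyses require
    (PO9, PO10, F8, FC1, C3, C4, Cz).
    """
    if n_channels not in _LAYOUTS:
        raise ValueError(
            f"unsupported montage size {n_channels}; "
            f"supported layouts: {', '.join(map(str, SUPPORTED_SIZES))}"
        )
    names = _LAYOUTS[n_channels]
    pos_map = _standard_positions()
    positions = np.array([pos_map[ch] for ch in names])
    return Montage(names=names, positions=positions)
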