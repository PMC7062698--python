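"""Synthetic Simon-task EEG cohorts with known ground truth.

Each simulated trial superimposes three class-informative components on
spatially mixed 1/f background noise:

* an N1-like parieto-occipital deflection at ~190-250 ms, larger over the
  hemisphere contralateral to the stimulus side;
* a fronto-central conflict negativity at ~300-400 ms, larger on conflict
  trials;
* a response-locked motor negativity over the central electrode
  contralateral to the responding hand, peaking at the response.

Component waveforms are Gaussian-windowed half-sine bumps; amplitudes are
in microvolts. Behavioral response times are lognormal with a planted
Simon effect (conflict slower than non-conflict) and error rates are
Bernoulli with a higher rate on conflict trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import CLASS_ORDER, ContinuousRecording, Event, TrialClass
from .montage import Montage, make_montage

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_subject",
    "simulate_cohort",
    "desk_scale_config",
    "planted_cells",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the simulated Simon-task session.

    Amplitudes are peak magnitudes in microvolts of negative-going bumps;
    RT means are the arithmetic means of the lognormal RT distributions.
    """

    n_trials: int = 400
    sfreq: float = 500.0
    n_channels: int = 60
    rsi_range_ms: tuple[float, float] = (2000.0, 2500.0)
    n1_amplitude: float = 12.0
    n1_window_ms: tuple[float, float] = (190.0, 250.0)
    conflict_neg_amplitude: float = 10.0
    conflict_window_ms: tuple[float, float] = (300.0, 400.0)
    motor_lat_amplitude: float = 7.0
    noise_scale: float = 10.0
    rt_nonconflict_ms: float = 393.0
    rt_conflict_ms: float = 430.0
    err_nonconflict: float = 0.034
    err_conflict: float = 0.096
    seed: int = 0
    # secondary shape parameters
    ipsi_gain: float = 0.4  # ipsilateral / contralateral N1 ratio
    nonconflict_neg_gain: float = 0.35  # N2 amplitude ratio non-conflict/conflict
    rt_sigma: float = 0.12  # lognormal shape of single-trial RTs
    hand_rt_effect_ms: float = 5.0  # left-hand minus right-hand mean RT
    amp_spread: float = 0.2  # between-subject lognormal sd of amplitudes
    rt_spread_ms: float = 15.0  # between-subject sd of RT means

    def __post_init__(self) -> None:
        for name in ("n1_amplitude", "conflict_neg_amplitude",
                     "motor_lat_amplitude", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("err_nonconflict", "err_conflict"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n1_window_ms", "conflict_window_ms"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi < 1500.0):
                raise ValueError(f"{name} must lie inside (0, 1500) ms")
        if self.n_trials < 4:
            raise ValueError("need at least 4 trials")


def desk_scale_config(**overrides) -> SimulationConfig:
    """Desk-scale study conditions: 16 channels at 250 Hz, 200 trials.

    These are the default conditions for end-to-end runs of the full
    pipeline on a single workstation; the full-size task (60 channels,
    500 Hz, 400 trials) is available through :class:`SimulationConfig`
    defaults.
    """
    params = dict(n_trials=200, sfreq=250.0, n_channels=16)
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class Cohort:
    """A simulated multi-subject dataset."""

    recordings: list[ContinuousRecording]
    behavior: pd.DataFrame
    config: SimulationConfig

    @property
    def subject_ids(self) -> list[str]:
        return [rec.subject_id for rec in self.recordings]


# ---------------------------------------------------------------------------
# component definitions


def _bump(n: int) -> np.ndarray:
    """Gaussian-windowed half-sine bump of n samples, unit peak at center."""
    u = (np.arange(n) + 0.5) / n
    return np.sin(np.pi * u) * np.exp(-0.5 * ((u - 0.5) / 0.3) ** 2)


def _weights(montage: Montage, table: dict[str, float]) -> np.ndarray:
    w = np.zeros(len(montage))
    for name, val in table.items():
        if name in montage.names:
            w[montage.index(name)] = val
    return w


def _n1_weights(montage: Montage, stimulus_side: str, ipsi_gain: float) -> np.ndarray:
    # contralateral hemisphere carries the larger deflection
    left_w = {"PO9": 1.0, "PO3": 0.6}
    right_w = {"PO10": 1.0, "PO4": 0.6}
    if stimulus_side == "left":
        contra, ipsi = right_w, left_w
    else:
        contra, ipsi = left_w, right_w
    table = dict(contra)
    table.update({k: v * ipsi_gain for k, v in ipsi.items()})
    return _weights(montage, table)


def _conflict_weights(montage: Montage) -> np.ndarray:
    return _weights(montage, {"FC1": 1.0, "F8": 0.8, "FC2": 0.5})


def _motor_weights(montage: Montage, hand: str) -> np.ndarray:
    contra = "C4" if hand == "left" else "C3"
    return _weights(montage, {contra: 1.0, "Cz": 0.2})


def _trial_components(
    tc: TrialClass, rt_ms: float, cfg: SimulationConfig, montage: Montage
) -> list[tuple[np.ndarray, float, tuple[float, float]]]:
    """(channel weights, signed peak amplitude, (t0_ms, t1_ms)) per component."""
    comps = []
    comps.append(
        (_n1_weights(montage, tc.stimulus_side, cfg.ipsi_gain),
         -cfg.n1_amplitude, cfg.n1_window_ms)
    )
    n2_gain = 1.0 if tc.conflict else cfg.nonconflict_neg_gain
    comps.append(
        (_conflict_weights(montage), -cfg.conflict_neg_amplitude * n2_gain,
         cfg.conflict_window_ms)
    )
    comps.append(
        (_motor_weights(montage, tc.hand), -cfg.motor_lat_amplitude,
         (rt_ms - 250.0, rt_ms + 50.0))
    )
    return comps


# ---------------------------------------------------------------------------
# noise


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sfreq: float) -> np.ndarray:
    """Unit-variance 1/f-power noise per channel (frequency-domain synthesis)."""
    spec = rng.standard_normal((n_channels, n_samples // 2 + 1)) + 1j * (
        rng.standard_normal((n_channels, n_samples // 2 + 1))
    )
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _mixing_matrix(montage: Montage, sigma_rad: float = 0.5) -> np.ndarray:
    """Distance-decay spatial mixing kernel, rows normalized to unit power."""
    ang = np.arccos(montage.cosine_angles())
    mix = np.exp(-0.5 * (ang / sigma_rad) ** 2)
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    return mix


# ---------------------------------------------------------------------------
# trial schedule and behavior


def _balanced_labels(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    base, extra = divmod(n_trials, 4)
    counts = np.full(4, base)
    counts[rng.permutation(4)[:extra]] += 1
    labels = np.repeat(np.arange(4), counts)
    return rng.permutation(labels)


def _draw_rt(tc: TrialClass, cfg: SimulationConfig, rt_shift_ms: float,
             rng: np.random.Generator) -> float:
    mean = cfg.rt_conflict_ms if tc.conflict else cfg.rt_nonconflict_ms
    mean += 0.5 * cfg.hand_rt_effect_ms * (1 if tc.hand == "left" else -1)
    mean += rt_shift_ms
    mu = np.log(mean) - 0.5 * cfg.rt_sigma**2
    return float(np.exp(rng.normal(mu, cfg.rt_sigma)))


# ---------------------------------------------------------------------------
# public API


def simulate_subject(
    config: SimulationConfig,
    subject_id: str,
    *,
    amp_gain: float = 1.0,
    rt_shift_ms: float = 0.0,
    seed: int | None = None,
) -> tuple[ContinuousRecording, pd.DataFrame]:
    """Simulate one subject's continuous recording and trial-level behavior.

    ``amp_gain`` and ``rt_shift_ms`` carry between-subject variation when
    called from :func:`simulate_cohort`; ``seed`` overrides
    ``config.seed`` for per-subject reproducibility.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    montage = make_montage(config.n_channels)
    sfreq = config.sfreq
    dt_ms = 1000.0 / sfreq

    labels = _balanced_labels(config.n_trials, rng)
    classes = [CLASS_ORDER[i] for i in labels]
    rts = np.array([_draw_rt(tc, config, rt_shift_ms, rng) for tc in classes])
    err_p = np.array(
        [config.err_conflict if tc.conflict else config.err_nonconflict
         for tc in classes]
    )
    correct = rng.random(config.n_trials) >= err_p

    # stimulus onsets: previous response + response-stimulus interval
    rsi = rng.uniform(*config.rsi_range_ms, size=config.n_trials)
    lead_ms = 2000.0
    onsets_ms = np.empty(config.n_trials)
    t = lead_ms
    for i in range(config.n_trials):
        onsets_ms[i] = t
        t += rts[i] + rsi[i]
    n_samples = int(np.ceil((t + 2000.0) / dt_ms))
    onset_samples = np.round(onsets_ms / dt_ms).astype(int)

    data = config.noise_scale * (
        _mixing_matrix(montage)
        @ _pink_noise(rng, len(montage), n_samples, sfreq)
    )

    for i, tc in enumerate(classes):
        for weights, amp, (t0_ms, t1_ms) in _trial_components(
            tc, rts[i], config, montage
        ):
            s0 = onset_samples[i] + int(round(t0_ms / dt_ms))
            s1 = onset_samples[i] + int(round(t1_ms / dt_ms))
            if s0 < 0 or s1 > n_samples:
                raise ValueError(
                    f"component window ({t0_ms}, {t1_ms}) ms falls outside "
                    "the recording"
                )
            data[:, s0:s1] += amp * np.outer(weights, _bump(s1 - s0))

    events = [
        Event(onset_sample=int(onset_samples[i]), trial_class=classes[i],
              correct=bool(correct[i]), rt_ms=float(rts[i]))
        for i in range(config.n_trials)
    ]
    recording = ContinuousRecording(
        subject_id=subject_id, sfreq=sfreq, data=data, events=events,
        montage=montage,
    )
    behavior = pd.DataFrame(
        {
            "subject": subject_id,
            "trial": np.arange(config.n_trials),
            "hand": [tc.hand for tc in classes],
            "conflict": [tc.conflict for tc in classes],
            "rt_ms": rts,
            "correct": correct,
        }
    )
    return recording, behavior


def simulate_cohort(n_subjects: int, config: SimulationConfig) -> Cohort:
    """Simulate a cohort with between-subject variation.

    Per-subject seeds are derived deterministically from ``config.seed``;
    subjects vary in overall component amplitude (lognormal,
    ``amp_spread``) and mean RT (normal, ``rt_spread_ms``).
    """
    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects "
                         "(leave-one-subject-out is undefined otherwise)")
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                     ss.spawn(n_subjects)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    gains = np.exp(rng.normal(0.0, config.amp_spread, size=n_subjects))
    shifts = rng.normal(0.0, config.rt_spread_ms, size=n_subjects)

    recordings, tables = [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        subj_cfg = dataclasses.replace(
            config,
            n1_amplitude=config.n1_amplitude * gains[i],
            conflict_neg_amplitude=config.conflict_neg_amplitude * gains[i],
            motor_lat_amplitude=config.motor_lat_amplitude * gains[i],
        )
        rec, beh = simulate_subject(
            subj_cfg, sid, rt_shift_ms=float(shifts[i]),
            seed=subject_seeds[i],
        )
        recordings.append(rec)
        tables.append(beh)
    return Cohort(
        recordings=recordings,
        behavior=pd.concat(tables, ignore_index=True),
        config=config,
    )


def expected_signal(
    config: SimulationConfig,
    montage: Montage,
    time_ms: np.ndarray,
    csd: bool = True,
) -> np.ndarray:
    """Magnitude of the expected noise-free injected signal per cell.

    For every trial class the deterministic stimulus-locked components
    (N1, conflict negativity) plus the response-locked motor component
    marginalized over the RT distribution are assembled on the stimulus
    time axis; with ``csd`` the surface-Laplacian operator applied by
    the preprocessing maps them into the space the classifier sees.
    Returns the maximum absolute signal over classes, channels x
    timepoints.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    n_t = len(time_ms)
    templates = []
    # marginalize the response-locked component over RT quantiles
    quantiles = np.linspace(0.05, 0.95, 10)
    for tc in CLASS_ORDER:
        sig = np.zeros((len(montage), n_t))

        def add(weights: np.ndarray, amp: float, t0: float, t1: float,
                scale: float = 1.0) -> None:
            sel = (time_ms >= t0) & (time_ms < t1)
            if sel.any():
                sig[:, sel] += scale * amp * np.outer(
                    weights, _bump(int(sel.sum()))
                )

        add(_n1_weights(montage, tc.stimulus_side, config.ipsi_gain),
            -config.n1_amplitude, *config.n1_window_ms)
        n2_gain = 1.0 if tc.conflict else config.nonconflict_neg_gain
        add(_conflict_weights(montage),
            -config.conflict_neg_amplitude * n2_gain,
            *config.conflict_window_ms)
        mean_rt = (config.rt_conflict_ms if tc.conflict
                   else config.rt_nonconflict_ms)
        mu = np.log(mean_rt) - 0.5 * config.rt_sigma**2
        for q in quantiles:
            rt = float(np.exp(mu + config.rt_sigma * norm.ppf(q)))
            add(_motor_weights(montage, tc.hand),
                -config.motor_lat_amplitude, rt - 250.0, rt + 50.0,
                scale=1.0 / len(quantiles))
        templates.append(sig)
    energy = np.abs(np.stack(templates))
    if csd:
        from .preprocess import csd_matrix

        mat = csd_matrix(montage)
        energy = np.abs(np.einsum("ij,kjt->kit", mat, np.stack(templates)))
    return energy.max(axis=0)



def planted_cells(
    config: SimulationConfig,
    montage: Montage,
    time_ms: np.ndarray,
    csd: bool = True,
    energy_fraction: float = 0.8,
) -> np.ndarray:
    """Boolean channels x timepoints mask of ground-truth informative cells.

    The mask is the compact support of the expected injected signal in
    the representation the classifier sees (after the CSD transform when
    ``csd``): the smallest set of cells capturing ``energy_fraction`` of
    the expected squared signal. The surface Laplacian redistributes
    focal sources onto flanking channels, so this support is wider than
    the raw injection channels, but the 80%-energy core remains a small
    fraction of all cells (< 5% under the default desk-scale geometry).
    """
    if not 0.0 < energy_fraction <= 1.0:
        raise ValueError("energy_fraction must lie in (0, 1]")
    energy = expected_signal(config, montage, time_ms, csd=csd) ** 2
    order = np.sort(energy.ravel())[::-1]
    cum = np.cumsum(order)
    k = int(np.searchsorted(cum, energy_fraction * cum[-1])) + 1
    return energy >= order[min(k, energy.size) - 1]
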