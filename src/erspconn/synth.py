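"""Synthetic multichannel EEG with known injected effects.

Generates epoched datasets whose statistical structure matches what the
downstream stages assume: 1/f background activity, band-limited power
modulations confined to channels/windows, phase-lagged inter-channel
coupling, zero-lag mixing, and high-amplitude frontal artifacts.  Every
injected effect is recorded in a ground-truth ledger.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import EpochSet, RawRecording

__all__ = [
    "Montage",
    "EffectSpec",
    "SimulationConfig",
    "make_montage",
    "simulate_dataset",
    "inject_power_modulation",
    "inject_lagged_coupling",
    "apply_mixing",
    "inject_amplitude_artifact",
    "epochs_to_raw",
]

EFFECT_KINDS = (
    "power_modulation",
    "lagged_coupling",
    "zero_lag_mixing",
    "amplitude_artifact",
)

#: fraction of the effect window spent ramping up/down (each side)
_TAPER_FRACTION = 0.05


@dataclass
class Montage:
    """Channel labels with 2-D positions in normalized head coordinates."""

    labels: list[str]
    pos2d: np.ndarray
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos2d = np.asarray(self.pos2d, dtype=np.float64)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.pos2d.shape != (len(self.labels), 2):
            raise ValueError("pos2d must be (n_channels, 2)")
        d = np.linalg.norm(self.pos2d[:, None] - self.pos2d[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d <= 0):
            raise ValueError("montage positions must be pairwise distinct")
        for name, members in self.groups.items():
            missing = set(members) - set(self.labels)
            if missing:
                raise ValueError(f"group {name!r} references unknown labels {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lb) for lb in labels], dtype=int)


# 32-channel layout used by the shipped preset: 30 scalp positions from the
# extended 10-05 system plus the two mastoids.  Coordinates are schematic
# (x → right, y → anterior, head radius ≈ 1).
_STUDY32 = {
    "AFp1": (-0.12, 0.90), "AFp2": (0.12, 0.90),
    "AFF5h": (-0.36, 0.70), "F1": (-0.12, 0.70), "F2": (0.12, 0.70), "AFF6h": (0.36, 0.70),
    "F7": (-0.48, 0.50), "FFC3h": (-0.24, 0.50), "FFC4h": (0.24, 0.50), "F8": (0.48, 0.50),
    "FC5": (-0.48, 0.30), "FC3": (-0.24, 0.30), "FC4": (0.24, 0.30), "FC6": (0.48, 0.30),
    "C3": (-0.36, 0.10), "C1": (-0.12, 0.10), "C2": (0.12, 0.10), "C4": (0.36, 0.10),
    "CP3": (-0.24, -0.10), "CP4": (0.24, -0.10),
    "P7": (-0.48, -0.30), "P3": (-0.24, -0.30), "P4": (0.24, -0.30), "P8": (0.48, -0.30),
    "M1": (-0.42, -0.46), "M2": (0.42, -0.46),
    "PPO1h": (-0.12, -0.50), "PPO2h": (0.12, -0.50),
    "POO1": (-0.12, -0.70), "POO2": (0.12, -0.70),
    "O1": (-0.12, -0.90), "O2": (0.12, -0.90),
}

_PRESETS = {"study32": _STUDY32}


def make_montage(preset_name: str) -> Montage:
    """Return a shipped montage preset.

    ``"study32"`` is the 32-channel layout with seeds POO1/POO2, the four
    frontal channels used for amplitude rejection, and mastoids M1/M2.
    """
    if preset_name not in _PRESETS:
        raise ValueError(
            f"unknown montage preset {preset_name!r}; "
            f"available: {sorted(_PRESETS)}"
        )
    layout = _PRESETS[preset_name]
    labels = list(layout)
    pos = np.array([layout[lb] for lb in labels])
    groups = {
        "frontal": ["AFp1", "AFp2", "AFF5h", "AFF6h"],
        "mastoids": ["M1", "M2"],
        "seeds": ["POO1", "POO2"],
        "scalp": [lb for lb in labels if lb not in ("M1", "M2")],
    }
    return Montage(labels, pos, groups)


@dataclass
class EffectSpec:
    """Parameterization of one injected effect.

    ``magnitude`` is in dB for power modulations, a coupling coefficient in
    [0, 1] for lagged coupling, and peak µV for amplitude artifacts.
    ``window`` is (start, stop) in ms relative to replay onset.  ``trials``
    optionally restricts artifact injection to specific trial indices
    (within the targeted condition's trials).
    """

    kind: str
    channels: list[str]
    band: tuple[float, float] | None = None
    window: tuple[float, float] | None = None
    magnitude: float = 0.0
    phase_lag: float = 0.0
    condition: str | None = None
    trials: list[int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}; one of {EFFECT_KINDS}")
        if not self.channels:
            raise ValueError("effect must name at least one channel")
        if not np.isfinite(self.magnitude):
            raise ValueError("effect magnitude must be finite")
        if self.band is not None:
            lo, hi = self.band
            if not 0 < lo < hi:
                raise ValueError(f"invalid band {self.band}")
        if self.phase_lag != 0.0 and self.band is None:
            raise ValueError("phase_lag requires a band (no carrier frequency)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Epoch layout defaults to the study's: rest −4000..−2000 ms, cue
    −2000..0 ms, replay 0..1000 ms, system adaptation 1000..2000 ms.
    """

    fs: float = 250.0
    n_subjects: int = 16
    n_trials_per_condition: int = 30
    epoch_ms: tuple[float, float] = (-4000.0, 2000.0)
    conditions: tuple[str, str] = ("supportive", "impeding")
    noise_exponent: float = 1.0
    noise_sd_uv: float = 10.0
    white_sd_uv: float = 1.0
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.epoch_ms[0] >= self.epoch_ms[1]:
            raise ValueError("epoch window must be non-empty")
        for eff in self.effects:
            if eff.band is not None and eff.band[1] >= self.fs / 2:
                raise ValueError(
                    f"effect band {eff.band} exceeds Nyquist ({self.fs / 2} Hz)"
                )
            if eff.window is not None:
                lo, hi = eff.window
                if lo < self.epoch_ms[0] or hi > self.epoch_ms[1]:
                    raise ValueError(
                        f"effect window {eff.window} outside epoch {self.epoch_ms}"
                    )

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_ms[1] - self.epoch_ms[0]) / 1000.0 * self.fs))

    def time_axis(self) -> np.ndarray:
        return self.epoch_ms[0] + np.arange(self.n_samples) * (1000.0 / self.fs)


def _powerlaw_noise(
    rng: np.random.Generator, shape: tuple, fs: float, exponent: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0.0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.empty_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC power
    out = np.fft.irfft(spec * shaping, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _bandpass_sos(band: tuple[float, float], fs: float):
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _window_taper(time_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Cosine-tapered indicator of the window; zero strictly outside it."""
    t0, t1 = window
    width = t1 - t0
    ramp = _TAPER_FRACTION * width
    w = np.zeros_like(time_ms)
    inside = (time_ms >= t0) & (time_ms < t1)
    w[inside] = 1.0
    if ramp > 0:
        up = inside & (time_ms < t0 + ramp)
        down = inside & (time_ms >= t1 - ramp)
        w[up] = 0.5 * (1 - np.cos(np.pi * (time_ms[up] - t0) / ramp))
        w[down] = 0.5 * (1 - np.cos(np.pi * (t1 - time_ms[down]) / ramp))
    return w


def _check_effect_channels(effect: EffectSpec, labels: list[str]) -> None:
    missing = set(effect.channels) - set(labels)
    if missing:
        raise ValueError(f"effect channels {sorted(missing)} not in montage")


def _trial_mask(epochs: EpochSet, effect: EffectSpec) -> np.ndarray:
    if effect.condition is None:
        mask = np.ones(epochs.n_trials, dtype=bool)
    else:
        mask = epochs.condition == effect.condition
    if effect.trials is not None:
        sub = np.zeros(epochs.n_trials, dtype=bool)
        cand = np.nonzero(mask)[0]
        for k in effect.trials:
            if not 0 <= k < len(cand):
                raise ValueError(f"trial index {k} out of range for effect")
            sub[cand[k]] = True
        mask = sub
    return mask


def inject_power_modulation(epochs: EpochSet, effect: EffectSpec) -> EpochSet:
    """Scale band power in the stated channels/window by 10^(magnitude/10).

    The band-limited component is extracted by zero-phase band-pass
    filtering and its amplitude rescaled inside a cosine-tapered window, so
    samples outside the declared window (and all other channels) are
    untouched.
    """
    if effect.kind != "power_modulation":
        raise ValueError("effect.kind must be 'power_modulation'")
    if effect.band is None or effect.window is None:
        raise ValueError("power modulation requires band and window")
    _check_effect_channels(effect, epochs.labels)
    if effect.magnitude == 0.0:
        return epochs.copy()
    out = epochs.copy()
    gain = 10.0 ** (effect.magnitude / 10.0)
    amp = np.sqrt(gain) - 1.0
    sos = _bandpass_sos(effect.band, epochs.fs)
    taper = _window_taper(epochs.time_ms, effect.window)
    ch = epochs.channel_indices(effect.channels)
    trials = _trial_mask(epochs, effect)
    sub = out.data[np.ix_(np.nonzero(trials)[0], ch)]
    band_component = signal.sosfiltfilt(sos, sub, axis=-1)
    out.data[np.ix_(np.nonzero(trials)[0], ch)] = sub + amp * taper * band_component
    return out


def inject_lagged_coupling(epochs: EpochSet, effect: EffectSpec) -> EpochSet:
    """Add a delayed, scaled copy of the source's band component to targets.

    ``effect.channels[0]`` is the source; the rest receive the coupling.
    The delay realizes ``phase_lag`` radians at the band's center
    frequency, rounded to whole samples.
    """
    if effect.kind != "lagged_coupling":
        raise ValueError("effect.kind must be 'lagged_coupling'")
    if effect.band is None:
        raise ValueError("lagged coupling requires a band")
    if len(effect.channels) < 2:
        raise ValueError("lagged coupling needs a source and ≥1 target channels")
    _check_effect_channels(effect, epochs.labels)
    out = epochs.copy()
    f_center = 0.5 * (effect.band[0] + effect.band[1])
    delay = int(round(effect.phase_lag / (2.0 * np.pi * f_center) * epochs.fs))
    sos = _bandpass_sos(effect.band, epochs.fs)
    window = effect.window if effect.window is not None else (
        epochs.time_ms[0],
        epochs.time_ms[-1] + 1000.0 / epochs.fs,
    )
    taper = _window_taper(epochs.time_ms, window)
    src = epochs.channel_index(effect.channels[0])
    tgt = epochs.channel_indices(effect.channels[1:])
    trials = np.nonzero(_trial_mask(epochs, effect))[0]
    band_src = signal.sosfiltfilt(sos, epochs.data[trials, src], axis=-1)
    if delay > 0:
        delayed = np.zeros_like(band_src)
        delayed[:, delay:] = band_src[:, :-delay]
    elif delay < 0:
        delayed = np.zeros_like(band_src)
        delayed[:, :delay] = band_src[:, -delay:]
    else:
        delayed = band_src
    contribution = effect.magnitude * taper * delayed
    for j in tgt:
        out.data[trials, j] += contribution
    return out


def apply_mixing(epochs: EpochSet, mixing_matrix: np.ndarray) -> EpochSet:
    """Premultiply every sample vector by a square channel-mixing matrix."""
    m = np.asarray(mixing_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("mixing matrix must be square")
    if m.shape[0] != epochs.n_channels:
        raise ValueError(
            f"mixing matrix size {m.shape[0]} does not match "
            f"{epochs.n_channels} channels"
        )
    out = epochs.copy()
    out.data = np.einsum("ij,tjs->tis", m, epochs.data)
    return out


def inject_amplitude_artifact(
    epochs: EpochSet, effect: EffectSpec
) -> tuple[EpochSet, list[int]]:
    """Add a transient deflection of ``magnitude`` µV peak amplitude.

    Returns the modified epochs and the list of contaminated trial indices
    (absolute indices into the trial axis) for the ground-truth ledger.
    """
    if effect.kind != "amplitude_artifact":
        raise ValueError("effect.kind must be 'amplitude_artifact'")
    _check_effect_channels(effect, epochs.labels)
    out = epochs.copy()
    trials = np.nonzero(_trial_mask(epochs, effect))[0]
    if len(trials) == 0 or effect.magnitude == 0.0:
        return out, []
    window = effect.window if effect.window is not None else (0.0, 400.0)
    sl = out.time_slice(*window)
    n_win = sl.stop - sl.start
    bump = effect.magnitude * np.hanning(n_win)
    ch = epochs.channel_indices(effect.channels)
    for t in trials:
        for j in ch:
            out.data[t, j, sl] += bump
    return out, [int(t) for t in trials]


def simulate_dataset(
    config: SimulationConfig, montage: Montage | None = None
) -> tuple[list[EpochSet], dict]:
    """Generate per-subject epoched datasets plus a ground-truth ledger.

    Identical configs (including seed) yield bit-identical data.  The
    ledger records every injected effect with its parameters and, for
    amplitude artifacts, the contaminated trial indices per subject.
    """
    if montage is None:
        montage = make_montage("study32")
    for eff in config.effects:
        _check_effect_channels(eff, montage.labels)
        if eff.condition is not None and eff.condition not in config.conditions:
            raise ValueError(
                f"effect condition {eff.condition!r} not in {config.conditions}"
            )

    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    n_per = config.n_trials_per_condition
    n_trials = n_per * len(config.conditions)
    condition = np.array(
        [c for c in config.conditions for _ in range(n_per)], dtype=object
    )
    time_ms = config.time_axis()

    ledger: dict = {
        "config": {
            "fs": config.fs,
            "n_subjects": config.n_subjects,
            "n_trials_per_condition": n_per,
            "epoch_ms": list(config.epoch_ms),
            "conditions": list(config.conditions),
            "noise_exponent": config.noise_exponent,
            "noise_sd_uv": config.noise_sd_uv,
            "white_sd_uv": config.white_sd_uv,
            "seed": config.seed,
        },
        "effects": [eff.to_dict() for eff in config.effects],
        "artifact_trials": {},
    }

    datasets: list[EpochSet] = []
    for s, seed_seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seed_seq)
        shape = (n_trials, montage.n_channels, config.n_samples)
        data = config.noise_sd_uv * _powerlaw_noise(
            rng, shape, config.fs, config.noise_exponent
        )
        if config.white_sd_uv > 0:
            data += config.white_sd_uv * rng.standard_normal(shape)
        epochs = EpochSet(data, time_ms, list(montage.labels), condition, config.fs)
        artifact_trials: list[int] = []
        for eff in config.effects:
            if eff.kind == "power_modulation":
                epochs = inject_power_modulation(epochs, eff)
            elif eff.kind == "lagged_coupling":
                epochs = inject_lagged_coupling(epochs, eff)
            elif eff.kind == "amplitude_artifact":
                epochs, hit = inject_amplitude_artifact(epochs, eff)
                artifact_trials.extend(hit)
            elif eff.kind == "zero_lag_mixing":
                # uniform leakage of magnitude between the named channels
                m = np.eye(montage.n_channels)
                idx = montage.indices(eff.channels)
                for a in idx:
                    for b in idx:
                        if a != b:
                            m[a, b] = eff.magnitude
                epochs = apply_mixing(epochs, m)
        ledger["artifact_trials"][str(s)] = sorted(set(artifact_trials))
        datasets.append(epochs)
    return datasets, ledger


def epochs_to_raw(
    epochs: EpochSet,
    gap_ms: float = 1000.0,
    marker_map: dict[str, str] | None = None,
) -> RawRecording:
    """Concatenate epochs into a continuous recording with onset markers.

    Each trial is laid out in order with ``gap_ms`` of zeros between
    trials; a marker is placed at each trial's replay-onset sample (time
    0 ms of the epoch axis).  ``marker_map`` maps condition name to marker
    description (default: the condition name itself).
    """
    gap = int(round(gap_ms / 1000.0 * epochs.fs))
    n_ep = epochs.n_samples
    onset_offset = int(np.searchsorted(epochs.time_ms, -1e-9))
    total = epochs.n_trials * (n_ep + gap) + gap
    data = np.zeros((epochs.n_channels, total))
    events = []
    for t in range(epochs.n_trials):
        start = gap + t * (n_ep + gap)
        data[:, start : start + n_ep] = epochs.data[t]
        name = epochs.condition[t]
        if marker_map is not None:
            name = marker_map[name]
        events.append((start + onset_offset, str(name)))
    return RawRecording(data, epochs.fs, list(epochs.labels), events)
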