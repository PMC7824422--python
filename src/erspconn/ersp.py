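"""Event-related spectral perturbation (ERSP) maps and band × window summaries.

Per-trial time-frequency power is computed with a sliding Hann-window
short-time Fourier transform on a configurable uniform grid (default
≈0.48 Hz × 33.33 ms, 1–45 Hz).  ERSP is divisive baseline normalization of
trial-averaged power on a dB scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EpochSet

__all__ = [
    "DEFAULT_BANDS",
    "DEFAULT_WINDOWS_MS",
    "TrialPower",
    "TimeFreqMap",
    "BandWindowSummary",
    "tf_decompose",
    "ersp_map",
    "band_window_summary",
]

#: frequency bands of interest, Hz (inclusive edges)
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 14.0),
    "beta": (15.0, 35.0),
    "gamma": (35.0, 45.0),
}

#: analysis windows in ms after adaptation onset
DEFAULT_WINDOWS_MS: tuple[tuple[float, float], ...] = (
    (0.0, 250.0),
    (250.0, 500.0),
    (500.0, 750.0),
    (750.0, 1000.0),
)


@dataclass
class TrialPower:
    """Per-trial spectral power on a uniform time-frequency grid."""

    power: np.ndarray  # trials × channels × freqs × times
    freqs: np.ndarray  # Hz
    times: np.ndarray  # ms, window centers
    fs: float
    condition: np.ndarray | None = None


@dataclass
class TimeFreqMap:
    """Trial-averaged, baseline-normalized power in dB."""

    values: np.ndarray  # channels × freqs × times
    freqs: np.ndarray
    times: np.ndarray
    baseline_window: tuple[float, float]
    n_trials_used: int
    labels: list[str] | None = None


@dataclass
class BandWindowSummary:
    """Mean ERSP per channel × band × window (dB)."""

    values: np.ndarray  # channels × bands × windows
    bands: dict[str, tuple[float, float]]
    windows_ms: tuple[tuple[float, float], ...]
    labels: list[str] | None = None


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1)).bit_length()


def tf_decompose(
    epochs: EpochSet,
    f_min: float = 1.0,
    f_max: float = 45.0,
    freq_step: float = 0.48,
    time_step_ms: float = 100.0 / 3.0,
    window_samples: int | None = None,
    kept_only: bool = True,
) -> TrialPower:
    """Sliding-window spectral power for every trial and channel.

    The output grid is configuration, not derived: frequencies run from
    ``f_min`` to ``f_max`` in ``freq_step`` steps (values mapped to the
    nearest zero-padded FFT bin) and times in ``time_step_ms`` steps
    (window centers mapped to the nearest sample).  Epochs are padded by
    half a window of circular wrap so the grid covers the whole epoch;
    wrap keeps stationary statistics unbiased (mirror padding adds
    coherent power at the edges), at the cost of mixing content across
    the epoch boundary within half a window of either edge.
    """
    if f_max >= epochs.fs / 2:
        raise ValueError(
            f"f_max={f_max} exceeds Nyquist ({epochs.fs / 2} Hz)"
        )
    if f_min <= 0 or f_min >= f_max:
        raise ValueError("need 0 < f_min < f_max")
    fs = epochs.fs
    if window_samples is None:
        window_samples = _next_pow2(int(round(fs)))
    half = window_samples // 2
    nfft = _next_pow2(max(window_samples, int(round(fs / freq_step))))
    fft_freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    grid = np.arange(f_min, f_max + 1e-9, freq_step)
    bin_idx = np.array([int(np.argmin(np.abs(fft_freqs - f))) for f in grid])

    t0, t1 = epochs.time_ms[0], epochs.time_ms[-1]
    times = np.arange(t0, t1 + 1e-9, time_step_ms)
    dt = 1000.0 / fs
    centers = np.clip(
        np.round((times - t0) / dt).astype(int), 0, epochs.n_samples - 1
    )

    data = epochs.data[epochs.kept_mask] if kept_only else epochs.data
    condition = (
        epochs.condition[epochs.kept_mask] if kept_only else epochs.condition
    )
    n_trials, n_ch, _ = data.shape
    padded = np.pad(data, ((0, 0), (0, 0), (half, half)), mode="wrap")
    starts = centers  # center c in the original axis starts at c in padded
    window = np.hanning(window_samples)

    power = np.empty((n_trials, n_ch, len(grid), len(times)))
    idx = starts[:, None] + np.arange(window_samples)[None, :]
    for t in range(n_trials):
        segs = padded[t][:, idx] * window  # channels × times × win
        spec = np.fft.rfft(segs, n=nfft, axis=-1)
        power[t] = np.abs(spec[..., bin_idx]).transpose(0, 2, 1) ** 2
    return TrialPower(power, grid, times, fs, condition)


def ersp_map(
    trial_power: TrialPower,
    baseline_window: tuple[float, float] = (-4000.0, -2000.0),
    labels: list[str] | None = None,
) -> TimeFreqMap:
    """Baseline-normalized, trial-averaged power in dB.

    ERSP(c, f, t) = 10·log10( meanTrials P(c,f,t) / meanBaselineTime
    meanTrials P(c,f,·) ).
    """
    times = trial_power.times
    in_base = (times >= baseline_window[0] - 1e-9) & (
        times < baseline_window[1] - 1e-9
    )
    if not in_base.any():
        raise ValueError(f"baseline window {baseline_window} outside epoch")
    if trial_power.power.shape[0] == 0:
        raise ValueError("no trials to average")
    mean_power = trial_power.power.mean(axis=0)  # channels × freqs × times
    baseline = mean_power[:, :, in_base].mean(axis=-1)  # channels × freqs
    bad = np.argwhere(baseline <= 0)
    if bad.size:
        c, f = bad[0]
        raise ValueError(
            f"zero baseline power at channel index {c}, "
            f"{trial_power.freqs[f]:.2f} Hz"
        )
    values = 10.0 * np.log10(mean_power / baseline[:, :, None])
    return TimeFreqMap(
        values,
        trial_power.freqs.copy(),
        times.copy(),
        tuple(baseline_window),
        int(trial_power.power.shape[0]),
        labels,
    )


def band_window_summary(
    tf_map: TimeFreqMap,
    bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
    windows_ms: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_MS,
    adaptation_onset_ms: float = 1000.0,
) -> BandWindowSummary:
    """Mean ERSP per channel over band bins × window bins.

    Window times are relative to adaptation onset (epoch time
    ``adaptation_onset_ms``).
    """
    if tf_map.times[-1] < adaptation_onset_ms + windows_ms[-1][1] - 1e-9 - (
        tf_map.times[1] - tf_map.times[0]
    ):
        raise ValueError("time-frequency map does not cover the adaptation phase")
    n_ch = tf_map.values.shape[0]
    out = np.full((n_ch, len(bands), len(windows_ms)), np.nan)
    for bi, (lo, hi) in enumerate(bands.values()):
        fmask = (tf_map.freqs >= lo - 1e-9) & (tf_map.freqs <= hi + 1e-9)
        if not fmask.any():
            raise ValueError(f"no frequency bins in band {lo}-{hi} Hz")
        for wi, (w0, w1) in enumerate(windows_ms):
            t0 = adaptation_onset_ms + w0
            t1 = adaptation_onset_ms + w1
            tmask = (tf_map.times >= t0 - 1e-9) & (tf_map.times < t1 - 1e-9)
            if not tmask.any():
                raise ValueError(f"no time bins in window {w0}-{w1} ms")
            out[:, bi, wi] = tf_map.values[:, fmask][:, :, tmask].mean(axis=(1, 2))
    return BandWindowSummary(out, dict(bands), tuple(windows_ms), tf_map.labels)
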