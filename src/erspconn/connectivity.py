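"""Multitaper coherency, corrected imaginary coherence, and ER-ciCOH.

Cross-spectra are estimated with Slepian (DPSS) tapers; coherency is the
normalized cross-spectrum; ciCOH rescales its imaginary part by
sqrt(1 − Re²) to compensate the spatial bias of plain imaginary coherence;
ER-ciCOH contrasts |ciCOH| in a post-stimulus window of interest against a
pre-stimulus baseline, per trial, seed-averaged into a whole-head map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows as sp_windows

from .ersp import DEFAULT_BANDS
from .types import EpochSet

__all__ = [
    "MultitaperConfig",
    "CoherencySet",
    "ErCicohMap",
    "dpss_tapers",
    "cross_spectrum",
    "coherency",
    "cicoh",
    "fisher_z",
    "er_contrast",
    "er_cicoh",
]


@dataclass
class MultitaperConfig:
    """Multitaper estimation parameters.

    ``n_tapers`` follows 2·bandwidth_param − 1; the FFT length is the next
    power of two ≥ the window length in samples.
    """

    window_ms: float = 1000.0
    step_ms: float = 100.0
    bandwidth_param: float = 3.0
    window_pooling: bool = False

    @property
    def n_tapers(self) -> int:
        return int(2 * self.bandwidth_param - 1)

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_ms / 1000.0 * fs))

    def step_samples(self, fs: float) -> int:
        return max(1, int(round(self.step_ms / 1000.0 * fs)))

    def nfft(self, fs: float) -> int:
        n = self.window_samples(fs)
        return 1 << (n - 1).bit_length()

    def freqs(self, fs: float) -> np.ndarray:
        return np.fft.rfftfreq(self.nfft(fs), d=1.0 / fs)


@dataclass
class CoherencySet:
    """Per-trial complex coherency and ciCOH per channel pair × frequency."""

    coh: np.ndarray  # trials × pairs × freqs, complex
    cicoh: np.ndarray  # trials × pairs × freqs, real
    pairs: list[tuple[int, int]]
    freqs: np.ndarray


@dataclass
class ErCicohMap:
    """Seed-averaged ER-ciCOH per electrode × band for one condition."""

    values: np.ndarray  # electrodes × bands; NaN at seed electrodes
    labels: list[str]
    bands: dict[str, tuple[float, float]]
    seeds: list[str]
    toi_window: tuple[float, float]
    baseline_window: tuple[float, float]
    n_trials: int = 0
    low_baseline_fraction: float = 0.0


def dpss_tapers(
    n_samples: int, bandwidth_param: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal Slepian tapers and their concentration eigenvalues.

    Returns K = 2·bandwidth_param − 1 tapers of unit energy, ordered by
    strictly decreasing concentration.
    """
    k = int(2 * bandwidth_param - 1)
    if k < 1:
        raise ValueError("bandwidth_param must give at least one taper")
    if k >= n_samples:
        raise ValueError(f"{k} tapers require more than {n_samples} samples")
    if n_samples < 2 * k:
        raise ValueError("need n_samples ≥ 2·n_tapers for stable tapers")
    tapers, ratios = sp_windows.dpss(
        n_samples, bandwidth_param, Kmax=k, return_ratios=True, norm=2
    )
    return tapers, ratios


def _tapered_fft(
    segment: np.ndarray, tapers: np.ndarray, nfft: int
) -> np.ndarray:
    """FFT of each channel under each taper: channels × tapers × freqs."""
    return np.fft.rfft(segment[:, None, :] * tapers[None, :, :], n=nfft, axis=-1)


def cross_spectrum(
    segment: np.ndarray, config: MultitaperConfig, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper cross-spectral matrix of one segment.

    ``segment`` is channels × samples.  The estimate averages over tapers
    and over every sliding window position that fits.  Returns ``(S,
    freqs)`` with S Hermitian, channels × channels × freqs.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 2:
        raise ValueError("segment must be 2-D (channels × samples)")
    if np.isnan(segment).any():
        raise ValueError("segment contains NaN")
    win = config.window_samples(fs)
    if segment.shape[1] < win:
        raise ValueError(
            f"segment length {segment.shape[1]} < window {win} samples"
        )
    step = config.step_samples(fs)
    nfft = config.nfft(fs)
    tapers, _ = dpss_tapers(win, config.bandwidth_param)
    starts = range(0, segment.shape[1] - win + 1, step)
    s = None
    n_win = 0
    for start in starts:
        x = _tapered_fft(segment[:, start : start + win], tapers, nfft)
        contrib = np.einsum("ikf,jkf->ijf", x, np.conj(x)) / tapers.shape[0]
        s = contrib if s is None else s + contrib
        n_win += 1
    s = s / n_win
    return s, config.freqs(fs)


def coherency(s: np.ndarray) -> np.ndarray:
    """Normalized cross-spectrum COH_ij = S_ij / sqrt(S_ii·S_jj)."""
    auto = np.real(np.einsum("iif->if", s))
    bad = np.argwhere(auto <= 0)
    if bad.size:
        c, f = bad[0]
        raise ValueError(
            f"zero auto-spectrum at channel index {c}, frequency bin {f}"
        )
    norm = np.sqrt(auto[:, None, :] * auto[None, :, :])
    return s / norm


def cicoh(
    coh: np.ndarray, return_degenerate: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Corrected imaginary coherence: Im(COH) / sqrt(1 − Re(COH)²).

    Entries with |Re(COH)| = 1 (pure real coherency, e.g. a channel with
    itself) are degenerate and set to 0; request ``return_degenerate`` for
    the mask.
    """
    re = np.real(coh)
    im = np.imag(coh)
    degenerate = np.abs(re) >= 1.0 - 1e-6
    re_safe = np.clip(re, -(1.0 - 1e-6), 1.0 - 1e-6)
    out = im / np.sqrt(1.0 - re_safe**2)
    out = np.where(degenerate, 0.0, out)
    if return_degenerate:
        return out, degenerate
    return out


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher z-transform (atanh); |values| ≥ 1 are clipped with a warning."""
    values = np.asarray(values, dtype=np.float64)
    clip = 1.0 - 1e-12
    if np.any(np.abs(values) >= 1.0):
        warnings.warn("values with |x| ≥ 1 clipped before atanh", stacklevel=2)
        values = np.clip(values, -clip, clip)
    return np.arctanh(values)


def er_contrast(
    toi: np.ndarray | float, baseline: np.ndarray | float, eps: float = 1e-3
) -> np.ndarray | float:
    """Event-related contrast (TOI − baseline) / max(baseline, eps)."""
    return (np.asarray(toi) - np.asarray(baseline)) / np.maximum(
        np.asarray(baseline), eps
    )


def _band_masks(
    freqs: np.ndarray, bands: dict[str, tuple[float, float]]
) -> list[np.ndarray]:
    masks = []
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        if not m.any():
            raise ValueError(f"no frequency bins in band {name} ({lo}-{hi} Hz)")
        masks.append(m)
    return masks


def _seed_abs_cicoh(
    segment: np.ndarray,
    seed_idx: np.ndarray,
    tapers: np.ndarray,
    nfft: int,
    step: int,
    window_pooling: bool,
) -> np.ndarray:
    """|ciCOH| between each seed and every channel: seeds × channels × freqs.

    The taper ensemble (optionally pooled over sliding windows) forms the
    cross-spectral average for this single segment.
    """
    win = tapers.shape[1]
    if window_pooling:
        starts = list(range(0, segment.shape[1] - win + 1, step))
    else:
        starts = [0]
    xs = [
        _tapered_fft(segment[:, s0 : s0 + win], tapers, nfft) for s0 in starts
    ]
    x = np.concatenate(xs, axis=1)  # channels × (tapers·windows) × freqs
    auto = np.einsum("ikf,ikf->if", x, np.conj(x)).real
    cross = np.einsum("skf,jkf->sjf", x[seed_idx], np.conj(x))
    norm = np.sqrt(auto[seed_idx][:, None, :] * auto[None, :, :])
    coh = cross / np.maximum(norm, 1e-300)
    return np.abs(cicoh(coh))


def er_cicoh(
    epochs: EpochSet,
    seeds: tuple[str, ...] = ("POO1", "POO2"),
    config: MultitaperConfig | None = None,
    bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
    toi_window: tuple[float, float] = (1000.0, 2000.0),
    baseline_window: tuple[float, float] = (-3000.0, -2000.0),
    eps: float = 1e-3,
    fisher_before_contrast: bool = False,
    condition: str | None = None,
) -> ErCicohMap:
    """Seed-based event-related ciCOH map for one condition.

    Per trial and seed–electrode pair, |ciCOH| is band-averaged over FOI
    bins in the TOI and baseline windows and contrasted as
    (TOI − baseline) / max(baseline, eps); the contrast is averaged over
    trials, then over seeds.  Seed electrodes are NaN in the output.
    """
    if config is None:
        config = MultitaperConfig()
    if condition is not None:
        epochs = epochs.select_condition(condition)
    else:
        sel = epochs.kept_mask
        epochs = EpochSet(
            epochs.data[sel],
            epochs.time_ms,
            list(epochs.labels),
            epochs.condition[sel],
            epochs.fs,
        )
    if epochs.n_trials == 0:
        raise ValueError("no kept trials for ER-ciCOH")
    if abs((toi_window[1] - toi_window[0]) - (baseline_window[1] - baseline_window[0])) > 1e-6:
        raise ValueError("TOI and baseline windows must have equal length")
    fs = epochs.fs
    win = config.window_samples(fs)
    toi_sl = epochs.time_slice(*toi_window)
    base_sl = epochs.time_slice(*baseline_window)
    for name, sl in (("TOI", toi_sl), ("baseline", base_sl)):
        if sl.stop - sl.start < win:
            raise ValueError(f"{name} window shorter than multitaper window")
    seed_idx = epochs.channel_indices(seeds)
    tapers, _ = dpss_tapers(win, config.bandwidth_param)
    nfft = config.nfft(fs)
    freqs = config.freqs(fs)
    masks = _band_masks(freqs, bands)
    step = config.step_samples(fs)

    n_ch = epochs.n_channels
    non_seed = np.ones(n_ch, dtype=bool)
    non_seed[seed_idx] = False
    contrasts = np.empty((epochs.n_trials, len(seeds), n_ch, len(bands)))
    low_baseline = 0
    for t in range(epochs.n_trials):
        vals = {}
        for key, sl in (("toi", toi_sl), ("base", base_sl)):
            ab = _seed_abs_cicoh(
                epochs.data[t, :, sl],
                seed_idx,
                tapers,
                nfft,
                step,
                config.window_pooling,
            )
            if fisher_before_contrast:
                ab = fisher_z(np.clip(ab, 0.0, 1.0 - 1e-12))
            vals[key] = np.stack([ab[:, :, m].mean(axis=-1) for m in masks], axis=-1)
        base = vals["base"]
        if np.any(base[:, non_seed, :] < eps):
            low_baseline += 1
        contrasts[t] = er_contrast(vals["toi"], base, eps)
    frac = low_baseline / epochs.n_trials
    if frac > 0.2:
        warnings.warn(
            f"baseline |ciCOH| below eps={eps} in {low_baseline} of "
            f"{epochs.n_trials} trials",
            stacklevel=2,
        )
    per_seed = contrasts.mean(axis=0)  # seeds × channels × bands
    values = per_seed.mean(axis=0)  # channels × bands
    values[seed_idx, :] = np.nan
    return ErCicohMap(
        values,
        list(epochs.labels),
        dict(bands),
        list(seeds),
        tuple(toi_window),
        tuple(baseline_window),
        epochs.n_trials,
        frac,
    )


def trial_coherency(
    epochs: EpochSet,
    pairs: list[tuple[int, int]],
    window: tuple[float, float],
    config: MultitaperConfig | None = None,
) -> CoherencySet:
    """Per-trial coherency and ciCOH for explicit channel pairs.

    Convenience used by simulation checks: estimates each trial's
    cross-spectrum in ``window`` from the taper ensemble and normalizes.
    """
    if config is None:
        config = MultitaperConfig()
    sl = epochs.time_slice(*window)
    fs = epochs.fs
    win = config.window_samples(fs)
    if sl.stop - sl.start < win:
        raise ValueError("window shorter than multitaper window")
    tapers, _ = dpss_tapers(win, config.bandwidth_param)
    nfft = config.nfft(fs)
    freqs = config.freqs(fs)
    step = config.step_samples(fs)
    coh_out = np.empty((epochs.n_trials, len(pairs), len(freqs)), dtype=complex)
    for t in range(epochs.n_trials):
        seg = epochs.data[t, :, sl]
        if config.window_pooling:
            starts = list(range(0, seg.shape[1] - win + 1, step))
        else:
            starts = [0]
        xs = [_tapered_fft(seg[:, s0 : s0 + win], tapers, nfft) for s0 in starts]
        x = np.concatenate(xs, axis=1)
        auto = np.einsum("ikf,ikf->if", x, np.conj(x)).real
        for p, (i, j) in enumerate(pairs):
            sij = np.einsum("kf,kf->f", x[i], np.conj(x[j]))
            coh_out[t, p] = sij / np.sqrt(
                np.maximum(auto[i] * auto[j], 1e-300)
            )
    return CoherencySet(coh_out, cicoh(coh_out), list(pairs), freqs)
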