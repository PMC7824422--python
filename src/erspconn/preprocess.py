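"""Preprocessing chain for continuous and epoched EEG.

Stages: per-channel linear detrend, re-reference to mathematically linked
mastoids, zero-phase band-pass FIR filtering, stimulus-locked segmentation,
frontal amplitude-based trial rejection, and ICA artifact removal using a
logistic infomax algorithm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .types import EpochSet, RawRecording

__all__ = [
    "detrend_and_reference",
    "bandpass_zero_phase",
    "segment",
    "reject_amplitude",
    "IcaModel",
    "ica_fit",
    "ica_flag",
    "ica_remove",
]


def detrend_and_reference(
    raw: RawRecording, mastoid_labels: tuple[str, str] = ("M1", "M2")
) -> RawRecording:
    """Remove per-channel linear trends and re-reference to linked mastoids.

    The mean of the two mastoid channels is subtracted from every channel,
    so after the operation ``(mastoid1 + mastoid2) / 2`` is identically
    zero.
    """
    for lb in mastoid_labels:
        if lb not in raw.labels:
            raise ValueError(f"mastoid channel {lb!r} not in recording")
    out = raw.copy()
    out.data = signal.detrend(out.data, axis=-1, type="linear")
    m1 = out.channel_index(mastoid_labels[0])
    m2 = out.channel_index(mastoid_labels[1])
    reference = 0.5 * (out.data[m1] + out.data[m2])
    out.data -= reference[None, :]
    return out


def _fir_taps(fs: float, transition_hz: float, n_samples: int) -> int:
    # Hamming-window design rule: ~3.3 / normalized transition width
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    # keep filtfilt's edge padding feasible on short recordings
    max_taps = max(3, (n_samples - 1) // 3)
    numtaps = min(numtaps, max_taps)
    return numtaps + 1 if numtaps % 2 == 0 else numtaps


def bandpass_zero_phase(
    raw: RawRecording,
    f_lo: float = 0.5,
    f_hi: float = 48.0,
    transition_hz: float = 0.5,
) -> RawRecording:
    """Zero-phase band-pass using a linear-phase windowed-sinc FIR.

    The filter is applied forward and backward (``filtfilt``) for zero net
    phase; the order is set by the transition width at the low edge.
    """
    if not 0 < f_lo < f_hi < raw.fs / 2:
        raise ValueError(
            f"need 0 < f_lo < f_hi < fs/2; got f_lo={f_lo}, f_hi={f_hi}, "
            f"fs={raw.fs}"
        )
    numtaps = _fir_taps(raw.fs, transition_hz, raw.n_samples)
    taps = signal.firwin(
        numtaps, [f_lo, f_hi], pass_zero=False, fs=raw.fs, window="hamming"
    )
    out = raw.copy()
    out.data = signal.filtfilt(taps, [1.0], out.data, axis=-1)
    return out


def segment(
    raw: RawRecording,
    marker_map: dict[str, str],
    epoch_ms: tuple[float, float] = (-4000.0, 2000.0),
) -> EpochSet:
    """Cut one epoch per condition-tagged replay-onset marker.

    Epoch time 0 is the marker sample.  Markers whose epoch would run past
    either recording edge are skipped (counted in a warning).  Markers not
    named in ``marker_map`` are ignored.  No markers yields an empty
    EpochSet.
    """
    n_pre = int(round(-epoch_ms[0] / 1000.0 * raw.fs))
    n_post = int(round(epoch_ms[1] / 1000.0 * raw.fs))
    n_ep = n_pre + n_post
    time_ms = epoch_ms[0] + np.arange(n_ep) * (1000.0 / raw.fs)

    picks, conditions, skipped = [], [], 0
    for sample, name in raw.events:
        if name not in marker_map:
            continue
        if sample - n_pre < 0 or sample + n_post > raw.n_samples:
            skipped += 1
            continue
        picks.append(sample)
        conditions.append(marker_map[name])
    if skipped:
        warnings.warn(
            f"skipped {skipped} marker(s) too close to recording edges",
            stacklevel=2,
        )
    data = np.empty((len(picks), raw.n_channels, n_ep))
    for t, sample in enumerate(picks):
        data[t] = raw.data[:, sample - n_pre : sample + n_post]
    return EpochSet(
        data, time_ms, list(raw.labels), np.array(conditions, dtype=object), raw.fs
    )


def reject_amplitude(
    epochs: EpochSet,
    channels: list[str] = ("AFp1", "AFp2", "AFF5h", "AFF6h"),
    threshold_uv: float = 200.0,
    mode: str = "mean_deviation",
) -> EpochSet:
    """Mark trials whose deviation on any listed channel exceeds threshold.

    ``mode="mean_deviation"`` measures max |x − per-channel epoch mean|;
    ``mode="peak_to_peak"`` measures max(x) − min(x) per channel.  A trial
    is rejected strictly above the threshold.  Signal values are never
    mutated — only ``kept_mask`` changes (ANDed with the existing mask).
    """
    channels = list(channels)
    if not channels:
        raise ValueError("channel group for rejection is empty")
    idx = epochs.channel_indices(channels)
    sub = epochs.data[:, idx, :]
    if mode == "mean_deviation":
        dev = np.abs(sub - sub.mean(axis=-1, keepdims=True)).max(axis=(-2, -1))
    elif mode == "peak_to_peak":
        dev = (sub.max(axis=-1) - sub.min(axis=-1)).max(axis=-1)
    else:
        raise ValueError(f"unknown rejection mode {mode!r}")
    out = epochs.copy()
    out.kept_mask = out.kept_mask & (dev <= threshold_uv)
    return out


# --------------------------------------------------------------------------
# ICA


@dataclass
class IcaModel:
    """Fitted ICA decomposition with per-component artifact flags."""

    unmixing: np.ndarray  # components × channels
    mixing: np.ndarray  # channels × components
    labels: list[str]
    component_flags: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_flags:
            self.component_flags = [None] * self.unmixing.shape[0]

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def flagged(self) -> list[int]:
        return [k for k, f in enumerate(self.component_flags) if f is not None]

    def sources(self, epochs: EpochSet) -> np.ndarray:
        """Per-trial component activations, trials × components × samples."""
        return np.einsum("kc,tcs->tks", self.unmixing, epochs.data)


def _logistic_infomax(
    x_white: np.ndarray,
    rng: np.random.Generator,
    lrate: float | None = None,
    max_iter: int = 500,
    w_change_tol: float = 1e-7,
    anneal: float = 0.9,
    anneal_deg: float = 60.0,
) -> np.ndarray:
    """Natural-gradient logistic infomax on whitened data (comps × samples).

    Block stochastic updates with learning-rate annealing when the update
    direction swings by more than ``anneal_deg`` degrees, following the
    classic runica schedule.
    """
    n_comp, n_samples = x_white.shape
    if lrate is None:
        lrate = 0.00065 / np.log(n_comp) if n_comp > 1 else 0.01
    block = int(np.ceil(min(5.0 * np.log(n_samples), 0.3 * n_samples)))
    w = np.eye(n_comp)
    eye = np.eye(n_comp)
    old_w = w.copy()
    old_delta = None
    for _ in range(max_iter):
        perm = rng.permutation(n_samples)
        for start in range(0, n_samples - block + 1, block):
            xb = x_white[:, perm[start : start + block]]
            u = w @ xb
            y = 1.0 / (1.0 + np.exp(-u))
            grad = eye + (1.0 - 2.0 * y) @ u.T / block
            w = w + lrate * grad @ w
            if not np.isfinite(w).all() or np.max(np.abs(w)) > 1e8:
                # blow-up: restart with a smaller rate
                w = np.eye(n_comp)
                old_w = w.copy()
                old_delta = None
                lrate *= 0.5
                break
        delta = (w - old_w).ravel()
        change = float(delta @ delta)
        if old_delta is not None and change > 0:
            cos = (delta @ old_delta) / np.sqrt(
                change * float(old_delta @ old_delta) + 1e-300
            )
            angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
            if angle > anneal_deg:
                lrate *= anneal
        old_delta = delta
        old_w = w.copy()
        if change < w_change_tol:
            break
    return w


def ica_fit(
    epochs: EpochSet,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
    min_samples_factor: float = 20.0,
) -> IcaModel:
    """Fit logistic-infomax ICA on the kept trials.

    Data are concatenated across kept trials, centered and PCA-whitened
    before rotation.  Requires at least ``min_samples_factor × n_channels²``
    samples (identifiability floor) and full-rank data.
    """
    kept = epochs.data[epochs.kept_mask]
    n_trials, n_ch, n_samp = kept.shape
    if n_components is None:
        n_components = n_ch
    if n_trials * n_samp < min_samples_factor * n_ch**2:
        raise ValueError(
            f"too few samples for ICA: {n_trials * n_samp} < "
            f"{min_samples_factor} × {n_ch}²"
        )
    x = kept.transpose(1, 0, 2).reshape(n_ch, -1)
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals[0], 1.0) * 1e-10
    rank = int(np.sum(evals > tol))
    if rank < n_components:
        raise ValueError(
            f"data rank {rank} < {n_components} requested components; "
            "reduce n_components (rank-deficient data)"
        )
    d = evals[:n_components]
    e = evecs[:, :n_components]
    whitener = (e / np.sqrt(d)).T  # components × channels
    x_white = whitener @ x
    rng = np.random.default_rng(seed)
    w_rot = _logistic_infomax(x_white, rng, max_iter=max_iter)
    unmixing = w_rot @ whitener
    mixing = np.linalg.pinv(unmixing)
    return IcaModel(unmixing, mixing, list(epochs.labels))


def ica_flag(
    model: IcaModel,
    epochs: EpochSet,
    montage,
    frontal_group: str = "frontal",
    frontal_ratio: float = 2.0,
    low_freq_fraction: float = 0.5,
    low_freq_hz: float = 4.0,
    high_slope_db: float = 0.0,
    edge_radius: float = 0.75,
    focality: float = 0.4,
    overrides: dict[int, str | None] | None = None,
) -> IcaModel:
    """Flag artifact components by deterministic heuristics.

    * ocular: topography dominated by the frontal channel group AND a
      large fraction of source power below ``low_freq_hz``.
    * muscular: spectrum rising above 20 Hz AND a focal topography peaked
      at a scalp-edge electrode.

    ``overrides`` maps component index to a reason (or None to clear a
    flag), providing the manual-selection path.
    """
    flags: list[str | None] = [None] * model.n_components
    src = model.sources(epochs)[epochs.kept_mask]  # trials × comps × samples
    fs = epochs.fs
    nper = min(epochs.n_samples, int(2 * fs))
    freqs, psd = signal.welch(
        src.transpose(1, 0, 2).reshape(model.n_components, -1),
        fs=fs,
        nperseg=nper,
        axis=-1,
    )
    frontal_idx = [epochs.channel_index(lb) for lb in montage.groups[frontal_group]]
    radius = np.linalg.norm(montage.pos2d, axis=1)
    for k in range(model.n_components):
        topo = np.abs(model.mixing[:, k])
        topo_n = topo / (topo.sum() + 1e-300)
        frontal_dom = topo[frontal_idx].mean() / (topo.mean() + 1e-300)
        low = psd[k, freqs < low_freq_hz].sum() / (psd[k].sum() + 1e-300)
        if frontal_dom > frontal_ratio and low > low_freq_fraction:
            flags[k] = "ocular"
            continue
        band_hi = psd[k, (freqs >= 25) & (freqs <= min(45, fs / 2 - 1))].mean()
        band_mid = psd[k, (freqs >= 8) & (freqs < 20)].mean()
        slope_db = 10 * np.log10((band_hi + 1e-300) / (band_mid + 1e-300))
        peak_ch = int(np.argmax(topo_n))
        if (
            slope_db > high_slope_db
            and radius[peak_ch] > edge_radius
            and topo_n[peak_ch] > focality
        ):
            flags[k] = "muscular"
    if overrides:
        for k, reason in overrides.items():
            flags[k] = reason
    return IcaModel(
        model.unmixing.copy(), model.mixing.copy(), list(model.labels), flags
    )


def ica_remove(model: IcaModel, epochs: EpochSet) -> EpochSet:
    """Reconstruct the epochs excluding flagged components.

    With no flagged components this is the identity (within float
    tolerance) since mixing ∘ unmixing = I on the retained subspace.
    """
    keep = [k for k in range(model.n_components) if k not in model.flagged]
    proj = model.mixing[:, keep] @ model.unmixing[keep, :]
    out = epochs.copy()
    out.data = np.einsum("cd,tds->tcs", proj, epochs.data)
    return out
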