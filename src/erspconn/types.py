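"""Core data containers shared across pipeline stages.

All signal amplitudes are in microvolts (µV); all epoch time axes are in
milliseconds with 0 ms at replay onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawRecording", "EpochSet"]


@dataclass
class RawRecording:
    """Continuous multichannel recording with event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names, unique.
    events : list of (int, str)
        ``(sample_index, marker_name)`` pairs, sample indices within bounds.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        n = self.data.shape[1]
        for idx, name in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event {name!r} at sample {idx} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(), self.fs, list(self.labels), list(self.events)
        )


@dataclass
class EpochSet:
    """Epoched data: trials × channels × samples.

    ``time_ms`` is a uniformly spaced axis with step ``1000 / fs`` ms and
    0 ms at replay onset.  ``kept_mask`` marks trials surviving rejection;
    data itself is never mutated by rejection.
    """

    data: np.ndarray
    time_ms: np.ndarray
    labels: list[str]
    condition: np.ndarray
    fs: float
    kept_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials × channels × samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.labels) != n_channels:
            raise ValueError("label count does not match channel axis")
        if self.time_ms.shape != (n_samples,):
            raise ValueError("time axis length does not match sample axis")
        if n_samples > 1:
            steps = np.diff(self.time_ms)
            if not np.all(steps > 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(steps, 1000.0 / self.fs, atol=1e-6):
                raise ValueError("time axis step must equal 1000/fs ms")
        if len(self.condition) != n_trials:
            raise ValueError("condition length does not match trial axis")
        if self.kept_mask is None:
            self.kept_mask = np.ones(n_trials, dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (n_trials,):
                raise ValueError("kept_mask length does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def channel_indices(self, labels) -> np.ndarray:
        return np.array([self.channel_index(lb) for lb in labels], dtype=int)

    def time_slice(self, t_start_ms: float, t_stop_ms: float) -> slice:
        """Half-open sample slice covering ``[t_start_ms, t_stop_ms)``."""
        sel = np.nonzero(
            (self.time_ms >= t_start_ms - 1e-9) & (self.time_ms < t_stop_ms - 1e-9)
        )[0]
        if sel.size == 0:
            raise ValueError(
                f"window [{t_start_ms}, {t_stop_ms}) ms outside epoch "
                f"[{self.time_ms[0]}, {self.time_ms[-1]}]"
            )
        return slice(int(sel[0]), int(sel[-1]) + 1)

    def select_condition(self, condition: str, kept_only: bool = True) -> "EpochSet":
        mask = self.condition == condition
        if kept_only:
            mask = mask & self.kept_mask
        return EpochSet(
            self.data[mask],
            self.time_ms.copy(),
            list(self.labels),
            self.condition[mask],
            self.fs,
            self.kept_mask[mask].copy(),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.time_ms.copy(),
            list(self.labels),
            self.condition.copy(),
            self.fs,
            self.kept_mask.copy(),
        )

    def with_data(self, data: np.ndarray) -> "EpochSet":
        out = self.copy()
        out.data = np.asarray(data, dtype=np.float64)
        if out.data.shape != self.data.shape:
            raise ValueError("replacement data must keep the original shape")
        return out
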