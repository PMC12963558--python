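"""In-memory containers for multichannel EEG segments and 1-s epochs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .montage import ChannelMontage, default_montage


@dataclass
class Recording:
    """A channels x samples EEG matrix in microvolts.

    ``meta`` carries subject/group/condition/kind labels plus, for synthetic
    recordings, the injected blink and spike event times (ground truth used
    by the artifact-handling tests).
    """

    samples: np.ndarray          # (n_channels, n_samples), uV
    fs: float                    # Hz
    montage: ChannelMontage = field(default_factory=default_montage)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.samples.shape[0]} rows for "
                f"{self.montage.n_channels} montage labels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.montage.index(label)]

    def copy(self) -> "Recording":
        return Recording(self.samples.copy(), self.fs, self.montage,
                         dict(self.meta))


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs with a per-epoch rejection mask.

    ``artifact_mask[e]`` is True when epoch ``e`` is rejected; band-power
    routines ignore rejected epochs.
    """

    epochs: np.ndarray           # (n_epochs, n_channels, n_samples_per_epoch)
    fs: float
    montage: ChannelMontage
    epoch_length: float = 1.0
    artifact_mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        expected = int(round(self.fs * self.epoch_length))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epochs have {self.epochs.shape[2]} samples, expected {expected}"
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.epochs.shape[0], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.epochs.shape[0],):
                raise ValueError("artifact_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_clean(self) -> int:
        return int((~self.artifact_mask).sum())

    def clean(self) -> np.ndarray:
        """Return the clean (unrejected) epochs as an array view."""
        return self.epochs[~self.artifact_mask]

    def copy(self) -> "EpochSet":
        return EpochSet(self.epochs.copy(), self.fs, self.montage,
                        self.epoch_length, self.artifact_mask.copy(),
                        dict(self.meta))
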