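"""Core in-memory containers shared across the pipeline.

An :class:`EMGRecording` holds raw (signed) multi-channel surface EMG in
sample time; a :class:`GaitCycleMatrix` holds the per-subject normalized
linear-envelope matrix in gait-cycle time (rows = percent of cycle,
columns = muscles), the object the factorization operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

#: Muscle channel order used throughout: gastrocnemius medialis, tibialis
#: anterior, vastus lateralis, gluteus maximus, biceps femoris.
DEFAULT_CHANNELS: tuple[str, ...] = ("GA", "TA", "VL", "GM", "BF")


@dataclass(frozen=True)
class EMGRecording:
    """Raw multi-channel EMG time series.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``, signed amplitude in
        arbitrary units.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        One unique muscle label per column.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if samples.shape[0] < 2:
            raise ValueError("recording must contain at least 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        labels = tuple(self.channel_labels)
        if len(labels) != samples.shape[1]:
            raise ValueError(
                f"{len(labels)} channel labels for {samples.shape[1]} channels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "EMGRecording":
        """Return a copy with the same metadata and new sample values."""
        return EMGRecording(samples, self.sampling_rate, self.channel_labels)


@dataclass(frozen=True)
class GaitCycleMatrix:
    """Per-subject normalized envelope matrix over one averaged gait cycle.

    ``values[t, m]`` is muscle ``m``'s envelope at cycle point ``t``
    expressed as a fraction of that muscle's per-cycle maximum, so all
    entries lie in [0, 1] and each column attains 1.

    ``provenance`` records how the matrix was produced (filter settings,
    cycle count, ...); it does not participate in equality.
    """

    values: np.ndarray
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    provenance: Mapping[str, Any] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (n_points, n_muscles) array")
        labels = tuple(self.channel_labels)
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} channel labels for {values.shape[1]} muscles"
            )
        if values.min() < -1e-12:
            raise ValueError("envelope values must be nonnegative")
        if values.max() > 1 + 1e-9:
            raise ValueError("envelope values must not exceed 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.values.shape[1]

    @property
    def cycle_percent(self) -> np.ndarray:
        """Grid of cycle positions in percent, 0 to 100 inclusive."""
        return np.linspace(0.0, 100.0, self.n_points)


def as_matrix(m: "GaitCycleMatrix | np.ndarray | Sequence") -> np.ndarray:
    """Coerce a GaitCycleMatrix or array-like to a float ndarray."""
    if isinstance(m, GaitCycleMatrix):
        return m.values
    return np.asarray(m, dtype=float)
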