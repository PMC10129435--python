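"""Linear-envelope extraction and gait-cycle normalization.

The chain turns a raw multi-channel EMG recording into the per-subject
normalized envelope matrix the factorization consumes:

band-pass (10-500 Hz) -> full-wave rectification -> 6 Hz Butterworth
low-pass -> per-cycle segmentation -> per-cycle submaximal amplitude
normalization -> cubic time-normalization to 101 points -> average across
cycles.

All filters are zero-phase (forward-backward Butterworth), so burst timing
on the cycle axis is not biased by filter lag. Sample indices are 0-based
and event windows half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .datatypes import DEFAULT_CHANNELS, EMGRecording, GaitCycleMatrix

__all__ = [
    "PreprocessParams",
    "bandpass_filter",
    "full_wave_rectify",
    "lowpass_envelope",
    "segment_cycles",
    "normalize_amplitude_per_cycle",
    "time_normalize",
    "build_subject_matrix",
    "preprocess",
]


from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the envelope chain with standard defaults."""

    band_low_hz: float = 10.0
    band_high_hz: float = 500.0
    filter_order: int = 4
    envelope_cutoff_hz: float = 6.0
    n_points: int = 101

    def as_dict(self) -> dict:
        return asdict(self)


def _check_length(rec: EMGRecording, sos: np.ndarray, stage: str) -> None:
    # sosfiltfilt needs n_samples > padlen; surface the minimum explicitly
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if rec.n_samples <= padlen:
        raise ValueError(
            f"{stage}: recording of {rec.n_samples} samples is shorter than "
            f"the filter warm-up length; need more than {padlen} samples"
        )


def bandpass_filter(
    rec: EMGRecording,
    low_hz: float = 10.0,
    high_hz: float = 500.0,
    order: int = 4,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    If ``high_hz`` reaches the Nyquist frequency the upper edge is clipped
    to 0.99 x Nyquist with a warning (a 10-500 Hz band at 1000 Hz sampling
    is nominally degenerate at the top edge).
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("band edges must satisfy 0 < low_hz < high_hz")
    if low_hz >= nyq:
        raise ValueError(f"low edge {low_hz} Hz is at or above Nyquist ({nyq} Hz)")
    if high_hz >= nyq:
        warnings.warn(
            f"band upper edge {high_hz} Hz >= Nyquist ({nyq} Hz); "
            f"clipping to {0.99 * nyq:.1f} Hz",
            stacklevel=2,
        )
        high_hz = 0.99 * nyq
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate,
        output="sos",
    )
    _check_length(rec, sos, "bandpass_filter")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples, axis=0))


def full_wave_rectify(rec: EMGRecording) -> EMGRecording:
    """Element-wise absolute value."""
    return rec.with_samples(np.abs(rec.samples))


def lowpass_envelope(
    rec: EMGRecording, cutoff_hz: float = 6.0, order: int = 4
) -> EMGRecording:
    """Zero-phase Butterworth low-pass; negative ringing clipped to 0."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=rec.sampling_rate,
                        output="sos")
    _check_length(rec, sos, "lowpass_envelope")
    out = signal.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.with_samples(np.clip(out, 0.0, None))


def segment_cycles(
    rec: EMGRecording, events: Sequence[tuple[int, int]]
) -> list[np.ndarray]:
    """Cut the recording into per-cycle sample blocks.

    ``events`` are 0-based half-open ``(start, end)`` windows; they must
    lie within the recording, be properly ordered, and not overlap.
    """
    ordered = sorted(range(len(events)), key=lambda i: events[i][0])
    prev_end = None
    for rank, i in enumerate(ordered):
        start, end = events[i]
        if start < 0 or end > rec.n_samples:
            raise ValueError(
                f"cycle {i}: window [{start}, {end}) outside recording "
                f"of {rec.n_samples} samples"
            )
        if start >= end:
            raise ValueError(f"cycle {i}: start {start} not before end {end}")
        if prev_end is not None and start < prev_end:
            raise ValueError(f"cycle {i}: window overlaps the previous cycle")
        prev_end = end
    return [rec.samples[start:end].copy() for start, end in events]


def normalize_amplitude_per_cycle(
    cycle: np.ndarray, channel_labels: Sequence[str] | None = None
) -> np.ndarray:
    """Submaximal normalization: divide each channel by its in-cycle max.

    Every output column has maximum exactly 1. An all-zero channel makes
    the division undefined and raises, naming the channel.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.min() < 0:
        raise ValueError("cycle must be nonnegative (rectified envelope)")
    maxima = cycle.max(axis=0)
    if np.any(maxima <= 0):
        bad = int(np.argmax(maxima <= 0))
        name = (
            channel_labels[bad]
            if channel_labels is not None
            else f"column {bad}"
        )
        raise ValueError(f"channel {name!r} is all zero within the cycle; "
                         "per-cycle maximum normalization is undefined")
    return cycle / maxima


def time_normalize(cycle: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Resample a cycle onto ``n_points`` equally spaced positions.

    Natural cubic-spline interpolation over the cycle's own sample grid,
    endpoints included (point 0 = cycle start, last point = cycle end).
    Negative interpolation overshoot is clipped to 0.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.ndim == 1:
        cycle = cycle[:, None]
    if cycle.shape[0] < 4:
        raise ValueError(
            f"cubic time-normalization needs >= 4 samples, got {cycle.shape[0]}"
        )
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = np.linspace(0.0, 1.0, cycle.shape[0])
    xi = np.linspace(0.0, 1.0, n_points)
    spline = CubicSpline(x, cycle, axis=0, bc_type="natural")
    return np.clip(spline(xi), 0.0, None)


def build_subject_matrix(
    cycles: Sequence[np.ndarray],
    channel_labels: Sequence[str] = DEFAULT_CHANNELS,
    provenance: dict | None = None,
) -> GaitCycleMatrix:
    """Average normalized cycles into the subject's envelope matrix.

    Cycles are averaged element-wise; because per-cycle-normalized curves
    rarely peak at the same cycle point, the averaged column maxima can
    fall below 1, so each column is re-divided by its own maximum to
    restore the 0-1 range contract.
    """
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    shapes = {np.asarray(c).shape for c in cycles}
    if len(shapes) != 1:
        raise ValueError(f"cycle shape mismatch: {sorted(shapes)}")
    mean = np.mean([np.asarray(c, dtype=float) for c in cycles], axis=0)
    mean = normalize_amplitude_per_cycle(mean, channel_labels)
    prov = dict(provenance or {})
    prov.setdefault("n_cycles_averaged", len(cycles))
    prov.setdefault("renormalized_after_averaging", True)
    return GaitCycleMatrix(mean, tuple(channel_labels), prov)


def preprocess(
    rec: EMGRecording,
    events: Sequence[tuple[int, int]],
    params: PreprocessParams = PreprocessParams(),
) -> GaitCycleMatrix:
    """Full envelope chain from raw recording to the normalized matrix.

    Stage failures are re-raised annotated with the stage name. The
    returned matrix carries the complete parameter set in its provenance.
    """
    if len(events) == 0:
        raise ValueError("preprocess: empty event list, nothing to segment")

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as e:
            raise ValueError(f"[{name}] {e}") from e

    filtered = _stage(
        "bandpass", bandpass_filter, rec,
        params.band_low_hz, params.band_high_hz, params.filter_order,
    )
    rectified = full_wave_rectify(filtered)
    envelope = _stage(
        "envelope", lowpass_envelope, rectified,
        params.envelope_cutoff_hz, params.filter_order,
    )
    raw_cycles = _stage("segment", segment_cycles, envelope, events)
    cycles = []
    for i, c in enumerate(raw_cycles):
        norm = _stage(
            f"normalize cycle {i}", normalize_amplitude_per_cycle,
            c, rec.channel_labels,
        )
        cycles.append(_stage(f"time-normalize cycle {i}", time_normalize,
                             norm, params.n_points))
    prov = {"params": params.as_dict(), "n_events": len(events)}
    return build_subject_matrix(cycles, rec.channel_labels, prov)
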