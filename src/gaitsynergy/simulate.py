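"""Synthetic walking-EMG generator with known synergy ground truth.

The generator runs the synergy model forward: per-synergy Gaussian
activation bursts placed on a circular gait-cycle axis (``H``) are mixed
through a nonnegative muscle-weight matrix (``W``) into per-muscle
envelopes, which then amplitude-modulate band-limited carrier noise to
produce raw-EMG-like signals. Because the ground-truth factors are known,
every downstream stage (envelope extraction, factorization, synergy-count
selection, group statistics) can be validated by parameter recovery.

Two cohorts ("A" and "B") are generated with optional multiplicative
perturbations of selected muscle weights in one group, emulating a
between-group difference in synergy composition at matched synergy counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .datatypes import DEFAULT_CHANNELS, EMGRecording, GaitCycleMatrix

__all__ = [
    "GroundTruthSynergyModel",
    "CohortSpec",
    "Cohort",
    "SubjectData",
    "default_walking_model",
    "make_activation_profiles",
    "synthesize_envelope",
    "synthesize_raw_emg",
    "generate_cohort",
    "generate_envelope_cohort",
]


@dataclass(frozen=True)
class GroundTruthSynergyModel:
    """Generative synergy model: k Gaussian bursts mixed by weights W.

    Attributes
    ----------
    k_true
        Number of synergies.
    W_true
        ``(k_true, n_muscles)`` nonnegative weights; each row is scaled so
        its maximum entry is 1 (canonical scale).
    burst_centers
        Activation-peak position of each synergy in percent of the gait
        cycle, distinct values in [0, 100]. The cycle axis is circular, so
        bursts near 0%/100% wrap around.
    burst_widths
        Gaussian standard deviation of each burst, in percent of cycle.
    noise_sigma
        Scale of multiplicative log-normal envelope noise (0 = noiseless).
    seed
        Base RNG seed for everything derived from this model.
    """

    k_true: int
    W_true: np.ndarray
    burst_centers: tuple[float, ...]
    burst_widths: tuple[float, ...]
    noise_sigma: float = 0.0
    seed: int = 0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        W = np.asarray(self.W_true, dtype=float)
        if W.shape[0] != self.k_true:
            raise ValueError("W_true must have k_true rows")
        if W.min() < 0:
            raise ValueError("W_true must be nonnegative")
        rowmax = W.max(axis=1)
        if np.any(rowmax <= 0):
            raise ValueError("every W_true row needs a positive entry")
        if not np.allclose(rowmax, 1.0, atol=1e-9):
            raise ValueError("W_true rows must be scaled to max 1 (canonical scale)")
        centers = tuple(float(c) for c in self.burst_centers)
        widths = tuple(float(w) for w in self.burst_widths)
        if len(centers) != self.k_true or len(widths) != self.k_true:
            raise ValueError("need one burst center and width per synergy")
        if len(set(centers)) != len(centers):
            raise ValueError("burst centers must be distinct")
        if any(c < 0 or c > 100 for c in centers):
            raise ValueError("burst centers must lie in [0, 100]")
        if any(w <= 0 for w in widths):
            raise ValueError("burst widths must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.channel_labels) != W.shape[1]:
            raise ValueError("channel_labels length must match W_true columns")
        object.__setattr__(self, "W_true", W)
        object.__setattr__(self, "burst_centers", centers)
        object.__setattr__(self, "burst_widths", widths)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_muscles(self) -> int:
        return self.W_true.shape[1]

    def with_weights(self, W: np.ndarray) -> "GroundTruthSynergyModel":
        """Copy of the model with a different (possibly non-canonical) W.

        Used internally for per-subject jittered/perturbed weights; skips
        the canonical-scale check by renormalizing nothing — the copy is
        built through object replacement on an already-validated template.
        """
        new = replace(self, W_true=np.ones_like(self.W_true))
        object.__setattr__(new, "W_true", np.asarray(W, dtype=float))
        return new


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a two-group simulated cohort.

    ``weight_perturbations`` maps ``(group, muscle, synergy)`` to a
    multiplicative factor applied to that entry of ``W_true`` for every
    subject in the group; ``synergy`` is a 0-based row index, ``muscle`` a
    channel label. ``cycle_duration_s`` is the (mean, SD) of simulated
    stride time. ``weight_jitter_sd`` is the relative SD of i.i.d.
    between-subject weight variation (truncated at 0).
    """

    n_subjects: int = 10
    n_cycles_per_subject: int = 3
    weight_perturbations: Mapping[tuple[str, str, int], float] = field(
        default_factory=dict
    )
    sampling_rate: float = 1000.0
    cycle_duration_s: tuple[float, float] = (1.1, 0.05)
    weight_jitter_sd: float = 0.10
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    envelope_floor: float = 0.02

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 per group")
        if self.n_cycles_per_subject < 1:
            raise ValueError("n_cycles_per_subject must be >= 1")
        mean, sd = self.cycle_duration_s
        if mean <= 0:
            raise ValueError("mean cycle duration must be positive")
        if sd < 0:
            raise ValueError("cycle duration SD must be >= 0")
        if any(f <= 0 for f in self.weight_perturbations.values()):
            raise ValueError("perturbation factors must be > 0")
        if self.weight_jitter_sd < 0:
            raise ValueError("weight_jitter_sd must be >= 0")
        lo, hi = self.carrier_band_hz
        if not (0 < lo < hi):
            raise ValueError("carrier band must satisfy 0 < low < high")
        if self.sampling_rate < 4 * 6.0:
            raise ValueError("sampling_rate too low for envelope bandwidth")


@dataclass(frozen=True)
class SubjectData:
    """One simulated subject: raw recording, events, and generative truth."""

    group: str
    subject_index: int
    recording: EMGRecording
    events: tuple[tuple[int, int], ...]
    W_subject: np.ndarray
    seed: int


@dataclass(frozen=True)
class Cohort:
    """Two simulated groups plus the shared ground-truth model."""

    model: GroundTruthSynergyModel
    spec: CohortSpec
    groups: Mapping[str, tuple[SubjectData, ...]]


def default_walking_model(
    seed: int = 0, noise_sigma: float = 0.1
) -> GroundTruthSynergyModel:
    """Four-synergy, five-muscle ground truth for level walking.

    The four modules follow the canonical organization of walking EMG:
    weight acceptance (knee/hip extensors, early stance), push-off
    (plantarflexors, mid/late stance), early swing (dorsiflexors), and
    late swing (hamstrings with quadriceps co-activation before contact).
    Columns are GA, TA, VL, GM, BF.
    """
    W = np.array(
        [
            # GA    TA    VL    GM    BF
            [0.05, 0.10, 0.30, 1.00, 0.15],  # weight acceptance
            [1.00, 0.05, 0.10, 0.10, 0.10],  # push-off
            [0.05, 1.00, 0.15, 0.10, 0.10],  # early swing
            [0.10, 0.30, 0.90, 0.15, 1.00],  # late swing
        ]
    )
    return GroundTruthSynergyModel(
        k_true=4,
        W_true=W,
        burst_centers=(10.0, 35.0, 62.0, 92.0),
        burst_widths=(9.0, 9.0, 9.0, 8.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_activation_profiles(
    model: GroundTruthSynergyModel, n_points: int
) -> np.ndarray:
    """Ground-truth activation coefficients H, one Gaussian burst per column.

    Column ``j`` is a unit-peak Gaussian bump centered at
    ``burst_centers[j]`` percent of the cycle, evaluated on a circular
    domain so bursts near 0%/100% wrap around the cycle boundary.

    Returns an ``(n_points, k_true)`` nonnegative array.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    pos = np.linspace(0.0, 100.0, n_points)
    H = np.empty((n_points, model.k_true))
    for j, (c, w) in enumerate(zip(model.burst_centers, model.burst_widths)):
        d = np.abs(pos - c)
        d = np.minimum(d, 100.0 - d)  # circular distance on the cycle
        H[:, j] = np.exp(-0.5 * (d / w) ** 2)
    return H


def synthesize_envelope(
    model: GroundTruthSynergyModel,
    n_points: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward-model envelope matrix ``H_true @ W_true`` with noise.

    Multiplicative log-normal noise of scale ``noise_sigma`` (mean 1) is
    applied element-wise; the result is clipped at 0. With
    ``noise_sigma=0`` the product is returned exactly.
    """
    H = make_activation_profiles(model, n_points)
    E = H @ model.W_true
    if model.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        s = model.noise_sigma
        noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=E.shape)
        E = E * noise
    return np.clip(E, 0.0, None)


def _carrier_sos(band: tuple[float, float], fs: float):
    from scipy import signal

    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def synthesize_raw_emg(
    model: GroundTruthSynergyModel,
    spec: CohortSpec,
    subject_seed: int,
) -> tuple[EMGRecording, tuple[tuple[int, int], ...]]:
    """Simulate one subject's raw EMG plus exact gait-event annotations.

    Each channel is zero-mean band-limited Gaussian carrier noise
    (band ``spec.carrier_band_hz``) amplitude-modulated by the channel's
    target envelope rendered in real time; consecutive cycles with
    seeded-random stride durations are concatenated. Events are 0-based
    half-open ``(start_sample, end_sample)`` windows, one per cycle.
    """
    from scipy import signal

    mean_T, sd_T = spec.cycle_duration_s
    fs = spec.sampling_rate
    rng = np.random.default_rng([int(subject_seed), int(model.seed)])
    sos = _carrier_sos(spec.carrier_band_hz, fs)

    chunks: list[np.ndarray] = []
    events: list[tuple[int, int]] = []
    cursor = 0
    for _ in range(spec.n_cycles_per_subject):
        T = rng.normal(mean_T, sd_T)
        T = max(T, 0.25 * mean_T)  # guard against non-physiological draws
        n = max(int(round(T * fs)), 8)
        env = synthesize_envelope(model, n, rng=rng)
        # small tonic floor so no channel is identically silent in a cycle
        peak = env.max()
        if peak <= 0:
            peak = 1.0
        env = env + spec.envelope_floor * peak
        carrier = rng.standard_normal((n, model.n_muscles))
        carrier = signal.sosfilt(sos, carrier, axis=0)
        rms = np.sqrt(np.mean(carrier**2, axis=0))
        carrier = carrier / np.where(rms > 0, rms, 1.0)
        chunks.append(carrier * env)
        events.append((cursor, cursor + n))
        cursor += n

    samples = np.vstack(chunks)
    rec = EMGRecording(samples, fs, model.channel_labels)
    return rec, tuple(events)


def _subject_weights(
    base_W: np.ndarray, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject weights: relative Gaussian jitter, truncated at 0."""
    if jitter_sd == 0:
        return base_W.copy()
    W = base_W * (1.0 + rng.normal(0.0, jitter_sd, size=base_W.shape))
    return np.clip(W, 0.0, None)


def _group_weights(
    model: GroundTruthSynergyModel, spec: CohortSpec, group: str
) -> np.ndarray:
    W = model.W_true.copy()
    labels = list(model.channel_labels)
    for (g, muscle, synergy), factor in spec.weight_perturbations.items():
        if g != group:
            continue
        if muscle not in labels:
            raise ValueError(f"unknown muscle {muscle!r} in perturbation")
        if not 0 <= synergy < model.k_true:
            raise ValueError(f"synergy index {synergy} out of range")
        W[synergy, labels.index(muscle)] *= factor
    return W


def generate_cohort(model: GroundTruthSynergyModel, spec: CohortSpec) -> Cohort:
    """Simulate two groups of raw-EMG subjects from one ground truth.

    Group "A" uses ``W_true`` as-is; group "B" additionally applies
    ``spec.weight_perturbations``. Each subject receives independent
    seeded weight jitter, so between-subject variance exists in both
    groups. Fully deterministic given ``model.seed``.
    """
    ss = np.random.SeedSequence(model.seed)
    children = ss.spawn(2 * spec.n_subjects)
    groups: dict[str, tuple[SubjectData, ...]] = {}
    for gi, group in enumerate(("A", "B")):
        base_W = _group_weights(model, spec, group)
        subjects = []
        for si in range(spec.n_subjects):
            child = children[gi * spec.n_subjects + si]
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            jit_rng = np.random.default_rng([sub_seed, 7])
            W_s = _subject_weights(base_W, spec.weight_jitter_sd, jit_rng)
            sub_model = model.with_weights(W_s)
            rec, events = synthesize_raw_emg(sub_model, spec, sub_seed)
            subjects.append(
                SubjectData(group, si, rec, events, W_s, sub_seed)
            )
        groups[group] = tuple(subjects)
    return Cohort(model, spec, groups)


def generate_envelope_cohort(
    model: GroundTruthSynergyModel,
    spec: CohortSpec,
    n_points: int = 101,
) -> dict[str, list[tuple[GaitCycleMatrix, np.ndarray]]]:
    """Envelope-level shortcut: per-subject normalized matrices directly.

    Skips the raw-EMG synthesis and envelope-extraction stages and emits
    each subject's averaged, per-muscle-max-normalized cycle matrix
    straight from the generative model (with per-cycle noise and
    between-subject jitter identical in kind to :func:`generate_cohort`).
    Intended for statistical calibration experiments where many cohorts
    are needed and the filtering chain is not the object under test.

    Returns ``{group: [(matrix, W_subject), ...]}``.
    """
    from .preprocess import build_subject_matrix, normalize_amplitude_per_cycle

    ss = np.random.SeedSequence(model.seed)
    children = ss.spawn(2 * spec.n_subjects)
    out: dict[str, list[tuple[GaitCycleMatrix, np.ndarray]]] = {}
    for gi, group in enumerate(("A", "B")):
        base_W = _group_weights(model, spec, group)
        subjects = []
        for si in range(spec.n_subjects):
            child = children[gi * spec.n_subjects + si]
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            jit_rng = np.random.default_rng([sub_seed, 7])
            W_s = _subject_weights(base_W, spec.weight_jitter_sd, jit_rng)
            sub_model = model.with_weights(W_s)
            env_rng = np.random.default_rng([sub_seed, 11])
            cycles = [
                normalize_amplitude_per_cycle(
                    synthesize_envelope(sub_model, n_points, rng=env_rng)
                    + spec.envelope_floor
                )
                for _ in range(spec.n_cycles_per_subject)
            ]
            mat = build_subject_matrix(cycles, channel_labels=model.channel_labels)
            subjects.append((mat, W_s))
        out[group] = subjects
    return out
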