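"""Cross-subject synergy matching and between-group statistics.

NMF returns synergies in arbitrary order, so before any averaging or
testing the synergies are (1) put in a canonical within-cycle order —
ascending position of each activation coefficient's peak — and (2)
aligned across subjects by the permutation maximizing the summed Pearson
correlation of activation coefficients with a reference subject.

Group-level outputs mirror the usual reporting of synergy studies:
group-mean activation coefficients and weights (with SD), a k x k Pearson
correlation matrix between the two groups' mean activation coefficients
with small/moderate/high similarity classes, and independent-samples
t-tests on per-(synergy, muscle) relative weights and on per-subject VAF,
with Shapiro-Wilk normality checks attached.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .extract import SynergyDecomposition

__all__ = [
    "BorderlineSimilarityWarning",
    "GroupSynergySet",
    "WeightTest",
    "VafTest",
    "GroupComparisonReport",
    "order_synergies",
    "align_subject_to_reference",
    "apply_permutation",
    "group_mean_synergies",
    "crossgroup_correlation",
    "classify_similarity",
    "compare_weights",
    "compare_vaf",
    "compare_groups",
]

#: Similarity bands on |r|: left-closed at 0.3 and 0.7 (the printed bands
#: 0.0-0.29 / 0.3-0.69 / 0.7-1 leave the gaps 0.29-0.3 and 0.69-0.7
#: unassigned; closing them on the left is the convention used here).
SIMILARITY_BANDS: tuple[tuple[float, str], ...] = (
    (0.3, "small"),
    (0.7, "moderate"),
    (np.inf, "high"),
)

#: Moderate-band correlations below this are additionally flagged: parts
#: of the gait literature describe such borderline values as weak, so a
#: bare band label can over- or under-state agreement between reports.
BORDERLINE_MODERATE = 0.35


class BorderlineSimilarityWarning(UserWarning):
    """A correlation falls in the disputed lower part of the moderate band."""


@dataclass(frozen=True)
class GroupSynergySet:
    """Aligned per-subject decompositions and their group-level summary."""

    group_label: str
    decompositions: tuple[SynergyDecomposition, ...]
    orderings: tuple[tuple[int, ...], ...]
    mean_H: np.ndarray
    mean_W: np.ndarray
    sd_W: np.ndarray

    @property
    def k(self) -> int:
        return self.mean_H.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.decompositions)

    @property
    def aligned_W(self) -> np.ndarray:
        """Stack of aligned weights, shape (n_subjects, k, n_muscles)."""
        return np.stack(
            [d.W[list(p)] for d, p in zip(self.decompositions, self.orderings)]
        )


@dataclass(frozen=True)
class WeightTest:
    """Two-sample t-test on one (synergy, muscle) relative weight."""

    synergy: int
    muscle: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    significant: bool
    shapiro_p_a: float
    shapiro_p_b: float
    missing: bool = False
    p_corrected: float | None = None


@dataclass(frozen=True)
class VafTest:
    """Two-sample t-test on per-subject global VAF at one synergy count."""

    k: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    significant: bool
    missing: bool = False


@dataclass(frozen=True)
class GroupComparisonReport:
    """Everything compared between the two groups at a common k."""

    group_a: GroupSynergySet
    group_b: GroupSynergySet
    correlation_matrix: np.ndarray
    similarity_class: np.ndarray  # dtype=object labels, same shape
    matched_pairs: tuple[float, ...]  # diagonal after alignment
    weight_tests: tuple[WeightTest, ...]
    vaf_tests: tuple[VafTest, ...]
    alpha: float
    notes: tuple[str, ...] = ()


def order_synergies(dec: SynergyDecomposition) -> tuple[int, ...]:
    """Canonical synergy order: ascending peak position of H columns.

    Ties (identical argmax index) are broken by larger total activation
    energy first, so the ordering is deterministic.
    """
    peaks = dec.H.argmax(axis=0)
    energy = (dec.H**2).sum(axis=0)
    return tuple(sorted(range(dec.k), key=lambda j: (peaks[j], -energy[j])))


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def align_subject_to_reference(
    subject_H: np.ndarray, reference_H: np.ndarray
) -> tuple[int, ...]:
    """Permutation matching subject synergies to a reference, by Pearson r.

    Returns ``perm`` such that subject column ``perm[i]`` corresponds to
    reference column ``i``; found by exhaustive search over all k!
    permutations (exact for the k <= 8 this analysis deals with).
    """
    if subject_H.shape != reference_H.shape:
        raise ValueError("subject and reference must share (n_points, k)")
    k = subject_H.shape[1]
    if k > 8:
        raise ValueError(
            "exhaustive matching is limited to k <= 8; use an assignment "
            "algorithm (e.g. Hungarian) for larger k"
        )
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            r = _safe_corr(reference_H[:, i], subject_H[:, j])
            C[i, j] = -np.inf if np.isnan(r) else r
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(C[i, perm[i]] for i in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    return best_perm


def apply_permutation(
    dec: SynergyDecomposition, perm: Sequence[int]
) -> SynergyDecomposition:
    """Reorder a decomposition's synergies; reconstruction is unchanged."""
    idx = list(perm)
    return SynergyDecomposition(
        H=dec.H[:, idx], W=dec.W[idx], k=dec.k,
        frobenius_loss=dec.frobenius_loss,
        vaf_muscle=dec.vaf_muscle, vaf_total=dec.vaf_total,
        seed_used=dec.seed_used, n_iterations=dec.n_iterations,
    )


def group_mean_synergies(
    decs: Sequence[SynergyDecomposition],
    orderings: Sequence[Sequence[int]],
    group_label: str = "",
) -> GroupSynergySet:
    """Average aligned factors across a group's subjects."""
    if len(decs) == 0:
        raise ValueError("empty group")
    if len(decs) != len(orderings):
        raise ValueError("one ordering per decomposition required")
    ks = {d.k for d in decs}
    if len(ks) != 1:
        raise ValueError(f"subjects must share a common k, got {sorted(ks)}")
    Hs = np.stack([d.H[:, list(p)] for d, p in zip(decs, orderings)])
    Ws = np.stack([d.W[list(p)] for d, p in zip(decs, orderings)])
    return GroupSynergySet(
        group_label=group_label,
        decompositions=tuple(decs),
        orderings=tuple(tuple(p) for p in orderings),
        mean_H=Hs.mean(axis=0),
        mean_W=Ws.mean(axis=0),
        sd_W=Ws.std(axis=0, ddof=1) if len(decs) > 1 else np.zeros_like(Ws[0]),
    )


def crossgroup_correlation(
    meanH_A: np.ndarray, meanH_B: np.ndarray
) -> np.ndarray:
    """k x k Pearson r between the groups' mean activation coefficients.

    Entry (i, j) correlates group A's i-th with group B's j-th coefficient
    over the cycle points. Zero-variance columns yield NaN with a warning.
    """
    if meanH_A.shape != meanH_B.shape:
        raise ValueError("groups must share (n_points, k)")
    k = meanH_A.shape[1]
    R = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            R[i, j] = _safe_corr(meanH_A[:, i], meanH_B[:, j])
    if np.isnan(R).any():
        warnings.warn(
            "constant activation coefficient: some correlations undefined "
            "(reported as NaN)", stacklevel=2,
        )
    return R


def classify_similarity(r: float, warn_borderline: bool = True) -> str:
    """Map a correlation to a similarity class on |r|.

    Bands: [0, 0.3) small, [0.3, 0.7) moderate, [0.7, 1] high. Moderate
    values below 0.35 additionally raise
    :class:`BorderlineSimilarityWarning`: published readings of such
    values disagree (the same study can label 0.30-0.33 "weak" in prose
    while its stated bands call it moderate), so the label alone should
    not be over-interpreted.
    """
    a = abs(float(r))
    if np.isnan(a):
        return "undefined"
    if a > 1 + 1e-9:
        raise ValueError("correlation must lie in [-1, 1]")
    for upper, label in SIMILARITY_BANDS:
        if a < upper:
            break
    if label == "moderate" and a < BORDERLINE_MODERATE and warn_borderline:
        warnings.warn(
            f"r={r:.3f} sits in the disputed lower moderate band "
            f"[0.30, {BORDERLINE_MODERATE}); some reports describe such "
            "correlations as weak",
            BorderlineSimilarityWarning, stacklevel=2,
        )
    return label


def _two_sample(
    a: np.ndarray, b: np.ndarray, nonparametric: bool
) -> tuple[float, float]:
    if nonparametric:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


def _shapiro_p(x: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    idx = [i for i, p in enumerate(pvals) if not np.isnan(p)]
    m = len(idx)
    order = sorted(idx, key=lambda i: pvals[i])
    adj = [np.nan] * len(pvals)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def compare_weights(
    group_a: GroupSynergySet,
    group_b: GroupSynergySet,
    muscles: Sequence[str],
    alpha: float = 0.05,
    correction: Literal[None, "holm"] = None,
    nonparametric: bool = False,
) -> tuple[WeightTest, ...]:
    """Independent-samples tests on each (synergy, muscle) relative weight.

    Cells with zero variance in both groups (e.g. a weight pinned at the
    canonical maximum 1 in every subject) are reported as missing. By
    default no multiple-testing correction is applied, mirroring common
    practice in synergy studies; ``correction="holm"`` reports adjusted
    p-values alongside and bases the significance flag on them.
    """
    if group_a.k != group_b.k:
        raise ValueError("groups must share a common synergy count")
    if group_a.n_subjects < 2 or group_b.n_subjects < 2:
        raise ValueError("need >= 2 subjects per group")
    Wa = group_a.aligned_W  # (n_a, k, m)
    Wb = group_b.aligned_W
    k, m = Wa.shape[1], Wa.shape[2]
    if len(muscles) != m:
        raise ValueError("muscle label count mismatch")

    cells: list[WeightTest] = []
    raw_p: list[float] = []
    for s in range(k):
        for mi, muscle in enumerate(muscles):
            a = Wa[:, s, mi]
            b = Wb[:, s, mi]
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                cells.append(WeightTest(
                    s, muscle, a.mean(), 0.0, b.mean(), 0.0,
                    np.nan, np.nan, False, np.nan, np.nan, missing=True,
                ))
                raw_p.append(np.nan)
                continue
            t, p = _two_sample(a, b, nonparametric)
            cells.append(WeightTest(
                s, muscle,
                float(a.mean()), float(a.std(ddof=1)),
                float(b.mean()), float(b.std(ddof=1)),
                t, p, bool(p < alpha),
                _shapiro_p(a), _shapiro_p(b),
            ))
            raw_p.append(p)

    if correction == "holm":
        adj = _holm(raw_p)
        cells = [
            WeightTest(
                c.synergy, c.muscle, c.mean_a, c.sd_a, c.mean_b, c.sd_b,
                c.t, c.p,
                bool(not c.missing and adj[i] < alpha),
                c.shapiro_p_a, c.shapiro_p_b, c.missing, adj[i],
            )
            for i, c in enumerate(cells)
        ]
    return tuple(cells)


def compare_vaf(
    vafs_a: Mapping[int, Sequence[float]],
    vafs_b: Mapping[int, Sequence[float]],
    alpha: float = 0.05,
) -> tuple[VafTest, ...]:
    """t-test per synergy count on per-subject global VAF values."""
    tests = []
    for k in sorted(set(vafs_a) & set(vafs_b)):
        a = np.asarray(vafs_a[k], dtype=float)
        b = np.asarray(vafs_b[k], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"k={k}: need >= 2 VAF values per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            tests.append(VafTest(k, a.mean(), 0.0, b.mean(), 0.0,
                                 np.nan, np.nan, False, missing=True))
            continue
        t, p = _two_sample(a, b, nonparametric=False)
        tests.append(VafTest(
            k, float(a.mean()), float(a.std(ddof=1)),
            float(b.mean()), float(b.std(ddof=1)),
            t, p, bool(p < alpha),
        ))
    return tuple(tests)


def compare_groups(
    decs_a: Sequence[SynergyDecomposition],
    decs_b: Sequence[SynergyDecomposition],
    muscles: Sequence[str],
    vafs_a: Mapping[int, Sequence[float]] | None = None,
    vafs_b: Mapping[int, Sequence[float]] | None = None,
    alpha: float = 0.05,
    correction: Literal[None, "holm"] = None,
    nonparametric: bool = False,
) -> GroupComparisonReport:
    """Full two-group comparison at a common synergy count.

    The first subject of group A, in canonical burst order, is the
    alignment reference for every other subject in both groups.
    """
    if len(decs_a) == 0 or len(decs_b) == 0:
        raise ValueError("both groups must be non-empty")
    ref_order = order_synergies(decs_a[0])
    reference_H = decs_a[0].H[:, list(ref_order)]

    def _orderings(decs):
        return [align_subject_to_reference(d.H, reference_H) for d in decs]

    ga = group_mean_synergies(decs_a, _orderings(decs_a), "A")
    gb = group_mean_synergies(decs_b, _orderings(decs_b), "B")

    R = crossgroup_correlation(ga.mean_H, gb.mean_H)
    notes: list[str] = []
    classes = np.empty(R.shape, dtype=object)
    for i in range(R.shape[0]):
        for j in range(R.shape[1]):
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                classes[i, j] = classify_similarity(R[i, j])
            for w in caught:
                if issubclass(w.category, BorderlineSimilarityWarning):
                    notes.append(f"synergy pair (A{i + 1}, B{j + 1}): {w.message}")

    weight_tests = compare_weights(ga, gb, muscles, alpha, correction,
                                   nonparametric)
    vaf_tests: tuple[VafTest, ...] = ()
    if vafs_a is not None and vafs_b is not None:
        vaf_tests = compare_vaf(vafs_a, vafs_b, alpha)

    return GroupComparisonReport(
        group_a=ga, group_b=gb,
        correlation_matrix=R,
        similarity_class=classes,
        matched_pairs=tuple(float(R[i, i]) for i in range(R.shape[0])),
        weight_tests=weight_tests,
        vaf_tests=vaf_tests,
        alpha=alpha,
        notes=tuple(notes),
    )
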