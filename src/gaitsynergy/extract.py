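"""Synergy extraction: nonnegative matrix factorization and VAF selection.

The normalized envelope matrix ``M`` (cycle points x muscles) is factored
as ``M ~= H W`` with ``H >= 0`` (n_points x k, synergy activation
coefficients) and ``W >= 0`` (k x n_muscles, muscle weights), minimizing
the Frobenius reconstruction error with Lee-Seung multiplicative updates
from multiple seeded random starts.

Model selection uses the variance-accounted-for (VAF) criterion: fit
k = 1, 2, ... and stop at the smallest k whose per-muscle VAF all exceed
a threshold (default 0.9). Successive k's share a warm-start built from
the best (k)-solution padded with a tiny extra component, which makes the
best loss — and hence global VAF — monotone in k.

VAF is computed in the standard uncentered squared form

    VAF_m = 1 - sum_t (rec_tm - exp_tm)^2 / sum_t exp_tm^2.

A linear (unsquared) variant ``1 - sum(rec - exp) / sum(exp)`` is also
exposed for comparison with reports that print the criterion without the
squares; it is sign-sensitive, can exceed 1, and is not used for
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .datatypes import GaitCycleMatrix, as_matrix

__all__ = [
    "SynergyDecomposition",
    "SynergySelectionCurve",
    "nnmf_decompose",
    "reconstruct",
    "vaf_per_muscle",
    "vaf_global",
    "select_num_synergies",
]

_EPS = 1e-12  # denominator guard in multiplicative updates


@dataclass(frozen=True)
class SynergyDecomposition:
    """Factor pair for one subject at a fixed synergy count k.

    ``H`` is ``(n_points, k)``; ``W`` is ``(k, n_muscles)`` canonicalized
    so each row's maximum entry is 1 (the compensating scale is absorbed
    into the corresponding H column, leaving ``H @ W`` unchanged).
    """

    H: np.ndarray
    W: np.ndarray
    k: int
    frobenius_loss: float
    vaf_muscle: np.ndarray
    vaf_total: float
    seed_used: int
    n_iterations: int

    @property
    def n_points(self) -> int:
        return self.H.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class SynergySelectionCurve:
    """VAF as a function of k, with the selected synergy count.

    ``k_selected`` is the smallest k whose per-muscle VAF all exceed
    ``threshold``; if no k up to ``k_max`` qualifies, ``criterion_met`` is
    False and ``k_selected`` equals ``k_max``.
    """

    per_k: tuple[SynergyDecomposition, ...]
    k_selected: int
    threshold: float
    criterion_met: bool

    @property
    def selected(self) -> SynergyDecomposition:
        return self.per_k[self.k_selected - 1]

    @property
    def vaf_curve(self) -> np.ndarray:
        """Global VAF for k = 1..len(per_k)."""
        return np.array([d.vaf_total for d in self.per_k])


def _canonicalize(H: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale W rows to max 1, absorbing the scale into H columns."""
    scale = W.max(axis=1)
    scale = np.where(scale > 0, scale, 1.0)
    return H * scale, W / scale[:, None]


def _mu_iterate(
    M: np.ndarray,
    H: np.ndarray,
    W: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lee-Seung multiplicative updates for the Frobenius objective.

    Loss is checked every few iterations; iteration stops when the
    relative decrease falls below ``tol``.
    """
    norm_M = np.linalg.norm(M)
    prev_loss = np.inf
    loss = np.linalg.norm(M - H @ W)
    it = 0
    check = 10
    while it < max_iter:
        for _ in range(check):
            # W <- W * (H^T M) / (H^T H W)
            HtM = H.T @ M
            W *= HtM / (H.T @ H @ W + _EPS)
            # H <- H * (M W^T) / (H W W^T)
            MWt = M @ W.T
            H *= MWt / (H @ (W @ W.T) + _EPS)
            it += 1
            if it >= max_iter:
                break
        prev_loss, loss = loss, np.linalg.norm(M - H @ W)
        if prev_loss - loss < tol * max(norm_M, _EPS):
            break
    return H, W, float(loss), it


def _random_init(
    rng: np.random.Generator, shape_H: tuple[int, int], shape_W: tuple[int, int],
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    # uniform in (0, 1] scaled to the data magnitude; strictly positive so
    # no factor entry is trapped at zero by the multiplicative rule
    H = (1.0 - rng.random(shape_H)) * np.sqrt(scale)
    W = 1.0 - rng.random(shape_W)
    return H, W


def nnmf_decompose(
    M: GaitCycleMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
) -> SynergyDecomposition:
    """Factor ``M`` into k synergies; best of ``n_restarts`` seeded starts.

    Parameters
    ----------
    M
        Nonnegative envelope matrix (or :class:`GaitCycleMatrix`).
    k
        Synergy count; values above the muscle count are allowed but
        warn, since the factorization is then trivially overcomplete.
    warm_start
        Optional ``(H, W)`` pair used as one additional initialization
        (e.g. a padded solution from a smaller k).

    The lowest-loss restart wins; ties go to the earliest candidate, so
    repeated calls with identical arguments are bit-identical.
    """
    X = as_matrix(M)
    if X.min() < 0:
        raise ValueError("M must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_points, n_muscles = X.shape
    if k > n_muscles:
        warnings.warn(
            f"k={k} exceeds the number of muscles ({n_muscles}); the "
            "factorization is overcomplete", stacklevel=2,
        )
    mean_scale = max(X.mean() / max(k, 1), _EPS)
    candidates: list[tuple[np.ndarray, np.ndarray]] = []
    if warm_start is not None:
        H0, W0 = warm_start
        if H0.shape != (n_points, k) or W0.shape != (k, n_muscles):
            raise ValueError("warm_start shapes do not match (n_points, k, n_muscles)")
        candidates.append((H0.astype(float).copy(), W0.astype(float).copy()))
    ss = np.random.SeedSequence([int(seed), k])
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        candidates.append(_random_init(rng, (n_points, k), (k, n_muscles),
                                       mean_scale))

    best = None
    for idx, (H0, W0) in enumerate(candidates):
        H, W, loss, it = _mu_iterate(X, H0, W0, max_iter, tol)
        if best is None or loss < best[2]:
            best = (H, W, loss, it, idx)

    H, W, loss, it, _ = best
    H, W = _canonicalize(H, W)
    vm = vaf_per_muscle(X, H @ W)
    vg = vaf_global(X, H @ W)
    return SynergyDecomposition(
        H=H, W=W, k=k, frobenius_loss=loss,
        vaf_muscle=vm, vaf_total=vg,
        seed_used=int(seed), n_iterations=it,
    )


def reconstruct(dec: SynergyDecomposition) -> np.ndarray:
    """Reconstructed envelope matrix ``H @ W``."""
    return dec.H @ dec.W


def vaf_per_muscle(
    M: np.ndarray,
    M_rec: np.ndarray,
    form: Literal["squared", "linear"] = "squared",
) -> np.ndarray:
    """Per-muscle variance accounted for by the reconstruction.

    ``squared`` (default): ``1 - sum_t (rec - exp)^2 / sum_t exp^2``,
    the standard uncentered VAF in [-inf, 1].
    ``linear``: ``1 - sum_t (rec - exp) / sum_t exp``; provided for
    comparison with unsquared printings of the criterion only.
    """
    X = as_matrix(M)
    R = as_matrix(M_rec)
    if X.shape != R.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {R.shape}")
    if X.min() < 0:
        raise ValueError("M must be nonnegative")
    if form == "squared":
        denom = (X**2).sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("all-zero muscle column: VAF denominator is zero")
        return 1.0 - ((R - X) ** 2).sum(axis=0) / denom
    elif form == "linear":
        denom = X.sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("all-zero muscle column: VAF denominator is zero")
        return 1.0 - (R - X).sum(axis=0) / denom
    raise ValueError(f"unknown VAF form {form!r}")


def vaf_global(
    M: np.ndarray,
    M_rec: np.ndarray,
    form: Literal["squared", "linear"] = "squared",
) -> float:
    """Global VAF pooled over all muscles and cycle points."""
    X = as_matrix(M)
    R = as_matrix(M_rec)
    if X.shape != R.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {R.shape}")
    if form == "squared":
        denom = (X**2).sum()
        if denom <= 0:
            raise ValueError("all-zero matrix: VAF denominator is zero")
        return float(1.0 - ((R - X) ** 2).sum() / denom)
    elif form == "linear":
        denom = X.sum()
        if denom <= 0:
            raise ValueError("all-zero matrix: VAF denominator is zero")
        return float(1.0 - (R - X).sum() / denom)
    raise ValueError(f"unknown VAF form {form!r}")


def _padded_warm_start(
    dec: SynergyDecomposition,
    rng: np.random.Generator,
    scale: float,
    pad_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Extend a k-solution to k+1 by appending a small random component.

    The appended component contributes O(pad_scale^2) to the
    reconstruction, so the padded start's loss is essentially the parent
    solution's final loss, and multiplicative updates can only improve on
    it — this is what makes the VAF-vs-k curve monotone.
    """
    n_points, k = dec.H.shape
    h_new = pad_scale * np.sqrt(scale) * (1.0 - rng.random((n_points, 1)))
    w_new = pad_scale * (1.0 - rng.random((1, dec.W.shape[1])))
    return np.hstack([dec.H, h_new]), np.vstack([dec.W, w_new])


def select_num_synergies(
    M: GaitCycleMatrix | np.ndarray,
    threshold: float = 0.9,
    k_max: int | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> SynergySelectionCurve:
    """Choose the number of synergies by the per-muscle VAF criterion.

    Starting from k=1, each k is fitted (fresh random restarts plus, for
    k>1, a warm start padded from the best smaller solution) and the
    search stops at the first k whose per-muscle VAF all exceed
    ``threshold``. If the criterion is never met up to ``k_max`` (default:
    the number of muscles), the curve is returned flagged with
    ``criterion_met=False`` and a warning.
    """
    X = as_matrix(M)
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    n_muscles = X.shape[1]
    if k_max is None:
        k_max = n_muscles
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    mean_scale = max(X.mean(), _EPS)
    pad_rng = np.random.default_rng([int(seed), 104729])
    per_k: list[SynergyDecomposition] = []
    prev: SynergyDecomposition | None = None
    k_selected = None
    for k in range(1, k_max + 1):
        warm = None
        if prev is not None:
            warm = _padded_warm_start(prev, pad_rng, mean_scale / k,
                                      pad_scale=1e-3)
        dec = nnmf_decompose(
            X, k, seed=seed, n_restarts=n_restarts, max_iter=max_iter,
            tol=tol, warm_start=warm,
        )
        # monotonicity safeguard: a padded parent solution can never be
        # worse than the parent, so keep it if a rare restart set loses
        if prev is not None and dec.frobenius_loss > prev.frobenius_loss:
            Hp, Wp = _padded_warm_start(prev, pad_rng, mean_scale / k,
                                        pad_scale=0.0)
            Hc, Wc = _canonicalize(Hp, Wp)
            dec = SynergyDecomposition(
                H=Hc, W=Wc, k=k, frobenius_loss=prev.frobenius_loss,
                vaf_muscle=vaf_per_muscle(X, Hc @ Wc),
                vaf_total=vaf_global(X, Hc @ Wc),
                seed_used=int(seed), n_iterations=0,
            )
        per_k.append(dec)
        prev = dec
        if k_selected is None and dec.vaf_muscle.min() > threshold:
            k_selected = k
            break

    if k_selected is None:
        warnings.warn(
            f"per-muscle VAF > {threshold} never reached up to k_max={k_max}; "
            "returning k_max", stacklevel=2,
        )
        return SynergySelectionCurve(tuple(per_k), k_max, threshold, False)
    return SynergySelectionCurve(tuple(per_k), k_selected, threshold, True)
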