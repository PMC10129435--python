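"""Synergy matching, similarity classification, and group statistics."""

import numpy as np
import pytest

from gaitsynergy import (
    align_subject_to_reference,
    classify_similarity,
    compare_vaf,
    compare_weights,
    crossgroup_correlation,
    group_mean_synergies,
    order_synergies,
)
from gaitsynergy.compare import (
    BorderlineSimilarityWarning,
    apply_permutation,
)
from gaitsynergy.extract import SynergyDecomposition, vaf_global, vaf_per_muscle


def _dec(H, W=None, seed=0):
    H = np.asarray(H, dtype=float)
    k = H.shape[1]
    if W is None:
        W = np.eye(k, 5)
        W[W.max(axis=1) == 0] = 1.0
    W = np.asarray(W, dtype=float)
    M = H @ W + 1e-6
    return SynergyDecomposition(
        H=H, W=W, k=k, frobenius_loss=0.0,
        vaf_muscle=vaf_per_muscle(M, H @ W), vaf_total=vaf_global(M, H @ W),
        seed_used=seed, n_iterations=1,
    )


def _bump(center, n=101, width=8.0):
    x = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((x - center) / width) ** 2)


class TestOrderSynergies:
    def test_sorts_by_peak_position(self):
        H = np.column_stack([_bump(60), _bump(10), _bump(90), _bump(30)])
        assert order_synergies(_dec(H)) == (1, 3, 0, 2)

    def test_already_ordered_gives_identity(self):
        H = np.column_stack([_bump(10), _bump(50), _bump(90)])
        assert order_synergies(_dec(H)) == (0, 1, 2)

    def test_tied_peaks_broken_by_energy(self):
        H = np.column_stack([0.5 * _bump(40), _bump(40, width=12)])
        # same argmax; wider/taller column has more energy, so it leads
        assert order_synergies(_dec(H)) == (1, 0)


class TestAlignment:
    def test_reference_aligns_to_itself_identically(self, rng):
        H = rng.random((101, 4))
        assert align_subject_to_reference(H, H) == (0, 1, 2, 3)

    def test_column_swap_recovered(self, rng):
        H = np.column_stack([_bump(10), _bump(40), _bump(70), _bump(95)])
        perm = (2, 0, 3, 1)
        shuffled = H[:, list(perm)]
        got = align_subject_to_reference(shuffled, H)
        np.testing.assert_array_equal(shuffled[:, list(got)], H)

    def test_noisy_copy_matches_greedy_oracle(self, rng):
        """Exhaustive matching agrees with independent greedy matching when
        columns are distinct enough that greedy is optimal."""
        H = np.column_stack([_bump(10), _bump(40), _bump(70), _bump(95)])
        noisy = H[:, [3, 1, 0, 2]] + rng.normal(0, 0.02, H.shape)
        got = align_subject_to_reference(noisy, H)

        C = np.array([
            [np.corrcoef(H[:, i], noisy[:, j])[0, 1] for j in range(4)]
            for i in range(4)
        ])
        greedy = [-1] * 4
        used = set()
        for i in np.argsort(-C.max(axis=1)):
            j = max((j for j in range(4) if j not in used),
                    key=lambda j: C[i, j])
            greedy[i] = j
            used.add(j)
        assert got == tuple(greedy) == (2, 1, 3, 0)

    def test_large_k_rejected(self, rng):
        H = rng.random((20, 9))
        with pytest.raises(ValueError, match="k <= 8"):
            align_subject_to_reference(H, H)

    def test_order_then_align_is_stable(self, rng):
        H = np.column_stack([_bump(70), _bump(10), _bump(40)])
        dec = _dec(H)
        ordered = apply_permutation(dec, order_synergies(dec))
        assert order_synergies(ordered) == (0, 1, 2)
        assert align_subject_to_reference(ordered.H, ordered.H) == (0, 1, 2)


class TestGroupMean:
    def test_single_subject_mean_is_that_subject(self, rng):
        H = rng.random((50, 3))
        dec = _dec(H)
        g = group_mean_synergies([dec], [(0, 1, 2)])
        np.testing.assert_array_equal(g.mean_H, H)
        np.testing.assert_array_equal(g.sd_W, 0.0)

    def test_identical_subjects_have_zero_weight_sd(self, rng):
        dec = _dec(rng.random((50, 3)))
        g = group_mean_synergies([dec, dec], [(0, 1, 2)] * 2)
        np.testing.assert_allclose(g.mean_H, dec.H)
        np.testing.assert_allclose(g.sd_W, 0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_mean_synergies([], [])

    def test_mixed_k_rejected(self, rng):
        with pytest.raises(ValueError, match="common k"):
            group_mean_synergies(
                [_dec(rng.random((20, 2))), _dec(rng.random((20, 3)))],
                [(0, 1), (0, 1, 2)],
            )


class TestCrossGroupCorrelation:
    def test_self_correlation_has_unit_diagonal(self, rng):
        H = rng.random((101, 4))
        R = crossgroup_correlation(H, H)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_symmetric_under_argument_transpose(self, rng):
        A, B = rng.random((101, 3)), rng.random((101, 3))
        np.testing.assert_allclose(
            crossgroup_correlation(A, B), crossgroup_correlation(B, A).T
        )

    def test_proportional_columns_correlate_perfectly(self):
        a = np.array([1.0, 2.0, 3.0])[:, None]
        b = 2.0 * a
        assert crossgroup_correlation(a, b)[0, 0] == pytest.approx(1.0)

    def test_inverted_ramp_anticorrelates(self):
        a = np.linspace(0, 1, 20)[:, None]
        b = np.linspace(1, 0, 20)[:, None]
        assert crossgroup_correlation(a, b)[0, 0] == pytest.approx(-1.0)

    def test_constant_column_reported_missing_with_warning(self, rng):
        A = rng.random((30, 2))
        B = A.copy()
        B[:, 1] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            R = crossgroup_correlation(A, B)
        assert np.isnan(R[:, 1]).all()


class TestSimilarityBands:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.0, "small"), (0.29, "small"), (0.299999, "small"),
            (0.3, "moderate"), (0.431, "moderate"), (0.457, "moderate"),
            (0.69, "moderate"), (0.7, "high"), (1.0, "high"),
            (-0.8, "high"), (-0.1, "small"),
        ],
    )
    def test_band_mapping(self, r, expected):
        assert classify_similarity(r, warn_borderline=False) == expected

    @pytest.mark.parametrize("r", [0.302, 0.329])
    def test_borderline_moderate_values_carry_advisory_warning(self, r):
        with pytest.warns(BorderlineSimilarityWarning):
            assert classify_similarity(r) == "moderate"

    @pytest.mark.parametrize("r", [0.431, 0.457, 0.75, 0.1])
    def test_clear_values_do_not_warn(self, r, recwarn):
        classify_similarity(r)
        assert not any(
            isinstance(w.message, BorderlineSimilarityWarning)
            for w in recwarn.list
        )

    def test_bands_partition_the_unit_interval(self):
        for r in np.linspace(0, 1, 2001):
            assert classify_similarity(float(r), warn_borderline=False) in (
                "small", "moderate", "high",
            )


def _group_from_weights(Ws, rng, label):
    """GroupSynergySet whose subjects share bursts but differ in weights."""
    H = np.column_stack([_bump(10), _bump(40), _bump(70), _bump(95)])
    decs = [_dec(H + rng.normal(0, 1e-3, H.shape), W) for W in Ws]
    return group_mean_synergies(decs, [(0, 1, 2, 3)] * len(Ws), label)


MUSCLES = ("GA", "TA", "VL", "GM", "BF")


class TestCompareWeights:
    def test_identical_groups_are_never_significant(self, rng):
        Ws = [rng.random((4, 5)) + 0.1 for _ in range(5)]
        ga = _group_from_weights(Ws, np.random.default_rng(0), "A")
        gb = _group_from_weights(Ws, np.random.default_rng(1), "B")
        for cell in compare_weights(ga, gb, MUSCLES):
            assert not cell.significant
            assert cell.missing or cell.p > 1 - 1e-9

    def test_pinned_weights_reported_missing(self, rng):
        W = rng.random((4, 5)) + 0.1
        W[:, 0] = 1.0  # every subject identical in muscle 0
        ga = _group_from_weights([W, W, W], rng, "A")
        gb = _group_from_weights([W, W, W], rng, "B")
        cells = {(c.synergy, c.muscle): c for c in compare_weights(ga, gb,
                                                                   MUSCLES)}
        assert all(cells[(s, "GA")].missing for s in range(4))

    def test_matches_hand_computed_t_statistic(self, rng):
        a_vals = np.array([0.90, 0.91, 0.90, 0.89])
        b_vals = np.array([0.95, 0.96, 0.95, 0.94])
        base = rng.random((4, 5)) + 0.1
        Ws_a = [base.copy() for _ in a_vals]
        Ws_b = [base.copy() for _ in b_vals]
        for W, v in zip(Ws_a, a_vals):
            W[1, 2] = v
        for W, v in zip(Ws_b, b_vals):
            W[1, 2] = v
        # jitter the other entries so no other cell is degenerate
        Ws_a = [W + np.where(np.arange(5) == 2, 0, 1e-3 * i)
                for i, W in enumerate(Ws_a)]
        Ws_b = [W + np.where(np.arange(5) == 2, 0, 1e-3 * i)
                for i, W in enumerate(Ws_b)]
        ga = _group_from_weights(Ws_a, np.random.default_rng(5), "A")
        gb = _group_from_weights(Ws_b, np.random.default_rng(6), "B")
        cell = {(c.synergy, c.muscle): c
                for c in compare_weights(ga, gb, MUSCLES)}[(1, "VL")]

        # pooled-variance two-sample t by the textbook formula
        na, nb = len(a_vals), len(b_vals)
        sp2 = ((na - 1) * a_vals.var(ddof=1) + (nb - 1) * b_vals.var(ddof=1)) \
            / (na + nb - 2)
        t_hand = (a_vals.mean() - b_vals.mean()) / np.sqrt(
            sp2 * (1 / na + 1 / nb)
        )
        assert cell.t == pytest.approx(t_hand)
        assert cell.significant and cell.p < 0.001

    def test_holm_correction_is_more_conservative(self, rng):
        Ws_a = [rng.random((4, 5)) + 0.1 for _ in range(6)]
        Ws_b = [W + rng.normal(0, 0.02, W.shape) for W in Ws_a]
        ga = _group_from_weights(Ws_a, np.random.default_rng(2), "A")
        gb = _group_from_weights(Ws_b, np.random.default_rng(3), "B")
        plain = compare_weights(ga, gb, MUSCLES)
        holm = compare_weights(ga, gb, MUSCLES, correction="holm")
        n_plain = sum(c.significant for c in plain)
        n_holm = sum(c.significant for c in holm)
        assert n_holm <= n_plain
        for c in holm:
            if not c.missing:
                assert c.p_corrected >= c.p - 1e-12


class TestCompareVaf:
    def test_identical_vaf_lists_not_significant(self):
        vafs = {4: [0.95, 0.96, 0.94, 0.95]}
        tests = compare_vaf(vafs, vafs)
        assert len(tests) == 1
        assert not tests[0].significant
        assert tests[0].p == pytest.approx(1.0)

    def test_separated_vaf_lists_significant(self):
        a = {4: [0.900, 0.901, 0.899, 0.900]}
        b = {4: [0.950, 0.951, 0.949, 0.950]}
        (t,) = compare_vaf(a, b)
        assert t.significant and t.p < 1e-6
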