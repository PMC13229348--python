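"""Structure metrics against brute-force oracles and closed-form cases."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinemorph.datatypes import TransitionWeightScheme, default_transition_scheme
from spinemorph.metrics import (
    UndefinedBTSError,
    bts,
    class_overlap,
    composite_scores,
    distance_correlations,
    lcmc,
    sensitivity_suite,
    trustworthiness,
)

from .oracles import (
    bts_oracle,
    lcmc_oracle,
    overlap_grid_oracle,
    pearson_oracle,
    spearman_oracle,
    trustworthiness_oracle,
)


class TestTrustworthiness:
    def test_perfect_for_informative_subspace(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(40, 3))
        X = np.hstack([Z, np.zeros((40, 4))])  # exactly 3 informative dims
        assert trustworthiness(X, Z, k=5) == pytest.approx(1.0, abs=1e-12)

    def test_line_with_swapped_pair_matches_enumeration(self):
        """8 collinear points with one interior pair swapped, k=2."""
        x = np.arange(8, dtype=float)[:, None]
        z = x.copy()
        z[[3, 4]] = z[[4, 3]]
        expected = trustworthiness_oracle(x, z, k=2)
        assert trustworthiness(x, z, k=2) == pytest.approx(expected, abs=1e-12)

    def test_shuffled_embedding_scores_below_identity(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 5))
            perm = rng.permutation(60)
            assert trustworthiness(X, X[perm], k=10) < trustworthiness(X, X, k=10)

    def test_normalization_bound_enforced(self):
        X = np.random.default_rng(1).normal(size=(10, 3))
        with pytest.raises(ValueError, match="normalization bound"):
            trustworthiness(X, X, k=7)  # 2n-3k-1 = -2


class TestLCMC:
    def test_identical_spaces(self):
        X = np.random.default_rng(2).normal(size=(25, 4))
        assert lcmc(X, X, k=5) == pytest.approx(1.0)

    def test_provably_disjoint_neighborhoods(self):
        high = np.array([[0.0], [1.0], [10.0], [11.0]])
        low = np.array([[0.0], [10.0], [1.0], [11.0]])
        assert lcmc(high, low, k=1) == 0.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        Z = rng.normal(size=(12, 2))
        assert lcmc(X, Z, k=3) == pytest.approx(lcmc_oracle(X, Z, 3), abs=1e-12)

    def test_k_bound(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="must be <"):
            lcmc(X, X, k=5)


class TestDistanceCorrelations:
    def test_rigid_scaling_gives_unit_correlations(self):
        X = np.random.default_rng(4).normal(size=(30, 4))
        r, rho = distance_correlations(X, 2.5 * X[:, :3] if False else 2.5 * X)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_monotone_nonlinear_map(self):
        """Embedded distances = exp(original distances): Spearman stays 1,
        Pearson drops below 1. Built as an explicit 3-point triangle whose
        side lengths are the exponentials of the original side lengths."""
        x = np.array([[0.0], [0.1], [0.3]])  # pairwise distances 0.1, 0.3, 0.2
        dab, dac, dbc = np.exp(0.1), np.exp(0.3), np.exp(0.2)
        bx = dab
        cx = (dac**2 - dbc**2 + bx**2) / (2 * bx)
        cy = np.sqrt(dac**2 - cx**2)
        z = np.array([[0.0, 0.0], [bx, 0.0], [cx, cy]])
        r, rho = distance_correlations(x, z)
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert r < 1.0 - 1e-6

    def test_matches_textbook_formulas_on_hand_data(self):
        X = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1], [2, 2]])
        Z = np.array([[0.0], [1.2], [1.9], [3.5], [2.8]])
        from scipy.spatial.distance import pdist

        r, rho = distance_correlations(X, Z)
        assert r == pytest.approx(pearson_oracle(pdist(X), pdist(Z)), abs=1e-12)
        assert rho == pytest.approx(spearman_oracle(pdist(X), pdist(Z)), abs=1e-12)

    def test_constant_distances_rejected(self):
        X = np.random.default_rng(6).normal(size=(4, 2))
        Z = np.zeros((4, 2))
        with pytest.raises(ValueError, match="constant distance"):
            distance_correlations(X, Z)


class TestCompositeScores:
    @pytest.mark.parametrize(
        "T,LCMC,r,rho,field,expected",
        [
            (0.935, 0.444, 0.961, 0.949, "GS", 0.955),  # linear-method row
            (0.975, 0.549, 0.770, 0.774, "LS", 0.762),  # local-optimal row
            (0.935, 0.444, 0.961, 0.949, "SPS", 0.822),
            (0.966, 0.545, 0.926, 0.914, "SPS", 0.838),
            (0.962, 0.543, 0.823, 0.823, "SPS", 0.788),
            (0.928, 0.435, 0.920, 0.900, "SPS", 0.796),
            (0.966, 0.545, 0.926, 0.914, "GS", 0.920),
            (0.928, 0.435, 0.920, 0.900, "GS", 0.910),
        ],
    )
    def test_published_score_table_arithmetic(self, T, LCMC, r, rho, field, expected):
        sc = composite_scores(T, LCMC, r, rho, w_LS=0.5)
        assert sc.rounded()[field] == expected

    @given(
        T=st.floats(0, 1),
        L=st.floats(0, 1),
        r=st.floats(-1, 1),
        rho=st.floats(-1, 1),
        w=st.floats(0, 1),
    )
    def test_exact_linear_identities(self, T, L, r, rho, w):
        sc = composite_scores(T, L, r, rho, w_LS=w)
        assert sc.LS == pytest.approx(0.5 * T + 0.5 * L, abs=1e-12)
        assert sc.GS == pytest.approx(0.5 * r + 0.5 * rho, abs=1e-12)
        assert sc.SPS == pytest.approx(w * sc.LS + (1 - w) * sc.GS, abs=1e-12)
        assert sc.w_LS + sc.w_GS == pytest.approx(1.0)

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValueError):
            composite_scores(0.9, 0.5, 0.9, 0.9, w_LS=1.2)


class TestBTS:
    def test_unit_score_when_all_distances_e_minus_one(self):
        """Equilateral triangle with side e−1, same label: every term is
        w·1/log(e) = 1, so BTS = 1."""
        s = np.e - 1.0
        Z = s * np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        res = bts(Z, ["mushroom"] * 3, k=2)
        assert res.bts == pytest.approx(1.0, abs=1e-9)

    def test_forbidden_transitions_only_raises(self):
        """Thin↔stubby pairs carry weight 0: the denominator vanishes."""
        Z = np.array([[0.0, 0], [0.1, 0], [100, 0], [100.1, 0]])
        with pytest.raises(UndefinedBTSError):
            bts(Z, ["thin", "stubby", "thin", "stubby"], k=1)

    def test_matches_hand_evaluated_double_sum(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(6, 2))
        labels = ["mushroom", "mushroom", "stubby", "thin", "stubby", "thin"]
        scheme = default_transition_scheme()
        expected = bts_oracle(Z, labels, scheme.weight, k=2)
        assert bts(Z, labels, k=2).bts == pytest.approx(expected, abs=1e-12)

    def test_cosine_metric_matches_oracle(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(8, 3))
        labels = ["mushroom", "stubby", "thin", "mushroom"] * 2
        scheme = default_transition_scheme()
        expected = bts_oracle(Z, labels, scheme.weight, k=3, metric="cosine")
        got = bts(Z, labels, k=3, metric="cosine").bts
        assert got == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_weight_preserving_relabeling(self):
        """Swapping thin and stubby leaves the default weight matrix fixed."""
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(20, 3))
        labels = list(rng.choice(["mushroom", "stubby", "thin"], size=20))
        swap = {"mushroom": "mushroom", "stubby": "thin", "thin": "stubby"}
        a = bts(Z, labels, k=4).bts
        b = bts(Z, [swap[lb] for lb in labels], k=4).bts
        assert a == pytest.approx(b, abs=1e-12)

    def test_strictly_decreasing_under_distance_scaling(self):
        rng = np.random.default_rng(10)
        Z = rng.normal(size=(15, 2))
        labels = list(rng.choice(["mushroom", "stubby"], size=15))
        assert bts(3.0 * Z, labels, k=3).bts < bts(Z, labels, k=3).bts

    def test_negative_weights_rejected_by_scheme(self):
        with pytest.raises(ValueError):
            TransitionWeightScheme(
                labels=("a", "b"), W=np.array([[1.0, -0.2], [-0.2, 1.0]])
            )


class TestClassOverlap:
    def test_identical_generators_overlap_high(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(400, 2))
        labels = ["a"] * 200 + ["b"] * 200
        overlaps, ao = class_overlap(Z, labels, seed=1)
        assert ao > 0.8

    def test_far_separated_overlap_negligible(self):
        rng = np.random.default_rng(12)
        Z = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(50, 1, (60, 2))])
        labels = ["a"] * 60 + ["b"] * 60
        _, ao = class_overlap(Z, labels, seed=1)
        assert ao < 0.01

    def test_known_gaussians_match_grid_integration(self):
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(13)
        A = rng.normal([0, 0], 1.0, (300, 2))
        B = rng.normal([2, 0], 1.0, (300, 2))
        overlaps, _ = class_overlap(np.vstack([A, B]), ["a"] * 300 + ["b"] * 300, seed=2)
        expected = overlap_grid_oracle(
            gaussian_kde(A.T), gaussian_kde(B.T), lo=(-6, -6), hi=(8, 6), steps=220
        )
        assert overlaps[("a", "b")] == pytest.approx(expected, abs=0.02)

    def test_small_class_rejected(self):
        Z = np.random.default_rng(14).normal(size=(10, 3))
        labels = ["a"] * 8 + ["b"] * 2
        with pytest.raises(ValueError, match="needs >="):
            class_overlap(Z, labels)

    def test_symmetric_and_rotation_invariant(self):
        rng = np.random.default_rng(15)
        Z = np.vstack([rng.normal(0, 1, (80, 2)), rng.normal(2, 1, (80, 2))])
        labels = ["a"] * 80 + ["b"] * 80
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        _, ao1 = class_overlap(Z, labels, seed=3)
        _, ao2 = class_overlap(Z @ R.T, labels, seed=3)
        assert ao1 == pytest.approx(ao2, abs=0.03)


class TestSensitivitySuite:
    def _embeddings(self, n=50, seed=16):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 5))
        return X, {"identity": X[:, :3].copy(), "shuffled": X[rng.permutation(n), :3]}

    def test_single_point_grids_row_count(self):
        X, lows = self._embeddings()
        labels = ["mushroom", "stubby"] * 25
        table, _ = sensitivity_suite(
            X, lows, labels, k_range=[10], w_range=[0.5], schemes=None
        )
        per_method = table.groupby("method").size()
        assert (per_method == 3 + 1 + 2).all()  # T/LCMC/LS + SPS + BTS x2 metrics

    def test_planted_winner_is_stable(self):
        X, lows = self._embeddings()
        labels = ["mushroom", "stubby"] * 25
        _, stability = sensitivity_suite(
            X, lows, labels, k_range=[5, 10, 15], w_range=[0.3, 0.5, 0.7]
        )
        assert stability["k"] and stability["w_LS"]

    def test_default_scheme_column_matches_direct_call(self):
        X, lows = self._embeddings()
        labels = ["mushroom", "stubby"] * 25
        table, _ = sensitivity_suite(X, lows, labels, k_range=[10], w_range=[0.5])
        row = table[
            (table.method == "identity")
            & (table.sweep == "bts_scheme")
            & (table.parameter == "default/euclidean")
        ]
        direct = bts(lows["identity"], labels, k=10).bts
        assert row.value.iloc[0] == pytest.approx(direct, abs=1e-12)
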