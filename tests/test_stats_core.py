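"""Unit and property tests of the core statistics against enumeration
oracles and independent library implementations."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from peckside import stats_core as sc

from oracles import (
    binomial_exact_oracle,
    mwu_oracle,
    pairwise_u_oracle,
    signed_rank_oracle,
)


class TestBinomialZ:
    @pytest.mark.parametrize(
        "k,n,expected_z",
        [(54, 74, 3.84), (33, 43, 3.35), (39, 54, 3.13), (24, 33, 2.44)],
    )
    def test_continuity_corrected_z_matches_printed_values(self, k, n, expected_z):
        assert sc.binomial_z(k, n).statistic == pytest.approx(expected_z, abs=0.005)

    def test_balanced_counts_give_zero(self):
        res = sc.binomial_z(37, 74)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @given(st.integers(1, 200), st.data())
    def test_antisymmetry(self, n, data):
        k = data.draw(st.integers(0, n))
        assert sc.binomial_z(k, n).statistic == pytest.approx(
            -sc.binomial_z(n - k, n).statistic
        )

    def test_n_zero_rejected(self):
        with pytest.raises(sc.InvalidInputError):
            sc.binomial_z(0, 0)


class TestBinomialExact:
    @pytest.mark.parametrize(
        "k,n,expected_p",
        [(15, 15, 2 * 0.5**15), (10, 20, 1.0), (1, 15, 2 * 16 / 32768)],
    )
    def test_frozen_examples(self, k, n, expected_p):
        res = sc.binomial_exact(k, n)
        assert res.p_value == pytest.approx(expected_p, rel=1e-12)
        assert res.exact

    def test_matches_pmf_summation_oracle_all_small_n(self):
        for n in range(1, 26):
            for k in range(n + 1):
                assert sc.binomial_exact(k, n).p_value == pytest.approx(
                    binomial_exact_oracle(k, n), abs=1e-12
                )

    def test_n_zero_rejected(self):
        with pytest.raises(sc.InvalidInputError):
            sc.binomial_exact(0, 0)


@st.composite
def tie_free_floats(draw, min_size, max_size):
    vals = draw(
        st.lists(
            st.integers(-1000, 1000),
            min_size=min_size,
            max_size=max_size,
            unique=True,
        )
    )
    return [v + 0.5 for v in vals]  # offset away from mu0 = 0


class TestWilcoxonSignedRank:
    def test_symmetric_sample_gives_zero_w(self):
        res = sc.wilcoxon_signed_rank([-2, -1, 1, 2])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_all_positive_small_sample(self):
        res = sc.wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.25)
        assert res.exact

    def test_degenerate_input_rejected(self):
        with pytest.raises(sc.DegenerateInputError):
            sc.wilcoxon_signed_rank([5], mu0=5)

    @given(tie_free_floats(2, 8))
    def test_exact_path_matches_sign_enumeration_oracle(self, values):
        w_oracle, p_oracle = signed_rank_oracle(values)
        res = sc.wilcoxon_signed_rank(values)
        assert res.exact
        assert res.statistic == pytest.approx(w_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self, rng):
        x = rng.normal(0.3, 1.0, size=60)
        ours = sc.wilcoxon_signed_rank(x)
        ref = sps.wilcoxon(x, correction=False, method="approx")
        assert not ours.exact
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestMannWhitney:
    def test_separated_groups(self):
        res = sc.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.exact

    def test_interleaved_groups_match_pairwise_count_oracle(self):
        a, b = [1, 3, 5], [2, 4, 6]
        assert sc.mann_whitney_u(a, b).statistic == pairwise_u_oracle(a, b)

    def test_identical_multisets_show_no_separation(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = sc.mann_whitney_u(a, a)
        assert res.statistic == len(a) ** 2 / 2
        assert res.p_value > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(sc.InvalidInputError):
            sc.mann_whitney_u([], [1.0])

    @given(tie_free_floats(2, 8), st.data())
    def test_exact_path_matches_labeling_enumeration_oracle(self, pooled, data):
        split = data.draw(st.integers(1, len(pooled) - 1))
        a, b = pooled[:split], pooled[split:]
        u_oracle, p_oracle = mwu_oracle(a, b)
        res = sc.mann_whitney_u(a, b)
        assert res.exact
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_normal_approximation_u_matches_scipy_min_u(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)
        ours = sc.mann_whitney_u(a, b)
        u1 = sps.mannwhitneyu(a, b).statistic
        assert ours.statistic == pytest.approx(min(u1, len(a) * len(b) - u1))


class TestKruskalWallis:
    @pytest.mark.parametrize(
        "groups,expected_h",
        [
            ([[1, 2, 3], [4, 5, 6], [7, 8, 9]], 7.2),
            ([[1, 3], [2, 4]], 0.6),
        ],
    )
    def test_hand_computed_h(self, groups, expected_h):
        assert sc.kruskal_wallis(groups).statistic == pytest.approx(expected_h)

    def test_matches_scipy_with_ties(self, rng):
        groups = [list(rng.integers(0, 6, size=8)) for _ in range(3)]
        ours = sc.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    @given(
        st.lists(
            st.lists(st.integers(-50, 50), min_size=2, max_size=6),
            min_size=2,
            max_size=4,
        )
    )
    def test_invariance_under_monotone_transform(self, groups):
        pooled = [v for g in groups for v in g]
        if len(set(pooled)) == 1:
            return
        h1 = sc.kruskal_wallis(groups).statistic
        transformed = [[np.exp(v / 25.0) for v in g] for g in groups]
        h2 = sc.kruskal_wallis(transformed).statistic
        assert h1 == pytest.approx(h2)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(sc.DegenerateInputError):
            sc.kruskal_wallis([[1, 1], [1, 1]])
        with pytest.raises(sc.InvalidInputError):
            sc.kruskal_wallis([[1, 2]])


class TestCohensKappa:
    def test_perfect_agreement(self):
        res = sc.cohens_kappa(np.diag([5, 7, 9]))
        assert res.statistic == pytest.approx(1.0)

    def test_independent_margins_give_zero(self):
        # counts proportional to row x column products
        m = np.outer([2, 3], [4, 1]).astype(float) / 10.0 * 10
        assert sc.cohens_kappa(m).statistic == pytest.approx(0.0, abs=1e-12)

    def test_algebraic_identity_po90_pe375(self):
        # explicit 3x3 matrix with Po = 0.90, Pe = 0.375
        m = [[8, 2, 0], [2, 8, 0], [0, 0, 20]]
        res = sc.cohens_kappa(m)
        assert np.trace(np.asarray(m)) / np.sum(m) == pytest.approx(0.90)
        assert res.statistic == pytest.approx((0.90 - 0.375) / 0.625)
        assert res.statistic == pytest.approx(0.84)
        assert res.extra["percent_agreement"] == pytest.approx(90.0)

    def test_kappa_and_se_match_statsmodels(self, rng):
        ir = pytest.importorskip("statsmodels.stats.inter_rater")
        for _ in range(10):
            m = rng.integers(0, 20, size=(3, 3)) + np.diag(rng.integers(5, 15, 3))
            ref = ir.cohens_kappa(m)
            ours = sc.cohens_kappa(m)
            assert ours.statistic == pytest.approx(ref.kappa)
            assert ours.extra["se"] == pytest.approx(np.sqrt(ref.var_kappa))

    @given(
        st.lists(
            st.lists(st.integers(0, 30), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        )
    )
    def test_kappa_at_most_one_and_one_iff_diagonal(self, m):
        m = np.asarray(m)
        if m.sum() < 1:
            return
        try:
            res = sc.cohens_kappa(m)
        except sc.DegenerateInputError:
            return
        assert res.statistic <= 1.0 + 1e-12
        off_diag = m.sum() - np.trace(m)
        assert (abs(res.statistic - 1.0) < 1e-12) == (off_diag == 0)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(sc.DegenerateInputError):
            sc.cohens_kappa([[5, 0], [0, 0]])


class TestPValueRange:
    """All p-values stay in [0,1] under randomized-input fuzzing."""

    def test_fuzz_all_tests(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            for fn in (sc.binomial_z, sc.binomial_exact):
                assert 0.0 <= fn(k, n).p_value <= 1.0
            x = rng.normal(0, 1, size=int(rng.integers(2, 25)))
            if np.any(x != 0):
                assert 0.0 <= sc.wilcoxon_signed_rank(x).p_value <= 1.0
            a = rng.integers(0, 8, size=int(rng.integers(1, 12))).astype(float)
            b = rng.integers(0, 8, size=int(rng.integers(1, 12))).astype(float)
            try:
                assert 0.0 <= sc.mann_whitney_u(a, b).p_value <= 1.0
            except sc.DegenerateInputError:
                pass
            groups = [
                list(rng.integers(0, 10, size=int(rng.integers(2, 6))))
                for _ in range(int(rng.integers(2, 5)))
            ]
            try:
                assert 0.0 <= sc.kruskal_wallis(groups).p_value <= 1.0
            except sc.DegenerateInputError:
                pass
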