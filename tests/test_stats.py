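"""Per-variant statistics against hand evaluations, enumeration oracles and
scipy's exact test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps
from scipy.special import comb

from bsaqtl.stats import (
    adjust_q,
    compute_statistics,
    delta_snp_index,
    euclidean_distance,
    fisher_test,
    g_statistic,
    snp_index,
)
from conftest import make_table


def fisher_two_sided_enumeration(rh, ah, rl, al):
    """Independent oracle: enumerate every 2x2 table with the observed
    margins and sum the probabilities of tables no more probable than the
    observed one (probabilities from binomial coefficients directly)."""
    n1, n2, K = rh + ah, rl + al, ah + al
    denom = comb(n1 + n2, K, exact=True)
    support = range(max(0, K - n2), min(K, n1) + 1)
    probs = {
        k: comb(n1, k, exact=True) * comb(n2, K - k, exact=True) / denom
        for k in support
    }
    p_obs = probs[ah]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestSnpIndexAndDelta:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(10, 0, 0.0), (0, 12, 1.0), (6, 6, 0.5)]
    )
    def test_snp_index_examples(self, ref, alt, expected):
        assert snp_index(ref, alt) == expected

    def test_zero_depth_flagged_nan(self):
        assert np.isnan(snp_index(0, 0))

    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 10, 10, 10), 0.0), ((0, 20, 20, 0), 1.0), ((5, 15, 15, 5), 0.5)],
    )
    def test_delta_examples(self, counts, expected):
        assert delta_snp_index(*counts) == pytest.approx(expected)


class TestEuclideanDistance:
    def test_examples(self):
        assert euclidean_distance(10, 10, 5, 5)[0] == pytest.approx(0.0)
        assert euclidean_distance(0, 20, 20, 0)[0] == pytest.approx(np.sqrt(2))
        ed, ed2 = euclidean_distance(5, 15, 15, 5, power=2)
        assert ed == pytest.approx(np.sqrt(2) * 0.5)
        assert ed2 == pytest.approx(0.5)

    def test_ed_equals_sqrt2_times_delta_fraction(self, rng):
        counts = rng.integers(0, 30, size=(200, 4)) + 1
        ed, _ = euclidean_distance(*counts.T)
        delta = delta_snp_index(*counts.T)
        np.testing.assert_allclose(ed, np.sqrt(2) * np.abs(delta), atol=1e-12)


class TestGStatistic:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 10, 10, 10), 0.0),
            ((20, 0, 0, 20), 80 * np.log(2)),
            ((15, 5, 5, 15), 2 * (30 * np.log(1.5) + 10 * np.log(0.5))),
        ],
    )
    def test_hand_evaluated_cell_sums(self, counts, expected):
        assert g_statistic(*counts) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_margins_give_zero(self):
        assert g_statistic(10, 0, 20, 0) == 0.0  # empty alt column
        assert g_statistic(0, 0, 10, 10) == 0.0  # empty high row

    def test_matches_scipy_power_divergence(self, rng):
        """Cross-check on random non-degenerate tables against scipy's
        log-likelihood-ratio statistic."""
        counts = rng.integers(1, 40, size=(100, 4))
        ours = g_statistic(*counts.T)
        for row, g in zip(counts, ours):
            table = row.reshape(2, 2)
            expected = sps.chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            ).statistic
            assert g == pytest.approx(expected, rel=1e-9)


class TestFisher:
    def test_modal_table_has_p_one(self):
        assert fisher_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_perfect_separation(self):
        expected = 2 / comb(20, 10, exact=True)
        assert fisher_test(0, 10, 10, 0) == pytest.approx(expected, rel=1e-10)

    def test_enumeration_oracle_small_margins(self):
        """Exhaustive check against the hypergeometric enumeration oracle on
        a lattice of tables with margins <= 12."""
        for n1, n2 in itertools.product([0, 1, 3, 7, 12], repeat=2):
            for ah, al in itertools.product(range(n1 + 1), range(n2 + 1)):
                if n1 + n2 == 0:
                    continue
                ours = fisher_test(n1 - ah, ah, n2 - al, al)
                oracle = fisher_two_sided_enumeration(n1 - ah, ah, n2 - al, al)
                assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_matches_scipy_fisher_exact(self, rng):
        counts = rng.integers(0, 50, size=(100, 4))
        counts = counts[(counts.sum(axis=1) > 0)]
        ours = fisher_test(*counts.T)
        for row, p in zip(counts, ours):
            ref = sps.fisher_exact(row.reshape(2, 2)).pvalue
            assert p == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_g_and_fisher_order_consistently_on_fixed_margins(self):
        """On tables sharing margins, larger G implies smaller-or-equal
        Fisher p (both order by departure from independence)."""
        n1 = n2 = 20
        for K in (10, 20, 30):
            rows = [
                (n1 - ah, ah, n2 - (K - ah), K - ah)
                for ah in range(max(0, K - n2), min(K, n1) + 1)
            ]
            g = np.array([g_statistic(*r) for r in rows])
            p = np.array([fisher_test(*r) for r in rows])
            order = np.argsort(g)
            assert (np.diff(p[order]) <= 1e-9).all()


class TestAdjustQ:
    def test_step_up_examples(self):
        np.testing.assert_allclose(adjust_q([1.0, 1.0, 1.0]), [1, 1, 1])
        np.testing.assert_allclose(
            adjust_q([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert adjust_q([0.37])[0] == pytest.approx(0.37)

    def test_hand_recursion(self):
        """q_i = min_{j>=i} p_(j) * m / j, checked against the step-up
        recursion computed directly."""
        p = np.array([0.005, 0.04, 0.03, 0.8, 0.2])
        order = np.argsort(p)
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        expected_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        np.testing.assert_allclose(adjust_q(p), expected)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(1e-6, 1, size=200)
        q = adjust_q(p)
        assert (q >= p - 1e-12).all()


class TestLabelSymmetry:
    @given(hst.integers(0, 123456))
    @settings(max_examples=25, deadline=None)
    def test_swapping_pools_negates_delta_only(self, seed):
        rng = np.random.default_rng(seed)
        rh, ah, rl, al = rng.integers(1, 60, size=4)
        assert delta_snp_index(rl, al, rh, ah) == pytest.approx(
            -delta_snp_index(rh, ah, rl, al)
        )
        assert euclidean_distance(rl, al, rh, ah)[0] == pytest.approx(
            euclidean_distance(rh, ah, rl, al)[0]
        )
        assert g_statistic(rl, al, rh, ah) == pytest.approx(
            g_statistic(rh, ah, rl, al), rel=1e-9
        )
        assert fisher_test(rl, al, rh, ah) == pytest.approx(
            fisher_test(rh, ah, rl, al), rel=1e-9
        )


class TestComputeStatistics:
    def test_zero_depth_site_excluded_from_all_statistics(self):
        t = make_table([
            ("Gm01", 100, 10, 10, 10, 10),
            ("Gm01", 200, 0, 0, 10, 10),
        ])
        out = compute_statistics(t)
        row = out.iloc[1]
        assert np.isnan(row[["delta_snp_index", "ed", "g_stat", "fisher_p",
                             "fisher_q"]].astype(float)).all()

    def test_null_type_one_error_rate_not_inflated(self, rng):
        """At independent null sites (both pools Binomial(20, 1/2)) the rate
        of fisher_p < 0.05 stays at or below 0.05 plus 3 SE (the exact test
        is conservative on discrete tables)."""
        n = 4000
        ah = rng.binomial(20, 0.5, n)
        al = rng.binomial(20, 0.5, n)
        t = make_table([
            ("Gm01", i + 1, int(20 - a), int(a), int(20 - b), int(b))
            for i, (a, b) in enumerate(zip(ah, al))
        ])
        out = compute_statistics(t)
        rate = (out["fisher_p"] < 0.05).mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_null_delta_mean_near_zero(self, rng):
        n = 4000
        ah = rng.binomial(20, 0.5, n)
        al = rng.binomial(20, 0.5, n)
        t = make_table([
            ("Gm01", i + 1, int(20 - a), int(a), int(20 - b), int(b))
            for i, (a, b) in enumerate(zip(ah, al))
        ])
        out = compute_statistics(t)
        se = out["delta_snp_index"].std() / np.sqrt(n)
        assert abs(out["delta_snp_index"].mean()) < 3 * se
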