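"""Nonparametric tests against exhaustive and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, rankdata

import lscpanel as lp


def u_statistic(a, b):
    """Brute-force Mann-Whitney U for the first sample (half credit for ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))


def exact_two_sided_p(a, b):
    """Exhaustive enumeration of all group labelings of the pooled sample."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mid = n1 * len(b) / 2.0
    u_obs = u_statistic(a, b)
    us = [
        u_statistic([pooled[i] for i in comb],
                    [pooled[i] for i in range(len(pooled)) if i not in set(comb)])
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    return float(np.mean([abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us]))


class TestMannWhitney:
    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2], [3, 4]),
            ([1, 5, 3], [2, 8, 9, 4]),
            ([10, 2, 7], [1, 3, 5, 6]),
            ([0.1, 0.9, 0.5, 0.7], [0.2, 0.3, 0.4, 0.6]),
            ([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12]),
        ],
    )
    def test_exact_p_matches_enumeration(self, a, b):
        r = lp.mann_whitney(a, b)
        assert r.statistic == u_statistic(a, b)
        assert r.p_value == pytest.approx(exact_two_sided_p(a, b), abs=1e-12)

    def test_smallest_case_closed_form(self):
        r = lp.mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(2 / math.comb(4, 2), abs=1e-12)

    def test_identical_multisets(self):
        a = [1.0, 2.0, 3.0]
        r = lp.mann_whitney(a, a)
        assert r.statistic == len(a) ** 2 / 2
        assert r.p_value > 0.9

    def test_large_shift_reaches_minimum_p(self):
        a = [1, 2, 3, 4, 5]
        b = [x + 1000 for x in a]
        r = lp.mann_whitney(a, b)
        assert r.p_value == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=15, unique=True),
           st.lists(st.integers(51, 150), min_size=3, max_size=15, unique=True))
    def test_monotone_transform_invariance(self, a, b):
        base = lp.mann_whitney(a, b)
        cubed = lp.mann_whitney([x**3 for x in a], [x**3 for x in b])
        assert cubed.statistic == base.statistic
        assert cubed.p_value == base.p_value

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            lp.mann_whitney([], [1.0])

    def test_null_p_values_uniform(self):
        """Under the null the asymptotic p-values are uniform within KS
        tolerance (2,000 fixed-seed replicates at n=30 per group)."""
        rng = np.random.default_rng(42)
        ps = [
            lp.mann_whitney(rng.normal(size=30), rng.normal(size=30)).p_value
            for _ in range(2000)
        ]
        assert kstest(ps, "uniform").statistic < 0.05


class TestKruskalWallis:
    def test_all_equal(self):
        r = lp.kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_two_group_equivalence_to_squared_deviate(self):
        """Tie-free two-group H equals the squared Mann-Whitney normal
        deviate (direct computation oracle)."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=8)  # continuous draws: tie-free a.s.
            b = rng.normal(size=11)
            u = u_statistic(a, b)
            n1, n2 = len(a), len(b)
            z = (u - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
            h = lp.kruskal_wallis([a, b]).statistic
            assert h == pytest.approx(z**2, abs=1e-10)

    def test_disjoint_groups_attain_maximum_h(self):
        """Three disjoint-range groups of 3 maximize H over all rank
        partitions (brute force at n=9)."""
        groups = [[1, 2, 3], [11, 12, 13], [21, 22, 23]]
        h_obs = lp.kruskal_wallis(groups).statistic
        ranks = list(range(1, 10))
        h_max = 0.0
        for g1 in itertools.combinations(ranks, 3):
            rest = [r for r in ranks if r not in g1]
            for g2 in itertools.combinations(rest, 3):
                g3 = [r for r in rest if r not in g2]
                n = 9
                h = (12 / (n * (n + 1))) * sum(
                    len(g) * (np.mean(g) - (n + 1) / 2) ** 2 for g in (g1, g2, g3)
                )
                h_max = max(h_max, h)
        assert h_obs == pytest.approx(h_max, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            lp.kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            lp.kruskal_wallis([[1.0], []])


class TestBonferroni:
    def test_three_posthoc_comparisons(self):
        assert round(lp.bonferroni(0.05, 3), 3) == 0.017

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_direct_values(self, alpha, m, expected):
        assert lp.bonferroni(alpha, m) == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 0.999), st.integers(1, 1000))
    def test_exact_inverse(self, alpha, m):
        assert lp.bonferroni(alpha, m) * m == pytest.approx(alpha, rel=1e-15)

    def test_errors(self):
        with pytest.raises(ValueError):
            lp.bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            lp.bonferroni(1.5, 3)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert lp.spearman(x, [10, 20, 30, 40, 50]) == pytest.approx(1.0)
        assert lp.spearman(x, [50, 40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_data_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = rng.integers(0, 5, 40).astype(float)
        expected = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert lp.spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            lp.spearman([1, 2, 3], [1, 2])


class TestProfileBands:
    def control(self, vals):
        return pd.DataFrame({"M": vals})

    def test_direct_arithmetic(self):
        bands = lp.profile_bands(self.control([8.0, 10.0, 12.0]))  # mean 10, SD 2
        values = pd.DataFrame({"M": [11.0, 13.0, 15.0]}, index=["a", "b", "c"])
        out = lp.assign_bands(values, bands)
        assert out["M"].tolist() == [0, 1, 2]

    def test_subject_at_control_mean_is_band_zero(self):
        bands = lp.profile_bands(self.control([8.0, 10.0, 12.0]))
        out = lp.assign_bands(pd.DataFrame({"M": [10.0]}), bands)
        assert out["M"].iloc[0] == 0

    def test_degenerate_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            bands = lp.profile_bands(self.control([0.0, 0.0, 0.0]))
        assert bands.loc["M", "degenerate"]
        out = lp.assign_bands(pd.DataFrame({"M": [0.5]}), bands)
        assert out["M"].iloc[0] == 2  # any positive value lands in the top band

    def test_too_few_controls(self):
        with pytest.raises(ValueError):
            lp.profile_bands(self.control([1.0]))


def test_compare_cohorts_structure(small_summaries):
    summaries, metadata = small_summaries
    ds = lp.build_dataset(summaries, metadata, "affected_area")
    out = lp.compare_cohorts(ds)
    assert set(out["marker"]) == set(ds.markers)
    assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()
    assert (out["significant"] == (out["p_value"] <= out["adjusted_alpha"])).all()
    # post hocs run at the Bonferroni level exactly when the omnibus test hits
    posthoc = out[out["comparison"].str.contains(" vs ")
                  & (out["adjusted_alpha"] < 0.05)]
    assert np.allclose(posthoc["adjusted_alpha"], 0.05 / 3)
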