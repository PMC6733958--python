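import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from specnet import synthesis
from specnet.cohort_io import MEDALIST, NON_MEDALIST
from specnet.comparison import (
    ComparisonError,
    compare_link_weights,
    compare_spectral_radii,
    oneway_anova,
    permutation_group_test,
    tukey_hsd,
)
from specnet.network import build_network

from conftest import network_from_matrix

# spectral radii printed for the five editions, medalists then non-medalists
MEDALIST_SR = [3.75, 3.5, 3.39, 2.91, 3.66]
NON_MEDALIST_SR = [2.18, 2.51, 2.23, 2.07, 2.04]


def sr_entries(values, group):
    return [
        SimpleNamespace(edition_label=f"E{i}", group_label=group, spectral_radius=v)
        for i, v in enumerate(values)
    ]


class TestOnewayAnova:
    def test_identical_groups(self):
        f, p = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        # SS_between = 8, SS_within = 10, df = (1, 6)
        f, p = oneway_anova([[1, 2, 3, 4], [3, 4, 5, 6]])
        assert f == pytest.approx(4.8, abs=1e-12)
        assert p == pytest.approx(stats.f.sf(4.8, 1, 6), abs=1e-12)
        assert p == pytest.approx(0.071, abs=5e-4)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(size=n) for n in (4, 7, 5)]
        f, p = oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_within_variance(self):
        with pytest.raises(ComparisonError, match="within-group variance"):
            oneway_anova([[1.0, 1.0], [2.0, 2.0]])

    def test_group_too_small(self):
        with pytest.raises(ComparisonError, match="n >= 2"):
            oneway_anova([[1.0], [2.0, 3.0]])

    def test_single_group_rejected(self):
        with pytest.raises(ComparisonError, match="at least 2 groups"):
            oneway_anova([[1.0, 2.0]])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_f_equals_t_squared_for_two_groups(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(3, 10)))
        b = rng.normal(1.0, size=int(rng.integers(3, 10)))
        f, p = oneway_anova([a, b])
        t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t.statistic**2, rel=1e-9, abs=1e-12)
        assert p == pytest.approx(t.pvalue, rel=1e-9)


class TestTukeyHsd:
    def test_identical_groups(self):
        pairs = tukey_hsd([[1, 2, 3], [1, 2, 3]])
        assert pairs[0].adjusted_p == pytest.approx(1.0, abs=1e-9)
        assert pairs[0].mean_diff == 0.0

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_q_is_sqrt_two_f_for_two_groups(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        a, b = rng.normal(size=n), rng.normal(0.5, size=n)
        f, p_anova = oneway_anova([a, b])
        pair = tukey_hsd([a, b])[0]
        assert pair.q_statistic == pytest.approx(np.sqrt(2 * f), abs=1e-9)
        assert pair.adjusted_p == pytest.approx(p_anova, abs=1e-6)

    def test_three_groups_match_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(17)
        groups = [rng.normal(loc, size=6) for loc in (0.0, 0.5, 1.2)]
        pairs = tukey_hsd(groups, labels=["a", "b", "c"])
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], 6)
        ref = statsmodels.pairwise_tukeyhsd(data, labels)
        for pair, p_ref in zip(pairs, ref.pvalues):
            assert pair.adjusted_p == pytest.approx(p_ref, abs=1e-6)

    def test_label_count_mismatch(self):
        with pytest.raises(ComparisonError, match="label"):
            tukey_hsd([[1, 2], [3, 4]], labels=["only_one"])


class TestCompareLinkWeights:
    def _net(self, rng, loc=0.0, label=MEDALIST, labels=("a", "b", "c", "d")):
        matrix = rng.normal(loc, 1.0, size=(8, len(labels)))
        return build_network(matrix, labels, group_label=label)

    def test_separated_constant_networks(self):
        w_hi = np.full((4, 4), 0.9)
        np.fill_diagonal(w_hi, 0.0)
        w_lo = np.full((4, 4), 0.3)
        np.fill_diagonal(w_lo, 0.0)
        net_a = network_from_matrix(w_hi)
        net_b = dataclasses.replace(
            network_from_matrix(w_lo), group_label=NON_MEDALIST
        )
        result = compare_link_weights(net_a, net_b)
        assert result.larger_group == MEDALIST
        assert result.anova_p == pytest.approx(0.0)

    def test_identical_networks(self, rng, small_network):
        result = compare_link_weights(small_network, small_network)
        assert result.anova_f == pytest.approx(0.0, abs=1e-12)
        assert result.anova_p == pytest.approx(1.0)
        assert result.larger_group is None

    def test_node_set_mismatch(self, rng):
        net_a = self._net(rng)
        net_b = self._net(rng, labels=("a", "b", "c", "e"))
        with pytest.raises(ComparisonError, match="node sets"):
            compare_link_weights(net_a, net_b)

    def test_mode_mismatch(self, rng, small_network):
        other = dataclasses.replace(small_network.copy(), weight_mode="signed")
        with pytest.raises(ComparisonError, match="weight mode"):
            compare_link_weights(small_network, other)

    def test_default_loadings_separate_groups(self):
        """Medalist-like loading (0.85) beats non-medalist (0.45) in >=90/100 runs."""
        rng = np.random.default_rng(31)
        params = synthesis.default_edition_params()
        sydney_med, sydney_non = params[0], params[1]
        wins = 0
        for _ in range(100):
            med = synthesis.generate_cohort(sydney_med, rng=rng)
            non = synthesis.generate_cohort(sydney_non, rng=rng, rank_start=4)
            mat_m = np.array(
                [[r.variable(v) for v in sydney_med.means] for r in med]
            )
            mat_n = np.array(
                [[r.variable(v) for v in sydney_med.means] for r in non]
            )
            net_m = build_network(mat_m, tuple(sydney_med.means), group_label=MEDALIST)
            net_n = build_network(
                mat_n, tuple(sydney_med.means), group_label=NON_MEDALIST
            )
            result = compare_link_weights(net_m, net_n)
            wins += result.larger_group == MEDALIST
        assert wins >= 90


class TestCompareSpectralRadii:
    def test_published_sr_lists(self):
        summaries = sr_entries(MEDALIST_SR, MEDALIST) + sr_entries(
            NON_MEDALIST_SR, NON_MEDALIST
        )
        result = compare_spectral_radii(summaries)
        by_label = {g.label: g for g in result.group_summaries}
        assert by_label[MEDALIST].mean == pytest.approx(3.442)
        assert by_label[NON_MEDALIST].mean == pytest.approx(2.206)
        assert result.larger_group == MEDALIST
        assert len(result.per_edition_ordering) == 5
        assert all(result.per_edition_ordering.values())
        assert result.anova_p < 0.05

    def test_identical_lists(self):
        summaries = sr_entries(MEDALIST_SR, MEDALIST) + sr_entries(
            MEDALIST_SR, NON_MEDALIST
        )
        result = compare_spectral_radii(summaries)
        assert result.anova_f == pytest.approx(0.0, abs=1e-12)
        assert not any(result.per_edition_ordering.values())
        assert result.larger_group is None

    def test_needs_two_values_per_group(self):
        summaries = sr_entries([3.0], MEDALIST) + sr_entries([2.0, 2.1], NON_MEDALIST)
        with pytest.raises(ComparisonError, match="need >= 2"):
            compare_spectral_radii(summaries)

    def test_needs_two_groups(self):
        with pytest.raises(ComparisonError, match="2 group labels"):
            compare_spectral_radii(sr_entries(MEDALIST_SR, MEDALIST))


class TestPermutationTest:
    def _cohort_pair(self, loading_a, loading_b, rng, params):
        med = dataclasses.replace(params, n_athletes=3).with_loading(loading_a)
        non = dataclasses.replace(params, n_athletes=5).with_loading(loading_b)
        return (
            synthesis.generate_cohort(med, rng=rng),
            synthesis.generate_cohort(non, rng=rng, rank_start=4),
        )

    def test_reproducible(self, sydney_medalists, rng):
        a, b = self._cohort_pair(0.8, 0.3, rng, sydney_medalists)
        p1, obs1 = permutation_group_test(a, b, n_permutations=199, seed=5)
        p2, obs2 = permutation_group_test(a, b, n_permutations=199, seed=5)
        assert p1 == p2
        assert obs1 == obs2

    def test_minimum_achievable_p(self, sydney_medalists):
        # a fully separated construction can reach p = 1/(n_perm + 1)
        rng = np.random.default_rng(0)
        best = 1.0
        for rep in range(20):
            a, b = self._cohort_pair(1.0, 0.0, rng, sydney_medalists)
            # vary the shuffle seed: a run whose 99 shuffles never redraw
            # the observed partition attains the minimum
            p, _ = permutation_group_test(a, b, n_permutations=99, seed=rep)
            best = min(best, p)
        assert best == pytest.approx(1.0 / 100.0)

    def test_p_at_least_minimum(self, sydney_medalists, rng):
        a, b = self._cohort_pair(0.9, 0.1, rng, sydney_medalists)
        p, _ = permutation_group_test(a, b, n_permutations=99, seed=1)
        assert p >= 1.0 / 100.0

    def test_null_rarely_significant(self, sydney_medalists):
        rng = np.random.default_rng(77)
        significant = 0
        for _ in range(100):
            a, b = self._cohort_pair(0.5, 0.5, rng, sydney_medalists)
            p, _ = permutation_group_test(a, b, n_permutations=99, seed=11)
            significant += p <= 0.05
        assert significant <= 10

    def test_too_few_permutations(self, sydney_medalists, rng):
        a, b = self._cohort_pair(0.5, 0.5, rng, sydney_medalists)
        with pytest.raises(ComparisonError, match="at least 99"):
            permutation_group_test(a, b, n_permutations=10)

    def test_too_few_athletes(self, sydney_medalists, rng):
        a, b = self._cohort_pair(0.5, 0.5, rng, sydney_medalists)
        with pytest.raises(ComparisonError, match="pooled"):
            permutation_group_test(a[:2], b[:2], n_permutations=99)
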