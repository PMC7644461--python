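import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import planktonet as pk
from planktonet.networks import CorrelationNetwork


def _midrank_pearson(x, y):
    """Independent Spearman oracle: mid-ranks then the Pearson formula."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearmanRho:
    def test_perfect_concordance(self):
        assert pk.spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert pk.spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [2, 1, 3, 4]
        assert pk.spearman_rho(x, y) == pytest.approx(_midrank_pearson(x, y), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert pk.spearman_rho(x, y) == pytest.approx(pk.spearman_rho(y, x), abs=1e-14)

    def test_constant_series_error(self):
        with pytest.raises(ValueError, match="constant"):
            pk.spearman_rho([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            pk.spearman_rho([1, 2, 3], [1, 2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=4, max_size=20, unique=True),
           st.integers(0, 2**31 - 1))
    def test_monotone_invariance(self, xs, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=len(xs))
        if np.ptp(y) == 0:
            return
        x = np.array(xs, dtype=float)
        r1 = pk.spearman_rho(x, y)
        r2 = pk.spearman_rho(np.exp(x / 10**6), y)  # strictly increasing transform
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPermutationPvalue:
    def test_identity_pair_n5_matches_enumeration(self):
        # exhaustive: only identity and reversal of 5 elements reach |rho|=1,
        # so the exceedance probability is 2/120 and the add-one estimate
        # converges there
        x = np.arange(5.0)
        rho, p = pk.permutation_pvalue(x, x, n_iter=49999, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120, abs=0.004)

    def test_all_permutations_tie_at_n3_monotone(self):
        # n=3 distinct values: |rho| of any permutation is 1 or 0.5; with the
        # observed |rho|=1 only 2 of 6 permutations tie -> p near 1/3
        rho, p = pk.permutation_pvalue([1, 2, 3], [1, 2, 3], n_iter=9999, seed=1)
        assert p == pytest.approx(1 / 3, abs=0.02)

    def test_p_in_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r1, p1 = pk.permutation_pvalue(x, y, n_iter=999, seed=7)
        r2, p2 = pk.permutation_pvalue(x, y, n_iter=999, seed=7)
        assert (r1, p1) == (r2, p2)
        assert 0 < p1 <= 1

    def test_swap_arguments_preserves_rho(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r_xy, _ = pk.permutation_pvalue(x, y, n_iter=99, seed=0)
        r_yx, _ = pk.permutation_pvalue(y, x, n_iter=99, seed=0)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)

    def test_type_i_error_near_alpha(self):
        # under independence, rejection rate at alpha=0.05 stays within the
        # 95% binomial interval (simulation, reduced iteration count)
        rng = np.random.default_rng(5)
        n_sims, alpha = 400, 0.05
        rejections = 0
        for _ in range(n_sims):
            x, y = rng.normal(size=19), rng.normal(size=19)
            _, p = pk.permutation_pvalue(x, y, n_iter=199, seed=rng)
            rejections += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rejections / n_sims - alpha) < 1.96 * se + 1 / n_sims


class TestBuildNetworks:
    def test_monotone_pair_lands_in_positive_network(self, small_taxa):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.lognormal(size=(15, 6)),
            index=pd.date_range("2015-01-01", periods=15, freq="7D"),
            columns=[1, 2, 3, 4, 5, 6],
        )
        m[2] = np.exp(np.log(m[1]) * 1.3)  # strictly increasing in column 1
        nets = pk.build_networks(m, n_iter=999, seed=0)
        pos_pairs = set(zip(nets["positive"].edges["taxon_a"], nets["positive"].edges["taxon_b"]))
        assert (1, 2) in pos_pairs

    def test_false_positive_rate_under_independence(self):
        # 12 independent columns: expected significant pairs ~ alpha * C(12,2)
        rng = np.random.default_rng(1)
        total_edges, reps = 0, 30
        for _ in range(reps):
            m = pd.DataFrame(
                rng.normal(size=(19, 12)),
                index=pd.date_range("2015-01-01", periods=19, freq="7D"),
                columns=range(1, 13),
            )
            nets = pk.build_networks(m, n_iter=199, seed=int(rng.integers(2**31)))
            total_edges += nets["combined"].n_edges
        expected = 0.05 * 66
        assert total_edges / reps == pytest.approx(expected, rel=0.5)

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            rng.normal(size=(10, 3)),
            index=pd.date_range("2015-01-01", periods=10, freq="7D"),
            columns=[1, 2, 3],
        )
        m[3] = 5.0
        nets = pk.build_networks(m, n_iter=99, seed=0)
        assert nets["combined"].dropped_taxa == [3]

    def test_combined_is_disjoint_union_of_signed_networks(self, small_campaign):
        m = small_campaign["abundance"].iloc[:12]
        nets = pk.build_networks(m, n_iter=199, seed=3)
        neg, pos, comb = nets["negative"], nets["positive"], nets["combined"]
        assert comb.n_edges == neg.n_edges + pos.n_edges
        key = lambda e: set(map(tuple, e.edges[["taxon_a", "taxon_b"]].to_numpy()))
        assert key(comb) == key(neg) | key(pos)
        assert not (key(neg) & key(pos))
        assert comb.n_nodes >= max(neg.n_nodes, pos.n_nodes)

    def test_edge_pvalues_independent_of_pair_order(self, small_campaign):
        # per-pair child seeds: removing columns does not change the p-value
        # of the remaining pairs
        m = small_campaign["abundance"].iloc[:12]
        full = pk.build_networks(m, n_iter=199, seed=9)["combined"].edges
        subset = pk.build_networks(m[list(m.columns[:10])], n_iter=199, seed=9)["combined"].edges
        merged = subset.merge(full, on=["taxon_a", "taxon_b"], suffixes=("_s", "_f"))
        assert len(merged) == len(subset)
        assert np.allclose(merged["p_s"], merged["p_f"])


class TestDescriptorsAndHubs:
    def test_mean_degree_and_degree_sum_invariants(self, small_campaign):
        m = small_campaign["abundance"].iloc[:12]
        for net in pk.build_networks(m, n_iter=199, seed=4).values():
            d = pk.descriptors(net)
            if d.n_nodes:
                assert d.mean_degree == round(2 * d.n_edges / d.n_nodes, 2)
            assert sum(d.degree_by_node.values()) == 2 * d.n_edges

    def test_empty_network_descriptors(self):
        empty = CorrelationNetwork(
            "x", "combined",
            pd.DataFrame(columns=["taxon_a", "taxon_b", "rho", "p", "sign"]),
            alpha=0.05, n_permutations=9,
        )
        d = pk.descriptors(empty)
        assert (d.n_nodes, d.n_edges, d.mean_degree) == (0, 0, 0.0)
        assert pk.hubs(empty) == []

    def test_star_graph_hub(self):
        edges = pd.DataFrame(
            [(1, c, 0.9, 0.01, "+") for c in (2, 3, 4, 5)],
            columns=["taxon_a", "taxon_b", "rho", "p", "sign"],
        )
        net = CorrelationNetwork("x", "positive", edges, alpha=0.05, n_permutations=9)
        top = pk.hubs(net, k=1)
        assert top == [(1, 4)]

    def test_tied_hubs_lower_id_first(self):
        edges = pd.DataFrame(
            [(1, 2, 0.9, 0.01, "+"), (3, 4, 0.9, 0.01, "+")],
            columns=["taxon_a", "taxon_b", "rho", "p", "sign"],
        )
        net = CorrelationNetwork("x", "positive", edges, alpha=0.05, n_permutations=9)
        assert pk.hubs(net, k=2) == [(1, 1), (2, 1)]


class TestAutocorrelationReport:
    def test_white_noise_flag_rate(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(
            rng.normal(size=(60, 40)),
            index=pd.date_range("2015-01-01", periods=60, freq="7D"),
            columns=range(1, 41),
        )
        rep = pk.autocorrelation_report(m, max_lag=5)
        rate = rep["significant"].mean()
        assert 0.0 < rate < 0.12  # around the nominal 5%

    def test_linear_trend_lag1_matches_closed_form(self):
        n = 30
        m = pd.DataFrame({1: np.arange(n, dtype=float), 2: np.random.default_rng(1).normal(size=n)},
                         index=pd.date_range("2015-01-01", periods=n, freq="7D"))
        rep = pk.autocorrelation_report(m, max_lag=1)
        # closed form for the lag-1 ACF of 0..n-1 with the biased estimator
        t = np.arange(n) - (n - 1) / 2
        expected = (t[1:] * t[:-1]).sum() / (t * t).sum()
        got = rep.loc[rep["taxon_id"] == 1, "acf"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_constant_column_reported_missing(self):
        m = pd.DataFrame({1: np.ones(12), 2: np.arange(12.0)},
                         index=pd.date_range("2015-01-01", periods=12, freq="7D"))
        rep = pk.autocorrelation_report(m, max_lag=2)
        assert rep.loc[rep["taxon_id"] == 1, "acf"].isna().all()

    def test_too_few_samples_error(self):
        m = pd.DataFrame({1: np.arange(5.0)}, index=pd.date_range("2015-01-01", periods=5))
        with pytest.raises(ValueError):
            pk.autocorrelation_report(m)
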