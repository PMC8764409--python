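import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from salinet import network, simulate
from salinet.io import ValidationError


class TestOccupancyFilter:
    def test_ceil_boundary(self):
        data = {"in8": [1] * 8 + [0, 0], "in7": [1] * 7 + [0] * 3}
        table = pd.DataFrame(data, index=[f"s{i}" for i in range(10)])
        kept = network.occupancy_filter(table, 0.8)
        assert list(kept.columns) == ["in8"]

    def test_full_occupancy_keeps_ubiquitous_only(self, small_table):
        kept = network.occupancy_filter(small_table, 1.0)
        assert list(kept.columns) == ["t4"]

    def test_idempotent(self, small_table):
        once = network.occupancy_filter(small_table, 0.6)
        twice = network.occupancy_filter(once, 0.6)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_result_is_error(self):
        table = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, index=["x", "y"])
        with pytest.raises(ValidationError):
            network.occupancy_filter(table, 1.0)


class TestAssociationScores:
    def test_self_like_pair(self):
        # two taxa with identical profiles behave like a self-pairing
        prof = [3, 1, 4, 1, 5]
        table = pd.DataFrame({"a": prof, "b": prof, "c": [5, 4, 3, 2, 1]},
                             index=[f"s{i}" for i in range(5)])
        scores = network.association_scores(table)
        assert scores["pearson"].loc["a", "b"] == pytest.approx(1.0)
        assert scores["kendall"].loc["a", "b"] == pytest.approx(0.0)
        assert scores["braycurtis"].loc["a", "b"] == pytest.approx(0.0)
        assert scores["kl"].loc["a", "b"] == pytest.approx(0.0)

    def test_reversed_ranks(self):
        table = pd.DataFrame({"up": [1, 2, 3, 4, 5], "down": [5, 4, 3, 2, 1]},
                             index=[f"s{i}" for i in range(5)])
        scores = network.association_scores(table)
        assert scores["spearman"].loc["up", "down"] == pytest.approx(-1.0)
        assert scores["kendall"].loc["up", "down"] == pytest.approx(1.0)

    def test_braycurtis_profile_hand_example(self):
        # equal per-sample totals keep the (2,2,0)/(0,2,2) profile shape on
        # the relative scale, where BC = 1 - 2*min/(sum) = 0.5
        table = pd.DataFrame({"x": [2, 2, 0], "y": [0, 2, 2],
                              "filler": [2, 0, 2]},
                             index=["s1", "s2", "s3"])
        scores = network.association_scores(table)
        assert scores["braycurtis"].loc["x", "y"] == pytest.approx(0.5)

    def test_matches_scipy_on_random_profiles(self, rng):
        table = pd.DataFrame(rng.integers(0, 40, (12, 5)),
                             columns=list("abcde"))
        rel = network.relative_abundance(table)
        scores = network.association_scores(table)
        for x, y in [("a", "b"), ("c", "e")]:
            assert scores["pearson"].loc[x, y] == pytest.approx(
                pearsonr(rel[x], rel[y]).statistic)
            assert scores["spearman"].loc[x, y] == pytest.approx(
                spearmanr(rel[x], rel[y]).statistic)
            tau = kendalltau(rel[x], rel[y]).statistic
            assert scores["kendall"].loc[x, y] == pytest.approx((1 - tau) / 2)

    def test_zero_variance_taxon_excluded_from_correlations(self):
        table = pd.DataFrame({"flat": [2, 2, 2, 2], "v": [1, 2, 3, 4]},
                             index=[f"s{i}" for i in range(4)])
        # equal per-sample totals keep 'flat' constant on the relative scale
        table["filler"] = 10 - table.sum(axis=1)
        scores = network.association_scores(table)
        assert np.isnan(scores["pearson"].loc["flat", "v"])
        assert np.isfinite(scores["braycurtis"].loc["flat", "v"])


class TestCandidateEdges:
    def _scores(self, values, taxa):
        df = pd.DataFrame(values, index=taxa, columns=taxa, dtype=float)
        np.fill_diagonal(df.values, np.nan)
        return df

    def test_small_instance_saturates_with_warning(self):
        taxa = [f"t{i}" for i in range(10)]
        scores = {"pearson": self._scores(np.ones((10, 10)), taxa)}
        with pytest.warns(UserWarning, match="all become candidates"):
            cands = network.candidate_edges(scores, n_top=500, n_bottom=500)
        assert len(cands) == 45

    def test_union_semantics_across_measures(self):
        taxa = [f"t{i}" for i in range(8)]
        base = np.zeros((8, 8))
        pearson = base.copy()
        kl = base.copy()
        pearson[0, 1] = pearson[1, 0] = 0.99  # top pair for pearson only
        kl[2, 3] = kl[3, 2] = 5.0            # top pair for kl only
        scores = {"pearson": self._scores(pearson, taxa),
                  "kl": self._scores(kl, taxa)}
        cands = network.candidate_edges(scores, n_top=1, n_bottom=1)
        assert ("t0", "t1") in cands
        assert ("t2", "t3") in cands

    def test_tie_break_is_deterministic(self):
        taxa = [f"t{i}" for i in range(8)]
        scores = {"pearson": self._scores(np.full((8, 8), 0.5), taxa)}
        a = network.candidate_edges(scores, n_top=3, n_bottom=3)
        b = network.candidate_edges(scores, n_top=3, n_bottom=3)
        assert a == b
        # all scores tied -> lexicographically smallest pairs selected
        assert a[0] == ("t0", "t1")


class TestRebootSupport:
    def test_determinism(self):
        otu, env, tree, truth = simulate.association_scenario(0, n_taxa=15)
        cands = [("OTU_0001", "OTU_0002"), ("OTU_0003", "OTU_0009")]
        a = network.reboot_support(otu, cands, n_perm=100, n_boot=100, seed=4)
        b = network.reboot_support(otu, cands, n_perm=100, n_boot=100, seed=4)
        assert a[0].p_values == b[0].p_values
        assert a[1].boot_ci == b[1].boot_ci

    def test_empirical_p_on_discrete_grid(self):
        otu, env, tree, truth = simulate.association_scenario(1, n_taxa=10)
        cands = [("OTU_0001", "OTU_0005")]
        edges = network.reboot_support(otu, cands, n_perm=100, n_boot=100,
                                       seed=0, p_method="empirical")
        for p in edges[0].p_values.values():
            assert abs(p * 101 - round(p * 101)) < 1e-9
            assert 0 < p <= 1

    def test_null_p_values_uniform(self):
        """Independent profiles give calibrated permutation p-values."""
        otu, env, tree, truth = simulate.association_scenario(2, n_taxa=40)
        taxa = list(otu.columns)
        cands = [(taxa[2 * i], taxa[2 * i + 1]) for i in range(20)]
        ps = {m: [] for m in ("pearson", "braycurtis")}
        for seed in range(10):
            otu, env, tree, truth = simulate.association_scenario(seed + 10, n_taxa=40)
            edges = network.reboot_support(otu, cands, n_perm=100, n_boot=100,
                                           seed=seed, p_method="empirical",
                                           measures=("pearson", "braycurtis"))
            for e in edges:
                for m in ps:
                    if m in e.p_values:
                        ps[m].append(e.p_values[m])
        for m, vals in ps.items():
            frac = np.mean(np.asarray(vals) < 0.05)
            assert abs(frac - 0.05) <= 0.03, m

    def test_planted_pair_power(self):
        """A rho=0.9 pair at n=45 reaches the smallest achievable empirical
        Pearson p (<= 0.001 at 1,000 permutations) in >= 95% of seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            otu, env, tree, truth = simulate.association_scenario(
                seed, n_taxa=16, n_planted_pairs=1, rho=0.9)
            pair = (truth.pairs[0].taxon_a, truth.pairs[0].taxon_b)
            pair = tuple(sorted(pair))
            edges = network.reboot_support(otu, [pair], n_perm=1000, n_boot=100,
                                           seed=seed, p_method="empirical",
                                           measures=("pearson",))
            hits += edges[0].p_values.get("pearson", 1.0) <= 0.001
        assert hits >= 0.95 * n_seeds

    def test_parameter_floors(self, small_table):
        with pytest.raises(ValidationError):
            network.reboot_support(small_table, [("t1", "t2")], n_perm=10,
                                   n_boot=100)
        with pytest.raises(ValidationError):
            network.reboot_support(small_table, [("t1", "t2")], n_perm=100,
                                   n_boot=100, p_method="bogus")


class TestSimesAndBh:
    def test_simes_hand_examples(self):
        assert network.simes_merge([0.01, 0.02, 0.03]) == pytest.approx(0.03)
        assert network.simes_merge([0.2]) == pytest.approx(0.2)
        assert network.simes_merge([0.5, 1.0]) == pytest.approx(1.0)

    def test_simes_bounds(self, rng):
        for _ in range(50):
            ps = rng.uniform(1e-6, 1, size=rng.integers(1, 6))
            merged = network.simes_merge(ps)
            bonferroni = min(1.0, len(ps) * ps.min())
            assert merged <= bonferroni + 1e-12
            assert merged >= ps.min() - 1e-12

    def test_simes_empty_rejected(self):
        with pytest.raises(ValidationError):
            network.simes_merge([])

    def test_bh_hand_examples(self):
        q, acc = network.bh_fdr([0.04], alpha=0.05)
        assert q[0] == pytest.approx(0.04) and acc[0]
        q, _ = network.bh_fdr([0.01, 0.02, 0.04, 0.8])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_bh_step_up_monotone_and_matches_statsmodels(self, rng):
        ps = rng.uniform(0, 1, 40)
        q, acc = network.bh_fdr(ps, alpha=0.05)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        sm_acc, sm_q, _, _ = multipletests(ps, alpha=0.05, method="fdr_bh")
        assert np.allclose(q, sm_q)
        assert (acc == sm_acc).all()


class TestFinalizeNetwork:
    def _edge(self, a, b, p, directions, surviving=None):
        e = network.EdgeCandidate(a, b)
        e.p_values = {m: p for m in directions}
        e.directions = directions
        e.surviving = surviving if surviving is not None else list(directions)
        e.merged_p = network.simes_merge([p] * len(e.surviving))
        return e

    def test_majority_vote_signs(self):
        edges = [
            self._edge("a", "b", 0.001, {"pearson": 1, "spearman": 1, "kl": 1}),
            self._edge("c", "d", 0.001, {"pearson": -1, "kl": -1, "braycurtis": 1}),
        ]
        g = network.finalize_network(edges, alpha=0.05)
        assert g.edges["a", "b"]["sign"] == "+"
        assert g.edges["c", "d"]["sign"] == "-"

    def test_tie_discarded_and_counted(self):
        edges = [self._edge("a", "b", 0.001, {"pearson": 1, "kl": -1})]
        g = network.finalize_network(edges, alpha=0.05)
        assert g.number_of_edges() == 0
        assert g.graph["n_discarded_sign_ties"] == 1

    def test_positive_fraction_arithmetic(self):
        edges = [
            self._edge(f"p{i}", f"q{i}", 0.0001, {"pearson": 1}) for i in range(8)
        ] + [
            self._edge(f"n{i}", f"m{i}", 0.0001, {"pearson": -1}) for i in range(2)
        ]
        g = network.finalize_network(edges, alpha=0.05)
        assert g.graph["positive_fraction"] == pytest.approx(0.8)

    def test_q_above_alpha_excluded(self):
        edges = [self._edge("a", "b", 0.5, {"pearson": 1})]
        g = network.finalize_network(edges, alpha=0.05)
        assert g.number_of_edges() == 0
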