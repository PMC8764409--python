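import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from salinet import assembly, simulate
from salinet.io import ValidationError


class TestBmntd:
    def test_identical_communities_zero(self, star_tree):
        table = pd.DataFrame([[1, 2, 3, 4]] * 2, index=["a", "b"],
                             columns=["t1", "t2", "t3", "t4"])
        dm = assembly.bmntd(table, star_tree)
        assert dm["a", "b"] == pytest.approx(0.0)

    def test_star_tree_disjoint_communities(self, star_tree):
        # A={t1,t2}, B={t3,t4}: every cross-tip distance is 2
        table = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"],
            columns=["t1", "t2", "t3", "t4"],
        )
        dm = assembly.bmntd(table, star_tree)
        assert dm["A", "B"] == pytest.approx(2.0)

    def test_weighted_equals_unweighted_for_equal_abundances(self, star_tree):
        table = pd.DataFrame(
            [[3, 3, 0, 0], [0, 3, 3, 0]], index=["A", "B"],
            columns=["t1", "t2", "t3", "t4"],
        )
        w = assembly.bmntd(table, star_tree, weighted=True)
        u = assembly.bmntd(table, star_tree, weighted=False)
        assert w["A", "B"] == pytest.approx(u["A", "B"])

    def test_empty_community_and_tip_mismatch(self, star_tree):
        table = pd.DataFrame([[0, 0, 0, 0], [1, 1, 1, 1]], index=["e", "f"],
                             columns=["t1", "t2", "t3", "t4"])
        with pytest.raises(ValidationError, match="empty"):
            assembly.bmntd(table, star_tree)
        bad = pd.DataFrame([[1], [1]], index=["a", "b"], columns=["missing"])
        with pytest.raises(ValidationError, match="missing"):
            assembly.bmntd(bad, star_tree)

    def test_weighted_matches_picante(self, tmp_path):
        """Independent oracle: picante::comdistnt (abundance-weighted) on a
        small simulated dataset."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        otu, env, tree, truth = simulate.simulate_dataset(
            n_taxa=15, seed=11, depth_range=(1000, 1100),
            design=(simulate.LakeGroup("A", 3, 1.0), simulate.LakeGroup("B", 3, 4.0)),
        )
        ours = assembly.bmntd(otu, tree).data
        otu.to_csv(tmp_path / "otu.tsv", sep="\t")
        tree.write(str(tmp_path / "tree.nwk"))
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(picante))\n"
            f"otu <- as.matrix(read.table('{tmp_path}/otu.tsv', header=TRUE, "
            "row.names=1, sep='\\t', check.names=FALSE))\n"
            f"tree <- read.tree('{tmp_path}/tree.nwk')\n"
            "tree$tip.label <- gsub(\"'\", '', tree$tip.label)\n"
            "d <- cophenetic(tree)\n"
            "m <- as.matrix(comdistnt(otu, d, abundance.weighted=TRUE))\n"
            f"write.table(m, '{tmp_path}/bmntd_r.tsv', sep='\\t')\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "bmntd_r.tsv", sep="\t").to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)


class TestBnti:
    def _dataset(self, seed=0, n_taxa=40, n=8):
        design = (simulate.LakeGroup("A", n // 2, 1.0),
                  simulate.LakeGroup("B", n - n // 2, 4.0))
        return simulate.simulate_dataset(n_taxa=n_taxa, seed=seed, design=design,
                                         depth_range=(1000, 2000))

    def test_determinism(self):
        otu, env, tree, truth = self._dataset()
        a = assembly.bnti(otu, tree, n_null=99, seed=5)
        b = assembly.bnti(otu, tree, n_null=99, seed=5)
        assert np.allclose(a.bnti, b.bnti, equal_nan=True)

    def test_identical_communities_degenerate_null_warns(self, star_tree):
        table = pd.DataFrame([[1, 2, 3, 4]] * 3, index=["a", "b", "c"],
                             columns=["t1", "t2", "t3", "t4"])
        with pytest.warns(UserWarning, match="degenerate"):
            res = assembly.bnti(table, star_tree, n_null=99, seed=0)
        assert np.isnan(res.bnti[0, 1])

    def test_equivariance_under_consistent_relabelling(self):
        otu, env, tree, truth = self._dataset(seed=2, n_taxa=20, n=6)
        res = assembly.bnti(otu, tree, n_null=99, seed=9)
        perm = np.random.default_rng(0).permutation(otu.shape[1])
        shuffled = otu.iloc[:, perm]
        res2 = assembly.bnti(shuffled, tree, n_null=99, seed=9)
        # observed betaMNTD is invariant; the null stream differs only via
        # taxon order, so compare the observed matrices
        assert np.allclose(res.bmntd_obs, res2.bmntd_obs)

    def test_n_null_floor(self, star_tree):
        table = pd.DataFrame([[1, 0, 1, 0], [0, 1, 0, 1]], index=["a", "b"],
                             columns=["t1", "t2", "t3", "t4"])
        with pytest.raises(ValidationError):
            assembly.bnti(table, star_tree, n_null=10)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (2.5, "variable_selection"),
            (-2.5, "homogeneous_selection"),
            (0.0, "stochastic"),
            (2.0, "stochastic"),
            (-2.0, "stochastic"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert assembly.classify_process(value) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            assembly.classify_process(float("nan"))


class TestMantel:
    def test_constant_matrix_warns_nan(self):
        x = np.zeros((4, 4))
        y = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            r, p = assembly.mantel(x, y, n_perm=99, seed=0)
        assert np.isnan(r)

    def test_null_calibration(self, rng):
        """With unrelated random matrices the permutation p is uniform."""
        n_seeds = 200
        hits = 0
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            a = g.random((8, 8))
            b = g.random((8, 8))
            x = (a + a.T) / 2
            y = (b + b.T) / 2
            np.fill_diagonal(x, 0)
            np.fill_diagonal(y, 0)
            r, p = assembly.mantel(x, y, n_perm=99, seed=seed)
            hits += p < 0.05
        assert abs(hits / n_seeds - 0.05) <= 0.03


class TestPhyloSignal:
    def test_constant_optima_warns(self, star_tree):
        table = pd.DataFrame([[1, 1, 1, 1]] * 4, index=list("abcd"),
                             columns=["t1", "t2", "t3", "t4"])
        env = pd.DataFrame({"salinity": [2.0] * 4, "group": list("aabb")},
                           index=list("abcd"))
        with pytest.warns(UserWarning):
            res = assembly.phylo_signal(star_tree, table, env, n_perm=99, seed=0)
        assert np.isnan(res.r)

    def test_niche_filtered_communities_show_signal(self):
        """Communities filtered on conserved niches carry phylogenetic
        signal in realised optima: Mantel p < 0.05 in >= 90% of seeds."""
        design = tuple(
            simulate.LakeGroup(f"g{i}", 4, s) for i, s in enumerate((0.5, 2, 4, 6))
        )
        n_seeds = 25
        hits = 0
        for seed in range(n_seeds):
            otu, env, tree, truth = simulate.simulate_dataset(
                n_taxa=100, seed=seed, design=design, depth_range=(1000, 2000),
                bm_rate=4.0, early_burst=0.0, tip_sd=None, tolerance_median=1.0,
            )
            res = assembly.phylo_signal(tree, otu, env, n_perm=199, seed=seed)
            hits += res.p < 0.05
        assert hits >= 0.9 * n_seeds
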