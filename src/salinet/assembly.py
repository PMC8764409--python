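"""Phylogenetic community assembly: betaMNTD, the betaNTI null model, and a
Mantel test for phylogenetic signal in salinity niches.

betaMNTD between two communities is the (abundance-weighted) mean
phylogenetic distance from each taxon to its nearest relative in the other
community.  betaNTI standardises the observed betaMNTD against a null
distribution obtained by shuffling tip labels across the whole tree
("taxa shuffle"), with both communities scored against the same shuffled
tree in each randomisation.  |betaNTI| > 2 is read as selection:
values above +2 as variable selection (divergent filtering), below -2 as
homogeneous selection (convergent filtering); |betaNTI| <= 2 as
stochastic assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .io import ValidationError, check_tree_matches_table, cophenetic_distances

__all__ = [
    "bmntd",
    "bnti",
    "BetaNtiResult",
    "classify_process",
    "mantel",
    "phylo_signal",
    "PhyloSignalResult",
]


def _community_arrays(table: pd.DataFrame, weighted: bool):
    """Per-sample present-taxon index arrays and weights (summing to 1)."""
    counts = table.to_numpy(dtype=float)
    present, weights = [], []
    for i, sample in enumerate(table.index):
        idx = np.flatnonzero(counts[i] > 0)
        if idx.size == 0:
            raise ValidationError(f"sample {sample!r} is empty")
        w = counts[i, idx]
        w = w / w.sum() if weighted else np.full(idx.size, 1.0 / idx.size)
        present.append(idx)
        weights.append(w)
    return present, weights


def _bmntd_pairs(D: np.ndarray, present, weights, perm: np.ndarray | None = None):
    """betaMNTD for all sample pairs under an optional taxon permutation.

    The taxa-shuffle null is equivalent to evaluating the observed
    communities on a permuted cophenetic matrix, so a permutation vector is
    all that changes between randomisations.
    """
    n = len(present)
    out = np.zeros((n, n))
    idxs = present if perm is None else [perm[ix] for ix in present]
    for a in range(n):
        ia, wa = idxs[a], weights[a]
        for b in range(a + 1, n):
            ib, wb = idxs[b], weights[b]
            sub = D[np.ix_(ia, ib)]
            val = 0.5 * (wa @ sub.min(axis=1) + wb @ sub.min(axis=0))
            out[a, b] = out[b, a] = val
    return out


def bmntd(table: pd.DataFrame, tree: skbio.TreeNode, weighted: bool = True) -> skbio.DistanceMatrix:
    """Observed betaMNTD matrix over samples."""
    check_tree_matches_table(tree, table.columns)
    D, _ = cophenetic_distances(tree, list(table.columns))
    present, weights = _community_arrays(table, weighted)
    mat = _bmntd_pairs(D, present, weights)
    return skbio.DistanceMatrix(mat, ids=[str(s) for s in table.index])


@dataclass
class BetaNtiResult:
    """Observed betaMNTD with its taxa-shuffle null mean/SD and betaNTI.

    ``bnti`` is NaN for pairs whose null SD is zero (degenerate null, e.g.
    identical communities).
    """

    sample_ids: list[str]
    bmntd_obs: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    bnti: np.ndarray
    n_randomizations: int

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.sample_ids)
        for a in range(n):
            for b in range(a + 1, n):
                val = self.bnti[a, b]
                rows.append(
                    {
                        "sample_a": self.sample_ids[a],
                        "sample_b": self.sample_ids[b],
                        "bmntd_obs": self.bmntd_obs[a, b],
                        "null_mean": self.null_mean[a, b],
                        "null_sd": self.null_sd[a, b],
                        "bnti": val,
                        "class": classify_process(val) if np.isfinite(val) else "undefined",
                    }
                )
        return pd.DataFrame(rows)

    def values_for(self, samples: list[str]) -> np.ndarray:
        """Pairwise betaNTI values among a subset of samples (finite only)."""
        pos = [self.sample_ids.index(s) for s in samples]
        vals = [
            self.bnti[a, b]
            for i, a in enumerate(pos)
            for b in pos[i + 1:]
        ]
        arr = np.array(vals, dtype=float)
        return arr[np.isfinite(arr)]


def bnti(
    table: pd.DataFrame,
    tree: skbio.TreeNode,
    n_null: int = 999,
    weighted: bool = True,
    seed: int | None = None,
) -> BetaNtiResult:
    """betaNTI: standardised effect size of betaMNTD against a taxa-shuffle null."""
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    check_tree_matches_table(tree, table.columns)
    D, _ = cophenetic_distances(tree, list(table.columns))
    present, weights = _community_arrays(table, weighted)
    obs = _bmntd_pairs(D, present, weights)
    rng = np.random.default_rng(seed)
    n_taxa = table.shape[1]
    n = table.shape[0]
    nulls = np.empty((n_null, n, n))
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[k] = _bmntd_pairs(D, present, weights, perm)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = (obs - null_mean) / null_sd
    iu = np.triu_indices(n, 1)
    degenerate = null_sd[iu] == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample pairs have a degenerate (zero-SD) "
            "null; betaNTI undefined for them"
        )
    ses[null_sd == 0] = np.nan
    np.fill_diagonal(ses, np.nan)
    return BetaNtiResult(
        sample_ids=[str(s) for s in table.index],
        bmntd_obs=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        bnti=ses,
        n_randomizations=n_null,
    )


def classify_process(bnti_value: float) -> str:
    """Assembly-process call from a betaNTI value.

    > 2: variable selection; < -2: homogeneous selection; |value| <= 2
    (boundaries included): stochastic.
    """
    if not np.isfinite(bnti_value):
        raise ValidationError("betaNTI value must be finite")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    return "stochastic"


def mantel(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mantel correlation between two square distance matrices.

    Pearson correlation of the condensed upper triangles; the permutation
    null rearranges the rows/columns of ``y``.  Returns ``(r, p)`` with the
    (1 + b) / (1 + m) permutation p-value estimator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValidationError("mantel needs two square matrices of equal shape")
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    xv = x[iu]
    if np.std(xv) == 0 or np.std(y[iu]) == 0:
        warnings.warn("constant distance matrix: Mantel r undefined")
        return float("nan"), float("nan")

    def corr(yy):
        yv = yy[iu]
        sy = yv.std()
        if sy == 0:
            return 0.0
        return float(((xv - xv.mean()) * (yv - yv.mean())).mean() / (xv.std() * sy))

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = corr(y[np.ix_(p, p)])
        if alternative == "greater":
            hits += r >= r_obs
        elif alternative == "less":
            hits += r <= r_obs
        else:
            hits += abs(r) >= abs(r_obs)
    return r_obs, (1 + hits) / (1 + n_perm)


@dataclass
class PhyloSignalResult:
    r: float
    p: float
    n_perm: int
    optima: pd.Series


def phylo_signal(
    tree: skbio.TreeNode,
    table: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Mantel test of phylogenetic signal in salinity niches.

    Each taxon's realised salinity optimum is estimated as the
    abundance-weighted mean salinity of the samples it occurs in; the test
    correlates cophenetic distances with pairwise optimum differences.
    """
    if table.shape[1] < 3:
        raise ValidationError("need at least 3 taxa")
    sal = env.loc[table.index, "salinity"].to_numpy(dtype=float)
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    keep = totals > 0
    opt = np.full(table.shape[1], np.nan)
    opt[keep] = (counts[:, keep] * sal[:, None]).sum(axis=0) / totals[keep]
    taxa = [t for t, k in zip(table.columns, keep) if k]
    optima = pd.Series(opt[keep], index=taxa, name="realized_optimum")
    D, _ = cophenetic_distances(tree, taxa)
    dopt = np.abs(optima.to_numpy()[:, None] - optima.to_numpy()[None, :])
    r, p = mantel(D, dopt, n_perm=n_perm, seed=seed, alternative="two-sided")
    return PhyloSignalResult(r=r, p=p, n_perm=n_perm, optima=optima)
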