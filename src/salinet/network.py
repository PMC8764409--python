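"""Ensemble co-occurrence network inference with permutation/bootstrap
edge support (ReBoot-style), Simes p-value merging and BH FDR control.

The pipeline is: restrict to prevalent taxa (>= 80% occupancy by default);
score every taxon pair with five association measures -- Pearson and
Spearman correlations (similarities) plus Kendall distance ``(1 - tau_b)/2``,
Bray-Curtis distance and symmetrised Kullback-Leibler divergence
(dissimilarities) -- on per-sample relative-abundance profiles; keep the
top/bottom-ranked edges per measure as candidates; attach to each candidate
and measure a permutation p-value (profile shuffle, two-tailed around the
null mean) and a bootstrap percentile confidence interval; drop
edge-measures whose null mean falls inside the bootstrap CI (instability);
merge the surviving per-measure p-values with Simes; control FDR across
edges with Benjamini-Hochberg; and sign each accepted edge by majority
vote of the surviving measures' directions (co-presence vs mutual
exclusion), discarding ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as _t_dist

from .io import ValidationError

__all__ = [
    "MEASURES",
    "SIMILARITY_MEASURES",
    "occupancy_filter",
    "relative_abundance",
    "association_scores",
    "candidate_edges",
    "reboot_support",
    "EdgeCandidate",
    "simes_merge",
    "bh_fdr",
    "finalize_network",
    "infer_network",
    "NetworkResult",
]

MEASURES = ("pearson", "spearman", "kendall", "braycurtis", "kl")
SIMILARITY_MEASURES = frozenset({"pearson", "spearman"})


def occupancy_filter(table: pd.DataFrame, min_occupancy: float = 0.8) -> pd.DataFrame:
    """Keep taxa present in at least ``ceil(min_occupancy * n_samples)`` samples."""
    if not (0 < min_occupancy <= 1):
        raise ValidationError("min_occupancy must be in (0, 1]")
    need = math.ceil(min_occupancy * table.shape[0])
    keep = (table > 0).sum(axis=0) >= need
    if not keep.any():
        raise ValidationError("no taxa survive the occupancy filter")
    return table.loc[:, keep]


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    x = table.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(x / totals, index=table.index, columns=table.columns)


class _ScoreEngine:
    """Vectorised association scores between taxon profiles.

    Holds per-taxon profile representations (z-scores, rank z-scores,
    pairwise sign tensors for tau_b, pseudo-counted probability rows for
    KL) so that observed, permuted and bootstrap scores all reduce to
    cheap array expressions.  ``counts`` is taxa x samples.
    """

    def __init__(self, counts: np.ndarray, pseudocount: float = 1.0):
        counts = np.asarray(counts, dtype=float)
        self.n_taxa, self.n = counts.shape
        totals = counts.sum(axis=0)
        totals[totals == 0] = 1.0
        self.R = counts / totals  # per-sample relative abundances
        self.Z = self._standardize(self.R)
        self.ZR = self._standardize(rankdata(self.R, axis=1))
        # Kendall: sign tensors and tie-corrected pair counts
        self.S = np.sign(self.R[:, :, None] - self.R[:, None, :])
        n0 = self.n * (self.n - 1) / 2
        ties = np.array([
            sum(c * (c - 1) / 2 for c in np.unique(row, return_counts=True)[1])
            for row in self.R
        ])
        self.kendall_v = n0 - ties  # 0 for constant profiles
        # KL: pseudocount on counts, then closure per taxon across samples
        P = counts + pseudocount
        P = P / P.sum(axis=1, keepdims=True)
        self.P = P
        self.logP = np.log(P)
        self.entropy = (P * self.logP).sum(axis=1)

    @staticmethod
    def _standardize(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = np.nan
        return z

    # ---- full taxa x taxa matrices (observed scores) ----

    def full_matrix(self, measure: str) -> np.ndarray:
        if measure == "pearson":
            return self._corr_full(self.Z)
        if measure == "spearman":
            return self._corr_full(self.ZR)
        if measure == "kendall":
            flat = self.S.reshape(self.n_taxa, -1)
            num = (flat @ flat.T) / 2.0
            with np.errstate(invalid="ignore", divide="ignore"):
                tau = num / np.sqrt(np.outer(self.kendall_v, self.kendall_v))
            tau[np.outer(self.kendall_v == 0, np.ones(self.n_taxa, bool))] = np.nan
            tau[np.outer(np.ones(self.n_taxa, bool), self.kendall_v == 0)] = np.nan
            return (1.0 - np.clip(tau, -1, 1)) / 2.0
        if measure == "braycurtis":
            out = np.empty((self.n_taxa, self.n_taxa))
            sums = self.R.sum(axis=1)
            for start in range(0, self.n_taxa, 64):
                blk = slice(start, min(start + 64, self.n_taxa))
                mins = np.minimum(self.R[blk, None, :], self.R[None, :, :]).sum(axis=-1)
                denom = sums[blk, None] + sums[None, :]
                with np.errstate(invalid="ignore", divide="ignore"):
                    out[blk] = 1.0 - 2.0 * mins / denom
            out[~np.isfinite(out)] = np.nan
            return out
        if measure == "kl":
            C = self.P @ self.logP.T
            return self.entropy[:, None] + self.entropy[None, :] - C - C.T
        raise ValidationError(f"unknown measure {measure!r}")

    def _corr_full(self, Z: np.ndarray) -> np.ndarray:
        Zf = np.nan_to_num(Z)
        r = (Zf @ Zf.T) / self.n
        invalid = np.isnan(Z).any(axis=1)
        r[invalid, :] = np.nan
        r[:, invalid] = np.nan
        return np.clip(r, -1, 1, out=r)

    # ---- full cross matrices with left-side column permutation ----
    # Scoring every taxon pair per randomisation reduces to a couple of
    # matrix products, which is much cheaper than per-edge indexing when
    # the candidate set approaches all pairs.

    def cross_matrix(self, measure: str, perm: np.ndarray) -> np.ndarray:
        """``M[i, j]`` = score of (taxon i with samples reordered by
        ``perm``, taxon j unpermuted)."""
        if measure in ("pearson", "spearman"):
            Z = self.Z if measure == "pearson" else self.ZR
            Zf = np.nan_to_num(Z)
            r = (Zf[:, perm] @ Zf.T) / self.n
            invalid = np.isnan(Z).any(axis=1)
            r[invalid, :] = np.nan
            r[:, invalid] = np.nan
            return np.clip(r, -1, 1, out=r)
        if measure == "kendall":
            flat = self.S.reshape(self.n_taxa, -1)
            flat_p = self.S[:, perm][:, :, perm].reshape(self.n_taxa, -1)
            num = (flat_p @ flat.T) / 2.0
            with np.errstate(invalid="ignore", divide="ignore"):
                tau = num / np.sqrt(np.outer(self.kendall_v, self.kendall_v))
            bad = self.kendall_v == 0
            tau[bad, :] = np.nan
            tau[:, bad] = np.nan
            return (1.0 - np.clip(tau, -1, 1)) / 2.0
        if measure == "braycurtis":
            Rp = self.R[:, perm]
            sums = self.R.sum(axis=1)
            out = np.empty((self.n_taxa, self.n_taxa))
            for start in range(0, self.n_taxa, 64):
                blk = slice(start, min(start + 64, self.n_taxa))
                mins = np.minimum(Rp[blk, None, :], self.R[None, :, :]).sum(axis=-1)
                denom = sums[blk, None] + sums[None, :]
                with np.errstate(invalid="ignore", divide="ignore"):
                    out[blk] = 1.0 - 2.0 * mins / denom
            out[~np.isfinite(out)] = np.nan
            return out
        if measure == "kl":
            # row entropies are permutation-invariant
            cross1 = self.P[:, perm] @ self.logP.T
            cross2 = self.logP[:, perm] @ self.P.T
            return self.entropy[:, None] + self.entropy[None, :] - cross1 - cross2
        raise ValidationError(f"unknown measure {measure!r}")


def association_scores(
    table: pd.DataFrame,
    measures=MEASURES,
    pseudocount: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Taxa x taxa score matrix for each association measure."""
    eng = _ScoreEngine(table.T.to_numpy(dtype=float), pseudocount)
    out = {}
    for m in measures:
        mat = eng.full_matrix(m)
        np.fill_diagonal(mat, np.nan)
        out[m] = pd.DataFrame(mat, index=table.columns, columns=table.columns)
    return out


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def candidate_edges(
    scores: dict[str, pd.DataFrame],
    n_top: int = 500,
    n_bottom: int = 500,
) -> list[tuple[str, str]]:
    """Union, over measures, of the top- and bottom-ranked taxon pairs.

    Ranking ties are broken by lexicographic pair id, which makes the
    candidate set deterministic.
    """
    if not scores:
        raise ValidationError("need at least one score matrix")
    first = next(iter(scores.values()))
    taxa = list(first.index)
    iu = np.triu_indices(len(taxa), 1)
    pairs = [_pair_key(taxa[i], taxa[j]) for i, j in zip(*iu)]
    n_pairs = len(pairs)
    if n_pairs <= n_top + n_bottom:
        warnings.warn(
            f"only {n_pairs} taxon pairs available; all become candidates"
        )
        return sorted(pairs)
    chosen: set[tuple[str, str]] = set()
    for m, df in scores.items():
        vals = df.to_numpy()[iu]
        ok = np.isfinite(vals)
        order = sorted(
            (i for i in range(n_pairs) if ok[i]),
            key=lambda i: (vals[i], pairs[i]),
        )
        chosen.update(pairs[i] for i in order[-n_top:])
        chosen.update(pairs[i] for i in order[:n_bottom])
    return sorted(chosen)


@dataclass
class EdgeCandidate:
    """Per-edge association statistics across the measure ensemble."""

    taxon_a: str
    taxon_b: str
    scores: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    null_means: dict[str, float] = field(default_factory=dict)
    boot_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    directions: dict[str, int] = field(default_factory=dict)
    surviving: list[str] = field(default_factory=list)
    merged_p: float | None = None
    q: float | None = None
    sign: int | None = None


def reboot_support(
    table: pd.DataFrame,
    candidates: list[tuple[str, str]],
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    measures=MEASURES,
    pseudocount: float = 1.0,
    ci_level: float = 0.95,
    p_method: str = "gaussian",
) -> list[EdgeCandidate]:
    """Permutation p-values and bootstrap stability for candidate edges.

    The permutation null shuffles one taxon's profile across samples
    (alternating which side is shuffled between randomisations).  With
    ``p_method="gaussian"`` (default) the two-tailed p-value comes from a
    parametric fit to the permutation null: the observed score is
    standardised by the null mean and SD and referred to a Student-t
    distribution with ``n_samples - 2`` degrees of freedom, whose heavier
    tail matches the finite-sample distribution of correlation-type
    statistics.  This keeps p-values continuous below 1/(n_perm+1) --
    necessary for step-up FDR over many candidate edges.
    ``p_method="empirical"`` uses the discrete count estimator
    ``(1 + hits) / (1 + n_perm)`` around the null mean.
    The bootstrap resamples samples with replacement and gives a
    percentile CI per measure; an edge-measure whose permutation-null mean
    lies inside that CI is unstable and discarded.
    """
    if n_perm < 100 or n_boot < 100:
        raise ValidationError("n_perm and n_boot must be >= 100")
    if p_method not in ("gaussian", "empirical"):
        raise ValidationError(f"unknown p_method {p_method!r}")
    if not candidates:
        return []
    counts = table.T.to_numpy(dtype=float)  # taxa x samples
    taxa_pos = {t: i for i, t in enumerate(table.columns)}
    a_idx = np.array([taxa_pos[a] for a, _ in candidates])
    b_idx = np.array([taxa_pos[b] for _, b in candidates])
    n_edges = len(candidates)
    n = table.shape[0]
    rng = np.random.default_rng(seed)
    eng = _ScoreEngine(counts, pseudocount)

    full_obs = {m: eng.full_matrix(m) for m in measures}
    obs = {m: full_obs[m][a_idx, b_idx] for m in measures}

    nulls = {m: np.empty((n_perm, n_edges)) for m in measures}
    for k in range(n_perm):
        perm = rng.permutation(n)
        left, right = (a_idx, b_idx) if k % 2 == 0 else (b_idx, a_idx)
        for m in measures:
            nulls[m][k] = eng.cross_matrix(m, perm)[left, right]

    cand_taxa = np.unique(np.concatenate([a_idx, b_idx]))
    boots = {m: np.empty((n_boot, n_edges)) for m in measures}
    attempts = 0
    drawn = 0
    while drawn < n_boot:
        if attempts >= 10 * n_boot:
            raise ValidationError("too many degenerate bootstrap replicates")
        attempts += 1
        idx = rng.integers(0, n, n)
        sub = counts[:, idx]
        if (sub[cand_taxa].sum(axis=1) == 0).any():
            continue  # a candidate taxon vanished; redraw
        beng = _ScoreEngine(sub, pseudocount)
        for m in measures:
            boots[m][drawn] = beng.full_matrix(m)[a_idx, b_idx]
        drawn += 1

    # vectorised per-measure statistics
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    stats: dict[str, dict[str, np.ndarray]] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for m in measures:
            center = np.nanmean(nulls[m], axis=0)
            n_ok = np.isfinite(nulls[m]).sum(axis=0)
            if p_method == "gaussian":
                sd = np.nanstd(nulls[m], axis=0, ddof=1)
                z = np.abs(obs[m] - center) / sd
                p = np.minimum(1.0, 2 * _t_dist.sf(z, max(n - 2, 1)))
                p = np.maximum(p, np.nextafter(0, 1))
                p[sd == 0] = np.nan
            else:
                hits = np.nansum(
                    np.abs(nulls[m] - center) >= np.abs(obs[m] - center), axis=0
                )
                p = (1.0 + hits) / (1.0 + n_ok)
            boot_ok = np.isfinite(boots[m]).sum(axis=0)
            ci = np.nanpercentile(boots[m], [lo_q, hi_q], axis=0)
            valid = (
                np.isfinite(obs[m])
                & np.isfinite(p)
                & (n_ok >= n_perm // 2)
                & (boot_ok >= n_boot // 2)
            )
            if m in SIMILARITY_MEASURES:
                direction = np.where(obs[m] > center, 1, -1)
            else:
                direction = np.where(obs[m] < center, 1, -1)
            stable = ~((ci[0] <= center) & (center <= ci[1]))
            stats[m] = {
                "center": center, "p": p, "ci_lo": ci[0], "ci_hi": ci[1],
                "valid": valid, "direction": direction, "stable": stable,
            }

    edges = []
    for e, (ta, tb) in enumerate(candidates):
        ec = EdgeCandidate(ta, tb)
        for m in measures:
            st = stats[m]
            if not st["valid"][e]:
                continue  # e.g. zero-variance taxon under a correlation
            ec.scores[m] = float(obs[m][e])
            ec.p_values[m] = float(st["p"][e])
            ec.null_means[m] = float(st["center"][e])
            ec.boot_ci[m] = (float(st["ci_lo"][e]), float(st["ci_hi"][e]))
            ec.directions[m] = int(st["direction"][e])
            if st["stable"][e]:
                ec.surviving.append(m)
        if ec.surviving:
            ec.merged_p = simes_merge([ec.p_values[m] for m in ec.surviving])
        edges.append(ec)
    return edges


def simes_merge(p_values) -> float:
    """Simes combination: min over i of ``m * p_(i) / i``, capped at 1."""
    ps = np.sort(np.asarray(list(p_values), dtype=float))
    if ps.size == 0:
        raise ValidationError("cannot merge an empty p-value list")
    if ((ps <= 0) | (ps > 1)).any():
        raise ValidationError("p-values must be in (0, 1]")
    m = ps.size
    return float(min(1.0, (m * ps / np.arange(1, m + 1)).min()))


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the accepted set at ``alpha``."""
    ps = np.asarray(list(p_values), dtype=float)
    m = ps.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(ps, kind="stable")
    q_sorted = ps[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def finalize_network(edges: list[EdgeCandidate], alpha: float = 0.05) -> nx.Graph:
    """BH-accept edges, sign them by majority vote, and build the graph.

    Edges whose surviving measures split evenly between co-presence and
    mutual exclusion are discarded and counted in the graph attribute
    ``n_discarded_sign_ties``.
    """
    scored = [e for e in edges if e.merged_p is not None]
    if scored:
        q, accept = bh_fdr([e.merged_p for e in scored], alpha=alpha)
        for e, qv in zip(scored, q):
            e.q = float(qv)
    net = nx.Graph()
    n_ties = 0
    n_pos = n_neg = 0
    for e in scored:
        if e.q is None or e.q > alpha:
            continue
        votes = sum(e.directions[m] for m in e.surviving)
        if votes == 0:
            n_ties += 1
            continue
        sign = 1 if votes > 0 else -1
        n_pos += sign > 0
        n_neg += sign < 0
        net.add_edge(
            e.taxon_a,
            e.taxon_b,
            sign="+" if sign > 0 else "-",
            n_supporting_measures=len(e.surviving),
            merged_p=float(e.merged_p),
            q=float(e.q),
        )
    total = n_pos + n_neg
    net.graph["n_discarded_sign_ties"] = n_ties
    net.graph["positive_fraction"] = n_pos / total if total else float("nan")
    net.graph["negative_fraction"] = n_neg / total if total else float("nan")
    net.graph["alpha"] = alpha
    return net


@dataclass
class NetworkResult:
    graph: nx.Graph
    edges: list[EdgeCandidate]
    candidate_pairs: list[tuple[str, str]]
    taxa: list[str]


def infer_network(
    table: pd.DataFrame,
    min_occupancy: float = 0.8,
    n_top: int = 500,
    n_bottom: int = 500,
    n_perm: int = 1000,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    measures=MEASURES,
    pseudocount: float = 1.0,
) -> NetworkResult:
    """End-to-end ensemble network inference on a count table."""
    filtered = occupancy_filter(table, min_occupancy)
    scores = association_scores(filtered, measures=measures, pseudocount=pseudocount)
    cands = candidate_edges(scores, n_top=n_top, n_bottom=n_bottom)
    edges = reboot_support(
        filtered,
        cands,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        measures=measures,
        pseudocount=pseudocount,
    )
    graph = finalize_network(edges, alpha=alpha)
    return NetworkResult(graph=graph, edges=edges, candidate_pairs=cands,
                         taxa=list(filtered.columns))
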