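"""Rarefaction, alpha diversity, core community, Bray-Curtis, niche breadth."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import ValidationError

__all__ = [
    "rarefy",
    "alpha_diversity",
    "core_fraction",
    "bray_curtis",
    "niche_breadth",
    "NicheBreadthResult",
    "hellinger",
]


def rarefy(
    table: pd.DataFrame,
    depth: int | None = None,
    seed: int | None = None,
    drop_empty: bool = False,
) -> pd.DataFrame:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample total (the convention of
    rarefying to the shallowest library).  A single seeded draw is taken
    per sample via the multivariate hypergeometric distribution.
    """
    totals = table.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    too_small = totals[totals < depth]
    if len(too_small):
        raise ValidationError(
            f"sample {too_small.index[0]!r} has total {int(too_small.iloc[0])} < depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.to_numpy())
    for i, row in enumerate(table.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row.astype(np.int64), depth)
    res = pd.DataFrame(out, index=table.index, columns=table.columns)
    if drop_empty:
        res = res.loc[:, res.sum(axis=0) > 0]
    return res


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon H (natural log) and Gini-Simpson 1 - sum p^2."""
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    rows = []
    for i, sample in enumerate(table.index):
        if totals[i] == 0:
            warnings.warn(f"sample {sample!r} is all-zero; diversity reported as 0")
            rows.append((0, 0.0, 0.0))
            continue
        p = counts[i][counts[i] > 0] / totals[i]
        rows.append((int((counts[i] > 0).sum()), float(-(p * np.log(p)).sum()),
                     float(1.0 - (p**2).sum())))
    return pd.DataFrame(rows, index=table.index,
                        columns=["richness", "shannon", "simpson"])


def core_fraction(table: pd.DataFrame, occupancy: float) -> tuple[list[str], float]:
    """Taxa present in at least ``ceil(occupancy * n_samples)`` samples.

    Returns the core taxon ids and their fraction of all taxa present in
    at least one sample.
    """
    if not (0 < occupancy <= 1):
        raise ValidationError("occupancy must be in (0, 1]")
    n = table.shape[0]
    need = math.ceil(occupancy * n)
    occ = (table > 0).sum(axis=0)
    present = occ[occ > 0]
    core = occ[occ >= need].index.tolist()
    frac = len(core) / len(present) if len(present) else 0.0
    return core, frac


def bray_curtis(table: pd.DataFrame, zero_policy: str = "error") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    A pair of all-zero samples has an undefined dissimilarity; this raises
    unless ``zero_policy="one"``, which reports 1 for such pairs.
    """
    if table.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    x = table.to_numpy(dtype=float)
    zero_rows = x.sum(axis=1) == 0
    if zero_rows.sum() >= 2 and zero_policy != "one":
        bad = table.index[zero_rows].tolist()
        raise ValidationError(f"all-zero samples give undefined Bray-Curtis pairs: {bad}")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(s) for s in table.index])


@dataclass
class NicheBreadthResult:
    """Levins niche breadth per taxon and its community (per-sample) mean."""

    taxon_breadth: pd.Series
    community_breadth: pd.Series


def niche_breadth(table: pd.DataFrame) -> NicheBreadthResult:
    """Levins B_j = 1 / sum_h P_jh^2 over the taxon's distribution across
    samples; B_com(sample) is the unweighted mean of B_j over the taxa
    present in that sample."""
    if table.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    counts = table.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} taxa with zero total excluded from niche breadth"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        b = 1.0 / (p**2).sum(axis=0)
    b[zero] = np.nan
    taxon_b = pd.Series(b, index=table.columns, name="levins_b")
    present = counts > 0
    bcom = np.full(table.shape[0], np.nan)
    for i in range(table.shape[0]):
        vals = b[present[i] & ~zero]
        if len(vals):
            bcom[i] = vals.mean()
    community = pd.Series(bcom, index=table.index, name="community_niche_breadth")
    return NicheBreadthResult(taxon_b, community)


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of per-sample relative abundances."""
    x = table.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return pd.DataFrame(np.sqrt(x / totals), index=table.index, columns=table.columns)
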