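"""Network topology metrics and Erdos-Renyi G(n, m) significance testing.

Metrics follow common co-occurrence-network practice: average degree
``2E/N``, density ``2E/(N(N-1))``, average path distance (mean unweighted
shortest-path length over the largest connected component) and modularity
Q from deterministic greedy (CNM) agglomeration.  Edge signs are ignored
for topology and reported separately as sign fractions.  The null model is
G(n, m): uniform simple graphs with the observed node and edge counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ValidationError

__all__ = ["TopologySummary", "topology_metrics", "er_null"]


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    apd: float | None
    modularity: float | None
    positive_fraction: float | None = None
    negative_fraction: float | None = None
    nulls: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "density": self.density,
            "apd": self.apd,
            "modularity": self.modularity,
            "positive_fraction": self.positive_fraction,
            "negative_fraction": self.negative_fraction,
            "nulls": self.nulls,
        }


def _metrics(g: nx.Graph) -> tuple[float, float, float | None, float | None]:
    n = g.number_of_nodes()
    m = g.number_of_edges()
    avg_k = 2.0 * m / n
    density = 2.0 * m / (n * (n - 1))
    if m == 0:
        return avg_k, density, None, None
    comps = max(nx.connected_components(g), key=len)
    lcc = g.subgraph(comps)
    apd = nx.average_shortest_path_length(lcc) if len(lcc) > 1 else None
    communities = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, communities)
    return avg_k, density, apd, float(q)


def topology_metrics(net: nx.Graph) -> TopologySummary:
    """Topology summary of a simple undirected graph (ER nulls unfilled)."""
    if net.number_of_nodes() < 2:
        raise ValidationError("need at least 2 nodes")
    avg_k, density, apd, q = _metrics(net)
    signs = [d.get("sign") for _, _, d in net.edges(data=True)]
    known = [s for s in signs if s in ("+", "-")]
    pos = sum(s == "+" for s in known)
    return TopologySummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        avg_degree=avg_k,
        density=density,
        apd=apd,
        modularity=q,
        positive_fraction=pos / len(known) if known else None,
        negative_fraction=(len(known) - pos) / len(known) if known else None,
    )


def er_null(
    observed: TopologySummary,
    n_reps: int = 1000,
    seed: int | None = None,
) -> TopologySummary:
    """Standardise the observed topology against G(n, m) random graphs.

    Per metric: null mean and SD, z-score, and an empirical two-sided
    p-value with the (1 + b) / (1 + n_reps) estimator.  Metrics fixed by
    construction (density, average degree) have zero null SD and an
    undefined z, reported as NaN with a warning.
    """
    n, m = observed.n_nodes, observed.n_edges
    if m > n * (n - 1) // 2:
        raise ValidationError("n_edges exceeds the simple-graph maximum")
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in ("avg_degree", "density", "apd", "modularity")}
    for _ in range(n_reps):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        avg_k, density, apd, q = _metrics(g)
        draws["avg_degree"].append(avg_k)
        draws["density"].append(density)
        if apd is not None:
            draws["apd"].append(apd)
        if q is not None:
            draws["modularity"].append(q)
    obs_vals = {
        "avg_degree": observed.avg_degree,
        "density": observed.density,
        "apd": observed.apd,
        "modularity": observed.modularity,
    }
    nulls = {}
    for metric, vals in draws.items():
        ov = obs_vals[metric]
        if not vals or ov is None:
            continue
        arr = np.array(vals)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        if sd <= 1e-12 * max(1.0, abs(mean)):
            sd = 0.0
            warnings.warn(f"degenerate ER null for {metric}: zero SD, z undefined")
            z = float("nan")
        else:
            z = (ov - mean) / sd
        b = int((np.abs(arr - mean) >= abs(ov - mean)).sum())
        nulls[metric] = {
            "mean": mean,
            "sd": sd,
            "z": z,
            "p": (1 + b) / (1 + len(arr)),
        }
    observed.nulls = nulls
    return observed
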