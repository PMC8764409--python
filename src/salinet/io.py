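"""Readers and writers for the external formats the pipeline touches.

Internal conventions
--------------------
* OTU tables are :class:`pandas.DataFrame` objects with **samples as rows**
  and taxa as columns, holding non-negative integer counts.
* Environmental tables are DataFrames indexed by sample id; the categorical
  lake/group label lives in a ``group`` column.
* Phylogenies are rooted :class:`skbio.TreeNode` objects with branch lengths.
* Signed co-occurrence networks are :class:`networkx.Graph` objects whose
  edges carry ``sign``, ``n_supporting_measures``, ``merged_p`` and ``q``.

All identifiers are case-sensitive and whitespace-trimmed on input.
"""

from __future__ import annotations

import io as _io
import math
import os
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import skbio

__all__ = [
    "ValidationError",
    "read_otu_table",
    "write_otu_table",
    "read_env_table",
    "write_env_table",
    "validate_otu_table",
    "read_tree",
    "cophenetic_distances",
    "check_tree_matches_table",
    "write_network",
    "read_network",
    "EDGE_COLUMNS",
]

EDGE_COLUMNS = ("taxon_a", "taxon_b", "sign", "n_supporting_measures", "merged_p", "q")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _trim_ids(index: pd.Index, what: str) -> pd.Index:
    trimmed = pd.Index([str(x).strip() for x in index])
    dup = trimmed[trimmed.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate {what} identifiers: {dup}")
    return trimmed


def validate_otu_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check OTU-table invariants and return an integer samples x taxa frame."""
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise ValidationError("OTU table must have at least one sample and one taxon")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        coerced = table.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & table.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValidationError(
                f"non-numeric count at sample {table.index[r]!r}, taxon {table.columns[c]!r}"
            )
        table = coerced
        arr = table.to_numpy()
    if np.isnan(arr.astype(float)).any():
        raise ValidationError("OTU table contains missing values")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"negative count at sample {table.index[r]!r}, taxon {table.columns[c]!r}"
        )
    if not np.allclose(arr.astype(float), np.round(arr.astype(float))):
        raise ValidationError("OTU table counts must be integers")
    out = table.astype(np.int64)
    out.index = _trim_ids(out.index, "sample")
    out.columns = _trim_ids(out.columns, "taxon")
    return out


def read_otu_table(path, orientation: str = "samples-as-rows") -> pd.DataFrame:
    """Read a TSV count table and normalise it to samples x taxa.

    Parameters
    ----------
    path
        TSV file with one header row and a leading id column.
    orientation
        ``"samples-as-rows"`` (default) or ``"taxa-as-rows"``.
    """
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    header = [h.strip() for h in header]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise ValidationError(f"duplicate column identifiers: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa-as-rows":
        df = df.T
    return validate_otu_table(df)


def write_otu_table(table: pd.DataFrame, path, orientation: str = "samples-as-rows") -> None:
    out = table if orientation == "samples-as-rows" else table.T
    out.to_csv(path, sep="\t", index_label="id")


def read_env_table(path, group_col: str = "group") -> pd.DataFrame:
    """Read per-sample environmental metadata (TSV, samples as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = _trim_ids(df.index, "sample")
    if "salinity" in df.columns and (pd.to_numeric(df["salinity"]) < 0).any():
        raise ValidationError("salinity must be non-negative")
    if group_col in df.columns:
        df[group_col] = df[group_col].astype(str)
    return df


def write_env_table(env: pd.DataFrame, path) -> None:
    env.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# trees


def read_tree(path, strict: bool = True) -> skbio.TreeNode:
    """Read a rooted Newick tree.

    Missing branch lengths are an error in strict mode and 0.0 otherwise;
    defaulting silently would corrupt phylogenetic turnover statistics.
    """
    tree = skbio.TreeNode.read(str(path) if not hasattr(path, "read") else path,
                               format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if strict:
                raise ValidationError(
                    f"branch without length above node {node.name!r} (strict mode)"
                )
            node.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    names = []
    for tip in tree.tips():
        if tip.name is None:
            raise ValidationError("tree contains an unnamed tip")
        tip.name = tip.name.strip()
        names.append(tip.name)
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate tip labels: {dup}")
    return tree


def check_tree_matches_table(tree: skbio.TreeNode, taxon_ids: Iterable[str]) -> None:
    """Require every analysis taxon to appear exactly once as a tip."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxon_ids) - tips)
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")


def cophenetic_distances(tree: skbio.TreeNode, taxon_ids: Sequence[str] | None = None):
    """Tip-to-tip (cophenetic) distance matrix.

    Returns ``(matrix, ids)`` with rows/columns ordered by ``taxon_ids``
    when given, otherwise by the tree's tip order.
    """
    dm = tree.tip_tip_distances()
    if taxon_ids is None:
        ids = list(dm.ids)
        return dm.data.copy(), ids
    check_tree_matches_table(tree, taxon_ids)
    idx = [dm.index(t) for t in taxon_ids]
    return dm.data[np.ix_(idx, idx)].copy(), list(taxon_ids)


# ---------------------------------------------------------------------------
# networks


def _edge_records(net: nx.Graph) -> list[dict]:
    rows = []
    for a, b, attrs in net.edges(data=True):
        ta, tb = sorted((str(a), str(b)))
        rows.append(
            {
                "taxon_a": ta,
                "taxon_b": tb,
                "sign": attrs.get("sign", "+"),
                "n_supporting_measures": int(attrs.get("n_supporting_measures", 0)),
                "merged_p": float(attrs.get("merged_p", math.nan)),
                "q": float(attrs.get("q", math.nan)),
            }
        )
    rows.sort(key=lambda r: (r["taxon_a"], r["taxon_b"]))
    return rows


def write_network(net: nx.Graph, path, format: str = "edge-list") -> None:
    """Write a signed network as an edge-list TSV or GraphML file."""
    if format in ("edge-list", "tsv"):
        df = pd.DataFrame(_edge_records(net), columns=list(EDGE_COLUMNS))
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        out = nx.Graph()
        out.add_nodes_from(str(n) for n in net.nodes)
        for r in _edge_records(net):
            out.add_edge(
                r["taxon_a"],
                r["taxon_b"],
                sign=r["sign"],
                n_supporting_measures=r["n_supporting_measures"],
                merged_p=r["merged_p"],
                q=r["q"],
            )
        nx.write_graphml(out, path)
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path, format: str | None = None) -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    if format is None:
        format = "graphml" if str(path).endswith(".graphml") else "edge-list"
    if format == "graphml":
        g = nx.read_graphml(path)
        net = nx.Graph()
        net.add_nodes_from(g.nodes)
        for a, b, attrs in g.edges(data=True):
            net.add_edge(
                a,
                b,
                sign=str(attrs["sign"]),
                n_supporting_measures=int(attrs["n_supporting_measures"]),
                merged_p=float(attrs["merged_p"]),
                q=float(attrs["q"]),
            )
        return net
    df = pd.read_csv(path, sep="\t", dtype={"taxon_a": str, "taxon_b": str})
    net = nx.Graph()
    for r in df.itertuples(index=False):
        net.add_edge(
            r.taxon_a,
            r.taxon_b,
            sign=str(r.sign),
            n_supporting_measures=int(r.n_supporting_measures),
            merged_p=float(r.merged_p),
            q=float(r.q),
        )
    return net
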