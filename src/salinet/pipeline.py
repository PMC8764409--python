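"""End-to-end orchestration of the salinity-gradient workflow.

Stages: simulate (or load) -> rarefy -> alpha diversity & core community ->
Bray-Curtis -> PerMANOVA -> MRT -> betaNTI -> niche breadth ->
Kruskal-Wallis / Spearman correlations -> per-group co-occurrence networks
-> topology + ER nulls.  Every stage seed is derived deterministically
from the master seed, and the JSON run report is byte-identical for a
fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from skbio.stats.ordination import pcoa

from . import assembly, diversity, io, multivariate, network, simulate, topology
from .io import ValidationError

__all__ = ["RunConfig", "run_pipeline", "kruskal_and_correlations", "stage_seed",
           "significance_stars"]

log = logging.getLogger("salinet")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration of a pipeline run.

    Defaults are desk-scale: they keep a full run (simulation included)
    within a couple of minutes on one CPU while preserving every stage of
    the study workflow.  The emulated study design itself (group sizes and
    salinities) always comes from the generator defaults unless input
    files are given.
    """

    # inputs: either simulate, or load these three paths
    otu_path: str | None = None
    env_path: str | None = None
    tree_path: str | None = None
    # simulation spec
    n_taxa: int = 400
    depth_min: int = 2000
    depth_max: int = 4000
    bm_rate: float = 38.0
    root_optimum: float = 3.0
    tolerance_median: float = 0.35
    tolerance_sigma: float = 0.5
    baseline_sigma: float = 0.8
    noise_sd: float = 1.2
    stress_halfsat: float | None = 3.0
    n_planted_pairs: int = 12
    planted_rho: float = 0.9
    neutral: bool = False
    # analysis parameters
    rarefy_depth: int | None = None  # None -> minimum sample total
    n_perm_permanova: int = 999
    n_null_bnti: int = 199
    n_perm_phylo_signal: int = 199
    cv_folds: int = 10
    min_occupancy: float = 0.8
    n_top: int = 500
    n_bottom: int = 500
    n_perm_network: int = 200
    n_boot_network: int = 200
    alpha: float = 0.05
    n_er: int = 200
    seed: int = 0
    out_dir: str = "salinet_run"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed hashed with the stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def kruskal_and_correlations(metrics: pd.DataFrame, env: pd.DataFrame,
                             group_col: str = "group") -> dict:
    """Kruskal-Wallis group tests per metric and Spearman correlations of
    each metric against salinity and nutrient variables."""
    groups = env.loc[metrics.index, group_col]
    if groups.nunique() < 2:
        raise ValidationError("need at least 2 groups")
    out: dict = {"kruskal": {}, "correlations": {}}
    env_vars = [v for v in ("salinity", "TN", "TP", "NH4N", "DOC", "COD")
                if v in env.columns]
    for metric in metrics.columns:
        vals = metrics[metric]
        samples = [vals[groups == g].to_numpy() for g in sorted(groups.unique())]
        if np.ptp(np.concatenate(samples)) == 0:
            out["kruskal"][metric] = {"H": 0.0, "p": 1.0, "stars": "ns"}
        else:
            H, p = stats.kruskal(*samples)
            out["kruskal"][metric] = {"H": float(H), "p": float(p),
                                      "stars": significance_stars(p)}
        out["correlations"][metric] = {}
        for v in env_vars:
            x = env.loc[metrics.index, v].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(vals.to_numpy()) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(vals.to_numpy(), x)
            out["correlations"][metric][v] = {
                "rho": float(rho), "p": float(p), "stars": significance_stars(p),
            }
    return out


def _round_floats(obj, ndigits: int = 10):
    """Round floats for a stable textual report (avoids last-ulp noise)."""
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write stage outputs plus ``report.json``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "stage_seeds": {},
    }

    def sseed(stage: str) -> int:
        s = stage_seed(config.seed, stage)
        report["stage_seeds"][stage] = s
        return s

    # ---- inputs -----------------------------------------------------------
    if config.otu_path:
        log.info("loading inputs")
        otu = io.read_otu_table(config.otu_path)
        env = io.read_env_table(config.env_path)
        tree = io.read_tree(config.tree_path)
        truth = None
    else:
        log.info("simulating community (n_taxa=%d)", config.n_taxa)
        otu, env, tree, truth = simulate.simulate_dataset(
            n_taxa=config.n_taxa,
            seed=sseed("simulate"),
            bm_rate=config.bm_rate,
            root_optimum=config.root_optimum,
            tolerance_median=config.tolerance_median,
            tolerance_sigma=config.tolerance_sigma,
            baseline_sigma=config.baseline_sigma,
            noise_sd=config.noise_sd,
            depth_range=(config.depth_min, config.depth_max),
            n_planted_pairs=config.n_planted_pairs,
            rho=config.planted_rho,
            neutral=config.neutral,
            stress_halfsat=config.stress_halfsat,
        )
        io.write_otu_table(otu, out_dir / "otu_table.tsv")
        io.write_env_table(env, out_dir / "env.tsv")
        tree.write(str(out_dir / "tree.nwk"))
        (out_dir / "truth.json").write_text(truth.to_json())
    env = env.loc[otu.index]
    groups = sorted(env["group"].unique())

    # ---- rarefaction ------------------------------------------------------
    rare = diversity.rarefy(otu, depth=config.rarefy_depth, seed=sseed("rarefy"))
    io.write_otu_table(rare, out_dir / "otu_rarefied.tsv")
    report["rarefaction_depth"] = int(rare.sum(axis=1).iloc[0])

    # ---- alpha diversity & core -------------------------------------------
    alpha = diversity.alpha_diversity(rare)
    alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t", index_label="sample")
    report["alpha_diversity"] = {
        g: {m: float(alpha.loc[env["group"] == g, m].mean()) for m in alpha.columns}
        for g in groups
    }
    core100, frac100 = diversity.core_fraction(rare, 1.0)
    core80, frac80 = diversity.core_fraction(rare, 0.8)
    report["core"] = {
        "core100_n": len(core100), "core100_fraction": frac100,
        "core80_n": len(core80), "core80_fraction": frac80,
    }

    # ---- beta diversity: Bray-Curtis, ordination, PerMANOVA ----------------
    bc = diversity.bray_curtis(rare)
    ord_res = pcoa(bc, number_of_dimensions=2)
    ord_res.samples.iloc[:, :2].to_csv(out_dir / "pcoa.tsv", sep="\t",
                                       index_label="sample")
    perm = multivariate.permanova(bc, env["group"],
                                  n_perm=config.n_perm_permanova,
                                  seed=sseed("permanova"))
    report["permanova"] = perm.to_dict()

    # ---- MRT ---------------------------------------------------------------
    mrt = multivariate.mrt_fit(rare, env, cv_folds=config.cv_folds,
                               seed=sseed("mrt"))
    report["mrt"] = mrt.to_dict()
    mrt.leaf_assignments_.to_csv(out_dir / "mrt_leaves.tsv", sep="\t",
                                 index_label="sample")

    # ---- betaNTI ------------------------------------------------------------
    log.info("betaNTI with %d randomizations", config.n_null_bnti)
    bn = assembly.bnti(rare, tree, n_null=config.n_null_bnti,
                       seed=sseed("bnti"))
    long = bn.to_long()
    long.to_csv(out_dir / "bnti.tsv", sep="\t", index=False)
    bnti_summary = {}
    for g in groups:
        samples = env.index[env["group"] == g].tolist()
        vals = bn.values_for(samples)
        if vals.size == 0:
            bnti_summary[g] = {"n_pairs": 0}
            continue
        classes = [assembly.classify_process(v) for v in vals]
        bnti_summary[g] = {
            "n_pairs": int(vals.size),
            "median": float(np.median(vals)),
            "fraction_variable_selection": classes.count("variable_selection") / len(classes),
            "fraction_homogeneous_selection": classes.count("homogeneous_selection") / len(classes),
            "fraction_stochastic": classes.count("stochastic") / len(classes),
        }
    all_vals = bn.bnti[np.triu_indices(len(bn.sample_ids), 1)]
    all_vals = all_vals[np.isfinite(all_vals)]
    report["bnti"] = {
        "within_group": bnti_summary,
        "overall_median": float(np.median(all_vals)) if all_vals.size else None,
        "overall_fraction_selection": float((np.abs(all_vals) > 2).mean()) if all_vals.size else None,
    }

    # ---- phylogenetic signal ------------------------------------------------
    sig = assembly.phylo_signal(tree, rare, env,
                                n_perm=config.n_perm_phylo_signal,
                                seed=sseed("phylo_signal"))
    report["phylo_signal"] = {"mantel_r": float(sig.r), "p": float(sig.p)}

    # ---- niche breadth ------------------------------------------------------
    nb = diversity.niche_breadth(rare)
    report["niche_breadth"] = {
        g: float(nb.community_breadth[env["group"] == g].mean()) for g in groups
    }

    # ---- group tests & correlations ----------------------------------------
    metrics = alpha.copy()
    metrics["niche_breadth"] = nb.community_breadth
    report["group_tests"] = kruskal_and_correlations(metrics, env)

    # ---- networks (per group, plus pooled across the gradient) -------------
    report["networks"] = {}
    pos_total = neg_total = 0
    for g in [*groups, "all"]:
        if g == "all":
            sub = rare
        else:
            sub = otu.loc[env["group"] == g]
            sub = diversity.rarefy(sub, seed=sseed(f"rarefy:{g}"))
        try:
            res = network.infer_network(
                sub,
                min_occupancy=config.min_occupancy,
                n_top=config.n_top,
                n_bottom=config.n_bottom,
                n_perm=config.n_perm_network,
                n_boot=config.n_boot_network,
                alpha=config.alpha,
                seed=sseed(f"network:{g}"),
            )
        except ValidationError as exc:
            report["networks"][g] = {"error": str(exc)}
            continue
        graph = res.graph
        io.write_network(graph, out_dir / f"network_{g}.tsv", format="edge-list")
        io.write_network(graph, out_dir / f"network_{g}.graphml", format="graphml")
        entry: dict = {
            "n_candidates": len(res.candidate_pairs),
            "n_taxa_filtered": len(res.taxa),
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "positive_fraction": graph.graph["positive_fraction"],
            "negative_fraction": graph.graph["negative_fraction"],
            "n_discarded_sign_ties": graph.graph["n_discarded_sign_ties"],
        }
        signs = [d["sign"] for _, _, d in graph.edges(data=True)]
        pos_total += signs.count("+")
        neg_total += signs.count("-")
        if graph.number_of_nodes() >= 2 and graph.number_of_edges() >= 1:
            summ = topology.topology_metrics(graph)
            summ = topology.er_null(summ, n_reps=config.n_er,
                                    seed=sseed(f"er:{g}"))
            entry["topology"] = summ.to_dict()
        report["networks"][g] = entry
    total = pos_total + neg_total
    report["positive_fraction_overall"] = pos_total / total if total else None

    report = _round_floats(report)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report
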