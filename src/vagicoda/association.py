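"""Cross-omics Spearman correlation screening and network assembly.

Pairwise Spearman correlations among taxa (prevalence-filtered relative
abundances), metabolites and dietary variables are screened at a raw
significance threshold; the surviving edges form a correlation network
whose bacterial nodes are clustered by their indicator group over the
three CST groups and whose metabolite/nutrient nodes join the bacterial
cluster they correlate with most positively.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .microbiome import IndicatorResult

RESIDUAL_CLUSTER = "no-difference"


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Tie-corrected Spearman correlation with a two-sided p-value.

    ``method="t"`` uses the t approximation with n-2 degrees of freedom;
    ``method="exact"`` enumerates all rank permutations (n <= 9 only).
    A constant input is reported as undefined (NaN), never as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", UserWarning, stacklevel=2)
        return SpearmanResult(math.nan, math.nan, n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p only for n <= 9")
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        return SpearmanResult(rho, hits / total, n)
    if method != "t":
        raise ValueError(f"unknown method {method!r}")
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n)
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), n)


def prevalence_filter(table: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Keep taxa whose relative abundance reaches ``threshold`` in >= 1 sample.

    The bound is inclusive: a taxon peaking exactly at the threshold is
    retained.
    """
    arr = table.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundances")
    keep = table.max(axis=0) >= threshold
    return table.loc[:, keep]


@dataclass
class EdgeTable:
    """Significant pairwise correlations plus node metadata."""

    edges: pd.DataFrame  # feature_a, class_a, feature_b, class_b, rho, p, n
    nodes: pd.DataFrame  # index feature, column class
    alpha: float


def correlation_screen(
    taxa: pd.DataFrame,
    metabolites: pd.DataFrame,
    nutrients: pd.DataFrame,
    alpha: float = 0.05,
) -> EdgeTable:
    """Screen all within- and cross-class Spearman correlations at ``alpha``.

    The three tables must share an identical sample index (same order).
    Constant features yield undefined correlations and contribute no
    edges.  Retained edges keep the signed rho and the sample count.
    """
    blocks = {"taxon": taxa, "metabolite": metabolites, "nutrient": nutrients}
    index = taxa.index
    for name, block in blocks.items():
        if not block.index.equals(index):
            raise ValueError(f"{name} table index is not aligned with the taxa table")
    features, classes = [], []
    mats = []
    for cls, block in blocks.items():
        for col in block.columns:
            features.append(str(col))
            classes.append(cls)
        mats.append(block.to_numpy(dtype=float))
    if len(set(features)) != len(features):
        raise ValueError("feature names must be unique across tables")
    x = np.hstack(mats)
    n = x.shape[0]
    constant = np.ptp(x, axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho_mat, p_mat = stats.spearmanr(x)
    rho_mat = np.atleast_2d(rho_mat)
    p_mat = np.atleast_2d(p_mat)
    rows = []
    for i, j in itertools.combinations(range(len(features)), 2):
        if constant[i] or constant[j]:
            continue
        p = p_mat[i, j]
        if np.isfinite(p) and p < alpha:
            rows.append(
                {
                    "feature_a": features[i],
                    "class_a": classes[i],
                    "feature_b": features[j],
                    "class_b": classes[j],
                    "rho": rho_mat[i, j],
                    "p": p,
                    "n": n,
                }
            )
    edges = pd.DataFrame(
        rows, columns=["feature_a", "class_a", "feature_b", "class_b", "rho", "p", "n"]
    )
    nodes = pd.DataFrame({"class": classes}, index=pd.Index(features, name="feature"))
    return EdgeTable(edges=edges, nodes=nodes, alpha=alpha)


def cluster_assign(
    edge_table: EdgeTable,
    indicator: IndicatorResult,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Cluster nodes by indicator groups and positive correlations.

    Taxa with a significant indicator value join the cluster named after
    their indicator group; non-significant taxa form the residual
    cluster ("no-difference").  Each metabolite/nutrient joins the
    bacterial cluster with the largest mean significant positive rho;
    nodes with significant positive edges into several clusters are
    flagged ``shared`` with all memberships listed; nodes with no
    significant positive taxon edge stay unassigned.
    """
    nodes = edge_table.nodes.copy()
    taxa = nodes.index[nodes["class"] == "taxon"]
    missing = [t for t in taxa if t not in indicator.stats.index]
    if missing:
        raise ValueError(f"taxa without indicator scores: {missing}")
    cluster = {}
    for t in taxa:
        row = indicator.stats.loc[t]
        cluster[t] = row["group"] if row["p"] <= significance else RESIDUAL_CLUSTER

    edges = edge_table.edges
    if edges.empty:
        warnings.warn("empty edge table: non-taxon nodes left unassigned", UserWarning, stacklevel=2)
    rows = []
    for node in nodes.index:
        cls = nodes.loc[node, "class"]
        if cls == "taxon":
            rows.append(
                {"feature": node, "class": cls, "cluster": cluster[node], "shared": False,
                 "memberships": cluster[node]}
            )
            continue
        pos = {}
        if not edges.empty:
            mask_a = (edges["feature_a"] == node) & (edges["class_b"] == "taxon")
            mask_b = (edges["feature_b"] == node) & (edges["class_a"] == "taxon")
            pairs = pd.concat(
                [
                    edges.loc[mask_a, ["feature_b", "rho"]].rename(columns={"feature_b": "taxon"}),
                    edges.loc[mask_b, ["feature_a", "rho"]].rename(columns={"feature_a": "taxon"}),
                ]
            )
            pairs = pairs[pairs["rho"] > 0]
            for _, pr in pairs.iterrows():
                c = cluster.get(pr["taxon"])
                if c is None:
                    continue
                pos.setdefault(c, []).append(pr["rho"])
        if not pos:
            rows.append(
                {"feature": node, "class": cls, "cluster": "unassigned", "shared": False,
                 "memberships": ""}
            )
            continue
        means = {c: float(np.mean(v)) for c, v in pos.items()}
        best = max(sorted(means), key=lambda c: means[c])
        rows.append(
            {
                "feature": node,
                "class": cls,
                "cluster": best,
                "shared": len(means) > 1,
                "memberships": ";".join(sorted(means)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def export_network(edge_table: EdgeTable, clusters: pd.DataFrame | None, out_dir) -> dict:
    """Write the correlation network as an edge-list TSV and GraphML.

    Node attributes: feature class and cluster ("none" when absent);
    edge attributes: rho, p, sign and weight = |rho|.  The GraphML file
    round-trips losslessly through :func:`read_network`.
    Returns the written paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if edge_table.nodes.empty:
        raise ValueError("empty node set")
    g = nx.Graph()
    for node, row in edge_table.nodes.iterrows():
        clu = "none"
        if clusters is not None and node in clusters.index:
            clu = str(clusters.loc[node, "cluster"])
        g.add_node(str(node), feature_class=str(row["class"]), cluster=clu)
    for _, e in edge_table.edges.iterrows():
        g.add_edge(
            str(e["feature_a"]),
            str(e["feature_b"]),
            rho=float(e["rho"]),
            p=float(e["p"]),
            sign="+" if e["rho"] >= 0 else "-",
            weight=abs(float(e["rho"])),
        )
    edge_path = out / "edges.tsv"
    graphml_path = out / "network.graphml"
    try:
        edge_table.edges.to_csv(edge_path, sep="\t", index=False)
        nx.write_graphml(g, graphml_path)
    except OSError as err:
        raise OSError(f"failed writing network files under {out}: {err}") from err
    return {"edges": edge_path, "graphml": graphml_path}


def read_network(graphml_path) -> nx.Graph:
    """Re-read an exported GraphML network."""
    return nx.read_graphml(graphml_path)
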