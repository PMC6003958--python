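"""Vicinity (ego) networks around seed genes and their topology statistics.

A vicinity network (VN) is the induced subgraph on a seed gene plus its
direct neighbours in the global co-expression network — the unit at which
the model is interpreted biologically.  Each VN is summarised by node and
edge counts, its mean clustering coefficient, the average number of
neighbours (mean degree) and the simple-graph density::

    avg_neighbors = 2 E / N
    density       = avg_neighbors / (N - 1) = 2 E / (N (N - 1))

matching the NetworkAnalyzer conventions.  VNs passing a retention filter
(strictly above a bound on density or clustering) are carried forward, and
member expression profiles are exported in long form for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import NormalizedMatrix
from .network import Network, mean_clustering, DegenerateMetricError

__all__ = [
    "VNStats",
    "VicinityNetwork",
    "avg_neighbors",
    "graph_density",
    "density_from_mean_degree",
    "extract_vicinity",
    "vn_stats",
    "filter_vns",
    "expression_profiles",
    "export_vn",
    "vn_summary",
]


def avg_neighbors(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N of a simple graph."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return 2.0 * n_edges / n_nodes


def density_from_mean_degree(n_nodes: int, mean_degree: float) -> float:
    """Simple-graph density as mean degree over (N-1)."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    return mean_degree / (n_nodes - 1)


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Simple-graph density 2E/(N(N-1)), i.e. mean degree over (N-1).

    Undefined (NaN) for a single-node graph.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    if n_nodes == 1:
        return float("nan")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


@dataclass(frozen=True)
class VNStats:
    n_nodes: int
    n_edges: int
    mean_cc: float
    avg_neighbors: float
    density: float


@dataclass(frozen=True)
class VicinityNetwork:
    """Seed gene plus its first-order neighbourhood as an induced subgraph."""

    seed: str
    graph: nx.Graph  # induced subgraph, includes the seed
    stats: VNStats

    @property
    def member_genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def is_isolated(self) -> bool:
        return self.stats.n_nodes == 1


def vn_stats(graph: nx.Graph) -> VNStats:
    """Topology statistics of a (vicinity) graph.

    ``mean_cc`` averages local clustering over vertices of degree >= 1 and is
    NaN for an edgeless graph; ``density`` is NaN for a single node.
    """
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    try:
        cc = mean_clustering(graph)
    except DegenerateMetricError:
        cc = float("nan")
    return VNStats(
        n_nodes=n,
        n_edges=e,
        mean_cc=cc,
        avg_neighbors=avg_neighbors(n, e),
        density=graph_density(n, e),
    )


def extract_vicinity(net: Network, seed: str, radius: int = 1) -> VicinityNetwork:
    """Extract the radius-1 ego network of ``seed`` from the global network.

    Members are the seed and every gene within ``radius`` edges of it; the
    edge set is the full induced subgraph on the members (neighbour–neighbour
    edges included).  A seed present in the gene universe but without any
    edge yields a single-node VN flagged by its stats (density NaN).
    """
    if seed not in net.gene_ids:
        raise KeyError(f"seed gene {seed!r} not in the gene universe")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if seed in net.graph:
        ego = nx.ego_graph(net.graph, seed, radius=radius)
        sub = net.graph.subgraph(ego.nodes).copy()
    else:
        sub = nx.Graph()
        sub.add_node(seed)
    return VicinityNetwork(seed, sub, vn_stats(sub))


def filter_vns(
    vns: Sequence[VicinityNetwork],
    metric: str = "density",
    min_value: float = 0.5,
) -> list[VicinityNetwork]:
    """Retain VNs whose chosen statistic is strictly above ``min_value``.

    ``metric`` is ``"density"`` (default) or ``"mean_cc"``.  A VN sitting
    exactly on the bound is dropped; NaN statistics never pass.
    """
    if metric not in {"density", "mean_cc"}:
        raise ValueError(f"unknown retention metric: {metric!r}")
    if not (0 <= min_value <= 1):
        raise ValueError("min_value must be in [0, 1]")
    return [vn for vn in vns if getattr(vn.stats, metric) > min_value]


def expression_profiles(
    vn: VicinityNetwork,
    nm: NormalizedMatrix,
) -> pd.DataFrame:
    """Long-format (gene, sample, group, cpm) table for the VN members.

    Samples are blocked by group label (alphabetical group order, e.g.
    inflorescence before shoot), preserving the matrix's within-group sample
    order; genes are ordered seed-first then alphabetically.
    """
    missing = sorted(g for g in vn.member_genes if g not in set(nm.gene_ids))
    if missing:
        raise KeyError(
            f"VN gene(s) absent from the expression matrix: {', '.join(missing)}"
        )
    group_order = sorted(set(nm.groups.values()))
    samples: list[str] = []
    for grp in group_order:
        samples.extend(s for s in nm.sample_ids if nm.groups[s] == grp)
    genes = [vn.seed] + sorted(g for g in vn.member_genes if g != vn.seed)
    records = [
        {
            "gene": g,
            "sample": s,
            "group": nm.groups[s],
            "cpm": float(nm.cpm.at[g, s]),
        }
        for g in genes
        for s in samples
    ]
    return pd.DataFrame(records, columns=["gene", "sample", "group", "cpm"])


def export_vn(vn: VicinityNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write a VN as GraphML plus node-attribute and edge-list TSV mirrors.

    GraphML nodes carry ``is_seed`` and ``degree`` attributes and edges carry
    the correlation as ``weight``; the files are Cytoscape-importable.
    Returns the written paths keyed by kind.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = nx.Graph()
    for node in sorted(vn.graph.nodes):
        g.add_node(node, is_seed=bool(node == vn.seed),
                   degree=int(vn.graph.degree(node)))
    for u, v, data in sorted(vn.graph.edges(data=True)):
        g.add_edge(u, v, weight=float(data.get("weight", float("nan"))))
    stem = vn.seed.replace("/", "_")
    paths = {
        "graphml": out_dir / f"vn_{stem}.graphml",
        "nodes": out_dir / f"vn_{stem}_nodes.tsv",
        "edges": out_dir / f"vn_{stem}_edges.tsv",
    }
    nx.write_graphml(g, paths["graphml"])
    with open(paths["nodes"], "w") as fh:
        fh.write("gene\tis_seed\tdegree\n")
        for node in sorted(g.nodes):
            fh.write(f"{node}\t{str(g.nodes[node]['is_seed']).lower()}"
                     f"\t{g.nodes[node]['degree']}\n")
    with open(paths["edges"], "w") as fh:
        fh.write("gene1\tgene2\trho\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.6g}\n")
    return paths


def vn_summary(vns: Sequence[VicinityNetwork],
               retained: Sequence[VicinityNetwork] | None = None) -> pd.DataFrame:
    """One row per seed: node/edge counts, meanCC, mean degree, density and
    whether the VN passed the retention filter."""
    kept = {vn.seed for vn in retained} if retained is not None else None
    rows = []
    for vn in vns:
        s = vn.stats
        rows.append({
            "seed_id": vn.seed,
            "n_nodes": s.n_nodes,
            "n_edges": s.n_edges,
            "mean_cc": s.mean_cc,
            "avg_neighbors": s.avg_neighbors,
            "density": s.density,
            "retained": (vn.seed in kept) if kept is not None else pd.NA,
        })
    return pd.DataFrame(rows, columns=["seed_id", "n_nodes", "n_edges",
                                       "mean_cc", "avg_neighbors", "density",
                                       "retained"])
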