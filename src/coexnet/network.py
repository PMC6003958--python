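"""Hard-thresholded co-expression networks and scale-free/small-world metrics.

The association matrix is converted to an unweighted simple graph by keeping
gene pairs with |rho| >= t for a threshold t.  For each candidate threshold
the following topology metrics are computed (one row of the refinement table):

========  ==============================================================
r2        coefficient of determination of an OLS fit of log10 n(k) on
          log10 k over the degree histogram (scale-free goodness of fit)
slope     slope of that fit (the power-law exponent estimate; negative)
meanCC    mean local clustering coefficient over used vertices
meanPath  mean shortest-path length over connected pairs in the largest
          component
%used     share of the gene universe with at least one edge
%bigComp  share of used vertices inside the largest connected component
========  ==============================================================

The "best" threshold is the row maximising r2 among rows passing all
selection criteria (r2 > 0.9, meanCC < 0.5, meanPath < 5, %used > 95,
%bigComp > 95 by default); when no row passes everything, the row satisfying
the most criteria (ties: higher r2, then larger threshold) is returned and
marked as a relaxed selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix

__all__ = [
    "Network",
    "ThresholdMetrics",
    "SelectionCriteria",
    "SelectionResult",
    "DegenerateMetricError",
    "DEFAULT_THRESHOLD_GRID",
    "threshold_adjacency",
    "degree_distribution_fit",
    "mean_clustering",
    "mean_path_length",
    "coverage_stats",
    "network_metrics",
    "refine_thresholds",
    "select_threshold",
    "metrics_table",
    "write_edge_list",
]

#: The refinement grid between the "best" and "alternative" proposals.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (0.845, 0.85, 0.855, 0.858, 0.86, 0.862)


class DegenerateMetricError(ValueError):
    """A topology metric is undefined on this graph (too small/degenerate)."""


@dataclass(frozen=True)
class Network:
    """Simple undirected co-expression graph over a fixed gene universe.

    ``graph`` holds only the *used* vertices (degree >= 1); ``gene_ids`` is
    the full filtered-gene universe the network was built over, which is the
    denominator of %used.  ``threshold`` records the cut used to build it
    (None for benchmark graphs).
    """

    graph: nx.Graph
    gene_ids: tuple[str, ...]
    threshold: float | None = None

    @property
    def used_vertices(self) -> list:
        return [n for n, d in self.graph.degree() if d >= 1]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def threshold_adjacency(
    am: AssociationMatrix,
    t: float,
    mode: str = "absolute",
) -> Network:
    """Build the simple graph keeping gene pairs whose correlation passes t.

    ``mode="absolute"`` (default) keeps |rho| >= t; ``"positive"`` keeps
    rho >= t only.  Edge weights store the signed correlation.
    """
    if not (0 < t <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if mode not in {"absolute", "positive"}:
        raise ValueError(f"unknown thresholding mode: {mode!r}")
    rho = am.rho
    n = rho.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = rho[iu, ju]
    keep = (np.abs(vals) >= t) if mode == "absolute" else (vals >= t)
    g = nx.Graph()
    ids = am.gene_ids
    for i, j, r in zip(iu[keep], ju[keep], vals[keep]):
        g.add_edge(ids[i], ids[j], weight=float(r))
    return Network(g, tuple(ids), t)


def degree_distribution_fit(net: Network | nx.Graph) -> tuple[float, float]:
    """Least-squares power-law fit of the degree histogram on log-log axes.

    Builds the histogram n(k) over the positive degrees present, regresses
    log10 n(k) on log10 k by OLS and returns ``(slope, r2)``.  A scale-free
    degree distribution n(k) ~ k^-gamma gives a straight line with slope
    -gamma and r2 near 1.  Needs at least two distinct positive degrees.
    """
    g = net.graph if isinstance(net, Network) else net
    degrees = np.array([d for _, d in g.degree() if d >= 1])
    if degrees.size == 0:
        raise DegenerateMetricError("no used vertices; degree fit undefined")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 2:
        raise DegenerateMetricError(
            "fewer than two distinct degrees; degree fit undefined"
        )
    x = np.log10(ks.astype(float))
    y = np.log10(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def mean_clustering(net: Network | nx.Graph) -> float:
    """Mean local clustering coefficient over vertices with degree >= 1.

    Degree-0 vertices are outside the network model; degree-1 vertices have
    no neighbour pair and contribute 0.
    """
    g = net.graph if isinstance(net, Network) else net
    used = [n for n, d in g.degree() if d >= 1]
    if not used:
        raise DegenerateMetricError("empty network; meanCC undefined")
    cc = nx.clustering(g, used)
    return float(np.mean(list(cc.values())))


def _largest_component(g: nx.Graph) -> set:
    comps = list(nx.connected_components(g))
    if not comps:
        return set()
    # deterministic under size ties: break toward the smallest member label
    biggest = max(len(c) for c in comps)
    return min((c for c in comps if len(c) == biggest), key=lambda c: min(map(str, c)))


def mean_path_length(net: Network | nx.Graph) -> float:
    """Mean shortest-path length over connected pairs in the largest component.

    Disconnected pairs have no finite distance, so the average is taken
    within the biggest component only (which holds ~all used vertices at the
    thresholds of interest).
    """
    g = net.graph if isinstance(net, Network) else net
    if g.number_of_edges() == 0:
        raise DegenerateMetricError("no edges; meanPath undefined")
    big = _largest_component(g)
    if len(big) < 2:
        raise DegenerateMetricError("largest component too small; meanPath undefined")
    return float(nx.average_shortest_path_length(g.subgraph(big)))


def coverage_stats(net: Network, total_genes: int | None = None) -> tuple[float, float]:
    """Return (%used, %bigComp).

    %used = 100 × used vertices / gene-universe size;
    %bigComp = 100 × largest-component vertices / used vertices.
    """
    if total_genes is None:
        total_genes = len(net.gene_ids)
    used = len(net.used_vertices)
    if total_genes < used:
        raise ValueError("total_genes smaller than the number of used vertices")
    if used == 0:
        return 0.0, float("nan")
    big = len(_largest_component(net.graph))
    return 100.0 * used / total_genes, 100.0 * big / used


@dataclass(frozen=True)
class ThresholdMetrics:
    """One row of the threshold-refinement table."""

    threshold: float
    r2: float
    slope: float
    mean_cc: float
    mean_path: float
    pct_used: float
    pct_big_comp: float
    n_used: int = 0
    n_edges: int = 0

    @property
    def degenerate(self) -> bool:
        return any(
            math.isnan(v)
            for v in (self.r2, self.slope, self.mean_cc, self.mean_path,
                      self.pct_big_comp)
        )


@dataclass(frozen=True)
class SelectionCriteria:
    """Bounds a candidate network must satisfy to count as scale-free and
    small-world: high power-law fit, moderate clustering, short paths, and
    near-complete coverage of the gene universe."""

    r2_min: float = 0.9
    mean_cc_max: float = 0.5
    mean_path_max: float = 5.0
    pct_used_min: float = 95.0
    pct_big_comp_min: float = 95.0

    def satisfied(self, row: ThresholdMetrics) -> int:
        """Number of the five criteria the row passes (NaN never passes)."""
        checks = (
            row.r2 > self.r2_min,
            row.mean_cc < self.mean_cc_max,
            row.mean_path < self.mean_path_max,
            row.pct_used > self.pct_used_min,
            row.pct_big_comp > self.pct_big_comp_min,
        )
        return sum(bool(c) for c in checks)

    @property
    def n_criteria(self) -> int:
        return 5


@dataclass(frozen=True)
class SelectionResult:
    """Chosen refinement row; ``relaxed`` is True when no row passed every
    criterion and the best-effort row was returned instead."""

    metrics: ThresholdMetrics
    relaxed: bool
    n_satisfied: int


def network_metrics(net: Network, total_genes: int | None = None) -> ThresholdMetrics:
    """Compute the full refinement-table row for one network."""
    nan = float("nan")
    pct_used, pct_big = coverage_stats(net, total_genes)
    try:
        slope, r2 = degree_distribution_fit(net)
    except DegenerateMetricError:
        slope, r2 = nan, nan
    try:
        mean_cc = mean_clustering(net)
    except DegenerateMetricError:
        mean_cc = nan
    try:
        mean_path = mean_path_length(net)
    except DegenerateMetricError:
        mean_path = nan
    return ThresholdMetrics(
        threshold=net.threshold if net.threshold is not None else nan,
        r2=r2,
        slope=slope,
        mean_cc=mean_cc,
        mean_path=mean_path,
        pct_used=pct_used,
        pct_big_comp=pct_big,
        n_used=len(net.used_vertices),
        n_edges=net.n_edges,
    )


def refine_thresholds(
    am: AssociationMatrix,
    thresholds: Sequence[float] | None = None,
    mode: str = "absolute",
) -> list[ThresholdMetrics]:
    """Build one network per threshold and tabulate its topology metrics.

    ``thresholds`` must be strictly increasing in (0, 1]; the default grid is
    the refinement range 0.845–0.862.  Degenerate metrics (e.g. an empty
    network at a very high cut) are reported as NaN sentinels in their row
    rather than aborting the sweep.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLD_GRID
    ts = list(thresholds)
    if any(not (0 < t <= 1) for t in ts):
        raise ValueError("thresholds must lie in (0, 1]")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for t in ts:
        net = threshold_adjacency(am, t, mode=mode)
        rows.append(network_metrics(net))
    return rows


def select_threshold(
    rows: Sequence[ThresholdMetrics],
    crit: SelectionCriteria | None = None,
) -> SelectionResult:
    """Pick the best refinement row under the selection criteria.

    Rows passing all criteria compete on r2 (ties broken toward the larger
    threshold).  If none passes everything, the selection is *relaxed*: the
    row satisfying the most criteria wins (ties: higher r2, then larger
    threshold) and the result is flagged accordingly.
    """
    if not rows:
        raise ValueError("no refinement rows to select from")
    if crit is None:
        crit = SelectionCriteria()
    scored = [(crit.satisfied(row), row) for row in rows]
    full = [(s, row) for s, row in scored if s == crit.n_criteria]
    pool = full if full else scored
    best_score, best_row = max(
        pool,
        key=lambda sr: (
            sr[0],
            -1e18 if math.isnan(sr[1].r2) else sr[1].r2,
            sr[1].threshold,
        ),
    )
    return SelectionResult(best_row, relaxed=not full, n_satisfied=best_score)


_TABLE_COLUMNS = ["threshold", "R2", "slope", "meanCC", "meanPath",
                  "pct_used", "pct_bigComp"]


def metrics_table(rows: Sequence[ThresholdMetrics]) -> pd.DataFrame:
    """Refinement rows as a DataFrame in the canonical column order."""
    return pd.DataFrame(
        [
            {
                "threshold": r.threshold,
                "R2": r.r2,
                "slope": r.slope,
                "meanCC": r.mean_cc,
                "meanPath": r.mean_path,
                "pct_used": r.pct_used,
                "pct_bigComp": r.pct_big_comp,
            }
            for r in rows
        ],
        columns=_TABLE_COLUMNS,
    )


def write_edge_list(net: Network, path) -> None:
    """3-column (gene1, gene2, rho) TSV, suitable for Cytoscape import."""
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\trho\n")
        for u, v, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('weight', float('nan')):.6g}\n")
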