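"""Pearson correlation networks among total oil and individual fatty acids.

Each node is the weekly (replicate-mean) series of either total seed-oil
content or one fatty-acid species; each unordered node pair carries a
Pearson r, a two-tailed p-value (t distribution with n-2 df, the classical
bivariate-correlation test), and an edge class: significant positive,
significant negative, or not significant at the chosen alpha.  Comparing
networks between cultivars highlights germplasm-specific couplings, e.g. a
20:1-total-oil correlation present in one species but absent in another.

No multiple-testing correction is applied by default (each edge is tested
marginally, as in standard bivariate-correlation software); a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .fame_quant import FATimeCourse

__all__ = ["Edge", "CorrelationNetwork", "correlate", "compare_networks"]

logger = logging.getLogger(__name__)

TOTAL_OIL = "total_oil"


@dataclass(frozen=True)
class Edge:
    r: float  # NaN when a series is constant
    p: float
    klass: str  # "positive" | "negative" | "ns"


@dataclass(frozen=True)
class CorrelationNetwork:
    cultivar: str
    nodes: tuple[str, ...]
    edges: dict[frozenset, Edge]
    alpha: float

    def edge(self, a: str, b: str) -> Edge:
        return self.edges[frozenset((a, b))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, e in self.edges.items():
            a, b = sorted(key)
            rows.append({"nodeA": a, "nodeB": b, "r": e.r, "p": e.p, "klass": e.klass})
        return pd.DataFrame(rows).sort_values(["nodeA", "nodeB"]).reset_index(drop=True)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph(cultivar=self.cultivar, alpha=self.alpha)
        g.add_nodes_from(self.nodes)
        for key, e in self.edges.items():
            a, b = sorted(key)
            g.add_edge(a, b, r=float(e.r), p=float(e.p), klass=e.klass)
        nx.write_graphml(g, path)


def correlate(
    tc: FATimeCourse,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> CorrelationNetwork:
    """Correlation network over the weekly series of one cultivar.

    n is the number of sampled weeks (values are replicate means); at least
    three weeks are required for the n-2 df test.  A constant series yields
    klass "ns" with r recorded as NaN for all its edges.
    """
    means = tc.replicate_means()
    if len(means.index) < 3:
        raise InsufficientDataError("correlation needs at least three sampled weeks")
    series = {TOTAL_OIL: means.sum(axis=1).to_numpy()}
    for sp in means.columns:
        series[sp] = means[sp].to_numpy()
    nodes = tuple(series)

    keys, rs, ps = [], [], []
    for a, b in itertools.combinations(nodes, 2):
        x, y = series[a], series[b]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            keys.append(frozenset((a, b)))
            rs.append(math.nan)
            ps.append(1.0)
            continue
        r, p = stats.pearsonr(x, y)
        keys.append(frozenset((a, b)))
        rs.append(float(r))
        ps.append(float(p))

    p_adj = list(ps)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        logger.info("applying Benjamini-Hochberg correction across %d edges", len(ps))
        _, p_adj, _, _ = multipletests(ps, method="fdr_bh")
        p_adj = list(p_adj)

    edges = {}
    for key, r, p in zip(keys, rs, p_adj):
        if math.isnan(r) or p >= alpha:
            klass = "ns"
        else:
            klass = "positive" if r > 0 else "negative"
        edges[key] = Edge(r=r, p=p, klass=klass)
    return CorrelationNetwork(cultivar=tc.cultivar, nodes=nodes, edges=edges, alpha=alpha)


def compare_networks(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork
) -> list[tuple[str, str, str, str]]:
    """Edges whose class differs between two networks on the same node set.

    Returns tuples (nodeA, nodeB, klass in net_a, klass in net_b).
    """
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks must share the same node set")
    diffs = []
    for key, ea in net_a.edges.items():
        eb = net_b.edges[key]
        if ea.klass != eb.klass:
            a, b = sorted(key)
            diffs.append((a, b, ea.klass, eb.klass))
    return sorted(diffs)
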