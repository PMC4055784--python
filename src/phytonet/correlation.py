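"""Phi-coefficient protein co-targeting network.

For every pair of targeted proteins, the binary plant-targeting profiles
form a 2×2 contingency table; the phi coefficient

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))

is the Pearson correlation of the two binary variables, and the associated
test statistic is chi² = n·phi² (1 df, no continuity correction — the
correction would break the identity).  P-values are Bonferroni-adjusted over
the evaluable pairs and edges with adjusted p ≤ alpha are retained,
including significant negative correlations (proteins consistently avoided
together).  Pairs with a degenerate marginal (a protein targeted by all
plants or by none) are not evaluable and do not count toward the
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Collection, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from phytonet.interactome import PlantProteinMatrix


@dataclass(frozen=True)
class PhiEdge:
    protein_a: str
    protein_b: str
    phi: float
    chi2: float
    n: int
    p_value: float
    p_adjusted: float


@dataclass
class PhiNetwork:
    """Significant co-targeting edges over the targeted protein space.

    ``node_sizes`` maps each targeted protein to the number of plants
    targeting it (the node-size attribute of the network view);
    ``n_tested`` is the Bonferroni multiplier (evaluable pairs).
    """

    nodes: list[str]
    node_sizes: dict[str, int]
    edges: list[PhiEdge]
    n_tested: int
    alpha: float
    components: list[set[str]] = field(default_factory=list)
    bridges: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.protein_a, e.protein_b, e.phi, e.chi2, e.p_value,
              e.p_adjusted) for e in self.edges],
            columns=["protein_a", "protein_b", "phi", "chi2", "p",
                     "p_adj"],
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, size=self.node_sizes.get(node, 0))
        for e in self.edges:
            g.add_edge(e.protein_a, e.protein_b, phi=e.phi, chi2=e.chi2,
                       p_adj=e.p_adjusted)
        return g


def phi_coefficient(table: Sequence[float]) -> float:
    """Phi from 2×2 counts (a, b, c, d) laid out row-wise.

    Returns NaN (the undefined marker) when any marginal is zero; raises on
    an all-zero table.
    """
    a, b, c, d = (float(x) for x in table)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return (a * d - b * c) / math.sqrt(denom)


def phi_test(table: Sequence[float]) -> tuple[float, float, float]:
    """(phi, chi², p) for a 2×2 table, chi² = n·phi² with 1 df.

    An undefined phi (zero marginal) propagates as NaN throughout: the pair
    is not evaluable.
    """
    phi = phi_coefficient(table)
    if math.isnan(phi):
        return math.nan, math.nan, math.nan
    n = float(sum(table))
    chi2 = n * phi * phi
    p = float(stats.chi2.sf(chi2, df=1))
    return phi, chi2, p


def build_phi_network(m: PlantProteinMatrix, alpha: float = 0.05
                      ) -> PhiNetwork:
    """Test all unordered pairs of targeted proteins and keep the
    Bonferroni-significant edges.

    n is the number of plants in the matrix (all plants, including those
    with no interactions).  A pair is evaluable when both proteins are
    targeted by at least one and missed by at least one plant.
    """
    inc = m.incidence.to_numpy(dtype=float)
    n_plants = inc.shape[0]
    col_sums = inc.sum(axis=0)
    targeted = col_sums >= 1
    proteins = np.asarray(m.proteins)[targeted]
    if proteins.size < 2:
        raise ValueError("need at least two targeted proteins")
    sub = inc[:, targeted]
    s = col_sums[targeted]
    co = sub.T @ sub  # pairwise co-targeting counts (the table's a)

    nondeg = (s > 0) & (s < n_plants)
    k = proteins.size
    iu, ju = np.triu_indices(k, 1)
    evaluable = nondeg[iu] & nondeg[ju]
    n_tested = int(evaluable.sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        num = n_plants * co[iu, ju] - s[iu] * s[ju]
        den = np.sqrt(s[iu] * (n_plants - s[iu]) * s[ju]
                      * (n_plants - s[ju]))
        phi = np.where(evaluable, num / np.where(den == 0, np.nan, den),
                       np.nan)
    chi2 = n_plants * phi ** 2
    p = stats.chi2.sf(chi2, df=1)
    p_adj = np.minimum(1.0, p * max(n_tested, 1))

    keep = evaluable & (p_adj <= alpha)
    edges = [
        PhiEdge(str(proteins[i]), str(proteins[j]), float(phi[t]),
                float(chi2[t]), int(n_plants), float(p[t]),
                float(p_adj[t]))
        for t, (i, j) in enumerate(zip(iu, ju)) if keep[t]
    ]
    net = PhiNetwork(
        nodes=[str(x) for x in proteins],
        node_sizes={str(x): int(c) for x, c in zip(proteins, s)},
        edges=edges,
        n_tested=n_tested,
        alpha=alpha,
    )
    net.components, net.bridges = components_and_bridges(net)
    return net


def components_and_bridges(net: PhiNetwork | nx.Graph
                           ) -> tuple[list[set[str]], set[str]]:
    """Connected components (by edge adjacency) and articulation nodes —
    proteins whose removal increases the component count."""
    g = net.graph() if isinstance(net, PhiNetwork) else net
    connected = g.subgraph([n for n in g if g.degree(n) > 0])
    components = sorted(
        (set(c) for c in nx.connected_components(connected)),
        key=lambda c: (-len(c), min(c)))
    bridges = set(nx.articulation_points(connected))
    return components, bridges


def intra_cluster_distance(
    proteins: Collection[str],
    ppi_edges: Iterable[tuple[str, str]] | pd.DataFrame,
) -> tuple[float, float, int]:
    """(mean, max, unreachable-pair count) of unweighted shortest-path
    distances between all unordered pairs of ``proteins`` over the PPI
    graph.  Mean and max are over reachable pairs only."""
    members = sorted(set(proteins))
    if len(members) < 2:
        raise ValueError("need at least two proteins")
    g = nx.Graph()
    if isinstance(ppi_edges, pd.DataFrame):
        rows = ppi_edges[["protein_a", "protein_b"]].itertuples(index=False)
    else:
        rows = ((e[0], e[1]) for e in ppi_edges)
    for a, b in rows:
        g.add_edge(a, b)
    dists: list[int] = []
    unreachable = 0
    member_set = set(members)
    for idx, src in enumerate(members):
        if src not in g:
            unreachable += len(members) - idx - 1
            continue
        lengths = nx.single_source_shortest_path_length(g, src)
        for dst in members[idx + 1:]:
            if dst in lengths:
                dists.append(lengths[dst])
            else:
                unreachable += 1
    if not dists:
        return math.nan, math.nan, unreachable
    return float(np.mean(dists)), float(max(dists)), unreachable
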