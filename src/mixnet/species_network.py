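"""Weighted species co-occurrence networks and betweenness ranks.

Species are nodes; an edge of weight w_ij joins species that co-occurred
in w_ij clusters.  Because any edge is possible in this system, the signal
is in the weights, so betweenness is computed on weighted shortest paths
with edge length 1/w_ij: a strong association is a short edge.  A binary
fallback (all edges length 1) is available.  Ranks, not raw scores, are
the comparison currency: rank 1 is the highest score, ties get the
average rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .association_stats import CoOccurrenceCounts, co_occurrence_counts
from .core_data import ClusterRecord, build_occurrence_matrix


@dataclass
class WeightedSpeciesNetwork:
    """Undirected species network; isolated nodes are retained."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def neighbors(self, species_id: str) -> set[str]:
        return set(self.graph.neighbors(species_id))

    def strength(self, species_id: str) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(species_id, data=True)))

    def edge_list_frame(self) -> pd.DataFrame:
        rows = [{"species_i": u, "species_j": v, "weight": w} for u, v, w in self.edges]
        return pd.DataFrame(rows, columns=["species_i", "species_j", "weight"])

    def to_dot(self) -> str:
        """Plain Graphviz export; edge `len` is 1/weight for spring layouts."""
        lines = ["graph species_network {", "  node [shape=circle];"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v, w in self.edges:
            lines.append(f'  "{u}" -- "{v}" [weight={w}, len={1.0 / w:.4f}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def network_from_counts(counts: CoOccurrenceCounts, min_weight: int = 1) -> WeightedSpeciesNetwork:
    g = nx.Graph()
    g.add_nodes_from(counts.species)
    s = counts.species
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            w = int(counts.w[i, j])
            if w >= min_weight and w > 0:
                g.add_edge(s[i], s[j], weight=w, length=1.0 / w)
    return WeightedSpeciesNetwork(g)


def build_network(
    records: list[ClusterRecord],
    species_subset: list[str] | None = None,
    min_weight: int = 1,
) -> WeightedSpeciesNetwork:
    """Network over all species in `species_subset` (or all observed species).

    `min_weight` defaults to 1 for analysis; 2 reproduces the display
    convention of dropping single co-occurrences from figures.
    """
    matrix = build_occurrence_matrix(records, species_subset=species_subset)
    counts = co_occurrence_counts(matrix)
    net = network_from_counts(counts, min_weight=min_weight)
    if species_subset is not None:
        net.graph.add_nodes_from(species_subset)  # keep never-sighted species as isolates
    return net


@dataclass
class BetweennessReport:
    """Per-species betweenness scores and descending average ranks."""

    scores: pd.Series  # index: species
    ranks: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"betweenness": self.scores, "rank": self.ranks}).rename_axis(
            "species"
        )


def betweenness(network: WeightedSpeciesNetwork, weighted: bool = True) -> BetweennessReport:
    """Unnormalized node betweenness; shortest paths use edge length 1/w.

    Equal-length paths split counts equally; unreachable pairs contribute
    nothing.  `weighted=False` treats every edge as length 1.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    bc = nx.betweenness_centrality(
        network.graph, weight="length" if weighted else None, normalized=False
    )
    scores = pd.Series(bc, dtype=float).reindex(network.nodes)
    ranks = pd.Series(
        rankdata(-scores.to_numpy(), method="average"), index=scores.index
    )
    return BetweennessReport(scores=scores, ranks=ranks)


def betweenness_ranks(report: BetweennessReport) -> dict[str, float]:
    """Species -> rank (1 = highest betweenness, ties averaged)."""
    return report.ranks.to_dict()


def rank_scores(scores: dict[str, float] | pd.Series) -> pd.Series:
    """Descending average ranks of arbitrary per-species scores."""
    s = pd.Series(scores, dtype=float)
    return pd.Series(rankdata(-s.to_numpy(), method="average"), index=s.index)
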