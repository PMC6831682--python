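"""Per-trial phonological networks and component-weighted statistics.

The nodes of a trial's network are the unique *correct* productions (tonal
syllables); two nodes share an edge iff their slot-wise edit distance is 1.
The stimulus itself is excluded from the graph for the structural measures
and added back only when hop distances from the stimulus are counted.

Because fluency networks are small and frequently fragmented, the usual
giant-component convention would discard exactly the behaviour of interest
(isolates and islands mark unsuccessful search).  All structural measures
are therefore *component-weighted*: the per-component value is averaged
across components with weights proportional to component size, and isolates
-- or components on which the statistic is undefined -- contribute zero.
E.g. a 10-node network made of a fully clustered 9-node component plus one
isolate has weighted mean clustering 0.9.

Measures:

* ``NC`` -- number of connected components (isolates included); network
  coherence, the quantitative replacement for "number of clusters".
* weighted mean clustering coefficient -- per-node clustering (triangles
  over possible neighbor pairs; 0 for degree < 2), averaged per component,
  then component-weighted.  Under the degree<2 -> 0 convention this equals
  the plain mean of local clustering over all nodes.
* weighted mixing by degree ``M`` -- per-component degree assortativity
  (Pearson correlation of endpoint degrees over edges, each edge in both
  orientations), component-weighted; components whose correlation is
  undefined (isolates, zero degree variance) contribute zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np

from .metric import edit_distance, is_immediate_neighbor
from .scoring import Trial
from .syllables import SegmentedSyllable

__all__ = [
    "FluencyNetwork",
    "build_network",
    "count_components",
    "local_clustering",
    "weighted_mean_clustering",
    "weighted_assortativity",
    "hop_distribution",
    "export_edge_list",
    "export_graphml",
]

#: Histogram key for response nodes unreachable from the stimulus.
DISCONNECTED = "disconnected"


def build_graph(syllables: Iterable[SegmentedSyllable]) -> nx.Graph:
    """Undirected edit-distance-1 graph over unique tonal syllables."""
    unique: Dict[tuple, SegmentedSyllable] = {}
    for s in syllables:
        unique.setdefault(s.slots, s)
    g = nx.Graph()
    nodes = list(unique.values())
    for s in nodes:
        g.add_node(s.slots, syllable=s, label=s.label or str(s))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if is_immediate_neighbor(a, b):
                g.add_edge(a.slots, b.slots)
    return g


def count_components(g: nx.Graph) -> int:
    """NC: number of connected components, isolates included."""
    return nx.number_connected_components(g)


def local_clustering(g: nx.Graph, node) -> float:
    """Proportion of a node's neighbor pairs that are themselves connected.

    Nodes of degree < 2 have no neighbor pairs and score 0, which keeps the
    component-weighted average well-defined.
    """
    return float(nx.clustering(g, node))


def weighted_mean_clustering(g: nx.Graph) -> float:
    """Component-weighted mean clustering coefficient; NaN on an empty graph.

    With per-node clustering set to 0 for degree < 2, the node-count-weighted
    average of per-component means equals the plain mean over all nodes.
    """
    if g.number_of_nodes() == 0:
        return math.nan
    cc = nx.clustering(g)
    return float(sum(cc.values()) / len(cc))


def _component_assortativity(g: nx.Graph, nodes: Sequence) -> float:
    """Degree assortativity of one component; 0 when undefined."""
    sub = g.subgraph(nodes)
    if sub.number_of_edges() == 0:
        return 0.0
    deg = dict(sub.degree())
    # Each edge contributes both orientations so the result is symmetric.
    x = np.array([deg[u] for u, v in sub.edges()] + [deg[v] for u, v in sub.edges()], float)
    y = np.array([deg[v] for u, v in sub.edges()] + [deg[u] for u, v in sub.edges()], float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0  # zero degree variance: correlation undefined, treated as isolates are
    r = np.corrcoef(x, y)[0, 1]
    return float(r) if np.isfinite(r) else 0.0


def weighted_assortativity(g: nx.Graph) -> float:
    """Component-weighted mixing by degree in [-1, 1]; NaN on an empty graph."""
    n = g.number_of_nodes()
    if n == 0:
        return math.nan
    total = 0.0
    for comp in nx.connected_components(g):
        total += len(comp) * _component_assortativity(g, list(comp))
    return float(total / n)


def hop_distribution(g: nx.Graph, stimulus: SegmentedSyllable) -> Dict[object, int]:
    """Histogram of shortest-path hops from the stimulus to each response node.

    The stimulus is added to a copy of the graph together with its edit-1
    edges to response nodes; responses unreachable from it are binned under
    ``"disconnected"``.  A response identical to the stimulus (hop 0) is
    not counted.
    """
    aug = g.copy()
    skey = ("#stimulus#", stimulus.slots)
    aug.add_node(skey, syllable=stimulus, label=stimulus.label or str(stimulus))
    for node, data in g.nodes(data=True):
        if edit_distance(stimulus, data["syllable"]) == 1:
            aug.add_edge(skey, node)
    lengths = nx.single_source_shortest_path_length(aug, skey)
    hist: Dict[object, int] = {}
    for node in g.nodes():
        if node == stimulus.slots:
            continue
        hop = lengths.get(node)
        key = hop if hop is not None else DISCONNECTED
        hist[key] = hist.get(key, 0) + 1
    return hist


@dataclass
class FluencyNetwork:
    """A trial's network together with its component-weighted statistics."""

    graph: nx.Graph
    stimulus: SegmentedSyllable
    NC: Optional[int]
    CC: float  # weighted mean clustering; NaN for an empty network
    M: float  # weighted mixing by degree; NaN for an empty network
    hops: Dict[object, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def hop_count(self, hop: int) -> int:
        return self.hops.get(hop, 0)

    @property
    def n_disconnected(self) -> int:
        return self.hops.get(DISCONNECTED, 0)


def build_network(trial: Trial, include_stimulus: bool = False) -> FluencyNetwork:
    """Build the edit-1 network over a trial's unique correct productions.

    ``include_stimulus=True`` adds the stimulus as a node for the structural
    measures as well (the alternative reading of the published figures);
    the default keeps it out and uses it only for hop counting.
    """
    if not trial.is_classified:
        raise ValueError("trial must be classified before building its network")
    correct = [p.syllable for p in trial.productions if p.is_correct]
    if include_stimulus:
        g = build_graph([trial.stimulus] + correct)
    else:
        g = build_graph(correct)
    if g.number_of_nodes() == 0:
        return FluencyNetwork(g, trial.stimulus, None, math.nan, math.nan, {})
    return FluencyNetwork(
        graph=g,
        stimulus=trial.stimulus,
        NC=count_components(g),
        CC=weighted_mean_clustering(g),
        M=weighted_assortativity(g),
        hops=hop_distribution(g, trial.stimulus),
    )


def _decorated(net: FluencyNetwork) -> nx.Graph:
    g = net.graph.copy()
    cc = nx.clustering(g)
    skey = ("#stimulus#", net.stimulus.slots)
    aug = net.graph.copy()
    aug.add_node(skey)
    for node, data in net.graph.nodes(data=True):
        if edit_distance(net.stimulus, data["syllable"]) == 1:
            aug.add_edge(skey, node)
    lengths = nx.single_source_shortest_path_length(aug, skey)
    for node, data in g.nodes(data=True):
        data["pinyin"] = data.pop("label")
        data["degree"] = g.degree(node)
        data["local_cc"] = float(cc[node])
        hop = lengths.get(node)
        data["hop"] = int(hop) if hop is not None else -1  # -1: disconnected from stimulus
        del data["syllable"]
    return g


def export_edge_list(net: FluencyNetwork, path: str | Path) -> None:
    """Write the network as a two-column TSV of pinyin labels."""
    labels = nx.get_node_attributes(net.graph, "label")
    lines = [f"{labels[u]}\t{labels[v]}" for u, v in sorted(net.graph.edges())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def export_graphml(net: FluencyNetwork, path: str | Path) -> None:
    """Write the network as GraphML with pinyin, hop, degree and local CC."""
    g = _decorated(net)
    out = nx.relabel_nodes(g, nx.get_node_attributes(g, "pinyin"))
    nx.write_graphml(out, str(path))
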