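"""Clock / oviposition connectome connectivity analysis.

Works on neuPrint-style connection tables (one row per directed neuron
pair with the summed synapse count between them, hemibrain v1.2.1
dialect). Connection strength classes follow the hemibrain convention:
0-2 synapses weak, 3-9 intermediate, >9 strong; weak connections are
reconstruction-error prone and are excluded from all aggregate analyses.

Neurons are grouped into clusters by a :class:`ClusterMap`. The default
map covers the 28 identified clock neurons -- with the six LNd cells and
the 5th s-LNv resolved into the evening-cell subgroups E1 = {LNd4, LNd5}
(Cry+), E2 = {LNd6, 5th-sLNv} (Cry+), E3 = {LNd1-3} (Cry-), and LPN-4
renamed LPN-L to mark its left-hemisphere position -- and the 25
identified oviposition-circuit neurons (oviDN, oviEN, oviIN, pC1a-e, U,
G groups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .records import RecordError
from .simulate import ParameterError

__all__ = [
    "SynapseEdge", "ClusterMap", "ConnectivityReport", "classify_strength",
    "bipartite_connectivity", "bidirectionality", "export_network",
    "read_network", "generate_connectome_fixture", "default_cluster_map",
    "read_edges", "write_edges", "CLOCK_CLUSTERS", "OVI_CLUSTERS",
]

STRENGTH_ORDER = {"weak": 0, "intermediate": 1, "strong": 2}
EDGE_CSV_HEADER = ["bodyId_pre", "instance_pre", "bodyId_post", "instance_post", "weight"]


def classify_strength(weight: int) -> str:
    """Strength class of a summed synapse count: <=2 weak, 3-9 intermediate, >9 strong."""
    w = int(weight)
    if w != weight or w < 0:
        raise RecordError(f"synapse count must be a non-negative integer, got {weight!r}")
    if w <= 2:
        return "weak"
    if w <= 9:
        return "intermediate"
    return "strong"


@dataclass(frozen=True)
class SynapseEdge:
    """One directed neuron-pair connection with its summed synapse count."""

    pre_id: int
    pre_name: str
    post_id: int
    post_name: str
    weight: int

    def __post_init__(self):
        classify_strength(self.weight)  # validates

    @property
    def strength(self) -> str:
        return classify_strength(self.weight)


# --- cluster membership -------------------------------------------------

CLOCK_CLUSTERS = {
    "sLNv": [f"s-LNv_{i}" for i in range(1, 5)],
    "lLNv": [f"l-LNv_{i}" for i in range(1, 5)],
    "E1": ["LNd4", "LNd5"],
    "E2": ["LNd6", "5th-sLNv"],
    "E3": ["LNd1", "LNd2", "LNd3"],
    "LPN": ["LPN-1", "LPN-2", "LPN-3", "LPN-L"],
    "DN1a": ["DN1a_1", "DN1a_2"],
    "DN1p": [f"DN1p_{i}" for i in range(1, 8)],
}

OVI_CLUSTERS = {
    "oviDN": [f"oviDN_{i}" for i in range(1, 9)],
    "oviEN": ["oviEN-R", "oviEN-L"],
    "oviIN": ["oviIN-R", "oviIN-L"],
    "pC1a": ["pC1a"],
    "pC1b": ["pC1b-R", "pC1b-L"],
    "pC1c": ["pC1c"],
    "pC1d": ["pC1d"],
    "pC1e": ["pC1e"],
    "U": ["U_1", "U_2"],
    "G": [f"G_{i}" for i in range(1, 6)],
}


@dataclass(frozen=True)
class ClusterMap:
    """Mapping from neuron instance names to cluster names."""

    neuron_to_cluster: dict

    def cluster_of(self, name: str):
        return self.neuron_to_cluster.get(name)

    def members(self, cluster: str) -> list:
        return [n for n, c in self.neuron_to_cluster.items() if c == cluster]

    @property
    def clusters(self) -> set:
        return set(self.neuron_to_cluster.values())


def default_cluster_map() -> ClusterMap:
    mapping = {}
    for table in (CLOCK_CLUSTERS, OVI_CLUSTERS):
        for cluster, members in table.items():
            for name in members:
                mapping[name] = cluster
    return ClusterMap(neuron_to_cluster=mapping)


def _body_ids(cmap: ClusterMap) -> dict:
    """Deterministic synthetic body ids for fixture neurons."""
    return {name: 900_000_000 + i
            for i, name in enumerate(sorted(cmap.neuron_to_cluster))}


# --- fixture generation -------------------------------------------------

def example_clock_ovi_spec() -> dict:
    """Cluster-level topology of the known clock/oviposition contacts.

    E1 and oviIN are bidirectionally connected (stronger from clock to
    oviposition side); E3 contacts only pC1b, bidirectionally; E2 makes
    no oviposition contacts; oviIN and LPN are bidirectionally connected
    with far more oviIN->LPN input (total 135 synapses) than LPN->oviIN
    output (16). Integer values are exact directed totals to realize;
    strings are strength classes.
    """
    return {
        ("E1", "oviIN"): "strong",
        ("oviIN", "E1"): "intermediate",
        ("E3", "pC1b"): "intermediate",
        ("pC1b", "E3"): "intermediate",
        ("oviIN", "LPN"): 135,
        ("LPN", "oviIN"): 16,
    }




_CLASS_WEIGHT_RANGE = {"weak": (1, 2), "intermediate": (3, 9), "strong": (10, 40)}


def generate_connectome_fixture(spec: dict, seed: int = 0,
                                cmap: ClusterMap | None = None) -> list:
    """Edge list realizing a cluster-level connectivity specification.

    ``spec`` maps directed cluster pairs ``(pre_cluster, post_cluster)``
    to either a strength-class name (``weak`` / ``intermediate`` /
    ``strong``; per neuron-pair weights drawn in the class range) or an
    integer total weight to split across the member neuron pairs. The
    output follows neuPrint connection-table semantics: one edge per
    directed neuron pair with the summed synapse count.
    """
    cmap = cmap or default_cluster_map()
    ids = _body_ids(cmap)
    rng = np.random.default_rng(seed)
    edges = []
    for (pre_c, post_c), want in sorted(spec.items(), key=lambda kv: kv[0]):
        pres, posts = sorted(cmap.members(pre_c)), sorted(cmap.members(post_c))
        if not pres or not posts:
            raise ParameterError(f"unknown cluster in pair {(pre_c, post_c)}")
        pairs = [(a, b) for a in pres for b in posts if a != b]
        if isinstance(want, str):
            if want not in _CLASS_WEIGHT_RANGE:
                raise ParameterError(f"unknown strength class {want!r}")
            lo, hi = _CLASS_WEIGHT_RANGE[want]
            weights = rng.integers(lo, hi + 1, size=len(pairs))
        else:
            total = int(want)
            if total < 0:
                raise ParameterError(f"total weight must be >= 0, got {want!r}")
            # split the requested total across pairs, at least 3 per used
            # pair so no share is discarded as weak
            weights = np.zeros(len(pairs), dtype=int)
            remaining = total
            for i in range(len(pairs)):
                if remaining <= 0:
                    break
                last = i == len(pairs) - 1
                take = remaining if last or remaining < 6 else int(
                    rng.integers(3, max(4, remaining - 3 * (len(pairs) - 1 - i))))
                weights[i] = take
                remaining -= take
        for (a, b), w in zip(pairs, weights):
            if w > 0:
                edges.append(SynapseEdge(pre_id=ids[a], pre_name=a,
                                         post_id=ids[b], post_name=b, weight=int(w)))
    return edges


def write_edges(edges, path) -> None:
    """Write an edge list in the neuPrint connection-table CSV dialect."""
    rows = [(e.pre_id, e.pre_name, e.post_id, e.post_name, e.weight) for e in edges]
    pd.DataFrame(rows, columns=EDGE_CSV_HEADER).to_csv(path, index=False)


def read_edges(path) -> list:
    df = pd.read_csv(path)
    missing = set(EDGE_CSV_HEADER) - set(df.columns)
    if missing:
        raise RecordError(f"edge CSV missing columns: {sorted(missing)}")
    return [SynapseEdge(pre_id=int(r.bodyId_pre), pre_name=str(r.instance_pre),
                        post_id=int(r.bodyId_post), post_name=str(r.instance_post),
                        weight=int(r.weight))
            for r in df.itertuples()]


# --- bipartite connectivity ---------------------------------------------

@dataclass(frozen=True)
class ConnectivityReport:
    """Cluster-level summary of retained (non-weak) directed connections."""

    pair_totals: dict                 # (pre_cluster, post_cluster) -> summed weight
    pair_edges: dict                  # same keys -> tuple of SynapseEdge
    unresolved: tuple = ()
    min_class: str = "intermediate"

    def total(self, pre_cluster: str, post_cluster: str) -> int:
        return self.pair_totals.get((pre_cluster, post_cluster), 0)

    def neurons(self) -> set:
        out = set()
        for edges in self.pair_edges.values():
            for e in edges:
                out.add(e.pre_name)
                out.add(e.post_name)
        return out

    def __eq__(self, other):
        if not isinstance(other, ConnectivityReport):
            return NotImplemented
        return (self.pair_totals == other.pair_totals
                and {k: tuple(sorted(v, key=lambda e: (e.pre_name, e.post_name)))
                     for k, v in self.pair_edges.items()}
                == {k: tuple(sorted(v, key=lambda e: (e.pre_name, e.post_name)))
                    for k, v in other.pair_edges.items()})


def bipartite_connectivity(edges, cmap: ClusterMap, side_a, side_b,
                           min_class: str = "intermediate") -> ConnectivityReport:
    """Cluster-pair totals of edges crossing between two cluster sets.

    Retains edges whose strength class is at least ``min_class`` and
    whose endpoints fall on opposite sides (either direction). Edges
    whose endpoint names do not resolve through ``cmap`` are collected in
    ``unresolved`` and excluded.
    """
    side_a, side_b = set(side_a), set(side_b)
    if not side_a or not side_b:
        raise ParameterError("cluster sets must be non-empty")
    if min_class not in STRENGTH_ORDER:
        raise ParameterError(f"unknown strength class {min_class!r}")
    min_rank = STRENGTH_ORDER[min_class]
    totals, lists, unresolved = {}, {}, []
    for e in edges:
        pre_c, post_c = cmap.cluster_of(e.pre_name), cmap.cluster_of(e.post_name)
        if pre_c is None or post_c is None:
            unresolved.extend(n for n, c in ((e.pre_name, pre_c), (e.post_name, post_c))
                              if c is None)
            continue
        if STRENGTH_ORDER[e.strength] < min_rank:
            continue
        crosses = (pre_c in side_a and post_c in side_b) or \
                  (pre_c in side_b and post_c in side_a)
        if not crosses:
            continue
        key = (pre_c, post_c)
        totals[key] = totals.get(key, 0) + e.weight
        lists.setdefault(key, []).append(e)
    return ConnectivityReport(
        pair_totals=totals,
        pair_edges={k: tuple(v) for k, v in lists.items()},
        unresolved=tuple(sorted(set(unresolved))),
        min_class=min_class,
    )


def bidirectionality(report: ConnectivityReport, pair):
    """Directional totals for a cluster pair and the dominant direction.

    Returns ``(weight_ab, weight_ba, dominant)`` where dominant is
    ``"a->b"``-style, ``"balanced"`` for a tie, or ``"none"`` when the
    pair carries no retained connections at all.
    """
    a, b = pair
    w_ab, w_ba = report.total(a, b), report.total(b, a)
    if w_ab == 0 and w_ba == 0:
        dominant = "none"
    elif w_ab == w_ba:
        dominant = "balanced"
    else:
        dominant = f"{a}->{b}" if w_ab > w_ba else f"{b}->{a}"
    return w_ab, w_ba, dominant


# --- network export -----------------------------------------------------

def _report_graph(report: ConnectivityReport, cmap: ClusterMap | None = None) -> nx.DiGraph:
    cmap = cmap or default_cluster_map()
    g = nx.DiGraph()
    for edges in report.pair_edges.values():
        for e in edges:
            for name, bid in ((e.pre_name, e.pre_id), (e.post_name, e.post_id)):
                g.add_node(name, body_id=int(bid),
                           cluster=cmap.cluster_of(name) or "")
            g.add_edge(e.pre_name, e.post_name, weight=int(e.weight),
                       strength=e.strength)
    g.graph["min_class"] = report.min_class
    return g


def export_network(report: ConnectivityReport, path, fmt: str = "graphml",
                   cmap: ClusterMap | None = None) -> None:
    """Write the retained network as GraphML, node-link JSON, or DOT.

    Nodes carry their cluster and body id; edges carry the synapse count
    and strength class. GraphML and JSON round-trip through
    :func:`read_network`; DOT is write-only (for Graphviz rendering).
    """
    g = _report_graph(report, cmap)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(nx.node_link_data(g, edges="edges"), fh, indent=1)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph connectivity {\n")
            for n, d in g.nodes(data=True):
                fh.write(f'  "{n}" [cluster="{d["cluster"]}"];\n')
            for u, v, d in g.edges(data=True):
                fh.write(f'  "{u}" -> "{v}" [label="{d["weight"]}", '
                         f'strength="{d["strength"]}"];\n')
            fh.write("}\n")
    else:
        raise ParameterError(f"unknown export format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> ConnectivityReport:
    """Rebuild a :class:`ConnectivityReport` from an exported network."""
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "json":
        with open(path) as fh:
            g = nx.node_link_graph(json.load(fh), directed=True, edges="edges")
    else:
        raise ParameterError(f"unknown import format {fmt!r}")
    min_class = g.graph.get("min_class", "intermediate")
    totals, lists = {}, {}
    for u, v, d in g.edges(data=True):
        pre_c = g.nodes[u].get("cluster", "")
        post_c = g.nodes[v].get("cluster", "")
        edge = SynapseEdge(pre_id=int(g.nodes[u]["body_id"]), pre_name=str(u),
                           post_id=int(g.nodes[v]["body_id"]), post_name=str(v),
                           weight=int(d["weight"]))
        key = (pre_c, post_c)
        totals[key] = totals.get(key, 0) + edge.weight
        lists.setdefault(key, []).append(edge)
    return ConnectivityReport(pair_totals=totals,
                              pair_edges={k: tuple(v) for k, v in lists.items()},
                              min_class=min_class)
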