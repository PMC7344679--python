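"""Bipartite sensory-attribute / molecular-feature association networks.

An edge links an attribute to a feature when the feature's VIP coefficient
in that attribute's sparse PLS model is strictly greater than a threshold
(default 1.0, the conventional "above average importance" cut); the edge
weight is the VIP itself, so heavier edges mean stronger associations.
A zero threshold (every positive VIP draws an edge) is also supported.

Aroma and taste attributes are usually assembled into separate networks;
:func:`split_networks` does this from one VIP dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .attributes import AROMA_ATTRIBUTES, TASTE_ATTRIBUTES


class NetworkError(ValueError):
    pass


@dataclass
class BiomarkerNetwork:
    """Bipartite graph: attribute nodes (kind="attribute") and feature
    nodes (kind="feature", with mz/rt/annotation when available)."""

    graph: nx.Graph
    threshold: float

    @property
    def attribute_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "attribute")

    @property
    def feature_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "feature")

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            if self.graph.nodes[u].get("kind") != "attribute":
                u, v = v, u
            out.append((u, v, float(d["weight"])))
        return sorted(out)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    vip_by_attribute: dict[str, pd.Series],
    threshold: float = 1.0,
    feature_info: pd.DataFrame | None = None,
) -> BiomarkerNetwork:
    """Build the bipartite network from per-attribute VIP vectors.

    All VIP vectors must be indexed by the same feature universe. Feature
    nodes appear only when incident to at least one edge; attribute nodes
    are always kept, flagged ``no_biomarkers=True`` when nothing passes
    the threshold. ``feature_info`` (indexed by feature id, optional
    columns mz/rt/annotation) decorates feature nodes.
    """
    if not vip_by_attribute:
        raise NetworkError("no VIP vectors supplied")
    universes = [tuple(v.index) for v in vip_by_attribute.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise NetworkError("VIP vectors are defined over different feature universes")

    g = nx.Graph(threshold=float(threshold))
    for attr, vips in vip_by_attribute.items():
        hits = vips[vips > threshold]
        g.add_node(attr, kind="attribute", no_biomarkers=bool(hits.empty))
        for fid, vip in hits.items():
            fid = str(fid)
            if fid not in g:
                node_attrs = {"kind": "feature"}
                if feature_info is not None and fid in feature_info.index:
                    row = feature_info.loc[fid]
                    for col in ("mz", "rt", "annotation"):
                        if col in feature_info.columns and not pd.isna(row[col]):
                            node_attrs[col] = row[col]
                g.add_node(fid, **node_attrs)
            g.add_edge(attr, fid, weight=float(vip))
    return BiomarkerNetwork(graph=g, threshold=float(threshold))


def split_networks(
    vip_by_attribute: dict[str, pd.Series],
    threshold: float = 1.0,
    feature_info: pd.DataFrame | None = None,
) -> dict[str, BiomarkerNetwork]:
    """Separate aroma and taste networks from one VIP dictionary."""
    out = {}
    for name, group in (("aroma", AROMA_ATTRIBUTES), ("taste", TASTE_ATTRIBUTES)):
        sub = {a: v for a, v in vip_by_attribute.items() if a in group}
        if sub:
            out[name] = build_network(sub, threshold=threshold, feature_info=feature_info)
    return out


def network_summary(net: BiomarkerNetwork) -> dict:
    """Topology summary: node/edge counts, per-attribute degree (edges per
    attribute), connected components, and features shared by >= 2
    attributes (with per-pair shared counts)."""
    g = net.graph
    attrs = net.attribute_nodes
    feats = net.feature_nodes
    degree = {a: g.degree(a) for a in attrs}
    shared = [f for f in feats if g.degree(f) >= 2]
    pair_shared: dict[str, int] = {}
    for f in shared:
        nbrs = sorted(g.neighbors(f))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                key = f"{nbrs[i]}|{nbrs[j]}"
                pair_shared[key] = pair_shared.get(key, 0) + 1
    n_edges = g.number_of_edges()
    return {
        "n_attribute_nodes": len(attrs),
        "n_feature_nodes": len(feats),
        "n_edges": n_edges,
        "degree_per_attribute": degree,
        "edges_per_attribute": n_edges / len(attrs) if attrs else 0.0,
        "n_connected_components": nx.number_connected_components(g) if len(g) else 0,
        "n_shared_features": len(shared),
        "shared_features_per_attribute_pair": pair_shared,
    }
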