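"""DC-annotated interactome networks and between-state comparison.

A network is the PPI reference restricted to the proteins detected in one
cellular state; detected proteins without any detected interaction partner
are kept as degree-0 nodes. Node attributes carry the DC statistics used
for styling in external viewers: ``neg_log10_p`` (node size),
``fold_change`` (node colour) and ``grey`` (DC.p > 0.1, or the protein is
absent from the DC table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .ppi import PPIReference

log = logging.getLogger(__name__)

__all__ = ["build_network", "diff_networks", "NetworkDiff"]


def build_network(
    detected: set[str],
    ppi: PPIReference,
    dc: pd.DataFrame | None = None,
    dc_alpha: float = 0.1,
) -> nx.Graph:
    """Induced PPI subgraph over the detected proteins, DC-annotated.

    Proteins absent from the DC table get neutral attributes
    (neg_log10_p=0, fold_change=1) and are flagged grey.
    """
    if not detected:
        raise ValueError("detected protein set is empty")
    g = nx.Graph()
    if dc is not None:
        in_dc = dc.index.isin(detected)
        stats = dc.loc[in_dc, ["neg_log10_p", "fold_change", "p_value"]]
    else:
        stats = pd.DataFrame(columns=["neg_log10_p", "fold_change", "p_value"])
    for protein in sorted(detected):
        if protein in stats.index:
            row = stats.loc[protein]
            g.add_node(
                protein,
                neg_log10_p=float(row["neg_log10_p"]),
                fold_change=float(row["fold_change"]),
                grey=bool(row["p_value"] > dc_alpha),
            )
        else:
            g.add_node(protein, neg_log10_p=0.0, fold_change=1.0, grey=True)
    for a, b in ppi.interactions:
        if a in g and b in g:
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        log.warning("network has no edges (no reference PPI between detected proteins)")
    return g


def _canonical_edges(g: nx.Graph) -> set[tuple[str, str]]:
    return {(a, b) if a <= b else (b, a) for a, b in g.edges()}


@dataclass
class NetworkDiff:
    """Shared/unique nodes and edges between two state networks.

    ``pct_nodes_affected`` / ``pct_edges_affected`` are
    100 * (|only_a| + |only_b|) / |union| by default; with
    ``denominator="baseline"`` the denominator is |a| instead (network ``a``
    taken as the baseline state).
    """

    nodes_shared: set[str]
    nodes_only_a: set[str]
    nodes_only_b: set[str]
    edges_shared: set[tuple[str, str]]
    edges_only_a: set[tuple[str, str]]
    edges_only_b: set[tuple[str, str]]
    denominator: str = "union"

    def _pct(self, shared: set, only_a: set, only_b: set) -> float:
        changed = len(only_a) + len(only_b)
        if self.denominator == "union":
            denom = len(shared) + changed
        elif self.denominator == "baseline":
            denom = len(shared) + len(only_a)
        else:
            raise ValueError(f"unknown denominator mode {self.denominator!r}")
        return 100.0 * changed / denom if denom else 0.0

    @property
    def pct_nodes_affected(self) -> float:
        return self._pct(self.nodes_shared, self.nodes_only_a, self.nodes_only_b)

    @property
    def pct_edges_affected(self) -> float:
        return self._pct(self.edges_shared, self.edges_only_a, self.edges_only_b)

    def summary(self) -> dict:
        return {
            "nodes_shared": len(self.nodes_shared),
            "nodes_only_a": len(self.nodes_only_a),
            "nodes_only_b": len(self.nodes_only_b),
            "edges_shared": len(self.edges_shared),
            "edges_only_a": len(self.edges_only_a),
            "edges_only_b": len(self.edges_only_b),
            "pct_nodes_affected": self.pct_nodes_affected,
            "pct_edges_affected": self.pct_edges_affected,
        }


def diff_networks(a: nx.Graph, b: nx.Graph, denominator: str = "union") -> NetworkDiff:
    """Set algebra over the node and edge sets of two state networks."""
    na, nb = set(a.nodes()), set(b.nodes())
    ea, eb = _canonical_edges(a), _canonical_edges(b)
    return NetworkDiff(
        nodes_shared=na & nb,
        nodes_only_a=na - nb,
        nodes_only_b=nb - na,
        edges_shared=ea & eb,
        edges_only_a=ea - eb,
        edges_only_b=eb - ea,
        denominator=denominator,
    )
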