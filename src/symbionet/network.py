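"""Co-occurrence network construction, module detection and node statistics.

An edge joins two OTUs when their basis correlation is robust
(|rho| above the threshold, 0.6 by default) and significant (permutation
pseudo-p below alpha, 0.05 two-sided).  Modules are Louvain modularity
classes on the filtered graph; downstream partner inference restricts
attention to the focal OTU's module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class CorrelationNetwork:
    graph: nx.Graph                      # nodes = OTU ids; edge attrs rho, p
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    rho_threshold: float
    alpha: float
    modules: dict[str, int] = field(default_factory=dict)
    modularity_q: float = 0.0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, d) for u, v, d in self.graph.edges(data=True)]

    def neighbors(self, otu: str) -> list[str]:
        return list(self.graph.neighbors(otu))


def build_network(
    rho: pd.DataFrame,
    pvalues: pd.DataFrame,
    rho_threshold: float = 0.6,
    alpha: float = 0.05,
    inclusive: bool = False,
    taxonomy: dict[str, tuple[str, ...]] | None = None,
) -> CorrelationNetwork:
    """Filter the correlation matrix into an undirected weighted graph.

    ``inclusive`` switches the magnitude rule from strict ``|rho| >`` to
    ``|rho| >=`` (both conventions circulate for the 0.6 cutoff; strict is
    the default).  Edge weight is the signed rho; ``abs_rho`` is stored for
    modularity, which needs non-negative weights.
    """
    if list(rho.index) != list(pvalues.index) or list(rho.columns) != list(pvalues.columns):
        raise ValueError("rho and p matrices must share index and columns")
    g = nx.Graph()
    ids = list(rho.index)
    for otu in ids:
        attrs = {}
        if taxonomy and otu in taxonomy:
            attrs["taxonomy"] = ";".join(taxonomy[otu])
        g.add_node(otu, **attrs)
    r = rho.to_numpy()
    p = pvalues.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            mag = abs(r[i, j])
            passes_rho = mag >= rho_threshold if inclusive else mag > rho_threshold
            if passes_rho and p[i, j] < alpha:
                g.add_edge(
                    ids[i], ids[j],
                    rho=float(r[i, j]), p=float(p[i, j]), abs_rho=float(mag),
                )
    return CorrelationNetwork(g, rho, pvalues, rho_threshold, alpha)


def detect_modules(network: CorrelationNetwork, seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain modularity classes (resolution 1.0) on |rho|-weighted edges.

    Node order is fixed by sorting ids before the seeded run, so a given
    (network, seed) always yields the same partition.  An edgeless network
    yields the empty partition with Q = 0.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        network.modules = {}
        network.modularity_q = 0.0
        return {}, 0.0
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_weighted_edges_from(
        sorted((u, v, d["abs_rho"]) for u, v, d in g.edges(data=True)), weight="weight"
    )
    communities = nx.community.louvain_communities(h, weight="weight", resolution=1.0, seed=seed)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    modules = {node: k for k, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(h, [set(c) for c in communities], weight="weight")
    network.modules = modules
    network.modularity_q = float(q)
    for node, m in modules.items():
        network.graph.nodes[node]["module"] = m
    return modules, float(q)


def network_stats(network: CorrelationNetwork) -> dict:
    """Per-node degree / weighted degree / clustering and global counts."""
    g = network.graph
    degree = dict(g.degree())
    wdegree = dict(g.degree(weight="abs_rho"))
    clustering = nx.clustering(g)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_modules": len(set(network.modules.values())) if network.modules else 0,
        "modularity_q": network.modularity_q,
        "degree": degree,
        "weighted_degree": {k: float(v) for k, v in wdegree.items()},
        "clustering": {k: float(v) for k, v in clustering.items()},
    }


def write_network(network: CorrelationNetwork, outdir: str | Path) -> dict[str, Path]:
    """Edge list TSV, rho/p matrices TSV and GraphML with node attributes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "network_edges.tsv",
        "rho": outdir / "rho.tsv",
        "pvalues": outdir / "pseudo_p.tsv",
        "graphml": outdir / "network.graphml",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("source\ttarget\trho\tp\tmodule_source\tmodule_target\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{d['rho']:.4f}\t{d['p']:.4f}"
                f"\t{network.modules.get(u, '')}\t{network.modules.get(v, '')}\n"
            )
    network.rho.to_csv(paths["rho"], sep="\t")
    network.pvalues.to_csv(paths["pvalues"], sep="\t")
    g = network.graph.copy()
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    nx.write_graphml(g, paths["graphml"])
    return paths
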