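"""Integration of network and recent-HGT evidence into ranked partner hypotheses.

The symbiont (focal OTU) cannot be cultured, so its host is inferred from
two independent evidence lines: a robust co-occurrence edge (the organisms
rise and fall together across samples) and a recent gene transfer (their
genomes were physically close long enough to exchange DNA).  Candidates
carrying both lines outrank any single-line candidate; within a tier the
ranking follows (number of recent-transfer pairs, |rho|, best pair
identity), with OTU id as the final deterministic tie-break.  The ranking is
deliberately lexicographic — fusing the two evidence lines into one score
would assert a weighting the underlying data cannot justify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr

from .hgt import RecentHgtPair
from .markers import OtuTable
from .network import CorrelationNetwork


@dataclass
class PartnerHypothesis:
    focal_otu: str
    candidate_otu: str
    rho: float | None
    pseudo_p: float | None
    shared_module: bool
    n_recent_hgt_pairs: int
    best_pair_identity: float | None
    best_pair_aligned_aa: int | None
    pearson_r: float | None
    r_squared: float | None
    n_co_observed_samples: int | None
    abundance_rank: int | None
    rank: int = 0

    @property
    def has_network_evidence(self) -> bool:
        return self.rho is not None

    @property
    def has_hgt_evidence(self) -> bool:
        return self.n_recent_hgt_pairs > 0

    @property
    def dual_evidence(self) -> bool:
        return self.has_network_evidence and self.has_hgt_evidence


def extract_focal_module(network: CorrelationNetwork, focal_otu: str) -> CorrelationNetwork:
    """The focal OTU's module restricted to its direct neighbours.

    Returns a copy of the network whose graph holds the focal OTU, its
    same-module direct neighbours, and the connecting edges.  An isolated
    focal OTU yields a single-node subnetwork.
    """
    if focal_otu not in network.graph:
        raise KeyError(f"focal OTU {focal_otu!r} not in network")
    if not network.modules:
        raise ValueError("run detect_modules before extracting the focal module")
    focal_mod = network.modules[focal_otu]
    keep = [focal_otu] + [
        n
        for n in network.graph.neighbors(focal_otu)
        if network.modules.get(n) == focal_mod
    ]
    sub = network.graph.subgraph(keep).copy()
    # only edges incident to the focal OTU are the subnetwork's subject
    sub.remove_edges_from([(u, v) for u, v in sub.edges if focal_otu not in (u, v)])
    out = CorrelationNetwork(
        sub, network.rho, network.pvalues, network.rho_threshold, network.alpha,
        {n: network.modules[n] for n in keep}, network.modularity_q,
    )
    return out


def depth_correlation(
    otu_table: OtuTable,
    otu_a: str,
    otu_b: str,
    mode: str = "co_observed",
) -> tuple[float, float, int]:
    """Pearson correlation of two OTUs' depths; returns (r, r^2, n used).

    ``co_observed`` restricts to samples where both depths are positive —
    the convention for sparse tables where joint absence says nothing about
    joint dynamics; ``all`` uses every sample.
    """
    if mode not in ("co_observed", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    a = otu_table.depth.loc[otu_a]
    b = otu_table.depth.loc[otu_b]
    if mode == "co_observed":
        mask = (a > 0) & (b > 0)
        a, b = a[mask], b[mask]
    n = len(a)
    if n < 3:
        raise ValueError(f"only {n} usable samples for {otu_a} vs {otu_b}; need >= 3")
    r = float(pearsonr(a, b).statistic)
    return r, r * r, n


def rank_partners(
    network: CorrelationNetwork,
    recent_pairs: Sequence[RecentHgtPair],
    otu_table: OtuTable,
    focal_otu: str,
    genome_to_otu: dict[str, str | None],
    correlation_mode: str = "co_observed",
) -> list[PartnerHypothesis]:
    """Rank candidate partner OTUs of the focal OTU.

    Candidates are the union of the focal OTU's network neighbours and the
    OTUs of genomes contributing passing recent-HGT pairs.  Genomes without
    a marker (no OTU) cannot enter via the network and are skipped here;
    their pairs remain visible in the scan output.
    """
    if focal_otu not in otu_table.depth.index:
        raise KeyError(f"focal OTU {focal_otu!r} not in the OTU table")
    neighbors = set(network.graph.neighbors(focal_otu)) if focal_otu in network.graph else set()

    passing = [p for p in recent_pairs if p.passes]
    pairs_by_otu: dict[str, list[RecentHgtPair]] = {}
    for p in passing:
        otu = genome_to_otu.get(p.partner_genome_id)
        if otu is not None and otu in otu_table.depth.index:
            pairs_by_otu.setdefault(otu, []).append(p)

    candidates = sorted((neighbors | set(pairs_by_otu)) - {focal_otu})
    if not candidates:
        return []

    # abundance rank of each OTU in the focal OTU's best sample
    focal_depths = otu_table.depth.loc[focal_otu]
    best_sample = focal_depths.idxmax()
    order = otu_table.depth[best_sample].rank(ascending=False, method="min")

    hypotheses = []
    for cand in candidates:
        rho = p_val = None
        if cand in neighbors:
            edge = network.graph.edges[focal_otu, cand]
            rho, p_val = edge["rho"], edge["p"]
        cpairs = pairs_by_otu.get(cand, [])
        best = max(cpairs, key=lambda p: p.identity_pct) if cpairs else None
        try:
            r, r2, n_used = depth_correlation(otu_table, focal_otu, cand, correlation_mode)
        except ValueError:
            r = r2 = n_used = None
        hypotheses.append(
            PartnerHypothesis(
                focal_otu=focal_otu,
                candidate_otu=cand,
                rho=rho,
                pseudo_p=p_val,
                shared_module=network.modules.get(cand) == network.modules.get(focal_otu)
                if network.modules
                else False,
                n_recent_hgt_pairs=len(cpairs),
                best_pair_identity=best.identity_pct if best else None,
                best_pair_aligned_aa=best.aligned_length_aa if best else None,
                pearson_r=r,
                r_squared=r2,
                n_co_observed_samples=n_used,
                abundance_rank=int(order[cand]),
            )
        )

    hypotheses.sort(
        key=lambda h: (
            -int(h.dual_evidence),
            -h.n_recent_hgt_pairs,
            -(abs(h.rho) if h.rho is not None else 0.0),
            -(h.best_pair_identity or 0.0),
            h.candidate_otu,
        )
    )
    for k, h in enumerate(hypotheses, start=1):
        h.rank = k
    return hypotheses


def hypotheses_to_rows(hypotheses: Sequence[PartnerHypothesis]) -> list[dict]:
    rows = []
    for h in hypotheses:
        rows.append(
            {
                "rank": h.rank,
                "focal_otu": h.focal_otu,
                "candidate_otu": h.candidate_otu,
                "rho": None if h.rho is None else round(h.rho, 4),
                "pseudo_p": h.pseudo_p,
                "shared_module": h.shared_module,
                "n_recent_hgt_pairs": h.n_recent_hgt_pairs,
                "best_pair_identity": None
                if h.best_pair_identity is None
                else round(h.best_pair_identity, 1),
                "best_pair_aligned_aa": h.best_pair_aligned_aa,
                "pearson_r": None if h.pearson_r is None else round(h.pearson_r, 4),
                "r_squared": None if h.r_squared is None else round(h.r_squared, 4),
                "n_co_observed_samples": h.n_co_observed_samples,
                "abundance_rank": h.abundance_rank,
                "dual_evidence": h.dual_evidence,
            }
        )
    return rows
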