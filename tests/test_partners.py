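import numpy as np
import pandas as pd
import pytest

from symbionet.hgt import RecentHgtPair
from symbionet.markers import Otu, OtuTable
from symbionet.network import build_network, detect_modules
from symbionet.partners import depth_correlation, extract_focal_module, rank_partners


def make_otu_table(depths, otu_ids=None, rng=None):
    otu_ids = otu_ids or [f"OTU_{i}" for i in range(depths.shape[0])]
    otus = [Otu(o, f"m{i}", [f"m{i}"]) for i, o in enumerate(otu_ids)]
    df = pd.DataFrame(
        depths, index=otu_ids, columns=[f"S{j}" for j in range(depths.shape[1])]
    )
    return OtuTable(otus, df, {f"m{i}": o for i, o in enumerate(otu_ids)})


def make_net(edges, ids):
    rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    p = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for a, b, r in edges:
        rho.loc[a, b] = rho.loc[b, a] = r
        p.loc[a, b] = p.loc[b, a] = 0.01
    net = build_network(rho, p)
    detect_modules(net, seed=0)
    return net


def xeno_pair(genome, identity=89.1, passes=True):
    return RecentHgtPair(
        focal_gene_id="f1",
        partner_gene_id=f"{genome}_g1",
        partner_genome_id=genome,
        identity_pct=identity,
        aligned_length_aa=150,
        query_coverage_pct=100.0,
        focal_terminal=False,
        partner_terminal=False,
        passes=passes,
        reasons=() if passes else ("LOW_IDENTITY",),
    )


class TestDepthCorrelation:
    def test_proportional_depths(self):
        t = make_otu_table(np.array([[1.0, 2, 3], [2, 4, 6]]))
        r, r2, n = depth_correlation(t, "OTU_0", "OTU_1")
        assert (r, r2, n) == (pytest.approx(1.0), pytest.approx(1.0), 3)

    def test_antiproportional(self):
        t = make_otu_table(np.array([[1.0, 2, 3], [3, 2, 1]]))
        r, _, _ = depth_correlation(t, "OTU_0", "OTU_1")
        assert r == pytest.approx(-1.0)

    def test_independent_depths_uncorrelated(self, rng):
        t = make_otu_table(rng.lognormal(0, 1, size=(2, 500)))
        r, _, n = depth_correlation(t, "OTU_0", "OTU_1")
        assert abs(r) < 0.15
        assert n == 500

    def test_co_observed_drops_joint_zeros(self):
        t = make_otu_table(np.array([[1.0, 2, 3, 0, 5], [2, 4, 6, 7, 0]]))
        _, _, n = depth_correlation(t, "OTU_0", "OTU_1", mode="co_observed")
        assert n == 3
        _, _, n_all = depth_correlation(t, "OTU_0", "OTU_1", mode="all")
        assert n_all == 5

    def test_modes_agree_at_full_occupancy(self, rng):
        t = make_otu_table(rng.lognormal(0, 1, size=(2, 40)))
        r_co, _, _ = depth_correlation(t, "OTU_0", "OTU_1", "co_observed")
        r_all, _, _ = depth_correlation(t, "OTU_0", "OTU_1", "all")
        assert r_co == pytest.approx(r_all)

    def test_too_few_samples_rejected(self):
        t = make_otu_table(np.array([[1.0, 0, 3], [2, 4, 0]]))
        with pytest.raises(ValueError, match="usable samples"):
            depth_correlation(t, "OTU_0", "OTU_1")


class TestFocalModule:
    def test_direct_neighbors_in_module(self):
        ids = ["f", "n1", "n2", "x1", "x2", "x3"]
        net = make_net(
            [("f", "n1", 0.9), ("f", "n2", 0.8), ("n1", "n2", 0.7),
             ("x1", "x2", 0.9), ("x2", "x3", 0.9), ("x1", "x3", 0.9)],
            ids,
        )
        sub = extract_focal_module(net, "f")
        assert sorted(sub.graph.nodes) == ["f", "n1", "n2"]
        # only focal-incident edges survive
        assert sorted(sub.graph.edges) == [("f", "n1"), ("f", "n2")]

    def test_isolated_focal_empty(self):
        net = make_net([("a", "b", 0.9)], ["f", "a", "b"])
        sub = extract_focal_module(net, "f")
        assert list(sub.graph.nodes) == ["f"]
        assert sub.graph.number_of_edges() == 0

    def test_other_module_neighbor_excluded(self):
        # f bridges into a tight foreign triangle; the triangle stays foreign
        ids = ["f", "a", "x1", "x2", "x3"]
        net = make_net(
            [("f", "a", 0.9), ("f", "x1", 0.61),
             ("x1", "x2", 0.95), ("x2", "x3", 0.95), ("x1", "x3", 0.95)],
            ids,
        )
        sub = extract_focal_module(net, "f")
        if net.modules["x1"] != net.modules["f"]:
            assert "x1" not in sub.graph.nodes

    def test_missing_focal_rejected(self):
        net = make_net([("a", "b", 0.9)], ["a", "b"])
        with pytest.raises(KeyError):
            extract_focal_module(net, "zzz")


class TestRankPartners:
    def setup_method(self):
        rng = np.random.default_rng(0)
        depths = rng.lognormal(0, 1, size=(4, 30))
        self.table = make_otu_table(depths, ["f", "host", "decoy", "other"])
        self.g2o = {"gh": "host", "gd": "decoy", "go": "other"}

    def test_dual_evidence_outranks_single(self):
        net = make_net([("f", "host", 0.9), ("f", "decoy", 0.8)], list(self.table.depth.index))
        pairs = [xeno_pair("gh")]
        hyps = rank_partners(net, pairs, self.table, "f", self.g2o)
        assert hyps[0].candidate_otu == "host"
        assert hyps[0].dual_evidence
        assert hyps[0].rank == 1

    def test_single_evidence_tiers_sorted_by_documented_key(self):
        net = make_net([("f", "decoy", 0.8)], list(self.table.depth.index))
        pairs = [xeno_pair("go")]  # HGT-only candidate
        hyps = rank_partners(net, pairs, self.table, "f", self.g2o)
        by_otu = {h.candidate_otu: h for h in hyps}
        assert not by_otu["decoy"].dual_evidence
        assert not by_otu["other"].dual_evidence
        # more recent pairs sorts first within the single-evidence tier
        assert by_otu["other"].rank < by_otu["decoy"].rank

    def test_failed_pairs_do_not_count(self):
        net = make_net([("f", "host", 0.9)], list(self.table.depth.index))
        pairs = [xeno_pair("gh", passes=False)]
        hyps = rank_partners(net, pairs, self.table, "f", self.g2o)
        assert hyps[0].n_recent_hgt_pairs == 0
        assert not hyps[0].dual_evidence

    def test_no_candidates_empty(self):
        net = make_net([("host", "decoy", 0.9)], list(self.table.depth.index))
        assert rank_partners(net, [], self.table, "f", self.g2o) == []

    def test_invariant_to_sample_column_order(self):
        net = make_net([("f", "host", 0.9), ("f", "decoy", 0.7)], list(self.table.depth.index))
        pairs = [xeno_pair("gh"), xeno_pair("gd", identity=75.0)]
        base = [h.candidate_otu for h in rank_partners(net, pairs, self.table, "f", self.g2o)]
        shuffled_depth = self.table.depth[list(reversed(self.table.depth.columns))]
        t2 = OtuTable(self.table.otus, shuffled_depth, self.table.marker_to_otu)
        redo = [h.candidate_otu for h in rank_partners(net, pairs, t2, "f", self.g2o)]
        assert redo == base

    def test_unmapped_genome_skipped(self):
        net = make_net([("f", "host", 0.9)], list(self.table.depth.index))
        pairs = [xeno_pair("gh"), xeno_pair("unknown_genome")]
        hyps = rank_partners(net, pairs, self.table, "f", {"gh": "host"})
        assert {h.candidate_otu for h in hyps} == {"host"}
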