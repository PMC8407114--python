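import numpy as np
import pytest

from symbionet.align import AlignmentResult, NormalizedHit
from symbionet.hgt import (
    TaxonomyGrouping,
    ThresholdFit,
    call_hgt,
    donor_summary,
    fit_thresholds,
    group_scores,
    hgt_gene_count_regression,
    recent_hgt_scan,
)
from symbionet.simulate import mutate_protein

from conftest import make_genome

GROUPING = TaxonomyGrouping(
    self_taxa=frozenset({"SpeciesA"}), close_taxa=frozenset({"DPANN"})
)


def hit(score, lineage, subject="s"):
    res = AlignmentResult("q", subject, score * 100, 80.0, 120, 90.0)
    return NormalizedHit(res, "g", tuple(lineage), score)


class TestGroupScores:
    def test_all_self_hits_zero(self):
        hits = [hit(0.9, ("Archaea", "P", "SpeciesA")) for _ in range(3)]
        assert group_scores(hits, GROUPING) == (0.0, 0.0)

    def test_close_and_distal_sums(self):
        hits = [
            hit(0.9, ("Archaea", "DPANN", "X")),
            hit(0.8, ("Archaea", "DPANN", "Y")),
            hit(0.5, ("Bacteria", "Firmicutes")),
        ]
        assert group_scores(hits, GROUPING) == (pytest.approx(1.7), pytest.approx(0.5))

    def test_max_hits_caps_each_group(self):
        hits = [
            hit(0.9, ("Archaea", "DPANN", "X")),
            hit(0.8, ("Archaea", "DPANN", "Y")),
            hit(0.5, ("Bacteria", "Firmicutes")),
            hit(0.4, ("Bacteria", "Proteobacteria")),
        ]
        assert group_scores(hits, GROUPING, max_hits=1) == (
            pytest.approx(0.9),
            pytest.approx(0.5),
        )

    def test_no_hits(self):
        assert group_scores([], GROUPING) == (0.0, 0.0)


class TestFitThresholds:
    def test_bimodal_close_scores_valley_between_modes(self, rng):
        scores = {}
        for i in range(25):
            scores[f"lo{i}"] = (float(rng.normal(0.1, 0.03)), 0.0)
        for i in range(25):
            scores[f"hi{i}"] = (float(rng.normal(2.0, 0.1)), 0.0)
        fit = fit_thresholds(scores)
        assert fit.method_close == "kde_valley"
        assert 0.3 < fit.tau_close < 1.5

    def test_unimodal_falls_back_to_quantiles(self, rng):
        scores = {f"g{i}": (float(rng.normal(1.0, 0.05)), float(rng.normal(1.0, 0.05)))
                  for i in range(40)}
        fit = fit_thresholds(scores)
        assert fit.method_close in ("quantile_fallback", "kde_valley")
        close = np.array([c for c, _ in scores.values()])
        if fit.method_close == "quantile_fallback":
            assert fit.tau_close == pytest.approx(np.quantile(close, 0.25))

    def test_constant_scores_degenerate(self):
        scores = {f"g{i}": (0.5, 0.5) for i in range(30)}
        fit = fit_thresholds(scores)
        assert fit.method_close == "degenerate"
        assert fit.tau_close == 0.5

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            fit_thresholds({f"g{i}": (0.1, 0.1) for i in range(10)})


class TestCallHgt:
    taus = ThresholdFit(0.2, 0.3, "kde_valley", "kde_valley")
    distal_hit = hit(0.8, ("Bacteria", "Firmicutes", "Z"))

    def test_low_close_high_distal_is_hgt(self):
        call = call_hgt("g1", 0.05, 0.8, self.taus, self.distal_hit, "Aenigmarchaeota")
        assert call.is_hgt
        assert call.donor_phylum == "Firmicutes"

    def test_high_close_blocks_call(self):
        call = call_hgt("g1", 1.5, 0.8, self.taus, self.distal_hit, "Aenigmarchaeota")
        assert not call.is_hgt

    def test_same_phylum_donor_not_interphylum(self):
        call = call_hgt("g1", 0.05, 0.8, self.taus, self.distal_hit, "Firmicutes")
        assert not call.is_hgt

    def test_no_distal_hit_no_call(self):
        call = call_hgt("g1", 0.0, 0.8, self.taus, None, "Aenigmarchaeota")
        assert not call.is_hgt

    def test_boundary_taus_flag_all_or_none(self):
        everything = ThresholdFit(float("inf"), 0.0, "kde_valley", "kde_valley")
        nothing = ThresholdFit(0.0, float("inf"), "kde_valley", "kde_valley")
        assert call_hgt("g", 5.0, 0.1, everything, self.distal_hit, "X").is_hgt
        assert not call_hgt("g", 0.0, 5.0, nothing, self.distal_hit, "X").is_hgt


class TestDonorSummary:
    def make_calls(self, counts):
        calls = []
        k = 0
        for phylum, n in counts.items():
            for _ in range(n):
                calls.append(
                    call_hgt(
                        f"g{k}", 0.0, 1.0,
                        ThresholdFit(0.1, 0.5, "kde_valley", "kde_valley"),
                        hit(0.9, ("X", phylum)), "Recipient",
                    )
                )
                k += 1
        return calls

    def test_published_style_accounting(self):
        # 2,579 interphylum transfers in total, anchored by 998 = 38.7%
        counts = {"Euryarchaeota": 998, "Bathyarchaeota": 193, "Firmicutes": 147,
                  "Other": 2579 - 998 - 193 - 147}
        rows = {ph: (n, pct) for ph, n, pct in donor_summary(self.make_calls(counts))}
        assert round(rows["Euryarchaeota"][1], 1) == 38.7
        assert round(rows["Firmicutes"][1], 2) == 5.70

    def test_single_call_is_100(self):
        rows = donor_summary(self.make_calls({"Euryarchaeota": 1}))
        assert rows[0][2] == 100.0

    def test_percents_sum_to_100(self):
        rows = donor_summary(self.make_calls({"A": 3, "B": 5, "C": 11}))
        assert sum(pct for _, _, pct in rows) == pytest.approx(100.0, abs=0.1)

    def test_order_invariance(self):
        calls = self.make_calls({"A": 3, "B": 5})
        assert donor_summary(calls) == donor_summary(list(reversed(calls)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            donor_summary([])


def test_regression_reports_r_squared():
    genes = [600, 700, 800, 900, 1000]
    hgts = [55, 72, 80, 95, 105]
    fit = hgt_gene_count_regression(hgts, genes)
    assert 0.9 < fit["r_squared"] <= 1.0
    assert fit["slope"] > 0


# ---------------------------------------------------------------------------
# recent-transfer scan
# ---------------------------------------------------------------------------

def scan_fixture(rng, identity_pct=89.1, terminal=False, partner_close=False,
                 scaffold_len=8000):
    """Focal genome with one planted xenolog against one community genome."""
    donor_prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=202))
    div = 1.0 - identity_pct / 100.0
    planted = mutate_protein(donor_prot, div, rng)
    filler = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150)) for _ in range(4)]

    ivs = ((100, 706), (1000, 1606), (2000, 2606))
    focal_prots = [filler[0], planted, filler[1]]
    if terminal:
        focal_prots = [planted, filler[0], filler[1]]
    focal = make_genome(
        "focal", (scaffold_len,), (ivs,), proteins=focal_prots,
        lineage=("Archaea", "DPANN", "Aenigmarchaeota-like"), close_clade=True,
    )
    partner = make_genome(
        "partner", (8000,), (ivs,), proteins=[filler[2], donor_prot, filler[3]],
        lineage=("Archaea", "DPANN") if partner_close else ("Archaea", "Crenarchaeota-like"),
        close_clade=partner_close,
    )
    return focal, partner


class TestRecentHgtScan:
    def test_planted_xenolog_passes(self, rng):
        focal, partner = scan_fixture(rng)
        pairs = recent_hgt_scan(focal, [focal, partner])
        passing = [p for p in pairs if p.passes]
        assert len(passing) == 1
        p = passing[0]
        assert round(p.identity_pct, 1) == 89.1
        assert p.aligned_length_aa >= 100

    def test_identity_below_threshold_rejected_with_reason(self, rng):
        # the planted 89.1% pair falls just under a raised cutoff: the hit is
        # reported, carries LOW_IDENTITY, and nothing passes
        focal, partner = scan_fixture(rng)
        pairs = recent_hgt_scan(focal, [focal, partner], min_identity=89.2)
        target = [p for p in pairs if p.identity_pct > 80]
        assert target and all("LOW_IDENTITY" in p.reasons for p in target)
        assert not any(p.passes for p in pairs)

    def test_well_below_threshold_rejected(self, rng):
        focal, partner = scan_fixture(rng, identity_pct=65.0)
        pairs = recent_hgt_scan(focal, [focal, partner])
        assert not any(p.passes for p in pairs)

    def test_terminal_gene_rejected(self, rng):
        focal, partner = scan_fixture(rng, terminal=True)
        pairs = recent_hgt_scan(focal, [focal, partner])
        target = [p for p in pairs if p.identity_pct > 80]
        assert target and all("TERMINAL_GENE" in p.reasons for p in target)

    def test_short_scaffold_rejected(self, rng):
        focal, partner = scan_fixture(rng, scaffold_len=4000)
        pairs = recent_hgt_scan(focal, [focal, partner])
        target = [p for p in pairs if p.identity_pct > 80]
        assert target and all("FOCAL_SHORT_SCAFFOLD" in p.reasons for p in target)

    def test_close_clade_partner_excluded(self, rng):
        focal, partner = scan_fixture(rng, partner_close=True)
        with pytest.raises(ValueError, match="close clade"):
            recent_hgt_scan(focal, [focal, partner])

    def test_ancient_transfer_never_retained(self, rng):
        focal, partner = scan_fixture(rng, identity_pct=42.0)
        pairs = recent_hgt_scan(focal, [focal, partner])
        assert not any(p.passes for p in pairs)

    def test_filters_monotone(self, rng):
        focal, partner = scan_fixture(rng)
        base = sum(p.passes for p in recent_hgt_scan(focal, [focal, partner]))
        stricter_id = sum(
            p.passes
            for p in recent_hgt_scan(focal, [focal, partner], min_identity=95.0)
        )
        stricter_len = sum(
            p.passes
            for p in recent_hgt_scan(focal, [focal, partner], min_aln_aa=300)
        )
        assert stricter_id <= base
        assert stricter_len <= base
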