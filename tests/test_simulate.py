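import numpy as np
import pandas as pd
import pytest

from symbionet.simulate import (
    CommunityConfig,
    GenomeConfig,
    HgtEvent,
    generate_community,
    generate_genomes,
    mutate_protein,
)
from symbionet._util import stream


class TestCommunity:
    def test_same_seed_identical_tables(self):
        cfg = CommunityConfig(n_otus=10, n_samples=30, seed=7)
        t1, _ = generate_community(cfg)
        t2, _ = generate_community(CommunityConfig(n_otus=10, n_samples=30, seed=7))
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        t1, _ = generate_community(CommunityConfig(n_otus=10, n_samples=30, seed=7))
        t2, _ = generate_community(CommunityConfig(n_otus=10, n_samples=30, seed=8))
        assert not t1.equals(t2)

    def test_null_pairs_uncorrelated(self):
        cfg = CommunityConfig(n_otus=10, n_samples=500, seed=11)
        table, _ = generate_community(cfg)
        x = table.to_numpy().astype(float)
        for i, j in [(0, 1), (2, 7), (4, 9), (3, 5)]:
            both = (x[i] > 0) & (x[j] > 0)
            r = np.corrcoef(np.log(x[i, both]), np.log(x[j, both]))[0, 1]
            assert abs(r) < 0.15

    def test_planted_correlation_realized_in_basis(self):
        cfg = CommunityConfig(
            n_otus=10, n_samples=500, planted_pairs=[(0, 1, 0.9)], occupancy=1.0, seed=5
        )
        _, truth = generate_community(cfg)
        r = np.corrcoef(truth.basis_log[0], truth.basis_log[1])[0, 1]
        assert 0.8 <= r <= 0.97

    def test_depth_columns_sum_to_read_depth(self):
        cfg = CommunityConfig(n_otus=6, n_samples=20, occupancy=1.0, read_depth=5000, seed=1)
        table, _ = generate_community(cfg)
        assert (table.sum(axis=0) == 5000).all()

    def test_occupancy_zeros_are_structural(self):
        cfg = CommunityConfig(n_otus=6, n_samples=50, occupancy=0.5, seed=2)
        table, truth = generate_community(cfg)
        absent = ~truth.presence
        assert (table.to_numpy()[absent] == 0).all()

    def test_non_psd_plant_rejected(self):
        cfg = CommunityConfig(
            n_otus=5,
            n_samples=10,
            planted_pairs=[(0, 1, 0.9), (0, 2, 0.9), (1, 2, -0.9)],
            seed=0,
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_community(cfg)

    @pytest.mark.parametrize(
        "kwargs", [dict(occupancy=0.0), dict(occupancy=1.2), dict(read_depth=0),
                   dict(planted_pairs=[(0, 0, 0.5)])]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_community(CommunityConfig(n_otus=5, n_samples=10, **kwargs))


class TestMutateProtein:
    def test_zero_divergence_identity(self, rng):
        p = "ACDEFGHIKLMNPQRSTVWY" * 5
        assert mutate_protein(p, 0.0, rng) == p

    @pytest.mark.parametrize("length, divergence", [(202, 22 / 202), (100, 0.15), (137, 0.3)])
    def test_exact_substitution_count(self, rng, length, divergence):
        p = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        q = mutate_protein(p, divergence, rng)
        diffs = sum(a != b for a, b in zip(p, q))
        assert diffs == round(length * divergence)
        assert len(q) == length


class TestGenomes:
    def test_same_seed_identical(self):
        cfg = GenomeConfig(n_genomes=3, seed=9)
        g1, _ = generate_genomes(cfg)
        g2, _ = generate_genomes(GenomeConfig(n_genomes=3, seed=9))
        assert [g.scaffolds for g in g1] == [g.scaffolds for g in g2]
        assert [[x.protein for x in g.genes] for g in g1] == [
            [x.protein for x in g.genes] for g in g2
        ]

    def test_planted_hgt_identity_exact(self):
        cfg = GenomeConfig(
            n_genomes=3,
            planted_hgt_events=[HgtEvent(donor_genome=1, recipient_genome=0, aa_divergence=0.109)],
            seed=4,
        )
        genomes, truth = generate_genomes(cfg)
        rec = truth.planted_hgt_genes[0]
        donor = next(
            g for gen in genomes for g in gen.genes if g.gene_id == rec["donor_gene"]
        )
        recip = next(
            g for gen in genomes for g in gen.genes if g.gene_id == rec["recipient_gene"]
        )
        n_sub = sum(a != b for a, b in zip(donor.protein, recip.protein))
        assert n_sub == round(len(donor.protein) * 0.109)
        expected = 100.0 * (len(donor.protein) - n_sub) / len(donor.protein)
        assert rec["expected_identity_pct"] == pytest.approx(expected)

    def test_terminal_event_places_at_scaffold_edge(self):
        cfg = GenomeConfig(
            n_genomes=3,
            planted_hgt_events=[
                HgtEvent(donor_genome=1, recipient_genome=0, aa_divergence=0.1, terminal=True)
            ],
            seed=4,
        )
        genomes, truth = generate_genomes(cfg)
        rec = truth.planted_hgt_genes[0]
        recipient = genomes[0]
        gene = next(g for g in recipient.genes if g.gene_id == rec["recipient_gene"])
        on_scaf = recipient.genes_on(gene.scaffold_id)
        assert gene.gene_id in (on_scaf[0].gene_id, on_scaf[-1].gene_id)

    def test_marker_counts_recorded(self):
        from symbionet.genome import ARCHAEAL_SCG_SET

        cfg = GenomeConfig(n_genomes=2, marker_presence={0: list(ARCHAEAL_SCG_SET[:7])}, seed=1)
        genomes, truth = generate_genomes(cfg)
        assert truth.planted_marker_counts["genome_000"] == 7
        planted = [g for g in genomes[0].genes if g.marker_label]
        assert len(planted) == 7

    def test_mislabeled_event_severity_rejected(self):
        with pytest.raises(ValueError):
            HgtEvent(donor_genome=0, recipient_genome=1, aa_divergence=0.4, label="recent").validate()
        with pytest.raises(ValueError):
            HgtEvent(donor_genome=0, recipient_genome=1, aa_divergence=0.4, label="ancient").validate()

    def test_unreachable_overlap_rejected(self):
        cfg = GenomeConfig(n_genomes=1, genes_per_scaffold=(1, 1), overlap_fraction=0.5)
        with pytest.raises(ValueError, match="unreachable"):
            generate_genomes(cfg)


def test_named_streams_are_independent():
    a1 = stream(123, "alpha").random(5)
    b1 = stream(123, "beta").random(5)
    a2 = stream(123, "alpha").random(5)
    assert np.allclose(a1, a2)
    assert not np.allclose(a1, b1)
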