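"""Synthetic communities and genome collections with planted ground truth.

Two generators make the whole pipeline testable without any download:

``generate_community``
    A log-normal compositional abundance model over (by default) 88 samples.
    Log-abundances of the OTUs follow a multivariate normal whose correlation
    matrix carries the planted host-symbiont basis correlations (a Gaussian
    copula on the log scale).  Per-OTU occupancy draws make absences
    structural (the organism is not there), per-sample totals are normalized
    to compositions, and sequencing depth is a multinomial draw — so the
    observed table is compositional count data, exactly the regime the
    basis-correlation estimator is built for.

``generate_genomes``
    Draft-genome collections with planted single-copy markers, an rpS3
    marker gene per genome, and planted horizontal transfers at a controlled
    amino-acid divergence: a donor protein is copied and exactly
    ``round(L * divergence)`` positions are substituted (never back to the
    original residue), so the expected global identity is analytic.

All randomness flows from one master seed through named substreams, making
every artifact byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stream
from .genome import ARCHAEAL_SCG_SET, Gene, GenomeRecord

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


# ---------------------------------------------------------------------------
# Community generator
# ---------------------------------------------------------------------------

@dataclass
class CommunityConfig:
    n_otus: int = 20
    n_samples: int = 88
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    mean_log_abundance: float = 0.0
    sd_log_abundance: float = 1.0
    occupancy: float = 1.0
    read_depth: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_otus < 2 or self.n_samples < 1:
            raise ValueError("need at least 2 OTUs and 1 sample")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError("occupancy must be in (0, 1]")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.sd_log_abundance <= 0:
            raise ValueError("sd_log_abundance must be positive")
        for a, b, r in self.planted_pairs:
            if a == b or not (0 <= a < self.n_otus) or not (0 <= b < self.n_otus):
                raise ValueError(f"bad planted pair ({a}, {b})")
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"planted correlation {r} outside [-1, 1]")


@dataclass
class GroundTruth:
    """Everything the generators planted, resolvable to generated ids."""

    true_basis_correlations: np.ndarray | None = None
    basis_log: np.ndarray | None = None          # latent log-abundances, OTU x sample
    presence: np.ndarray | None = None           # occupancy mask, OTU x sample
    planted_partner: tuple[str, str] | None = None
    planted_hgt_genes: list[dict] = field(default_factory=list)
    planted_marker_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_basis_correlations": None
            if self.true_basis_correlations is None
            else self.true_basis_correlations.tolist(),
            "planted_partner": self.planted_partner,
            "planted_hgt_genes": self.planted_hgt_genes,
            "planted_marker_counts": self.planted_marker_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _planted_correlation_matrix(cfg: CommunityConfig) -> np.ndarray:
    corr = np.eye(cfg.n_otus)
    for a, b, r in cfg.planted_pairs:
        corr[a, b] = corr[b, a] = r
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(
            "planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g}); weaken or triangulate the planted pairs"
        )
    return corr


def generate_community(cfg: CommunityConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an OTU x sample depth table.

    Returns the count table (rows ``otu_###``, columns ``S###``) and the
    ground truth holding the planted correlation matrix, the latent basis
    log-abundances and the occupancy mask.
    """
    cfg.validate()
    corr = _planted_correlation_matrix(cfg)
    rng_ab = stream(cfg.seed, "community.abundance")
    rng_occ = stream(cfg.seed, "community.occupancy")
    rng_count = stream(cfg.seed, "community.counts")

    # Gaussian copula on the log scale: eigh-based factor for reproducibility
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng_ab.standard_normal((cfg.n_otus, cfg.n_samples))
    logs = cfg.mean_log_abundance + cfg.sd_log_abundance * (root @ z)
    basis = np.exp(logs)

    presence = rng_occ.random((cfg.n_otus, cfg.n_samples)) < cfg.occupancy
    abundance = np.where(presence, basis, 0.0)

    counts = np.zeros_like(abundance, dtype=np.int64)
    for j in range(cfg.n_samples):
        total = abundance[:, j].sum()
        if total <= 0:
            continue
        fractions = abundance[:, j] / total
        counts[:, j] = rng_count.multinomial(cfg.read_depth, fractions)

    otu_ids = [f"otu_{i:04d}" for i in range(cfg.n_otus)]
    sample_ids = [f"S{j:03d}" for j in range(cfg.n_samples)]
    table = pd.DataFrame(counts, index=otu_ids, columns=sample_ids)

    truth = GroundTruth(
        true_basis_correlations=corr,
        basis_log=logs,
        presence=presence,
        planted_partner=(
            (otu_ids[cfg.planted_pairs[0][0]], otu_ids[cfg.planted_pairs[0][1]])
            if cfg.planted_pairs
            else None
        ),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Genome generator
# ---------------------------------------------------------------------------

@dataclass
class HgtEvent:
    donor_genome: int
    recipient_genome: int
    n_genes: int = 1
    aa_divergence: float = 0.1
    terminal: bool = False
    label: str = "recent"  # "recent" (< 0.3) or "ancient" (>= 0.5)

    def validate(self) -> None:
        if self.donor_genome == self.recipient_genome:
            raise ValueError("HGT donor and recipient must differ")
        if not (0.0 <= self.aa_divergence < 1.0):
            raise ValueError("aa_divergence must be in [0, 1)")
        if self.label == "recent" and self.aa_divergence >= 0.3:
            raise ValueError("a 'recent' event must have divergence < 0.3")
        if self.label == "ancient" and self.aa_divergence < 0.5:
            raise ValueError("an 'ancient' event must have divergence >= 0.5")


@dataclass
class GenomeConfig:
    n_genomes: int = 8
    scaffolds_per_genome: tuple[int, int] = (2, 3)
    scaffold_length: tuple[int, int] = (8_000, 15_000)
    genes_per_scaffold: tuple[int, int] = (8, 12)
    protein_length: tuple[int, int] = (80, 160)
    gc_content: float = 0.40
    overlap_fraction: float = 0.15
    marker_presence: dict[int, list[str]] = field(default_factory=dict)
    # per-genome divergence of planted single-copy markers from the shared
    # reference: keeps marker pairs between genomes well below the recent-
    # transfer identity threshold, as real inter-phylum orthologs are
    marker_divergence: float = 0.35
    planted_hgt_events: list[HgtEvent] = field(default_factory=list)
    close_clade_members: set[int] = field(default_factory=set)
    lineages: dict[int, tuple[str, ...]] = field(default_factory=dict)
    rps3_groups: dict[int, int] | None = None  # genome -> OTU group; None = own group
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("need at least one genome")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.overlap_fraction > 0 and self.genes_per_scaffold[1] < 2:
            raise ValueError(
                "overlap_fraction > 0 unreachable with fewer than 2 genes per scaffold"
            )
        for ev in self.planted_hgt_events:
            ev.validate()
            for g in (ev.donor_genome, ev.recipient_genome):
                if not (0 <= g < self.n_genomes):
                    raise ValueError(f"HGT event references unknown genome {g}")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(PROTEIN_ALPHABET), size=length))

def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(rng.choice(list(NUCLEOTIDES), size=length, p=p))


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(L * divergence) positions, never silently.

    Each chosen position receives one of the 19 other residues uniformly, so
    realized identity equals ``1 - round(L*d)/L`` exactly.
    """
    n_sub = int(round(len(protein) * divergence))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for i in positions:
        alternatives = [a for a in PROTEIN_ALPHABET if a != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def mutate_dna(seq: str, divergence: float, rng: np.random.Generator) -> str:
    n_sub = int(round(len(seq) * divergence))
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for i in positions:
        alternatives = [b for b in NUCLEOTIDES if b != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def reference_marker_proteins(length: int = 120) -> dict[str, str]:
    """Fixed reference protein for each of the 54 single-copy markers."""
    out = {}
    for m in ARCHAEAL_SCG_SET:
        rng = stream(0xC0FFEE, f"marker.{m}")
        out[m] = _random_protein(rng, length)
    return out


def reference_rps3_nucleotide(group: int, length: int = 648) -> str:
    """Fixed rpS3 nucleotide reference for an OTU group (groups ~ <80% identity)."""
    rng = stream(0x5EED, f"rps3.group{group}")
    return _random_dna(rng, length, 0.45)


def generate_genomes(cfg: GenomeConfig) -> tuple[list[GenomeRecord], GroundTruth]:
    """Simulate a genome collection with planted markers, rpS3 genes and HGTs."""
    cfg.validate()
    refs = reference_marker_proteins()
    truth = GroundTruth()
    genomes: list[GenomeRecord] = []

    for gi in range(cfg.n_genomes):
        rng = stream(cfg.seed, f"genomes.{gi}")
        gid = f"genome_{gi:03d}"
        n_scaf = int(rng.integers(cfg.scaffolds_per_genome[0], cfg.scaffolds_per_genome[1] + 1))
        scaffolds: list[tuple[str, str]] = []
        genes: list[Gene] = []

        # which extra proteins must be planted in this genome
        markers = list(cfg.marker_presence.get(gi, []))
        group = gi if cfg.rps3_groups is None else cfg.rps3_groups.get(gi, gi)
        rps3_nt = mutate_dna(reference_rps3_nucleotide(group), 0.01, rng)
        special: list[tuple[str, str | None, bool]] = [(rps3_nt, None, True)]
        special += [
            (mutate_protein(refs[m], cfg.marker_divergence, rng), m, False) for m in markers
        ]

        gene_counter = 0
        for si in range(n_scaf):
            sid = f"{gid}_scaf{si:02d}"
            n_genes = int(rng.integers(cfg.genes_per_scaffold[0], cfg.genes_per_scaffold[1] + 1))
            pos = 1 + int(rng.integers(10, 60))
            placed: list[Gene] = []
            for _ in range(n_genes):
                if special:
                    payload, marker_label, is_rps3 = special.pop(0)
                else:
                    payload, marker_label, is_rps3 = (
                        _random_protein(rng, int(rng.integers(*cfg.protein_length))),
                        None,
                        False,
                    )
                if is_rps3:
                    # community profiling works on the nucleotide marker; the
                    # protein field just keeps the record well-formed
                    glen = len(payload)
                    protein = _random_protein(rng, glen // 3)
                else:
                    protein = payload
                    glen = 3 * len(protein)
                if placed and rng.random() < cfg.overlap_fraction:
                    overlap = int(rng.integers(1, min(30, placed[-1].length_bp // 2)))
                    start = placed[-1].end - overlap + 1
                else:
                    start = pos + int(rng.integers(1, 40))
                end = start + glen - 1
                g = Gene(
                    gene_id=f"{gid}_g{gene_counter:04d}",
                    scaffold_id=sid,
                    # rpS3 kept on + so its nucleotide sequence reads off the
                    # scaffold slice directly
                    start=start,
                    end=end,
                    strand="+" if (is_rps3 or rng.random() < 0.5) else "-",
                    rank_on_scaffold=len(placed),
                    protein=protein,
                    marker_label=marker_label,
                    is_marker_rps3=is_rps3,
                )
                placed.append(g)
                gene_counter += 1
                pos = end
            scaf_len = placed[-1].end + int(rng.integers(20, 80)) if placed else 1000
            scaf_len = max(scaf_len, int(rng.integers(*cfg.scaffold_length)))
            seq = _random_dna(rng, scaf_len, cfg.gc_content)
            for g in placed:
                if g.is_marker_rps3:
                    seq = seq[: g.start - 1] + rps3_nt + seq[g.end :]
            scaffolds.append((sid, seq))
            genes.extend(placed)

        lineage = cfg.lineages.get(
            gi, ("Archaea", f"Phylum_{gi}", f"Class_{gi}", f"Genus_{gi}", f"Species_{gi}")
        )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                scaffolds=scaffolds,
                genes=genes,
                lineage=lineage,
                close_clade=gi in cfg.close_clade_members,
            )
        )
        truth.planted_marker_counts[gid] = len(set(markers))

    # plant HGT events after all genomes exist (donor proteins must be final)
    used_targets: set[str] = set()
    for ei, ev in enumerate(cfg.planted_hgt_events):
        rng = stream(cfg.seed, f"hgt.{ei}")
        donor = genomes[ev.donor_genome]
        recipient = genomes[ev.recipient_genome]
        # donor proteins long enough that a recent copy clears a 100-aa
        # aligned-length filter even after end trimming, and interior on
        # their scaffold (terminal donor copies are filtered downstream)
        donor_terminal: set[str] = set()
        for sid, _ in donor.scaffolds:
            gs = donor.genes_on(sid)
            if gs:
                donor_terminal.update({gs[0].gene_id, gs[-1].gene_id})
        donor_pool = [
            g
            for g in donor.genes
            if not g.is_marker_rps3
            and g.marker_label is None
            and len(g.protein) >= 110
            and g.gene_id not in donor_terminal
        ]
        chosen = rng.choice(len(donor_pool), size=ev.n_genes, replace=False)
        for ci in chosen:
            dgene = donor_pool[int(ci)]
            mutated = mutate_protein(dgene.protein, ev.aa_divergence, rng)
            target = _pick_recipient_gene(recipient, ev.terminal, rng, used_targets)
            used_targets.add(target.gene_id)
            # replace the target's protein in place; coordinates resized to fit
            target.protein = mutated
            target.end = target.start + 3 * len(mutated) - 1
            scaf_len = recipient.scaffold_lengths[target.scaffold_id]
            if target.end > scaf_len:
                target.end = scaf_len
                target.start = max(1, target.end - 3 * len(mutated) + 1)
            n_sub = int(round(len(dgene.protein) * ev.aa_divergence))
            truth.planted_hgt_genes.append(
                {
                    "recipient_gene": target.gene_id,
                    "recipient_genome": recipient.genome_id,
                    "donor_gene": dgene.gene_id,
                    "donor_genome": donor.genome_id,
                    "expected_identity_pct": 100.0 * (len(dgene.protein) - n_sub) / len(dgene.protein),
                    "terminal": ev.terminal,
                    "label": ev.label,
                }
            )
    return genomes, truth


def _pick_recipient_gene(
    genome: GenomeRecord, terminal: bool, rng: np.random.Generator, used: set[str] = frozenset()
) -> Gene:
    """Choose a plain gene to overwrite: terminal (first/last on its scaffold) or interior."""
    candidates = []
    for sid, _ in genome.scaffolds:
        genes = genome.genes_on(sid)
        if len(genes) < 3:
            continue
        pool = [genes[0], genes[-1]] if terminal else genes[1:-1]
        candidates += [
            g
            for g in pool
            if g.marker_label is None and not g.is_marker_rps3 and g.gene_id not in used
        ]
    if not candidates:
        raise ValueError(f"no eligible recipient gene in {genome.genome_id}")
    return candidates[int(rng.integers(len(candidates)))]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_depth_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="otu_id")

def read_depth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)

def write_taxonomy(genomes: list[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tlineage\tclose_clade\n")
        for g in genomes:
            fh.write(f"{g.genome_id}\t{';'.join(g.lineage)}\t{int(g.close_clade)}\n")

def read_taxonomy(path: str | Path) -> dict[str, dict]:
    out = {}
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        out[row["genome_id"]] = {
            "lineage": tuple(str(row["lineage"]).split(";")),
            "close_clade": bool(int(row["close_clade"])),
        }
    return out
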