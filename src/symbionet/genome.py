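"""Genome records and per-genome quality/architecture statistics.

A :class:`GenomeRecord` bundles the scaffolds, gene models and taxonomy of
one metagenome-assembled genome (MAG).  The statistics computed here are the
standard draft-genome descriptors: completeness against a fixed set of 54
archaeal single-copy marker genes, duplicate-marker rate, GC content, N50,
coding density (union of gene intervals over total length) and the number of
genes overlapping a neighbour on the same scaffold — a hallmark of the
streamlined genomes of ultra-small archaea.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_pct

#: The 54 archaeal single-copy marker genes used for completeness.  Labels
#: follow ribosomal-protein / core-machinery nomenclature; the set size is
#: what matters downstream (completeness is "distinct markers present / 54").
ARCHAEAL_SCG_SET: tuple[str, ...] = tuple(
    [f"rpL{i}" for i in (2, 3, 4, 5, 6, 13, 14, 15, 16, 18, 22, 24, 29, 30)]
    + [f"rpS{i}" for i in (2, 3, 4, 5, 7, 8, 9, 10, 11, 12, 13, 15, 17, 19)]
    + [
        "rpL7ae", "rpL10e", "rpL15e", "rpL18e", "rpL21e", "rpL31e", "rpL37e",
        "rpL39e", "rpL44e", "rpS3ae", "rpS6e", "rpS8e", "rpS19e", "rpS24e",
        "SecY", "EF2", "IF2", "RNAPa", "RNAPb", "RNAPd", "PheRS", "ProRS",
        "ArgRS", "HisRS", "TopoVIb", "PCNA",
    ]
)
assert len(ARCHAEAL_SCG_SET) == 54


@dataclass
class Gene:
    """A protein-coding gene on a scaffold; coordinates 1-based inclusive."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    rank_on_scaffold: int
    protein: str
    marker_label: str | None = None
    is_marker_rps3: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One genome: scaffolds, genes, lineage, and the close-clade flag."""

    genome_id: str
    scaffolds: list[tuple[str, str]]
    genes: list[Gene]
    lineage: tuple[str, ...] = ()
    close_clade: bool = False

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.genome_id}: duplicate scaffold ids")
        lengths = self.scaffold_lengths
        for g in self.genes:
            if g.scaffold_id not in lengths:
                raise ValueError(f"{g.gene_id}: unknown scaffold {g.scaffold_id}")
            if g.end > lengths[g.scaffold_id]:
                raise ValueError(f"{g.gene_id}: end beyond scaffold")

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.scaffolds}

    @property
    def phylum(self) -> str:
        return self.lineage[1] if len(self.lineage) > 1 else "unclassified"

    def genes_on(self, scaffold_id: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes if g.scaffold_id == scaffold_id),
            key=lambda g: (g.start, g.end),
        )


@dataclass
class GenomeStatsReport:
    genome_id: str
    completeness_pct: float
    duplicate_marker_pct: float
    gc_pct: float
    n50_bp: int
    coding_density_pct: float
    n_genes: int
    mean_gene_length_bp: float
    n_overlapped_genes: int
    overlapped_pct: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self)).drop("genome_id").rename(self.genome_id)


def _check_marker_set(marker_set: Sequence[str]) -> set[str]:
    ms = set(marker_set)
    if len(ms) != 54:
        raise ValueError(f"marker set must contain exactly 54 distinct ids, got {len(ms)}")
    return ms


def completeness(genome: GenomeRecord, marker_set: Sequence[str] = ARCHAEAL_SCG_SET) -> float:
    """Percent of the 54 single-copy markers present at least once.

    Duplicated markers count once; the value is reported to one decimal.
    """
    ms = _check_marker_set(marker_set)
    present = {g.marker_label for g in genome.genes if g.marker_label in ms}
    return round_pct(100.0 * len(present) / 54)


def duplicate_marker_pct(genome: GenomeRecord, marker_set: Sequence[str] = ARCHAEAL_SCG_SET) -> float:
    """Percent of marker ids found two or more times (each counted once)."""
    ms = _check_marker_set(marker_set)
    counts: dict[str, int] = {}
    for g in genome.genes:
        if g.marker_label in ms:
            counts[g.marker_label] = counts.get(g.marker_label, 0) + 1
    dups = sum(1 for c in counts.values() if c >= 2)
    return round_pct(100.0 * dups / 54)


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that scaffolds of length >= L hold half the assembly."""
    ls = sorted(int(x) for x in lengths)
    if not ls or ls[0] <= 0:
        raise ValueError("n50 requires a non-empty list of positive lengths")
    half = sum(ls) / 2.0
    acc = 0
    for x in reversed(ls):
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals, counted once."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def coding_density(genome: GenomeRecord) -> float:
    """Percent of total scaffold length covered by the union of gene intervals."""
    total = sum(genome.scaffold_lengths.values())
    if total == 0:
        return 0.0
    covered = 0
    for sid, _ in genome.scaffolds:
        covered += _union_length([(g.start, g.end) for g in genome.genes_on(sid)])
    return round_pct(100.0 * covered / total)


def overlapped_genes(genome: GenomeRecord) -> tuple[int, float]:
    """Count genes sharing >=1 bp with another gene on the same scaffold.

    Strand is ignored.  Returns (count, percent of all genes).
    """
    n = 0
    for sid, _ in genome.scaffolds:
        genes = genome.genes_on(sid)
        # sorted by start: g overlaps something iff a previous gene reaches
        # g.start, or the next gene begins before g ends
        max_prev_end = 0
        for i, g in enumerate(genes):
            hit = max_prev_end >= g.start or (
                i + 1 < len(genes) and genes[i + 1].start <= g.end
            )
            n += hit
            max_prev_end = max(max_prev_end, g.end)
    total = len(genome.genes)
    pct = round_pct(100.0 * n / total) if total else 0.0
    return n, pct


def gc_percent(sequences: Iterable[str] | str) -> float:
    """GC percent over unambiguous bases (A/C/G/T only in the denominator)."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = acgt = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        acgt += sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous bases in input")
    return round_pct(100.0 * gc / acgt)


def genome_stats(genome: GenomeRecord, marker_set: Sequence[str] = ARCHAEAL_SCG_SET) -> GenomeStatsReport:
    """All per-genome statistics in one report."""
    n_ov, pct_ov = overlapped_genes(genome)
    lengths = [g.length_bp for g in genome.genes]
    return GenomeStatsReport(
        genome_id=genome.genome_id,
        completeness_pct=completeness(genome, marker_set),
        duplicate_marker_pct=duplicate_marker_pct(genome, marker_set),
        gc_pct=gc_percent(seq for _, seq in genome.scaffolds),
        n50_bp=n50(genome.scaffold_lengths.values()),
        coding_density_pct=coding_density(genome),
        n_genes=len(genome.genes),
        mean_gene_length_bp=round(sum(lengths) / len(lengths), 1) if lengths else 0.0,
        n_overlapped_genes=n_ov,
        overlapped_pct=pct_ov,
    )


def stats_table(genomes: Iterable[GenomeRecord]) -> pd.DataFrame:
    """Genome x statistic table (one column per genome, report-style)."""
    return pd.DataFrame({g.genome_id: genome_stats(g).as_series() for g in genomes})


# ---------------------------------------------------------------------------
# I/O: FASTA (via Biopython) and GFF3 (1-based inclusive, ID= attributes)
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeRecord, outdir: str | Path) -> dict[str, Path]:
    """Write scaffolds FASTA, proteins FASTA and a GFF3 gene table."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffolds": outdir / f"{genome.genome_id}.fna",
        "proteins": outdir / f"{genome.genome_id}.faa",
        "genes": outdir / f"{genome.genome_id}.gff",
    }
    SeqIO.write(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in genome.scaffolds],
        paths["scaffolds"], "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(g.protein), id=g.gene_id, description="") for g in genome.genes],
        paths["proteins"], "fasta",
    )
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genome.genes, key=lambda g: (g.scaffold_id, g.start)):
            attrs = f"ID={g.gene_id};rank={g.rank_on_scaffold}"
            if g.marker_label:
                attrs += f";marker={g.marker_label}"
            if g.is_marker_rps3:
                attrs += ";rps3=1"
            fh.write(
                f"{g.scaffold_id}\tsymbionet\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )
    return paths


def read_genome(
    genome_id: str,
    scaffold_fasta: str | Path,
    protein_fasta: str | Path,
    gff: str | Path,
    lineage: tuple[str, ...] = (),
    close_clade: bool = False,
) -> GenomeRecord:
    """Load a genome from scaffolds FASTA + proteins FASTA + GFF3."""
    from Bio import SeqIO

    scaffolds = [(r.id, str(r.seq)) for r in SeqIO.parse(str(scaffold_fasta), "fasta")]
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}
    genes: list[Gene] = []
    with open(gff) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sid, _src, _type, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            gid = kv["ID"]
            genes.append(
                Gene(
                    gene_id=gid,
                    scaffold_id=sid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rank_on_scaffold=int(kv.get("rank", 0)),
                    protein=proteins.get(gid, ""),
                    marker_label=kv.get("marker"),
                    is_marker_rps3=kv.get("rps3") == "1",
                )
            )
    return GenomeRecord(genome_id, scaffolds, genes, lineage, close_clade)
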