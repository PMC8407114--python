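"""rpS3 marker profiling: OTU clustering, depth aggregation, occurrence filter.

Community structure is profiled through the single-copy ribosomal protein S3
gene, extracted once per genome bin.  Marker sequences are clustered into
OTUs at 95% global nucleotide identity by greedy centroid clustering (the
USEARCH ``-cluster_smallmem`` strategy): sequences are processed longest
first, each either joins the first centroid it matches at or above the
threshold or founds a new OTU, and centroids are never re-assigned.  Member
depths are then summed per OTU and rare OTUs — present in fewer than six
samples — are dropped before network inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import align_global
from .genome import GenomeRecord


@dataclass
class MarkerSequence:
    marker_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.marker_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Otu:
    otu_id: str
    representative: str
    members: list[str]
    taxonomy: tuple[str, ...] = ()


@dataclass
class OtuTable:
    """OTU membership plus the OTU x sample depth matrix."""

    otus: list[Otu]
    depth: pd.DataFrame  # index = otu ids, columns = sample ids
    marker_to_otu: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.depth.columns)

    def otu_of_genome(self, genome_id: str, markers: list[MarkerSequence]) -> str | None:
        for m in markers:
            if m.genome_id == genome_id and m.marker_id in self.marker_to_otu:
                return self.marker_to_otu[m.marker_id]
        return None


def extract_markers(genomes: list[GenomeRecord]) -> list[MarkerSequence]:
    """Pull the rpS3 nucleotide sequence out of each genome (exactly one each)."""
    out = []
    for g in genomes:
        rps3 = [x for x in g.genes if x.is_marker_rps3]
        if len(rps3) != 1:
            raise ValueError(f"{g.genome_id}: expected exactly one rpS3 gene, found {len(rps3)}")
        gene = rps3[0]
        scaffold = dict(g.scaffolds)[gene.scaffold_id]
        nt = scaffold[gene.start - 1 : gene.end]
        out.append(MarkerSequence(marker_id=gene.gene_id, genome_id=g.genome_id, sequence=nt))
    return out


def cluster_markers(
    markers: list[MarkerSequence],
    identity_threshold: float = 0.95,
    taxonomy: dict[str, tuple[str, ...]] | None = None,
) -> list[Otu]:
    """Greedy centroid clustering at the given global-identity threshold.

    Input order never matters: sequences are sorted by decreasing length,
    ties broken by marker id, before the single greedy pass.  OTU taxonomy is
    the majority lineage of member genomes, ties resolved in favour of the
    representative's lineage.
    """
    if not markers:
        raise ValueError("no marker sequences to cluster")
    ordered = sorted(markers, key=lambda m: (-m.length, m.marker_id))
    centroids: list[MarkerSequence] = []
    membership: list[list[str]] = []
    member_genomes: list[list[str]] = []
    for m in ordered:
        placed = False
        for ci, c in enumerate(centroids):
            res = align_global(m.sequence, c.sequence, m.marker_id, c.marker_id, moltype="nt")
            if res.identity_pct / 100.0 >= identity_threshold:
                membership[ci].append(m.marker_id)
                member_genomes[ci].append(m.genome_id)
                placed = True
                break
        if not placed:
            centroids.append(m)
            membership.append([m.marker_id])
            member_genomes.append([m.genome_id])

    otus = []
    for ci, c in enumerate(centroids):
        tax: tuple[str, ...] = ()
        if taxonomy:
            lineages = [taxonomy.get(g, ()) for g in member_genomes[ci]]
            counts: dict[tuple[str, ...], int] = {}
            for ln in lineages:
                counts[ln] = counts.get(ln, 0) + 1
            best = max(counts.values())
            winners = [ln for ln, n in counts.items() if n == best]
            rep_lineage = taxonomy.get(c.genome_id, ())
            tax = rep_lineage if rep_lineage in winners else winners[0]
        otus.append(
            Otu(
                otu_id=f"OTU_{ci:04d}",
                representative=c.marker_id,
                members=sorted(membership[ci]),
                taxonomy=tax,
            )
        )
    return otus


def otu_depths(otus: list[Otu], marker_depths: pd.DataFrame) -> OtuTable:
    """Aggregate member marker depths into the OTU x sample table."""
    missing = [m for o in otus for m in o.members if m not in marker_depths.index]
    if missing:
        raise KeyError(f"depth table lacks rows for markers: {sorted(missing)}")
    rows = {o.otu_id: marker_depths.loc[o.members].sum(axis=0) for o in otus}
    depth = pd.DataFrame(rows).T
    depth.index.name = "otu_id"
    mapping = {m: o.otu_id for o in otus for m in o.members}
    return OtuTable(otus=otus, depth=depth, marker_to_otu=mapping)


def occurrence_filter(table: OtuTable, min_samples: int = 6) -> OtuTable:
    """Drop OTUs observed (depth > 0) in fewer than ``min_samples`` samples."""
    present = (table.depth > 0).sum(axis=1)
    keep = present[present >= min_samples].index
    if len(keep) == 0:
        raise ValueError("occurrence filter removed every OTU; no network can be built")
    kept_otus = [o for o in table.otus if o.otu_id in set(keep)]
    depth = table.depth.loc[[o.otu_id for o in kept_otus]]
    mapping = {m: o.otu_id for o in kept_otus for m in o.members}
    return OtuTable(otus=kept_otus, depth=depth, marker_to_otu=mapping)


def write_otu_table(table: OtuTable, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"membership": outdir / "otu_membership.tsv", "depth": outdir / "otu_depth.tsv"}
    with open(paths["membership"], "w") as fh:
        fh.write("otu_id\trepresentative\tmembers\ttaxonomy\n")
        for o in table.otus:
            fh.write(
                f"{o.otu_id}\t{o.representative}\t{','.join(o.members)}\t{';'.join(o.taxonomy)}\n"
            )
    table.depth.to_csv(paths["depth"], sep="\t")
    return paths
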