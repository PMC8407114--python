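import numpy as np
import pytest

from symbionet.genome import Gene, GenomeRecord


def make_genome(
    genome_id="g",
    scaffold_lengths=(10_000,),
    intervals=((),),
    proteins=None,
    markers=None,
    lineage=("Archaea", "TestPhylum"),
    close_clade=False,
    seed=0,
):
    """Build a GenomeRecord from explicit per-scaffold gene intervals.

    ``intervals`` is a tuple per scaffold of (start, end) pairs; proteins
    default to poly-M of length (end-start+1)//3; ``markers`` maps gene
    index (global, in listing order) to a marker label.
    """
    rng = np.random.default_rng(seed)
    scaffolds = []
    genes = []
    k = 0
    for si, (length, ivs) in enumerate(zip(scaffold_lengths, intervals)):
        sid = f"{genome_id}_s{si}"
        seq = "".join(rng.choice(list("ACGT"), size=length))
        scaffolds.append((sid, seq))
        for rank, (start, end) in enumerate(sorted(ivs)):
            prot = (
                proteins[k]
                if proteins is not None and k < len(proteins) and proteins[k]
                else "M" * max(1, (end - start + 1) // 3)
            )
            genes.append(
                Gene(
                    gene_id=f"{genome_id}_g{k:04d}",
                    scaffold_id=sid,
                    start=start,
                    end=end,
                    strand="+",
                    rank_on_scaffold=rank,
                    protein=prot,
                    marker_label=(markers or {}).get(k),
                )
            )
            k += 1
    return GenomeRecord(genome_id, scaffolds, genes, lineage, close_clade)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
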