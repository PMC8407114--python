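"""Independent brute-force oracles used only by tests."""

from itertools import combinations

import networkx as nx
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def local_align_score_dp(a: str, b: str, gap_open=-11.0, gap_extend=-1.0) -> float:
    """Affine-gap Smith-Waterman score by explicit three-state DP.

    ``gap_open`` is the cost of the first gap residue, ``gap_extend`` of
    each further one.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]   # match/mismatch state
    X = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (a advances)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a (b advances)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


def _partitions(items):
    """All set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_modularity_partition(graph: nx.Graph, weight=None):
    """Exhaustive modularity maximization; feasible up to ~8 nodes."""
    best_q, best_part = float("-inf"), None
    for part in _partitions(list(graph.nodes)):
        q = nx.community.modularity(graph, [set(p) for p in part], weight=weight)
        if q > best_q:
            best_q, best_part = q, [set(p) for p in part]
    return best_part, best_q


def overlapped_genes_quadratic(genome):
    """O(n^2) pairwise interval check for genes sharing >=1 bp."""
    flagged = set()
    for g in genome.genes:
        for h in genome.genes:
            if g.gene_id == h.gene_id or g.scaffold_id != h.scaffold_id:
                continue
            if h.start <= g.end and g.start <= h.end:
                flagged.add(g.gene_id)
                break
    return len(flagged)
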