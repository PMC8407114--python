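"""Pairwise alignment kernel shared by OTU clustering and HGT detection.

Thin, opinionated layer over Biopython's :class:`PairwiseAligner` that fixes
the conventions used throughout the package:

* identity is computed over ALL alignment columns, gap columns included
  (the BLAST ``pident`` convention, which the field's 70%-identity and
  95%-identity thresholds presuppose);
* protein scoring is BLOSUM62 with affine gaps (first gap residue -11,
  each further residue -1); nucleotide scoring is match +1 / mismatch -1
  with gaps -5/-2;
* homology searches are exhaustive (every query against every subject) and
  report a self-normalized score, score(q, s) / score(q, q), which is
  database-size independent and lies in (0, 1] for genuine hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = "ACGT"


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    aligned_length: int
    query_coverage_pct: float

    @property
    def is_hit(self) -> bool:
        return self.score > 0 and self.aligned_length >= 1


@dataclass
class NormalizedHit:
    """An alignment hit annotated with subject taxonomy and self-normalized score."""

    result: AlignmentResult
    subject_genome_id: str
    subject_lineage: tuple[str, ...]
    normalized_score: float

    @property
    def subject_phylum(self) -> str:
        return self.subject_lineage[1] if len(self.subject_lineage) > 1 else "unclassified"


def _guess_moltype(seq: str) -> str:
    return "nt" if set(seq.upper()) <= set(NUCLEOTIDE_ALPHABET + "N") else "aa"


@lru_cache(maxsize=8)
def _aligner(mode: str, moltype: str) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = mode
    if moltype == "aa":
        aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aln.open_gap_score = -11.0
        aln.extend_gap_score = -1.0
    else:
        aln.match_score = 1.0
        aln.mismatch_score = -1.0
        aln.open_gap_score = -5.0
        aln.extend_gap_score = -2.0
    return aln


def _summarize(alignment, query: str, qid: str, sid: str, mode: str) -> AlignmentResult:
    counts = alignment.counts()  # gaps, identities, mismatches over the aligned block
    ncols = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / ncols if ncols else 0.0
    if mode == "local":
        q_aligned = alignment.aligned[0]
        # query residues spanned by the optimal local block
        qs, qe = (q_aligned[0][0], q_aligned[-1][1]) if len(q_aligned) else (0, 0)
        cov = 100.0 * (qe - qs) / len(query)
    else:
        cov = 100.0  # the full query is inside a global alignment by definition
    return AlignmentResult(
        query_id=qid,
        subject_id=sid,
        score=float(alignment.score),
        identity_pct=float(identity),
        aligned_length=int(ncols),
        query_coverage_pct=float(cov),
    )


def _check(a: str, b: str, moltype: str | None, strict: bool = True) -> str:
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ta, tb = _guess_moltype(a), _guess_moltype(b)
    if moltype is None and ta != tb:
        if strict:
            raise ValueError(f"alphabet mismatch: {ta} vs {tb}")
        return "aa"  # local mode scores the pair anyway; BLOSUM covers ACGT rows
    return moltype or ta


def align_global(
    a: str, b: str, qid: str = "query", sid: str = "subject", moltype: str | None = None
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment.

    Identity is over all alignment columns, so two sequences of different
    lengths can never reach 100%.  ``moltype`` ("aa" or "nt") overrides the
    alphabet guess, which matters only for short all-ACGT peptides.  The pair
    is aligned in a canonical orientation so that identity(a, b) equals
    identity(b, a) even when co-optimal alignments differ in gap placement.
    """
    mt = _check(a, b, moltype)
    first, second = ((a, b) if (len(a), a) <= (len(b), b) else (b, a))
    alignment = _aligner("global", mt).align(first, second)[0]
    return _summarize(alignment, a, qid, sid, "global")


def align_local(
    a: str, b: str, qid: str = "query", sid: str = "subject", moltype: str | None = None
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment; score 0 means no hit.

    The first optimal trace reported by the aligner is used, which gives a
    deterministic tie-break at equal score.
    """
    mt = _check(a, b, moltype, strict=False)
    aligner = _aligner("local", mt)
    if aligner.score(a, b) <= 0:
        return AlignmentResult(qid, sid, 0.0, 0.0, 0, 0.0)
    alignment = aligner.align(a, b)[0]
    return _summarize(alignment, a, qid, sid, "local")


def identity(a: str, b: str) -> float:
    """Global-alignment percent identity (gap columns in the denominator)."""
    return align_global(a, b).identity_pct


@dataclass
class DatabaseEntry:
    seq_id: str
    sequence: str
    genome_id: str = ""
    lineage: tuple[str, ...] = ()


def search_all(
    queries: Sequence[DatabaseEntry],
    database: Sequence[DatabaseEntry],
    min_score: float = 0.0,
) -> dict[str, list[NormalizedHit]]:
    """Exhaustively align every query to every database entry.

    Returns per-query hit lists sorted by raw score (descending), subject id
    ascending on ties.  Hits with raw score < ``min_score`` (or score 0) are
    dropped.  A query whose self-alignment score is not positive is rejected.
    """
    if not database:
        raise ValueError("database is empty")
    out: dict[str, list[NormalizedHit]] = {}
    for q in queries:
        self_score = align_local(q.sequence, q.sequence).score
        if self_score <= 0:
            raise ValueError(f"query {q.seq_id} has non-positive self-score")
        hits: list[NormalizedHit] = []
        for s in database:
            # cheap score pass first; the full trace is only computed for
            # subjects that can clear the reporting threshold
            mt = _check(q.sequence, s.sequence, None, strict=False)
            if _aligner("local", mt).score(q.sequence, s.sequence) < max(min_score, 1e-9):
                continue
            res = align_local(q.sequence, s.sequence, q.seq_id, s.seq_id, moltype=mt)
            if not res.is_hit or res.score < min_score:
                continue
            hits.append(
                NormalizedHit(
                    result=res,
                    subject_genome_id=s.genome_id,
                    subject_lineage=tuple(s.lineage),
                    normalized_score=res.score / self_score,
                )
            )
        hits.sort(key=lambda h: (-h.result.score, h.result.subject_id))
        out[q.seq_id] = hits
    return out


def hits_to_rows(hits: dict[str, list[NormalizedHit]]) -> list[dict]:
    """Flatten search results into outfmt-6-like rows for a TSV."""
    rows = []
    for qid, hlist in hits.items():
        for h in hlist:
            rows.append(
                {
                    "query": qid,
                    "subject": h.result.subject_id,
                    "pident": round(h.result.identity_pct, 1),
                    "length": h.result.aligned_length,
                    "qcovs": round(h.result.query_coverage_pct, 1),
                    "score": h.result.score,
                    "normalized_score": round(h.normalized_score, 4),
                    "subject_taxonomy": ";".join(h.subject_lineage),
                }
            )
    return rows
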