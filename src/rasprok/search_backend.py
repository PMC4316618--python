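"""Desk-scale protein similarity search.

Optimal Smith-Waterman local alignment under affine gap penalties (via
Biopython's C PairwiseAligner) with a Karlin-Altschul-form E-value using
fixed published ungapped BLOSUM62 constants.  The E-value is a monotone
ranking surrogate: it preserves the semantics of a significance cutoff
(default 1e-4) on a database of known residue count, without aiming for
numeric parity with any particular BLAST release.

Externally computed hit tables in the same 12-column dialect are fully
interchangeable with this backend downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SimilarityHit

__all__ = ["SearchParams", "align_local", "evalue", "search_all"]

# Ungapped BLOSUM62 Karlin-Altschul constants (natural-log lambda).
KA_LAMBDA = 0.3176
KA_K = 0.134

_VALID = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class SearchParams:
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11  # positive penalty for opening a gap
    gap_extend: int = 1
    e_value_threshold: float = 1e-4
    database_size: int | None = None  # total residues; defaults to actual db size

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.e_value_threshold <= 0:
            raise ValueError("e_value_threshold must be > 0")


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.substitution_matrix)
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    return aligner


def _check_sequence(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"empty {what} sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"illegal residue symbols in {what}: {sorted(bad)}")


def _align_details(query: str, subject: str, params: SearchParams = SearchParams()):
    _check_sequence(query, "query")
    _check_sequence(subject, "subject")
    aligner = _make_aligner(params)
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, 0, 0, 0, 0, 0.0, 0
    aln = aligner.align(query, subject)[0]
    (qa, sa) = aln.aligned  # blocks of (start, end) 0-based half-open
    q_from, q_to = int(qa[0][0]) + 1, int(qa[-1][1])
    s_from, s_to = int(sa[0][0]) + 1, int(sa[-1][1])
    ident = aligned = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        aligned += qe - qs
        ident += sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
    # count gap columns into alignment length, outfmt-6 style
    gaps = (q_to - q_from + 1 - aligned) + (s_to - s_from + 1 - aligned)
    ali_len = aligned + gaps
    pct = 100.0 * ident / ali_len if ali_len else 0.0
    return float(score), q_from, q_to, s_from, s_to, pct, ali_len


def align_local(query: str, subject: str, params: SearchParams = SearchParams()):
    """Optimal local alignment.

    Returns ``(score, q_from, q_to, s_from, s_to, pct_identity)`` with
    1-based inclusive coordinates of the optimal path.  An all-negative
    comparison yields score 0 and empty coordinates (0, 0, 0, 0).
    """
    return _align_details(query, subject, params)[:6]


def evalue(score: float, query_len: int, database_size: int, params: SearchParams = SearchParams()) -> float:
    """Karlin-Altschul-form expectation: E = K * m * n * exp(-lambda * S).

    `database_size` is the total residue count of the searched database;
    E is strictly decreasing in the raw score and linear in m and n.
    """
    if score < 0:
        raise ValueError("score must be >= 0")
    n = params.database_size if params.database_size is not None else database_size
    return KA_K * query_len * n * math.exp(-KA_LAMBDA * score)


def search_all(
    queries: dict[str, str],
    database: dict[str, str],
    params: SearchParams = SearchParams(),
) -> list[SimilarityHit]:
    """Search every query against every database protein.

    Only hits with E-value <= threshold are kept (self-hits included;
    deduplication is the harvester's job).  Ordering is deterministic:
    by query id, then E-value, then subject id.
    """
    if not database:
        raise ValueError("empty database")
    db_size = sum(len(s) for s in database.values())
    aligner = _make_aligner(params)
    hits: list[SimilarityHit] = []
    db_items = sorted(database.items())
    for qid in sorted(queries):
        qseq = queries[qid]
        _check_sequence(qseq, "query")
        for sid, sseq in db_items:
            score = aligner.score(qseq, sseq)
            if score <= 0:
                continue
            e = evalue(score, len(qseq), db_size, params)
            if e > params.e_value_threshold:
                continue
            _, q_from, q_to, s_from, s_to, pct, ali_len = _align_details(qseq, sseq, params)
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=pct,
                    ali_length=ali_len,
                    q_from=q_from,
                    q_to=q_to,
                    s_from=s_from,
                    s_to=s_to,
                    e_value=e,
                    bit_score=float(score),
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.e_value, h.subject_id))
    return hits
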