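"""Simple deterministic multiple sequence alignment (center-star).

A desk-scale progressive aligner for the low-divergence protein families
this package analyses: the center sequence is the one with the highest
total pairwise alignment score, every other sequence is aligned to it
semi-globally (end gaps free), and the pairwise alignments are merged
under the classic "once a gap, always a gap" rule.  Externally computed
alignments (aligned FASTA) can be used anywhere this aligner's output is
accepted.
"""

from __future__ import annotations

from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["align_sequences"]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # BLOSUM45: keeps distant-homolog interiors aligned where BLOSUM62
    # would favour staggered end-gap paths
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM45")
    aligner.open_gap_score = -13
    aligner.extend_gap_score = -1
    # end gaps free (semi-global)
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def _choose_center(seqs: Mapping[str, str], max_sample: int = 60) -> str:
    """Id of the sequence with the highest total score against the others.

    For large inputs the total is taken over a deterministic subsample.
    Ties break lexicographically by id.
    """
    ids = sorted(seqs)
    if len(ids) <= 2:
        return ids[0]
    if len(ids) > max_sample:
        step = -(-len(ids) // max_sample)
        others = ids[::step]
    else:
        others = ids
    aligner = _make_aligner()
    best_id, best_score = None, None
    for cid in ids:
        total = sum(aligner.score(seqs[cid], seqs[oid]) for oid in others if oid != cid)
        if best_score is None or total > best_score:
            best_id, best_score = cid, total
    return best_id


def align_sequences(seqs: Mapping[str, str], center_id: str | None = None) -> dict[str, str]:
    """Center-star MSA; returns id -> aligned sequence (equal lengths).

    Empty input yields an empty dict; a single sequence is returned as-is.
    """
    if not seqs:
        return {}
    ids = list(seqs)
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    if center_id is None:
        center_id = _choose_center(seqs)
    center = seqs[center_id]
    Lc = len(center)
    aligner = _make_aligner()

    # per sequence: cols[i] = residue aligned to center position i (or '-'),
    # ins[i] = residues inserted before center position i (i in 0..Lc)
    per_seq: dict[str, tuple[list[str], dict[int, str]]] = {}
    for sid in ids:
        if sid == center_id:
            per_seq[sid] = (list(center), {})
            continue
        q = seqs[sid]
        aln = aligner.align(center, q)[0]
        ca, qa = aln.aligned
        cols = ["-"] * Lc
        ins: dict[int, str] = {}
        prev_c_end, prev_q_end = 0, 0
        for (cs, ce), (qs, qe) in zip(ca, qa):
            if qs > prev_q_end:
                ins[cs] = ins.get(cs, "") + q[prev_q_end:qs]
            for t in range(ce - cs):
                cols[cs + t] = q[qs + t]
            prev_c_end, prev_q_end = ce, qe
        if prev_q_end < len(q):
            ins[Lc] = ins.get(Lc, "") + q[prev_q_end:]
        per_seq[sid] = (cols, ins)

    ins_width = [0] * (Lc + 1)
    for _, ins in per_seq.values():
        for i, s in ins.items():
            ins_width[i] = max(ins_width[i], len(s))

    out: dict[str, str] = {}
    for sid in ids:
        cols, ins = per_seq[sid]
        parts: list[str] = []
        for i in range(Lc + 1):
            if ins_width[i]:
                s = ins.get(i, "")
                parts.append(s + "-" * (ins_width[i] - len(s)))
            if i < Lc:
                parts.append(cols[i])
        out[sid] = "".join(parts)
    assert len({len(v) for v in out.values()}) == 1
    return out
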