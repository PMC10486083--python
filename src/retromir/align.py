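"""Pairwise alignment wrappers used across classification and selection.

Thin layer over Bio.Align.PairwiseAligner with fixed, documented scoring:
match +1, mismatch -1, affine gaps (first gap column ``gap_open``, each
further column ``gap_extend``).  The first optimal alignment in biopython's
deterministic enumeration order is reported, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


@dataclass
class AlignmentResult:
    query_aln: str
    subject_aln: str
    score: float
    identities: int
    mismatches: int
    gaps: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def columns(self) -> int:
        return len(self.query_aln)

    def identity(self, exclude_end_gaps: bool = False) -> float:
        """Identities over alignment columns; optionally ignore terminal
        gap columns (so truncation is not penalized)."""
        q, s = self.query_aln, self.subject_aln
        lo, hi = 0, len(q)
        if exclude_end_gaps:
            while lo < hi and (q[lo] == "-" or s[lo] == "-"):
                lo += 1
            while hi > lo and (q[hi - 1] == "-" or s[hi - 1] == "-"):
                hi -= 1
        ncols = hi - lo
        if ncols == 0:
            return 0.0
        ident = sum(1 for a, b in zip(q[lo:hi], s[lo:hi]) if a == b and a != "-")
        return ident / ncols


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _aligner(mode: str, match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al

def _result(q: str, s: str, aln) -> AlignmentResult:
    qa, sa = str(aln[0]), str(aln[1])
    gaps = ident = mism = 0
    for a, b in zip(qa, sa):
        if a == "-" or b == "-":
            gaps += 1
        elif a == b:
            ident += 1
        else:
            mism += 1
    blocks_q, blocks_s = aln.aligned
    if len(blocks_q):
        qspan = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
        sspan = (int(blocks_s[0][0]), int(blocks_s[-1][1]))
    else:  # degenerate: no aligned residues
        qspan = sspan = (0, 0)
    return AlignmentResult(qa, sa, float(aln.score), ident, mism, gaps, qspan, sspan)


def align_global(
    q: str,
    s: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -2,
    gap_extend: float = -1,
) -> AlignmentResult:
    """Optimal Needleman-Wunsch alignment with affine gaps."""
    if not q or not s:
        raise ValueError("align_global: empty sequence")
    al = _aligner("global", match, mismatch, gap_open, gap_extend)
    return _result(q, s, al.align(_normalize(q), _normalize(s))[0])


def align_local(
    q: str,
    s: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -2,
    gap_extend: float = -1,
) -> AlignmentResult:
    """Optimal Smith-Waterman alignment with affine gaps.

    ``query_span``/``subject_span`` bound the locally aligned region; the
    aligned strings cover only that region.
    """
    if not q or not s:
        raise ValueError("align_local: empty sequence")
    al = _aligner("local", match, mismatch, gap_open, gap_extend)
    return _result(q, s, al.align(_normalize(q), _normalize(s))[0])


def align_protein(q: str, s: str, mode: str = "global", gap_open: float = -11, gap_extend: float = -1) -> AlignmentResult:
    """BLOSUM62 protein alignment (global by default), blastp-style gaps."""
    if not q or not s:
        raise ValueError("align_protein: empty sequence")
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return _result(q, s, al.align(q, s)[0])
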