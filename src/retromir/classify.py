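"""Origination class of a confirmed retro-miR: R, EJ or N.

The precursor (with ~60 nt of retrocopy flank on each side, which anchors
the placement even when the precursor itself is heavily mutated) is aligned
locally to the spliced parental mRNA; the placed span is projected back to
parental genomic blocks.  The decision cascade is fixed and ordered:

1. EJ -- the placement projects to >= 2 genomic blocks separated by an
   intron of at least ``min_intron`` bp: the hairpin is contiguous only in
   the retrocopy, split by an intron in the parent.
2. R  -- an annotated parental exonic miRNA overlaps the placed locus and
   the mature differs by at most 1 nt (retroduplication of an existing
   miRNA, small drift tolerated outside structural evidence).
3. N  -- the mature differs by more than 1 nt and the equivalent parental
   region does not fold into a stem-loop: the hairpin arose de novo from
   post-insertion mutations.

Anything else is reported as ``unclassified`` rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import AlignmentResult, align_local
from .core import (
    GenomicInterval,
    MiRNARecord,
    SeqRecordSet,
    TranscriptModel,
    fetch,
    overlap_bp,
    project_to_genome,
    splice,
)
from .discovery import CandidateRetroMiR
from .structure import FoldResult, assess_hairpin

log = logging.getLogger(__name__)

CLASSES = ("R", "EJ", "N", "unclassified")


@dataclass
class Placement:
    """Best local placement of a retro-miR precursor on the parental mRNA."""

    mrna_span: tuple[int, int]
    parental_blocks: list[GenomicInterval]
    identity: float                      # matches over precursor length
    mature_mismatches: int
    precursor_mismatches: int
    alignment: AlignmentResult


@dataclass
class RetroMiRCall:
    candidate: CandidateRetroMiR
    cls: str
    placement: Placement | None = None
    parental_has_annotated_mirna: bool = False
    parental_hairpin: tuple[bool, FoldResult] | None = None
    note: str = ""

    @property
    def id(self) -> str:
        return self.candidate.id


def _spans_in_retro(c: CandidateRetroMiR) -> tuple[tuple[int, int], tuple[int, int]]:
    """Precursor and mature spans in retrocopy (mRNA-sense) coordinates."""
    r, p = c.retrocopy.interval, c.mirna.precursor
    if r.strand == "+":
        prec = (p.start - r.start, p.end - r.start)
    else:
        prec = (r.end - p.end, r.end - p.start)
    m = c.mirna.matures[0][1] if c.mirna.matures else p
    if r.strand == "+":
        mat = (m.start - r.start, m.end - r.start)
    else:
        mat = (r.end - m.end, r.end - m.start)
    return prec, mat


def locate_in_parent(
    candidate: CandidateRetroMiR,
    parental_tx: TranscriptModel,
    genome: SeqRecordSet,
    flank: int = 60,
    min_identity: float = 0.6,
) -> Placement | None:
    """Place the precursor on the spliced parental mRNA; None if identity
    over the precursor falls below ``min_identity`` (unplaceable)."""
    mrna = splice(genome, parental_tx)
    retro_seq = candidate.retrocopy.sequence
    (p0, p1), (m0, m1) = _spans_in_retro(candidate)
    if not (0 <= p0 < p1 <= len(retro_seq)):
        # precursor not within the retrocopy record (unstranded edge case):
        # align the bare precursor sequence instead
        prec = fetch(genome, candidate.mirna.precursor)
        q0, q1 = 0, len(prec)
        query = prec
        mm0, mm1 = 0, 0  # mature offsets unknown; treat whole precursor
    else:
        q0 = max(0, p0 - flank)
        q1 = min(len(retro_seq), p1 + flank)
        query = retro_seq[q0:q1]
        mm0, mm1 = m0 - q0, m1 - q0
    res = align_local(query, mrna)

    # per-query-position subject coordinate and match flag; gap columns that
    # fall inside the precursor count against its identity (no gap credit)
    qpos, spos = res.query_span[0], res.subject_span[0]
    prec_range = range(p0 - q0, p1 - q0) if p1 > p0 else range(len(query))
    sub_at: dict[int, int] = {}
    match_at: dict[int, bool] = {}
    gap_cols_in_prec = 0
    for a, b in zip(res.query_aln, res.subject_aln):
        if a != "-" and b != "-":
            sub_at[qpos] = spos
            match_at[qpos] = a == b
        elif prec_range.start < qpos < prec_range.stop:
            gap_cols_in_prec += 1
        if a != "-":
            qpos += 1
        if b != "-":
            spos += 1

    matches = sum(1 for i in prec_range if match_at.get(i, False))
    identity = matches / (len(prec_range) + gap_cols_in_prec)
    if identity < min_identity:
        log.warning("%s: unplaceable on parent (identity %.2f)", candidate.id, identity)
        return None
    placed = [sub_at[i] for i in prec_range if i in sub_at]
    span = (min(placed), max(placed) + 1)
    blocks = project_to_genome(parental_tx, span)
    prec_mm = sum(1 for i in prec_range if not match_at.get(i, False))
    if mm1 > mm0:
        mat_mm = sum(1 for i in range(mm0, mm1) if not match_at.get(i, False))
    else:
        mat_mm = prec_mm
    return Placement(
        mrna_span=span, parental_blocks=blocks, identity=identity,
        mature_mismatches=mat_mm, precursor_mismatches=prec_mm, alignment=res,
    )


def classify(
    candidate: CandidateRetroMiR,
    parental_tx: TranscriptModel,
    parental_mirnas: list[MiRNARecord],
    genome: SeqRecordSet,
    min_intron: int = 30,
    max_r_mature_mismatches: int = 1,
) -> RetroMiRCall:
    """Assign the origination class by the EJ -> R -> N cascade."""
    placement = locate_in_parent(candidate, parental_tx, genome)
    if placement is None:
        return RetroMiRCall(candidate=candidate, cls="unclassified", note="unplaceable")

    call = RetroMiRCall(candidate=candidate, cls="unclassified", placement=placement)

    # (1) exon-junction evidence: split across an intron in the parent.
    # EJ retro-miRs are near-exact copies of the junction-spanning region,
    # so heavy mature divergence (a de novo hairpin that happens to straddle
    # a junction) must fall through to the N rule.
    blocks = placement.parental_blocks
    if len(blocks) >= 2 and placement.mature_mismatches <= max_r_mature_mismatches:
        max_gap = 0
        for prev, nxt in zip(blocks, blocks[1:]):
            gap = nxt.start - prev.end if parental_tx.strand == "+" else prev.start - nxt.end
            max_gap = max(max_gap, gap)
        if max_gap >= min_intron:
            call.cls = "EJ"
            return call

    # (2) retroduplicated: annotated parental exonic miRNA at the placed locus
    call.parental_has_annotated_mirna = any(
        overlap_bp(pm.precursor, b, stranded=True) > 0
        for pm in parental_mirnas
        for b in blocks
    )
    if call.parental_has_annotated_mirna and placement.mature_mismatches <= max_r_mature_mismatches:
        call.cls = "R"
        return call

    # (3) de novo: mutated mature and no stem-loop at the parental region
    if placement.mature_mismatches > max_r_mature_mismatches:
        mrna = splice(genome, parental_tx)
        a, b = placement.mrna_span
        call.parental_hairpin = assess_hairpin(mrna[a:b])
        if not call.parental_hairpin[0]:
            call.cls = "N"
            return call

    call.note = "no decisive evidence"
    return call
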