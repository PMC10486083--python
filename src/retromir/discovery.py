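"""Stage 1: candidate retro-miRs and the DNA-mediated duplication screen.

A candidate is a miRNA precursor whose genomic coordinates overlap a
retrocopy by at least ``min_overlap`` bp (5 bp by default, strand-aware by
default since retro-miR/retrocopy co-orientation is biologically expected).
Candidates sitting mostly inside annotated repeats are flagged and routed
to a review output -- the mobile-element exclusion that was a manual step
in the original analyses, automated here with an explicit threshold.
Folding confirmation delegates to :func:`retromir.structure.assess_hairpin`.

The duplication counter-screen asks whether a gene also has DNA-mediated
(exon-intron preserving) copies: its protein is aligned against six-frame
translations of the genome (tblastn-style, BLOSUM62) and a non-self hit
counts when its score reaches 0.7 of the self-alignment score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align

from .core import (
    GenomicInterval,
    MiRNARecord,
    RetrocopyRecord,
    SeqRecordSet,
    fetch,
    overlap_bp,
    revcomp,
    total_overlap,
)
from .structure import FoldResult, assess_hairpin

log = logging.getLogger(__name__)


@dataclass
class CandidateRetroMiR:
    mirna: MiRNARecord
    retrocopy: RetrocopyRecord
    overlap_bp: int
    repeat_overlap: bool = False
    hairpin_ok: bool | None = None
    fold: FoldResult | None = None

    @property
    def id(self) -> str:
        return f"{self.mirna.id}@{self.retrocopy.id}"


@dataclass
class DuplicationCall:
    gene_id: str
    locus: GenomicInterval
    score_ratio: float


def find_candidates(
    mirnas: list[MiRNARecord],
    retrocopies: list[RetrocopyRecord],
    min_overlap: int = 5,
    stranded: bool = True,
) -> list[CandidateRetroMiR]:
    """All (precursor, retrocopy) pairs overlapping by >= ``min_overlap`` bp.

    Deterministic order: (chrom, start, miRNA id, retrocopy id).  Empty
    inputs yield an empty list.
    """
    out = []
    for m in mirnas:
        for r in retrocopies:
            ov = overlap_bp(m.precursor, r.interval, stranded=stranded)
            if ov >= min_overlap:
                out.append(CandidateRetroMiR(mirna=m, retrocopy=r, overlap_bp=ov))
    out.sort(key=lambda c: (c.mirna.precursor.chrom, c.mirna.precursor.start,
                            c.mirna.id, c.retrocopy.id))
    log.info("find_candidates: %d candidates from %d miRNAs x %d retrocopies",
             len(out), len(mirnas), len(retrocopies))
    return out


def exclude_repeats(
    candidates: list[CandidateRetroMiR],
    repeats: list[GenomicInterval],
    min_frac: float = 0.5,
) -> tuple[list[CandidateRetroMiR], list[CandidateRetroMiR]]:
    """Partition candidates into (kept, flagged-for-review).

    A candidate is flagged when at least ``min_frac`` of its precursor lies
    inside annotated repeats; flagged candidates are returned, never
    silently deleted.
    """
    kept, review = [], []
    for c in candidates:
        cov = total_overlap(c.mirna.precursor, repeats)
        c.repeat_overlap = cov >= min_frac * len(c.mirna.precursor)
        (review if c.repeat_overlap else kept).append(c)
    log.info("exclude_repeats: %d kept, %d flagged", len(kept), len(review))
    return kept, review


def confirm_hairpin(
    candidate: CandidateRetroMiR,
    genome: SeqRecordSet,
    min_stem: int = 18,
    max_loop: int = 40,
    min_paired_frac: float = 0.4,
) -> CandidateRetroMiR:
    """Fold the precursor sequence and set ``hairpin_ok``.

    Sequences with more than 10% non-ACGT(U) characters are rejected;
    scattered ambiguity codes below that are replaced by 'A' (non-pairing).
    """
    seq = fetch(genome, candidate.mirna.precursor).upper()
    bad = sum(1 for ch in seq if ch not in "ACGTU")
    if bad > 0.1 * len(seq):
        raise ValueError(
            f"{candidate.id}: {bad}/{len(seq)} non-nucleotide characters in precursor"
        )
    if bad:
        seq = "".join(ch if ch in "ACGTU" else "A" for ch in seq)
    ok, fr = assess_hairpin(seq, min_stem=min_stem, max_loop=max_loop,
                            min_paired_frac=min_paired_frac)
    candidate.hairpin_ok = ok
    candidate.fold = fr
    return candidate


# ------------------------------------------------------------ DNA-mediated duplication

_FRAME_STRANDS = [(f, "+") for f in range(3)] + [(f, "-") for f in range(3)]


def _translate_frame(seq: str, frame: int) -> str:
    from .selection import _STOPS, _AA

    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append(_AA[codon])
    return "".join(out)


def find_dna_duplications(
    proteins: dict[str, tuple[str, GenomicInterval]],
    genome: SeqRecordSet,
    ratio_min: float = 0.7,
    min_protein_len: int = 30,
) -> list[DuplicationCall]:
    """Translated (six-frame, BLOSUM62, affine-gap) search of each protein
    against the genome; exhaustive over frames at toy-genome scale.

    ``proteins`` maps gene id to (protein sequence, own genomic locus); the
    gene's own locus is excluded ("at least one alignment besides its own").
    A call requires score / self-score >= ``ratio_min``; the self-ratio of
    an exact copy is 1.0 by construction.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1

    calls: list[DuplicationCall] = []
    for gene_id in sorted(proteins):
        prot, own = proteins[gene_id]
        if len(prot) < min_protein_len:
            log.warning("find_dna_duplications: %s protein < %d aa, skipped",
                        gene_id, min_protein_len)
            continue
        self_score = float(aligner.score(prot, prot))
        # mask the gene's own locus so the self-hit cannot shadow a
        # co-optimal duplicate in the same reading frame
        frames: dict[tuple[str, int, str], str] = {}
        for chrom, seq in genome.sequences.items():
            if chrom == own.chrom:
                seq = seq[: own.start] + "N" * len(own) + seq[own.end :]
            for f in range(3):
                frames[(chrom, f, "+")] = _translate_frame(seq, f)
                frames[(chrom, f, "-")] = _translate_frame(revcomp(seq), f)
        for (chrom, f, strand), aa in sorted(frames.items()):
            if not aa:
                continue
            alns = aligner.align(prot, aa)
            if alns.score <= 0:
                continue
            aln = alns[0]
            blocks = aln.aligned[1]
            aa0, aa1 = int(blocks[0][0]), int(blocks[-1][1])
            L = len(genome.sequences[chrom])
            if strand == "+":
                g0, g1 = f + 3 * aa0, f + 3 * aa1
            else:
                g0, g1 = L - (f + 3 * aa1), L - (f + 3 * aa0)
            locus = GenomicInterval(chrom, g0, g1, strand)
            if overlap_bp(locus, own) > 0:
                continue  # the gene's own locus
            ratio = float(alns.score) / self_score
            if ratio >= ratio_min:
                calls.append(DuplicationCall(gene_id=gene_id, locus=locus, score_ratio=ratio))
    calls.sort(key=lambda c: (c.gene_id, c.locus.chrom, c.locus.start))
    return calls
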