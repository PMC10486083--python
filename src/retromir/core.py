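"""Domain types and coordinate algebra shared by every pipeline stage.

All coordinates are 0-based, half-open (``[start, end)``), on a named
chromosome, with strand ``+``, ``-`` or ``.`` (unstranded).  GTF/GFF input is
1-based inclusive and is converted at the I/O boundary (:mod:`retromir.io`),
never inside analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
_STRANDS = {"+", "-", "."}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA-alphabet)."""
    return seq.translate(COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Invariants: ``0 <= start < end`` and strand in ``{+, -, .}``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def strands_compatible(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Same strand, or either feature unstranded."""
    return a.strand == "." or b.strand == "." or a.strand == b.strand


def overlap_bp(a: GenomicInterval, b: GenomicInterval, stranded: bool = False) -> int:
    """Overlap in bp between two intervals; 0 across chromosomes.

    With ``stranded=True`` incompatible strands also yield 0 (unstranded
    features are compatible with everything).
    """
    if a.chrom != b.chrom:
        return 0
    if stranded and not strands_compatible(a, b):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class TranscriptModel:
    """A transcript with its exon chain in transcription (5'->3') order."""

    id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.interval.strand not in "+-":
            raise ValueError(f"transcript {self.id}: explicit strand required")
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(f"transcript {self.id}: exon {e} off transcript chrom/strand")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"transcript {self.id}: exon {e} outside transcript span")
        for prev, nxt in zip(genomic, genomic[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        expect = genomic if self.interval.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise ValueError(f"transcript {self.id}: exons not in transcription order")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class MiRNARecord:
    """An annotated miRNA: precursor locus plus its mature products.

    ``matures`` holds ``(id, interval, sequence)`` triples; sequences are RNA
    (``U`` not ``T``), read in the precursor's transcription sense.
    """

    id: str
    precursor: GenomicInterval
    matures: list[tuple[str, GenomicInterval, str]]
    host_context: str = "intergenic"

    def __post_init__(self) -> None:
        if self.precursor.strand not in "+-":
            raise ValueError(f"miRNA {self.id}: explicit strand required")
        if self.host_context not in {"exonic", "intronic", "intergenic"}:
            raise ValueError(f"miRNA {self.id}: bad host_context {self.host_context!r}")
        for mid, iv, seq in self.matures:
            if iv.chrom != self.precursor.chrom or not (
                self.precursor.start <= iv.start and iv.end <= self.precursor.end
            ):
                raise ValueError(f"mature {mid} not inside precursor of {self.id}")
            if not 18 <= len(iv) <= 26:
                raise ValueError(f"mature {mid}: length {len(iv)} outside [18, 26]")
            if seq and (len(seq) != len(iv) or set(seq) - set("ACGU")):
                raise ValueError(f"mature {mid}: sequence inconsistent with interval/alphabet")


@dataclass
class RetrocopyRecord:
    """A retrocopy locus with its parental-gene link.

    ``sequence`` is the retrocopy read in mRNA sense (reverse-complemented
    from the reference for ``-`` insertions), same length as the interval.
    """

    id: str
    interval: GenomicInterval
    parental_gene_id: str
    parental_transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.interval):
            raise ValueError(f"retrocopy {self.id}: sequence length != interval length")


@dataclass
class SeqRecordSet:
    """Mapping of unique ids to sequences with a single alphabet tag."""

    sequences: dict[str, str] = field(default_factory=dict)
    alphabet: str = "dna"

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __contains__(self, key: str) -> bool:
        return key in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def fetch(genome: SeqRecordSet | dict, iv: GenomicInterval) -> str:
    """Extract the sequence of an interval, reverse-complemented on '-'."""
    seqs = genome.sequences if isinstance(genome, SeqRecordSet) else genome
    if iv.chrom not in seqs:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    chrom = seqs[iv.chrom]
    if iv.end > len(chrom):
        raise ValueError(f"interval {iv} beyond end of {iv.chrom} (len {len(chrom)})")
    s = chrom[iv.start : iv.end]
    return revcomp(s) if iv.strand == "-" else s


def splice(genome: SeqRecordSet | dict, tx: TranscriptModel) -> str:
    """Spliced mRNA of a transcript: exon sequences joined in transcription
    order, reverse-complemented on the '-' strand."""
    return "".join(fetch(genome, e) for e in tx.exons)


def project_to_genome(tx: TranscriptModel, mrna_span: tuple[int, int]) -> list[GenomicInterval]:
    """Map a span on the spliced mRNA back to genomic blocks.

    Returns blocks in transcription order; more than one block exactly when
    the span crosses at least one exon-exon junction.
    """
    start, end = mrna_span
    if not (0 <= start < end <= tx.spliced_length):
        raise ValueError(
            f"span {mrna_span} outside spliced transcript {tx.id} (len {tx.spliced_length})"
        )
    blocks: list[GenomicInterval] = []
    offset = 0
    for exon in tx.exons:
        elen = len(exon)
        lo = max(start, offset)
        hi = min(end, offset + elen)
        if lo < hi:
            if tx.strand == "+":
                g0 = exon.start + (lo - offset)
                g1 = exon.start + (hi - offset)
            else:
                g0 = exon.end - (hi - offset)
                g1 = exon.end - (lo - offset)
            blocks.append(GenomicInterval(exon.chrom, g0, g1, tx.strand))
        offset += elen
    return blocks


def total_overlap(iv: GenomicInterval, others: Iterable[GenomicInterval]) -> int:
    """Total bp of ``iv`` covered by a set of intervals (union-aware)."""
    segs = sorted(
        (max(iv.start, o.start), min(iv.end, o.end))
        for o in others
        if o.chrom == iv.chrom and o.start < iv.end and o.end > iv.start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered
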