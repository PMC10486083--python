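"""Synthetic genomes with planted retro-miRs and a machine-readable truth ledger.

The generator emulates every input the pipeline consumes: a toy genome with
multi-exon protein-coding genes, retrotransposition events carrying planted
retro-miRs of all three origination classes (R: retroduplicated with an
annotated parental exonic miRNA; EJ: hairpin contiguous only across a
parental exon-exon junction; N: de novo hairpin created by post-insertion
substitutions), ortholog panels with controlled divergence, codon pairs
evolved under a controlled dN/dS regime, negative-binomial expression
matrices with planted tumor overexpression, 3'UTR sets with planted
seed-match sites over a rejection-cleaned background, and survival tables
whose hazard is tied to one feature.  Every planted entity has exactly one
row in the :class:`TruthLedger`, which suffices to score each stage.

Coordinate bookkeeping stays exact because the default mutation model has
no indels, and "insertion" of a retrocopy appends it to a dedicated
retrocopy chromosome (separated by spacer sequence) rather than splicing
bases into an existing contig.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    MiRNARecord,
    RetrocopyRecord,
    SeqRecordSet,
    project_to_genome,
    revcomp,
    splice,
    to_rna,
)
from .selection import _STOPS
from .structure import assess_hairpin

_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Raised when a configuration cannot be realised (infeasible plant,
    exhausted rejection sampling, or no room left for an insertion)."""


# ------------------------------------------------------------ configuration

@dataclass
class ExpressionSpec:
    n_tissues: int = 5
    samples_per_tissue: int = 8
    n_tumor: int = 20
    n_tumor_normal: int = 20
    baseline: float = 200.0
    fold: float = 4.0
    dispersion: float = 0.3
    n_overexpressed: int = 6
    tissue_presence: float = 0.7
    fold_noise_sd: float = 0.25
    n_background: int = 8


@dataclass
class SurvivalSpec:
    n_patients: int = 200
    baseline_hazard: float = 1.0 / 1000.0  # per day
    beta: float = math.log(2.0)
    n_features: int = 5
    censoring_rate: float = 0.25


@dataclass
class UTRSpec:
    n_utrs: int = 80
    length: int = 300
    n_mirnas: int = 3
    eightmer_genes: int = 6
    sevenmer_genes: int = 4
    max_attempts: int = 1000


@dataclass
class OrthologSpec:
    divergence_low: float = 0.02
    divergence_high: float = 0.10
    distant_divergence: float = 0.30
    distant_prob: float = 0.5


@dataclass
class CdsOrthologSpec:
    omega_regimes: tuple[float, ...] = (0.1, 1.0)
    steps_per_codon: float = 1.0
    flank_divergence: float = 0.03


@dataclass
class SimConfig:
    """All knobs of the generator; fixed seed implies byte-identical output."""

    seed: int = 1
    n_genes: int = 24
    exons_per_gene: tuple[int, int] = (2, 4)
    intron_len: tuple[int, int] = (80, 300)
    utr5_len: int = 60
    cds_codons: tuple[int, int] = (120, 180)
    utr3_len: int = 220
    n_retrocopies: int = 15
    point_mutation_rate: float = 0.0
    truncation_prob: float = 0.0
    indel_rate: float = 0.0
    plant_r: int = 4
    plant_ej: int = 4
    plant_n: int = 4
    plant_repeat_decoy: bool = True
    stem_len: int = 24
    loop_len: int = 8
    mature_len: int = 22
    spacer_len: tuple[int, int] = (400, 800)
    retro_spacer: tuple[int, int] = (300, 600)
    max_retro_chrom: int = 500_000
    orthologs: OrthologSpec = field(default_factory=OrthologSpec)
    cds_ortholog: CdsOrthologSpec = field(default_factory=CdsOrthologSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    utr: UTRSpec = field(default_factory=UTRSpec)

    def validate(self) -> None:
        for name in ("point_mutation_rate", "truncation_prob", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.n_genes, self.n_retrocopies, self.plant_r, self.plant_ej, self.plant_n) < 0:
            raise ValueError("counts must be >= 0")
        if self.plant_r + self.plant_ej + self.plant_n > self.n_retrocopies:
            raise ValueError("more plants than retrocopies")
        if self.plant_r + self.plant_ej + self.plant_n > self.n_genes:
            raise ValueError("more plants than genes")
        hp = 2 * self.stem_len + self.loop_len
        if hp + 20 > self.utr3_len:
            raise SimulationError(
                f"hairpin ({hp} nt) does not fit in the 3'UTR ({self.utr3_len} nt)"
            )
        if self.mature_len > self.stem_len:
            raise SimulationError("mature longer than one stem arm")

    @property
    def hairpin_len(self) -> int:
        return 2 * self.stem_len + self.loop_len


@dataclass
class TruthLedger:
    """Ground truth of every planted entity, one row each."""

    retromirs: list[dict] = field(default_factory=list)
    retrocopies: list[dict] = field(default_factory=list)
    orthologs: list[dict] = field(default_factory=list)
    cds_orthologs: list[dict] = field(default_factory=list)
    expression: list[dict] = field(default_factory=list)
    utr_sites: list[dict] = field(default_factory=list)
    survival: list[dict] = field(default_factory=list)
    tss: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


# ------------------------------------------------------------ low-level helpers

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _rand_loop(rng: np.random.Generator, n: int) -> str:
    # A/C only: cannot base-pair internally, keeps the terminal loop open
    return "".join(rng.choice(np.array(["A", "C"]), size=n))


def _rand_sense_codons(rng: np.random.Generator, n: int) -> str:
    out = []
    while len(out) < n:
        c = _rand_seq(rng, 3)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _make_hairpin(rng: np.random.Generator, stem: int, loop: int, max_attempts: int = 100) -> str:
    """An inverted repeat that the assessor accepts, by construction."""
    for _ in range(max_attempts):
        arm = _rand_seq(rng, stem)
        hp = arm + _rand_loop(rng, loop) + revcomp(arm)
        ok, _fr = assess_hairpin(hp, min_stem=min(18, stem))
        if ok:
            return hp
    raise SimulationError("could not draw an acceptable hairpin")


# ------------------------------------------------------------ genome

@dataclass
class _GeneMeta:
    role: str                      # "R_parent" | "EJ_parent" | "plain"
    mrna: str
    utr3_span: tuple[int, int]
    cds_span: tuple[int, int]
    precursor_span: tuple[int, int] | None = None
    mature_span: tuple[int, int] | None = None
    junction_in_precursor: int | None = None   # mRNA coordinate of the junction
    parental_mirna_id: str | None = None


def _draw_junctions(
    rng: np.random.Generator,
    mrna_len: int,
    n_exons: int,
    forbidden: tuple[int, int] | None,
    forced: int | None,
    min_exon: int = 40,
    max_attempts: int = 200,
) -> list[int]:
    need = n_exons - 1 - (1 if forced is not None else 0)
    for _ in range(max_attempts):
        js = sorted(rng.integers(min_exon, mrna_len - min_exon, size=need).tolist())
        if forced is not None:
            js = sorted(js + [forced])
        cuts = [0] + js + [mrna_len]
        if any(b - a < min_exon for a, b in zip(cuts, cuts[1:])):
            continue
        if forbidden is not None:
            lo, hi = forbidden
            if any(lo < j < hi for j in js if j != forced):
                continue
        return js
    raise SimulationError("could not place exon junctions under the constraints")


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SeqRecordSet, dict, list[MiRNARecord], dict]:
    """Build the parental chromosome: genes, transcripts, parental miRNAs.

    Returns (genome, transcripts, parental miRNA records, per-transcript
    metadata used by the retrotransposition simulator).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    hp_len = cfg.hairpin_len

    roles = (
        ["R_parent"] * cfg.plant_r
        + ["EJ_parent"] * cfg.plant_ej
        + ["plain"] * (cfg.n_genes - cfg.plant_r - cfg.plant_ej)
    )
    chrom_parts: list[str] = []
    cursor = 0
    transcripts: dict[str, object] = {}
    mirnas: list[MiRNARecord] = []
    meta: dict[str, _GeneMeta] = {}

    for gi, role in enumerate(roles):
        gene_id, tx_id = f"GENE{gi:03d}", f"TX{gi:03d}"
        ncod = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
        cds = "ATG" + _rand_sense_codons(rng, ncod) + "TAA"
        # in-frame stop at the end of the 5'UTR pins the longest ORF to the CDS
        utr5 = _rand_seq(rng, cfg.utr5_len - 3) + "TAA"
        utr3 = list(_rand_seq(rng, cfg.utr3_len))
        l5, lc = len(utr5), len(cds)
        prec_span = mature_span = None
        if role in ("R_parent", "EJ_parent"):
            off = int(rng.integers(10, cfg.utr3_len - hp_len - 10))
            hp = _make_hairpin(rng, cfg.stem_len, cfg.loop_len)
            utr3[off : off + hp_len] = list(hp)
            p0 = l5 + lc + off
            prec_span = (p0, p0 + hp_len)
            m0 = p0 + cfg.stem_len + cfg.loop_len
            mature_span = (m0, m0 + cfg.mature_len)
        mrna = utr5 + cds + "".join(utr3)

        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        forced = None
        forbidden = None
        if role == "R_parent":
            forbidden = (prec_span[0] - 5, prec_span[1] + 5)
        elif role == "EJ_parent":
            cut = int(rng.integers(20, cfg.stem_len + cfg.loop_len + 5))
            forced = prec_span[0] + cut
            forbidden = (prec_span[0] - 5, prec_span[1] + 5)
            n_exons = max(n_exons, 2)
        junctions = _draw_junctions(rng, len(mrna), n_exons, forbidden, forced)

        strand = str(rng.choice(np.array(["+", "-"])))
        cuts = [0] + junctions + [len(mrna)]
        exon_seqs = [mrna[a:b] for a, b in zip(cuts, cuts[1:])]
        introns = [_rand_seq(rng, int(rng.integers(*cfg.intron_len))) for _ in exon_seqs[:-1]]
        pre = exon_seqs[0] + "".join(i + e for i, e in zip(introns, exon_seqs[1:]))

        spacer = int(rng.integers(*cfg.spacer_len))
        chrom_parts.append(_rand_seq(rng, spacer))
        cursor += spacer
        gstart = cursor
        chrom_parts.append(pre if strand == "+" else revcomp(pre))
        cursor += len(pre)

        # exon offsets within the pre-mRNA (transcription sense)
        offs, off = [], 0
        for eseq, intr in zip(exon_seqs, introns + [None]):
            offs.append((off, off + len(eseq)))
            off += len(eseq) + (len(intr) if intr else 0)
        if strand == "+":
            exons = [GenomicInterval("chr1", gstart + a, gstart + b, "+") for a, b in offs]
        else:
            L = len(pre)
            exons = [GenomicInterval("chr1", gstart + L - b, gstart + L - a, "-") for a, b in offs]
        from .core import TranscriptModel  # local import to avoid cycle at module load

        tx = TranscriptModel(
            id=tx_id,
            gene_id=gene_id,
            interval=GenomicInterval("chr1", gstart, gstart + len(pre), strand),
            exons=exons,
        )
        transcripts[tx_id] = tx

        gm = _GeneMeta(
            role=role, mrna=mrna, utr3_span=(l5 + lc, len(mrna)), cds_span=(l5, l5 + lc),
            precursor_span=prec_span, mature_span=mature_span,
            junction_in_precursor=forced,
        )
        if role == "R_parent":
            mid = f"mir-P{gi:02d}"
            prec_iv = project_to_genome(tx, prec_span)[0]
            mat_iv = project_to_genome(tx, mature_span)[0]
            mat_seq = to_rna(mrna[mature_span[0] : mature_span[1]])
            mirnas.append(
                MiRNARecord(
                    id=mid, precursor=prec_iv,
                    matures=[(f"{mid}-3p", mat_iv, mat_seq)],
                    host_context="exonic",
                )
            )
            gm.parental_mirna_id = mid
        meta[tx_id] = gm

    chrom_parts.append(_rand_seq(rng, int(rng.integers(*cfg.spacer_len))))
    genome = SeqRecordSet({"chr1": "".join(chrom_parts)}, "dna")
    return genome, transcripts, mirnas, meta


# ------------------------------------------------------------ retrotransposition

class RetroChromBuilder:
    """Accumulates retrocopy insertions on a dedicated chromosome,
    separated by spacer sequence; raises when the chromosome is full."""

    def __init__(self, rng: np.random.Generator, cfg: SimConfig, chrom: str = "chr2"):
        self.chrom = chrom
        self.rng = rng
        self.cfg = cfg
        self.parts: list[str] = []
        self.cursor = 0

    def insert(self, seq: str) -> int:
        spacer = int(self.rng.integers(*self.cfg.retro_spacer))
        if self.cursor + spacer + len(seq) > self.cfg.max_retro_chrom:
            raise SimulationError("no intergenic space left for retrocopy insertion")
        self.parts.append(_rand_seq(self.rng, spacer))
        self.cursor += spacer
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start

    def finish(self) -> str:
        tail = _rand_seq(self.rng, int(self.rng.integers(*self.cfg.retro_spacer)))
        return "".join(self.parts) + tail


def retrocopy_sequence(
    mrna: str, rate: float, trunc_prob: float, rng: np.random.Generator
) -> tuple[str, list[int], int]:
    """Copy an mRNA with Bernoulli(rate) substitutions and optional 5'
    truncation.  Returns (sequence, mutated mRNA positions, truncation)."""
    seq = list(mrna)
    positions: list[int] = []
    if rate > 0:
        hits = np.nonzero(rng.random(len(seq)) < rate)[0]
        for i in hits:
            alts = [b for b in "ACGT" if b != seq[i]]
            seq[i] = alts[int(rng.integers(0, 3))]
            positions.append(int(i))
    trunc = 0
    if trunc_prob > 0 and rng.random() < trunc_prob:
        trunc = int(rng.integers(1, max(2, len(seq) // 3)))
    return "".join(seq[trunc:]), positions, trunc


def _mrna_to_genomic(span: tuple[int, int], start: int, length: int, strand: str, chrom: str) -> GenomicInterval:
    a, b = span
    if strand == "+":
        return GenomicInterval(chrom, start + a, start + b, "+")
    return GenomicInterval(chrom, start + length - b, start + length - a, "-")


def simulate_retrotransposition(
    genome: SeqRecordSet,
    tx,
    cfg: SimConfig,
    rng: np.random.Generator,
    builder: RetroChromBuilder,
    rid: str,
    plant: str = "none",
    meta: _GeneMeta | None = None,
) -> tuple[RetrocopyRecord, MiRNARecord | None, list[dict]]:
    """Splice, mutate, and insert one retrocopy; annotate its retro-miR.

    ``plant`` is one of ``none | R | EJ | N``.  R and EJ inherit the hairpin
    already present in the (spliced) parental mRNA; N applies targeted
    substitutions that create a hairpin absent from the parent.
    """
    mrna = splice(genome, tx)
    seq, mutated, trunc = retrocopy_sequence(mrna, cfg.point_mutation_rate, cfg.truncation_prob, rng)
    truth_rows: list[dict] = []
    prec_span = mature_span = None

    if plant in ("R", "EJ"):
        if meta is None or meta.precursor_span is None:
            raise SimulationError(f"{plant}-plant requires a parent with a planted hairpin")
        p0, p1 = meta.precursor_span
        if p0 < trunc:
            raise SimulationError("truncation removed the planted precursor")
        prec_span = (p0 - trunc, p1 - trunc)
        mature_span = (meta.mature_span[0] - trunc, meta.mature_span[1] - trunc)
    elif plant == "N":
        if meta is None:
            raise SimulationError("N-plant requires parent metadata")
        hp_len = cfg.hairpin_len
        a, b = meta.utr3_span
        lo, hi = max(a, trunc) + 5, b - hp_len - 5
        if hi <= lo:
            raise SimulationError("no 3'UTR room for a de novo hairpin")
        seq_l = list(seq)
        # a de novo hairpin arises by the minimal mutational path: among all
        # 3'UTR windows, prefer the one whose 3' arm is already closest to
        # the reverse complement of its 5' arm; only the 3' arm is edited
        # and the natural loop is kept
        def n_subs(o: int) -> int:
            arm1 = seq[o : o + cfg.stem_len]
            arm2 = seq[o + cfg.stem_len + cfg.loop_len : o + hp_len]
            return _hamming(arm2, revcomp(arm1))

        offsets = sorted(range(lo - trunc, hi - trunc), key=lambda o: (n_subs(o), o))
        planted = False
        for o in offsets[:200]:
            o_m = o + trunc                           # mRNA coordinate
            parent_win = mrna[o_m : o_m + hp_len]
            if assess_hairpin(parent_win, min_stem=min(18, cfg.stem_len))[0]:
                continue  # parent already folds here; pick elsewhere
            arm1 = "".join(seq_l[o : o + cfg.stem_len])
            loop = "".join(seq_l[o + cfg.stem_len : o + cfg.stem_len + cfg.loop_len])
            hp = arm1 + loop + revcomp(arm1)
            if not assess_hairpin(hp, min_stem=min(18, cfg.stem_len))[0]:
                continue
            m_lo, m_hi = cfg.stem_len + cfg.loop_len, cfg.stem_len + cfg.loop_len + cfg.mature_len
            mm = sum(1 for k in range(m_lo, m_hi) if hp[k] != parent_win[k])
            if mm < 2:
                continue
            new_muts = [o_m + k for k in range(hp_len) if hp[k] != parent_win[k]]
            seq_l[o : o + hp_len] = list(hp)
            mutated = sorted(set(mutated) | set(new_muts))
            prec_span = (o, o + hp_len)
            mature_span = (o + m_lo, o + m_hi)
            planted = True
            break
        if not planted:
            raise SimulationError("could not plant a de novo hairpin")
        seq = "".join(seq_l)

    strand = str(rng.choice(np.array(["+", "-"])))
    start = builder.insert(seq if strand == "+" else revcomp(seq))
    iv = GenomicInterval(builder.chrom, start, start + len(seq), strand)
    retro = RetrocopyRecord(
        id=rid, interval=iv, parental_gene_id=tx.gene_id,
        parental_transcript_id=tx.id, sequence=seq,
    )
    truth_rows.append(
        dict(kind="retrocopy", id=rid, parental_transcript_id=tx.id,
             n_mutations=len(mutated), mutated_mrna_positions=mutated, truncation=trunc)
    )

    mirna = None
    if plant != "none":
        mir_id = f"retro-{rid}-mir"
        prec_iv = _mrna_to_genomic(prec_span, start, len(seq), strand, builder.chrom)
        mat_iv = _mrna_to_genomic(mature_span, start, len(seq), strand, builder.chrom)
        mat_seq = to_rna(seq[mature_span[0] : mature_span[1]])
        mirna = MiRNARecord(
            id=mir_id, precursor=prec_iv,
            matures=[(f"{mir_id}-3p", mat_iv, mat_seq)],
            host_context="intergenic",
        )
        truth_rows.append(
            dict(
                kind="retromir", id=mir_id, true_class=plant, retrocopy_id=rid,
                parental_gene_id=tx.gene_id, parental_transcript_id=tx.id,
                precursor_retro_span=list(prec_span), mature_retro_span=list(mature_span),
                mature_seq=mat_seq, strand=strand,
                parental_mirna_id=(meta.parental_mirna_id if plant == "R" else None),
                junction_mrna_pos=(meta.junction_in_precursor if plant == "EJ" else None),
                mutated_positions=(mutated if plant == "N" else []),
            )
        )
    return retro, mirna, truth_rows


# ------------------------------------------------------------ orthologs & codon pairs

def simulate_ortholog(
    seq: str, divergence: float, rng: np.random.Generator, indel_rate: float = 0.0
) -> str:
    """Mutate a sequence with per-site substitution probability ``divergence``
    (uniform over the three alternatives); optional small indels."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < divergence)[0]
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(0, 3))]
    if indel_rate > 0:
        res: list[str] = []
        for ch in out:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            res.append(ch)
            if indel_rate / 2 <= r < indel_rate:
                res.append(_rand_seq(rng, int(rng.integers(1, 4))))
        out = res
    return "".join(out)


def evolve_cds(
    cds: str, omega_true: float, steps: int, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Evolve a CDS by ``steps`` proposed single-nucleotide changes.

    Synonymous proposals are always accepted; nonsynonymous ones with
    probability ``omega_true``; proposals creating stop codons are rejected.
    Returns (sequence, accepted synonymous, accepted nonsynonymous).
    """
    from .selection import _translate_codon

    seq = list(cds)
    n_syn = n_non = 0
    for _ in range(steps):
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == old:
            continue
        c0 = pos - pos % 3
        codon = "".join(seq[c0 : c0 + 3])
        cand = codon[: pos - c0] + new + codon[pos - c0 + 1 :]
        if cand in _STOPS or codon in _STOPS:
            continue
        if _translate_codon(cand) == _translate_codon(codon):
            seq[pos] = new
            n_syn += 1
        elif rng.random() < omega_true:
            seq[pos] = new
            n_non += 1
    return "".join(seq), n_syn, n_non


def simulate_codon_pair(
    n_codons: int, omega_true: float, steps: int, rng: np.random.Generator
) -> tuple[str, str]:
    """A random sense-codon CDS and a copy evolved under ``omega_true``."""
    cds1 = _rand_sense_codons(rng, n_codons)
    cds2, _, _ = evolve_cds(cds1, omega_true, steps, rng)
    return cds1, cds2


# ------------------------------------------------------------ expression / survival / UTRs

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_expression(
    cfg: SimConfig, rng: np.random.Generator, retromir_matures: list[str], parent_matures: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Counts matrix (features x samples), sample metadata, feature lengths.

    Normal tissues get baseline negative-binomial counts with per-tissue
    presence/absence; the tumor cohort plants a lognormal-noised fold change
    on the first ``n_overexpressed`` retro-miR matures.  The last retro-miR
    mature is silent in all normal samples but expressed in tumors (a
    cancer-only feature).
    """
    ex = cfg.expression
    features = (
        list(retromir_matures)
        + list(parent_matures)
        + [f"mir-BG{i:02d}" for i in range(ex.n_background)]
    )
    silent = retromir_matures[-1] if retromir_matures else None
    over = set(retromir_matures[: ex.n_overexpressed])

    samples, tissues, conditions = [], [], []
    cols = []
    base_mean = {
        f: float(np.exp(rng.normal(math.log(ex.baseline), 0.4))) for f in features
    }
    present = {
        f: rng.random(ex.n_tissues) < ex.tissue_presence for f in features
    }
    for t in range(ex.n_tissues):
        for s in range(ex.samples_per_tissue):
            samples.append(f"T{t}_S{s}")
            tissues.append(f"tissue{t}")
            conditions.append("normal")
            mu = np.array(
                [
                    0.0 if f == silent or not present[f][t] else base_mean[f]
                    for f in features
                ]
            )
            cols.append(_nb_draw(rng, mu, ex.dispersion))
    for grp, n in (("tumor", ex.n_tumor), ("normal", ex.n_tumor_normal)):
        for s in range(n):
            samples.append(f"CA_{grp}_{s}")
            tissues.append("cancer_cohort")
            conditions.append(grp)
            mu = []
            for f in features:
                m = base_mean[f]
                if f == silent:
                    m = base_mean[f] if grp == "tumor" else 0.0
                elif f in over and grp == "tumor":
                    m *= ex.fold * float(np.exp(rng.normal(0.0, ex.fold_noise_sd)))
                mu.append(m)
            cols.append(_nb_draw(rng, np.array(mu), ex.dispersion))

    counts = pd.DataFrame(
        np.column_stack(cols).astype(int), index=features, columns=samples
    )
    meta = pd.DataFrame({"sample": samples, "tissue": tissues, "condition": conditions})
    lengths = pd.DataFrame({"feature": features, "length": [22] * len(features)})
    truth = [
        dict(kind="expression", feature=f,
             overexpressed=bool(f in over), fold=(ex.fold if f in over else 1.0),
             silent_normal=bool(f == silent))
        for f in features
    ]
    return counts, meta, lengths, truth


def simulate_survival(
    cfg: SimConfig, rng: np.random.Generator, feature_ids: list[str]
) -> tuple[pd.DataFrame, list[dict]]:
    """Exponential survival times with hazard tied to the first feature.

    h_i = h0 * exp(beta * z_i) with z the standardized log1p expression of
    the prognostic feature; independent exponential censoring tuned to the
    requested censoring rate.
    """
    sv = cfg.survival
    feats = feature_ids[: sv.n_features]
    X = np.exp(rng.normal(math.log(100.0), 1.0, size=(sv.n_patients, len(feats))))
    z = np.log1p(X)
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    betas = np.zeros(len(feats))
    betas[0] = sv.beta
    score = z @ betas
    T = rng.exponential(1.0 / (sv.baseline_hazard * np.exp(score)))
    cr = min(max(sv.censoring_rate, 1e-9), 0.95)
    c_rate = sv.baseline_hazard * cr / (1.0 - cr)
    C = rng.exponential(1.0 / c_rate, size=sv.n_patients)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(sv.n_patients)],
                       "time": np.round(time, 2) + 0.01, "event": event})
    for j, f in enumerate(feats):
        df[f] = np.round(X[:, j], 3)
    truth = [dict(kind="survival", feature=f, beta_true=float(betas[j]))
             for j, f in enumerate(feats)]
    return df, truth


def _seed_core(mature_rna: str) -> str:
    """DNA reverse complement of the seed (mature positions 2-8)."""
    seed = mature_rna[1:8]
    return revcomp(seed.replace("U", "T"))


def simulate_utrs(
    cfg: SimConfig, rng: np.random.Generator, matures: dict[str, str]
) -> tuple[dict[str, str], list[dict], pd.DataFrame, dict[str, set[str]]]:
    """3'UTR set with planted 8mer-1a / 7mer-m8 sites and a clean background.

    Background UTRs are rejection-sampled until they contain no seed-core
    match for *any* provided mature; planted UTRs are re-scanned after
    insertion so ledger counts are exact.
    """
    u = cfg.utr
    cores = {mid: _seed_core(seq) for mid, seq in matures.items()}
    genes = [f"G{i:04d}" for i in range(u.n_utrs)]

    def clean(seq: str) -> bool:
        return not any(c in seq for c in cores.values())

    utrs: dict[str, str] = {}
    for g in genes:
        for att in range(u.max_attempts):
            s = _rand_seq(rng, u.length)
            if clean(s):
                utrs[g] = s
                break
        else:
            raise SimulationError("could not draw a site-free UTR background")

    site_rows: list[dict] = []
    plant_ids = list(matures)[: u.n_mirnas]
    gene_pool = list(genes)
    for mid in plant_ids:
        core = cores[mid]
        n8, n7 = u.eightmer_genes, u.sevenmer_genes
        chosen = [gene_pool.pop(0) for _ in range(n8 + n7)]
        for k, g in enumerate(chosen):
            stype = "8mer-1a" if k < n8 else "7mer-m8"
            site = core + ("A" if stype == "8mer-1a" else str(rng.choice(np.array(list("CGT")))))
            for att in range(u.max_attempts):
                pos = int(rng.integers(5, u.length - len(site) - 5))
                cand = utrs[g][:pos] + site + utrs[g][pos + len(site):]
                # exact-count check: this insertion must create exactly the
                # planted matches and nothing else, for every mature
                n_matches = sum(cand.count(c) for c in cores.values())
                expected = sum(1 for r in site_rows if r["utr_id"] == g) + 1
                if n_matches == expected:
                    utrs[g] = cand
                    site_rows.append(
                        dict(kind="utr_site", utr_id=g, mirna_id=mid,
                             site_type=stype, position=pos)
                    )
                    break
            else:
                raise SimulationError("could not plant a clean target site")

    # validated table: half of each planted gene set, plus two validated-only genes
    rows = []
    for mid in plant_ids:
        planted = [r["utr_id"] for r in site_rows if r["mirna_id"] == mid]
        for g in planted[::2]:
            rows.append(dict(mirna_id=mid, gene_id=g))
    for mid, g in zip(plant_ids, gene_pool[:2]):
        rows.append(dict(mirna_id=mid, gene_id=g))
    validated = pd.DataFrame(rows)

    target_genes = sorted({r["utr_id"] for r in site_rows} | set(validated.gene_id))
    others = [g for g in genes if g not in target_genes]
    gene_sets = {
        "TARGET_PATHWAY": set(target_genes[: max(4, len(target_genes) * 3 // 4)]) | set(others[:2]),
        "RANDOM_SET_A": set(others[2:12]),
        "RANDOM_SET_B": set(others[12:22] + target_genes[-1:]),
    }
    return utrs, site_rows, validated, gene_sets


# ------------------------------------------------------------ end-to-end generation

@dataclass
class SimResult:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    genome: SeqRecordSet
    transcripts: dict
    parent_mirnas: list[MiRNARecord]
    retrocopies: list[RetrocopyRecord]
    retro_mirnas: list[MiRNARecord]
    decoy_mirnas: list[MiRNARecord]
    repeats: list[GenomicInterval]
    truth: TruthLedger
    ortholog_panels: dict[str, dict[str, str]]
    cds_orthologs: dict[str, str]
    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    lengths: pd.DataFrame
    survival: pd.DataFrame
    utrs: dict[str, str]
    validated: pd.DataFrame
    gene_sets: dict[str, set[str]]
    tss: list[GenomicInterval]
    ccre: list[GenomicInterval]

    @property
    def all_mirnas(self) -> list[MiRNARecord]:
        return self.parent_mirnas + self.retro_mirnas + self.decoy_mirnas


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _ortholog_with_margin(
    seq: str, d: float, rng: np.random.Generator, conserved: bool, max_attempts: int = 50
) -> str:
    """Draw an ortholog whose realized divergence matches its planted regime
    with margin (conserved: < 0.18 substituted; diverged: > 0.22), so the
    ledger's conserved/absent semantics are exact."""
    for _ in range(max_attempts):
        o = simulate_ortholog(seq, d, rng)
        frac = _hamming(seq, o) / len(seq)
        if (conserved and frac < 0.18) or (not conserved and frac > 0.22):
            return o
    raise SimulationError("could not draw an ortholog matching its regime")


def simulate_all(cfg: SimConfig) -> SimResult:
    """Run the whole generator under one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome, transcripts, parent_mirnas, meta = simulate_genome(cfg, rng)
    builder = RetroChromBuilder(rng, cfg)
    truth = TruthLedger()

    tx_ids = list(transcripts)
    r_parents = tx_ids[: cfg.plant_r]
    ej_parents = tx_ids[cfg.plant_r : cfg.plant_r + cfg.plant_ej]
    plain = tx_ids[cfg.plant_r + cfg.plant_ej :]
    n_parents = plain[: cfg.plant_n]
    n_background = cfg.n_retrocopies - cfg.plant_r - cfg.plant_ej - cfg.plant_n
    bg_parents = [plain[(cfg.plant_n + i) % len(plain)] for i in range(n_background)] if plain else []

    assignments = (
        [("R", t) for t in r_parents]
        + [("EJ", t) for t in ej_parents]
        + [("N", t) for t in n_parents]
        + [("none", t) for t in bg_parents]
    )
    retrocopies: list[RetrocopyRecord] = []
    retro_mirnas: list[MiRNARecord] = []
    for i, (plant, tid) in enumerate(assignments):
        rid = f"RC{i:03d}"
        retro, mir, rows = simulate_retrotransposition(
            genome, transcripts[tid], cfg, rng, builder, rid, plant=plant, meta=meta[tid]
        )
        retrocopies.append(retro)
        if mir is not None:
            retro_mirnas.append(mir)
        for r in rows:
            (truth.retromirs if r["kind"] == "retromir" else truth.retrocopies).append(r)

    # repeat decoy: a miRNA annotated inside a mobile-element-like repeat
    decoy_mirnas: list[MiRNARecord] = []
    repeats: list[GenomicInterval] = []
    bg_retros = [r for r in retrocopies if r.id not in {t["retrocopy_id"] for t in truth.retromirs}]
    if cfg.plant_repeat_decoy and bg_retros:
        host = bg_retros[0]
        span = (40, 40 + 70)
        prec_iv = _mrna_to_genomic(span, host.interval.start, len(host.sequence),
                                   host.interval.strand, host.interval.chrom)
        mat_span = (span[0] + 20, span[0] + 42)
        mat_iv = _mrna_to_genomic(mat_span, host.interval.start, len(host.sequence),
                                  host.interval.strand, host.interval.chrom)
        decoy = MiRNARecord(
            id="mir-TE00", precursor=prec_iv,
            matures=[("mir-TE00-3p", mat_iv, to_rna(host.sequence[mat_span[0]:mat_span[1]]))],
            host_context="intergenic",
        )
        decoy_mirnas.append(decoy)
        repeats.append(GenomicInterval(prec_iv.chrom, max(0, prec_iv.start - 10),
                                       prec_iv.end + 10, "."))
        truth.retromirs.append(
            dict(kind="decoy", id=decoy.id, true_class="repeat", retrocopy_id=host.id,
                 parental_gene_id=host.parental_gene_id,
                 parental_transcript_id=host.parental_transcript_id,
                 precursor_retro_span=list(span), mature_retro_span=list(mat_span),
                 mature_seq=to_rna(host.sequence[mat_span[0]:mat_span[1]]),
                 strand=host.interval.strand, parental_mirna_id=None,
                 junction_mrna_pos=None, mutated_positions=[])
        )

    genome.sequences["chr2"] = builder.finish()

    # ortholog panels for each planted retro-miR precursor
    from .selection import SPECIES_ORDER

    osp = cfg.orthologs
    panels: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES_ORDER[1:]}
    retro_by_id = {r.id: r for r in retrocopies}
    for row in truth.retromirs:
        if row["true_class"] == "repeat":
            continue
        rc = retro_by_id[row["retrocopy_id"]]
        a, b = row["precursor_retro_span"]
        prec_seq = rc.sequence[a:b]
        k = int(rng.integers(0, len(SPECIES_ORDER)))  # 0 = human-specific
        for j, sp in enumerate(SPECIES_ORDER[1:], start=1):
            if j <= k:
                d = float(rng.uniform(osp.divergence_low, osp.divergence_high))
                panels[sp][row["id"]] = _ortholog_with_margin(prec_seq, d, rng, conserved=True)
                truth.orthologs.append(dict(kind="ortholog", retromir_id=row["id"],
                                            species=sp, divergence=d, conserved_expected=True))
            elif j == k + 1 and rng.random() < osp.distant_prob:
                d = osp.distant_divergence
                panels[sp][row["id"]] = _ortholog_with_margin(prec_seq, d, rng, conserved=False)
                truth.orthologs.append(dict(kind="ortholog", retromir_id=row["id"],
                                            species=sp, divergence=d, conserved_expected=False))
        age = ("human-specific" if k == 0
               else "all primates" if k == len(SPECIES_ORDER) - 1
               else SPECIES_ORDER[k])
        row["age_true"] = age

    # CDS orthologs of each retrocopy under a planted omega regime
    cds_orthologs: dict[str, str] = {}
    co = cfg.cds_ortholog
    for i, rc in enumerate(retrocopies):
        gm = meta[rc.parental_transcript_id]
        trunc = next(t["truncation"] for t in truth.retrocopies if t["id"] == rc.id)
        c0, c1 = gm.cds_span[0] - trunc, gm.cds_span[1] - trunc
        if c0 < 0:
            continue  # CDS truncated away
        omega = co.omega_regimes[i % len(co.omega_regimes)]
        ncod = (c1 - c0) // 3
        steps = int(round(co.steps_per_codon * ncod))
        cds = rc.sequence[c0:c1]
        body, _, _ = evolve_cds(cds[3:], omega, steps, rng)
        left = simulate_ortholog(rc.sequence[:c0], co.flank_divergence, rng)
        right = simulate_ortholog(rc.sequence[c1:], co.flank_divergence, rng)
        cds_orthologs[rc.id] = left + cds[:3] + body + right
        truth.cds_orthologs.append(dict(kind="cds_ortholog", retrocopy_id=rc.id,
                                        omega_true=float(omega), steps=steps, n_codons=ncod))

    # expression, survival, UTR targets
    rm_matures = [m[0] for r in retro_mirnas for m in r.matures]
    p_matures = [m[0] for r in parent_mirnas for m in r.matures]
    counts, sample_meta, lengths, exp_rows = simulate_expression(cfg, rng, rm_matures, p_matures)
    truth.expression.extend(exp_rows)
    surv, surv_rows = simulate_survival(cfg, rng, rm_matures)
    truth.survival.extend(surv_rows)
    mature_seqs = {m[0]: m[2] for r in retro_mirnas for m in r.matures}
    utrs, site_rows, validated, gene_sets = simulate_utrs(cfg, rng, mature_seqs)
    truth.utr_sites.extend(site_rows)

    # TSS and cCRE evidence; the silent retro-miR gets no TSS within range
    silent_mir = retro_mirnas[-1].id if retro_mirnas else None
    tss: list[GenomicInterval] = []
    ccre: list[GenomicInterval] = []
    for r in retro_mirnas:
        dist = 6000 if r.id == silent_mir else int(rng.integers(200, 3500))
        p = r.precursor
        pos = p.start - dist if p.strand == "+" else p.end + dist - 1
        if pos >= 0:
            tss.append(GenomicInterval(p.chrom, pos, pos + 1, p.strand))
        truth.tss.append(dict(kind="tss", retromir_id=r.id, distance=dist,
                              within_window=bool(dist <= 4000)))
    for rc in retrocopies:
        off = int(rng.integers(0, 10000))
        start = max(0, rc.interval.start - off - 200)
        ccre.append(GenomicInterval(rc.interval.chrom, start, start + 200, "."))

    return SimResult(
        config=cfg, genome=genome, transcripts=transcripts, parent_mirnas=parent_mirnas,
        retrocopies=retrocopies, retro_mirnas=retro_mirnas, decoy_mirnas=decoy_mirnas,
        repeats=repeats, truth=truth, ortholog_panels=panels, cds_orthologs=cds_orthologs,
        counts=counts, sample_meta=sample_meta, lengths=lengths, survival=surv,
        utrs=utrs, validated=validated, gene_sets=gene_sets, tss=tss, ccre=ccre,
    )


def write_outputs(res: SimResult, outdir: str | Path) -> None:
    """Write every emulated input format the pipeline consumes."""
    from . import io as rio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_fasta(out / "genome.fa", res.genome)
    rio.write_transcripts(out / "annotation.gtf", res.transcripts.values())
    rio.write_mirnas(out / "mirnas.gff3", res.all_mirnas)
    rio.write_retrocopies(out / "retrocopies.tsv", res.retrocopies)
    rio.write_bed(out / "repeats.bed", res.repeats, [f"repeat{i}" for i in range(len(res.repeats))])
    rio.write_bed(out / "tss.bed", res.tss, [f"tss{i}" for i in range(len(res.tss))])
    rio.write_bed(out / "ccre.bed", res.ccre, [f"ccre{i}" for i in range(len(res.ccre))])
    odir = out / "orthologs"
    odir.mkdir(exist_ok=True)
    for sp, panel in res.ortholog_panels.items():
        rio.write_fasta(odir / f"{sp}.fa", dict(sorted(panel.items())))
    rio.write_fasta(out / "retro_cds_orthologs.fa", res.cds_orthologs)
    rio.write_tsv(out / "counts.tsv", res.counts.reset_index(names="feature"))
    rio.write_tsv(out / "samples.tsv", res.sample_meta)
    rio.write_tsv(out / "lengths.tsv", res.lengths)
    rio.write_tsv(out / "survival.tsv", res.survival)
    rio.write_fasta(out / "utrs.fa", res.utrs)
    rio.write_tsv(out / "validated_targets.tsv", res.validated)
    rio.write_gmt(out / "gene_sets.gmt", res.gene_sets)
    res.truth.to_json(out / "truth.json")
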