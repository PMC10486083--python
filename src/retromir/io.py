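"""Readers and writers for the plain-text formats the pipeline speaks.

FASTA goes through Bio.SeqIO.  GTF/GFF3/BED are parsed here because the
contract is strict: loss-free attribute round-trip, 1-based-inclusive to
0-based-half-open conversion exactly at this boundary, and malformed lines
reported with file name and 1-based line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GenomicInterval, MiRNARecord, RetrocopyRecord, SeqRecordSet, TranscriptModel, fetch, to_rna

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input line; message carries file and 1-based line number."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, alphabet: str = "dna") -> SeqRecordSet:
    log.info("reading FASTA %s", path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return SeqRecordSet(seqs, alphabet)


def write_fasta(path: str | Path, seqs: SeqRecordSet | dict, width: int = 60) -> None:
    log.info("writing FASTA %s", path)
    mapping = seqs.sequences if isinstance(seqs, SeqRecordSet) else seqs
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in mapping.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------- GTF / GFF3

def _parse_gxf_line(line: str, path, lineno: int, dialect: str):
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 9:
        raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}")
    chrom, source, ftype, start, end, score, strand, frame, attrs = parts
    try:
        start_i, end_i = int(start), int(end)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}") from None
    if start_i < 1 or end_i < start_i:
        raise ParseError(f"{path}:{lineno}: invalid 1-based span {start_i}-{end_i}")
    if strand not in "+-.":
        raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
    attr: dict[str, str] = {}
    if dialect == "gtf":
        for chunk in attrs.rstrip(";").split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if " " not in chunk:
                raise ParseError(f"{path}:{lineno}: malformed GTF attribute {chunk!r}")
            key, val = chunk.split(" ", 1)
            attr[key] = val.strip().strip('"')
    else:
        for chunk in attrs.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "=" not in chunk:
                raise ParseError(f"{path}:{lineno}: malformed GFF3 attribute {chunk!r}")
            key, val = chunk.split("=", 1)
            attr[key] = val
    # 1-based inclusive -> 0-based half-open
    return dict(
        chrom=chrom, source=source, type=ftype, start=start_i - 1, end=end_i,
        score=score, strand=strand, frame=frame, attributes=attr,
    )


def read_gxf(path: str | Path, dialect: str) -> list[dict]:
    """Parse a GTF ('gtf') or GFF3 ('gff3') file into feature dicts with
    internal 0-based half-open coordinates."""
    log.info("reading %s %s", dialect.upper(), path)
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feats.append(_parse_gxf_line(line, path, lineno, dialect))
    return feats


def _fmt_attrs(attr: dict[str, str], dialect: str) -> str:
    if dialect == "gtf":
        return " ".join(f'{k} "{v}";' for k, v in attr.items())
    return ";".join(f"{k}={v}" for k, v in attr.items())


def write_gxf(path: str | Path, feats: Iterable[dict], dialect: str) -> None:
    log.info("writing %s %s", dialect.upper(), path)
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for f in feats:
            fh.write(
                "\t".join(
                    [
                        f["chrom"], f.get("source", "retromir"), f["type"],
                        str(f["start"] + 1), str(f["end"]),
                        f.get("score", "."), f["strand"], f.get("frame", "."),
                        _fmt_attrs(f["attributes"], dialect),
                    ]
                )
                + "\n"
            )


def read_transcripts(path: str | Path, dialect: str = "gtf") -> dict[str, TranscriptModel]:
    """Build TranscriptModels from a GTF/GFF3 with transcript + exon rows."""
    feats = read_gxf(path, dialect)
    tx_feats = {}
    exons: dict[str, list] = {}
    for f in feats:
        tid = f["attributes"].get("transcript_id") or f["attributes"].get("ID")
        if f["type"] == "transcript":
            tx_feats[tid] = f
        elif f["type"] == "exon":
            parent = f["attributes"].get("transcript_id") or f["attributes"].get("Parent")
            exons.setdefault(parent, []).append(f)
    models = {}
    for tid, f in tx_feats.items():
        iv = GenomicInterval(f["chrom"], f["start"], f["end"], f["strand"])
        ex = [
            GenomicInterval(e["chrom"], e["start"], e["end"], e["strand"])
            for e in exons.get(tid, [])
        ]
        ex.sort(key=lambda e: e.start, reverse=(f["strand"] == "-"))
        models[tid] = TranscriptModel(
            id=tid,
            gene_id=f["attributes"].get("gene_id", tid),
            interval=iv,
            exons=ex,
        )
    return models


def write_transcripts(path: str | Path, models: Iterable[TranscriptModel], dialect: str = "gtf") -> None:
    feats = []
    for tx in models:
        base = {"gene_id": tx.gene_id, "transcript_id": tx.id}
        feats.append(
            dict(chrom=tx.interval.chrom, type="transcript", start=tx.interval.start,
                 end=tx.interval.end, strand=tx.strand, attributes=dict(base))
        )
        for i, e in enumerate(tx.exons, start=1):
            attrs = dict(base)
            attrs["exon_number"] = str(i)
            feats.append(
                dict(chrom=e.chrom, type="exon", start=e.start, end=e.end,
                     strand=e.strand, attributes=attrs)
            )
    write_gxf(path, feats, dialect)


# ---------------------------------------------------------------- miRNA GFF3 (miRBase-style)

def read_mirnas(path: str | Path, genome: SeqRecordSet | None = None) -> list[MiRNARecord]:
    """Read a miRBase-dialect GFF3 (miRNA_primary_transcript + miRNA rows
    linked by Derives_from).  Mature sequences are extracted from ``genome``
    when given, else left empty."""
    feats = read_gxf(path, "gff3")
    precursors: dict[str, dict] = {}
    matures: dict[str, list] = {}
    for f in feats:
        if f["type"] == "miRNA_primary_transcript":
            precursors[f["attributes"]["ID"]] = f
        elif f["type"] == "miRNA":
            matures.setdefault(f["attributes"]["Derives_from"], []).append(f)
    records = []
    for pid, f in sorted(precursors.items()):
        piv = GenomicInterval(f["chrom"], f["start"], f["end"], f["strand"])
        mats = []
        for m in sorted(matures.get(pid, []), key=lambda m: m["attributes"]["ID"]):
            miv = GenomicInterval(m["chrom"], m["start"], m["end"], m["strand"])
            seq = to_rna(fetch(genome, miv)) if genome is not None else ""
            mats.append((m["attributes"]["ID"], miv, seq))
        records.append(
            MiRNARecord(
                id=pid, precursor=piv, matures=mats,
                host_context=f["attributes"].get("host_context", "intergenic"),
            )
        )
    return records


def write_mirnas(path: str | Path, records: Iterable[MiRNARecord]) -> None:
    feats = []
    for r in records:
        feats.append(
            dict(chrom=r.precursor.chrom, type="miRNA_primary_transcript",
                 start=r.precursor.start, end=r.precursor.end, strand=r.precursor.strand,
                 attributes={"ID": r.id, "Name": r.id, "host_context": r.host_context})
        )
        for mid, iv, _seq in r.matures:
            feats.append(
                dict(chrom=iv.chrom, type="miRNA", start=iv.start, end=iv.end,
                     strand=iv.strand,
                     attributes={"ID": mid, "Name": mid, "Derives_from": r.id})
            )
    write_gxf(path, feats, "gff3")


# ---------------------------------------------------------------- BED6

def read_bed(path: str | Path) -> list[GenomicInterval]:
    log.info("reading BED %s", path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start < 0 or end <= start:
                raise ParseError(f"{path}:{lineno}: invalid BED span {start}-{end}")
            strand = parts[5] if len(parts) >= 6 else "."
            if strand not in "+-.":
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(parts[0], start, end, strand))
    return out


def write_bed(path: str | Path, ivs: Iterable[GenomicInterval], names: Iterable[str] | None = None) -> None:
    log.info("writing BED %s", path)
    ivs = list(ivs)
    names = list(names) if names is not None else [f"feat{i}" for i in range(len(ivs))]
    with open(path, "w") as fh:
        for iv, name in zip(ivs, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------- TSV tables

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    log.info("reading TSV %s", path)
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path: str | Path, df: pd.DataFrame, index: bool = False, **kwargs) -> None:
    log.info("writing TSV %s", path)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", **kwargs)


def read_retrocopies(path: str | Path) -> list[RetrocopyRecord]:
    df = read_tsv(path, dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RetrocopyRecord(
                id=row.id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                parental_gene_id=row.parental_gene_id,
                parental_transcript_id=row.parental_transcript_id,
                sequence=row.sequence,
            )
        )
    return out


def write_retrocopies(path: str | Path, records: Iterable[RetrocopyRecord]) -> None:
    rows = [
        dict(id=r.id, chrom=r.interval.chrom, start=r.interval.start, end=r.interval.end,
             strand=r.interval.strand, parental_gene_id=r.parental_gene_id,
             parental_transcript_id=r.parental_transcript_id, sequence=r.sequence)
        for r in records
    ]
    write_tsv(path, pd.DataFrame(rows))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs >= 3 fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(path: str | Path, sets: dict[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")
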