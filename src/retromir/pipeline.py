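"""End-to-end orchestration: discover -> fold -> classify -> conserve ->
dnds -> express -> targets/enrich -> survive, driven by one config.

Each stage writes its table under the output directory and feeds the next;
the final report (JSON + human-readable text) carries per-stage record
counts, the class tally with percentages, and the headline statistics of
every downstream analysis.  Reports contain no timestamps and all
randomness is seeded from the config, so identical configs give
byte-identical reports (the config hash is embedded for verification).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .classify import RetroMiRCall, classify
from .core import GenomicInterval, overlap_bp, to_rna
from .discovery import confirm_hairpin, exclude_repeats, find_candidates
from .expression import associate_ccre, associate_tss, normalize, summarize, tumor_vs_normal
from .selection import (
    SPECIES_ORDER,
    call_conservation,
    codon_align,
    dnds_ng86,
    find_longest_orf,
    test_neutrality,
)
from .align import align_protein
from .structure import assess_hairpin  # noqa: F401  (re-exported for CLI convenience)
from .survival import bootstrap_signature, evaluate_signature
from .targets import enrich, merge_validated, scan_sites

log = logging.getLogger(__name__)

__version__ = "0.1.0"

_PARAM_DEFAULTS = dict(
    min_overlap=5,
    repeat_frac=0.5,
    stranded=True,
    min_stem=18,
    max_loop=40,
    min_paired_frac=0.4,
    min_intron=30,
    conservation_threshold=0.80,
    dnds_boot=1000,
    tss_window=4000,
    ccre_window=20000,
    fe_min=1.5,
    fdr_max=0.05,
    surv_boot=100,
    keep_frac=0.8,
    cox_lambda=0.1,
)

_INPUT_KEYS = (
    "genome_fa", "annotation_gtf", "mirna_gff3", "retrocopies_tsv", "repeats_bed",
    "tss_bed", "ccre_bed", "ortholog_dir", "cds_ortholog_fa", "counts_tsv",
    "samples_tsv", "lengths_tsv", "utrs_fa", "validated_tsv", "gene_sets_gmt",
    "survival_tsv",
)


@dataclass
class PipelineConfig:
    """Input paths, per-stage parameters, seed, and output directory."""

    inputs: dict[str, str]
    outdir: str
    seed: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - set(_INPUT_KEYS)
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        missing = set(_INPUT_KEYS) - set(self.inputs)
        if missing:
            raise ValueError(f"missing input keys: {sorted(missing)}")
        unknown_p = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown_p:
            raise ValueError(f"unknown parameters: {sorted(unknown_p)}")
        self.params = {**_PARAM_DEFAULTS, **self.params}

    def validate_paths(self) -> None:
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {key}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - {"inputs", "outdir", "seed", "params"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(inputs=raw["inputs"], outdir=raw["outdir"],
                   seed=raw.get("seed", 1), params=raw.get("params", {}))

    @classmethod
    def for_directory(cls, indir: str | Path, outdir: str | Path, seed: int = 1,
                      params: dict | None = None) -> "PipelineConfig":
        """Point every input at the file names the simulator writes."""
        d = Path(indir)
        inputs = dict(
            genome_fa=str(d / "genome.fa"), annotation_gtf=str(d / "annotation.gtf"),
            mirna_gff3=str(d / "mirnas.gff3"), retrocopies_tsv=str(d / "retrocopies.tsv"),
            repeats_bed=str(d / "repeats.bed"), tss_bed=str(d / "tss.bed"),
            ccre_bed=str(d / "ccre.bed"), ortholog_dir=str(d / "orthologs"),
            cds_ortholog_fa=str(d / "retro_cds_orthologs.fa"),
            counts_tsv=str(d / "counts.tsv"), samples_tsv=str(d / "samples.tsv"),
            lengths_tsv=str(d / "lengths.tsv"), utrs_fa=str(d / "utrs.fa"),
            validated_tsv=str(d / "validated_targets.tsv"),
            gene_sets_gmt=str(d / "gene_sets.gmt"), survival_tsv=str(d / "survival.tsv"),
        )
        return cls(inputs=inputs, outdir=str(outdir), seed=seed, params=params or {})

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def tally_classes(calls: list[RetroMiRCall] | list[str]) -> dict[str, tuple[int, float]]:
    """Counts and half-up one-decimal percentages per class (R/EJ/N).

    Accepts calls or bare class labels; unclassified labels are excluded
    from the percentage base.  Raises on an empty tally.
    """
    labels = [c.cls if isinstance(c, RetroMiRCall) else c for c in calls]
    labels = [l for l in labels if l in ("R", "EJ", "N")]
    if not labels:
        raise ValueError("no classified candidates")
    total = len(labels)
    out = {}
    for cls in ("R", "EJ", "N"):
        n = labels.count(cls)
        pct = float(Decimal(100 * n / total).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        out[cls] = (n, pct)
    return out


def _round_floats(obj, nd=6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_all(config: PipelineConfig, resume: bool = False) -> dict:
    """Run every stage; returns the report dict (also written to disk)."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    if resume and report_path.exists():
        with open(report_path) as fh:
            cached = json.load(fh)
        if cached.get("config_hash") == config.hash():
            log.info("resume: report with matching config hash found, skipping run")
            return cached

    P = config.params
    report: dict = {"version": __version__, "config_hash": config.hash(), "stages": {}}

    # ---- load
    genome = rio.read_fasta(config.inputs["genome_fa"])
    transcripts = rio.read_transcripts(config.inputs["annotation_gtf"])
    mirnas = rio.read_mirnas(config.inputs["mirna_gff3"], genome)
    retrocopies = rio.read_retrocopies(config.inputs["retrocopies_tsv"])
    repeats = rio.read_bed(config.inputs["repeats_bed"])

    # ---- discover
    candidates = find_candidates(mirnas, retrocopies, min_overlap=P["min_overlap"],
                                 stranded=P["stranded"])
    kept, review = exclude_repeats(candidates, repeats, min_frac=P["repeat_frac"])
    rio.write_tsv(out / "candidates.tsv", pd.DataFrame(
        [dict(id=c.id, mirna=c.mirna.id, retrocopy=c.retrocopy.id, overlap_bp=c.overlap_bp)
         for c in kept]))
    rio.write_tsv(out / "review_repeat_overlap.tsv", pd.DataFrame(
        [dict(id=c.id, mirna=c.mirna.id, retrocopy=c.retrocopy.id, overlap_bp=c.overlap_bp)
         for c in review]))
    report["stages"]["discover"] = {"candidates": len(candidates), "kept": len(kept),
                                    "repeat_flagged": len(review)}

    # ---- fold
    confirmed = []
    fold_rows = []
    for c in kept:
        confirm_hairpin(c, genome, min_stem=P["min_stem"], max_loop=P["max_loop"],
                        min_paired_frac=P["min_paired_frac"])
        fold_rows.append(dict(id=c.id, hairpin_ok=c.hairpin_ok, n_pairs=c.fold.n_pairs,
                              longest_helix=c.fold.longest_helix, loop_len=c.fold.loop_len,
                              paired_fraction=round(c.fold.paired_fraction, 4),
                              dotbracket=c.fold.dotbracket))
        if c.hairpin_ok:
            confirmed.append(c)
    rio.write_tsv(out / "folds.tsv", pd.DataFrame(fold_rows))
    report["stages"]["fold"] = {"in": len(kept), "confirmed": len(confirmed)}

    # ---- classify
    calls = []
    for c in confirmed:
        tx = transcripts[c.retrocopy.parental_transcript_id]
        parental_mirnas = [m for m in mirnas
                           if overlap_bp(m.precursor, tx.interval, stranded=True) > 0]
        calls.append(classify(c, tx, parental_mirnas, genome, min_intron=P["min_intron"]))
    rio.write_tsv(out / "classes.tsv", pd.DataFrame(
        [dict(id=k.id, cls=k.cls,
              mature_mismatches=(k.placement.mature_mismatches if k.placement else None),
              precursor_mismatches=(k.placement.precursor_mismatches if k.placement else None),
              n_parental_blocks=(len(k.placement.parental_blocks) if k.placement else 0),
              parental_has_annotated_mirna=k.parental_has_annotated_mirna,
              note=k.note)
         for k in calls]))
    tally = tally_classes(calls)
    report["stages"]["classify"] = {
        "in": len(confirmed),
        "tally": {cls: {"n": n, "pct": pct} for cls, (n, pct) in tally.items()},
        "unclassified": sum(1 for k in calls if k.cls == "unclassified"),
    }

    # ---- conserve
    panels: dict[str, dict[str, str]] = {}
    odir = Path(config.inputs["ortholog_dir"])
    for sp in SPECIES_ORDER[1:]:
        f = odir / f"{sp}.fa"
        panels[sp] = rio.read_fasta(f).sequences if f.exists() else {}
    cons_rows = []
    for k in calls:
        c = k.candidate
        prec_seq = _precursor_seq(c)
        panel = {sp: panels[sp][c.mirna.id] for sp in panels if c.mirna.id in panels[sp]}
        call = call_conservation(c.mirna.id, prec_seq, panel,
                                 threshold=P["conservation_threshold"])
        row = dict(id=c.mirna.id, age=call.age)
        for sp in SPECIES_ORDER[1:]:
            row[f"identity_{sp}"] = round(call.identity[sp], 4) if sp in call.identity else None
            row[f"conserved_{sp}"] = call.conserved.get(sp)
        cons_rows.append(row)
    rio.write_tsv(out / "conservation.tsv", pd.DataFrame(cons_rows))
    report["stages"]["conserve"] = {
        "in": len(calls),
        "ages": {r["id"]: r["age"] for r in cons_rows},
    }

    # ---- dnds
    cds_orth = rio.read_fasta(config.inputs["cds_ortholog_fa"]).sequences
    sel_rows = []
    seen_rc = []
    for k in calls:
        rc = k.candidate.retrocopy
        if rc.id in seen_rc:
            continue
        seen_rc.append(rc.id)
        row = dict(retrocopy=rc.id, dN=None, dS=None, omega=None, p=None, regime="NA")
        orth = cds_orth.get(rc.id)
        orf1 = find_longest_orf(rc.sequence)
        orf2 = find_longest_orf(orth) if orth else None
        if orf1 and orf2:
            paln = align_protein(orf1[2], orf2[2])
            cds1 = rc.sequence[orf1[1][0] : orf1[1][1] - 3]
            cds2 = orth[orf2[1][0] : orf2[1][1] - 3]
            pairs = codon_align(paln, cds1, cds2)
            if len(pairs) >= 20:
                res = dnds_ng86(pairs, retrocopy_id=rc.id)
                res = test_neutrality(res, pairs, n_boot=P["dnds_boot"],
                                      seed=config.seed + 101)
                row.update(dN=res.dN, dS=res.dS, omega=res.omega, p=res.p_neutral,
                           regime=res.regime)
        sel_rows.append(row)
    rio.write_tsv(out / "selection.tsv", pd.DataFrame(_round_floats(sel_rows)))
    report["stages"]["dnds"] = {
        "in": len(seen_rc),
        "regimes": {r["retrocopy"]: r["regime"] for r in sel_rows},
    }

    # ---- express
    counts = rio.read_tsv(config.inputs["counts_tsv"]).set_index("feature")
    meta = rio.read_tsv(config.inputs["samples_tsv"])
    lengths = rio.read_tsv(config.inputs["lengths_tsv"]).set_index("feature")["length"]
    tpm = normalize(counts, lengths, "TPM")
    rio.write_tsv(out / "tpm.tsv", tpm.round(3).reset_index(names="feature"))
    med, breadth = summarize(tpm, meta)
    rio.write_tsv(out / "expression_summary.tsv",
                  med.round(3).assign(breadth=breadth).reset_index(names="feature"))
    tss_set = rio.read_bed(config.inputs["tss_bed"])
    ccre_set = rio.read_bed(config.inputs["ccre_bed"])
    retro_by_id = {r.id: r for r in retrocopies}
    exp_rows = []
    de_rows = []
    for k in calls:
        m = k.candidate.mirna
        tss = associate_tss(m.id, m.precursor, tss_set, window=P["tss_window"])
        host = retro_by_id[k.candidate.retrocopy.id]
        ccre_found, ccre_dist = associate_ccre(host.interval, ccre_set,
                                               window_bp=P["ccre_window"])
        exp_rows.append(dict(id=m.id, tss_found=tss.tss_found, tss_distance=tss.distance,
                             ccre_nearby=ccre_found, ccre_distance=ccre_dist))
        for mid, _iv, _seq in m.matures:
            if mid in tpm.index:
                u, p, st = tumor_vs_normal(tpm, meta, mid, cohort="cancer_cohort")
                de_rows.append(dict(feature=mid, U=u, p=p, stars=st,
                                    breadth=int(breadth.get(mid, 0))))
    rio.write_tsv(out / "tss_ccre.tsv", pd.DataFrame(exp_rows))
    rio.write_tsv(out / "tumor_vs_normal.tsv", pd.DataFrame(_round_floats(de_rows, 8)))
    report["stages"]["express"] = {
        "in": len(calls),
        "tss_found": sum(1 for r in exp_rows if r["tss_found"]),
        "ccre_nearby": sum(1 for r in exp_rows if r["ccre_nearby"]),
        "tumor_up_significant": sum(1 for r in de_rows if r["stars"]),
        "tested": len(de_rows),
    }

    # ---- targets + enrich
    utrs = rio.read_fasta(config.inputs["utrs_fa"]).sequences
    validated = rio.read_tsv(config.inputs["validated_tsv"])
    gene_sets = rio.read_gmt(config.inputs["gene_sets_gmt"])
    sites = []
    for k in calls:
        for mid, _iv, seq in k.candidate.mirna.matures:
            seq = seq or to_rna(_mature_seq(k.candidate, genome))
            sites.extend(scan_sites(mid, seq, utrs))
    site_df = pd.DataFrame([vars(s) for s in sites])
    rio.write_tsv(out / "target_sites.tsv", site_df)
    gene_table = merge_validated(sites, validated)
    rio.write_tsv(out / "target_genes.tsv", gene_table)
    query = sorted(set(gene_table.gene_id)) if len(gene_table) else []
    universe = sorted(utrs)
    enr = enrich(query, gene_sets, universe, fe_min=P["fe_min"],
                 fdr_max=P["fdr_max"]) if query else []
    rio.write_tsv(out / "enrichment.tsv", pd.DataFrame(_round_floats([vars(e) for e in enr])))
    report["stages"]["targets"] = {
        "sites": len(sites),
        "target_genes": len(set(gene_table.gene_id)) if len(gene_table) else 0,
        "enriched_sets": [e.set_id for e in enr if e.passed],
    }

    # ---- survive
    surv = rio.read_tsv(config.inputs["survival_tsv"])
    feat_cols = [c for c in surv.columns if c not in ("patient_id", "time", "event")]
    model = bootstrap_signature(surv, feat_cols, n_boot=P["surv_boot"],
                                keep_frac=P["keep_frac"], lam=P["cox_lambda"],
                                seed=config.seed + 202)
    sig_report = {"candidates": feat_cols, "signature": model.features,
                  "coefficients": model.coefficients}
    if model.features:
        ev = evaluate_signature(model, surv)
        sig_report.update(logrank_chi2=ev.chi2, logrank_p=ev.p,
                          median_survival_low=ev.median_low,
                          median_survival_high=ev.median_high)
        ev.km_low.assign(group="low").pipe(
            lambda lo: pd.concat([lo, ev.km_high.assign(group="high")])
        ).pipe(lambda df: rio.write_tsv(out / "km_curves.tsv", df.round(6)))
    report["stages"]["survive"] = _round_floats(sig_report, 8)

    report = _round_floats(report)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_text_report(out / "report.txt", report)
    return report


def _precursor_seq(candidate) -> str:
    from .classify import _spans_in_retro

    (p0, p1), _ = _spans_in_retro(candidate)
    if 0 <= p0 < p1 <= len(candidate.retrocopy.sequence):
        return candidate.retrocopy.sequence[p0:p1]
    raise ValueError(f"{candidate.id}: precursor outside retrocopy record")


def _mature_seq(candidate, genome) -> str:
    from .core import fetch

    return fetch(genome, candidate.mirna.matures[0][1])


def _write_text_report(path: Path, report: dict) -> None:
    lines = [f"retromir pipeline report (version {report['version']}, "
             f"config {report['config_hash']})", ""]
    for stage, data in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in data.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
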