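"""Seed-match target prediction and gene-set over-representation.

Canonical site grammar: the seed is mature positions 2-8 (5'->3'); a core
match is the reverse complement of the seed found in the 3'UTR (read
5'->3').  A core match followed immediately (3' side, opposite miRNA
position 1) by an 'A' is an 8mer-1a site; without that 'A' it is a 7mer-m8.
Each UTR position anchors at most one reported site, the stronger type.

Predicted targets are merged with experimentally validated interactions by
union (a validated gene with no predicted site is kept).  Enrichment of a
query gene list in GMT gene sets uses the hypergeometric upper tail with
Benjamini-Hochberg FDR; a set passes at fold enrichment > 1.5 and
FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import revcomp, to_rna


@dataclass
class TargetSite:
    utr_id: str
    mirna_id: str
    site_type: str          # 8mer-1a | 7mer-m8
    position: int           # 0-based 5' end of the core match in the UTR
    site_sequence: str


@dataclass
class EnrichmentRow:
    set_id: str
    k: int                  # query hits in the set
    K: int                  # set size (within the universe)
    n: int                  # query size
    N: int                  # universe size
    fold_enrichment: float
    p: float
    fdr: float
    passed: bool


def seed_core(mature_seq: str) -> str:
    """Reverse complement (RNA) of the seed, mature positions 2-8."""
    mature = to_rna(mature_seq)
    if len(mature) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature!r}")
    return to_rna(revcomp(mature[1:8]))


def scan_sites(mirna_id: str, mature_seq: str, utrs: dict[str, str]) -> list[TargetSite]:
    """All 8mer-1a / 7mer-m8 sites of one miRNA across a UTR set.

    Overlapping core matches are all reported; at a given position the
    8mer-1a call wins over 7mer-m8 (strongest-site convention).
    """
    core = seed_core(mature_seq)
    out: list[TargetSite] = []
    for utr_id in sorted(utrs):
        s = to_rna(utrs[utr_id])
        pos = s.find(core)
        while pos != -1:
            if pos + len(core) < len(s) and s[pos + len(core)] == "A":
                out.append(TargetSite(utr_id, mirna_id, "8mer-1a", pos, s[pos : pos + 8]))
            else:
                out.append(TargetSite(utr_id, mirna_id, "7mer-m8", pos, s[pos : pos + 7]))
            pos = s.find(core, pos + 1)
    return out


def merge_validated(predicted: list[TargetSite], validated: pd.DataFrame) -> pd.DataFrame:
    """Gene-level target table with evidence in {predicted, validated, both}.

    ``validated`` needs columns mirna_id and gene_id; union semantics, so
    validated genes without a predicted site are kept.
    """
    pred_pairs = {(s.mirna_id, s.utr_id) for s in predicted}
    val_pairs = (
        {(r.mirna_id, r.gene_id) for r in validated.itertuples(index=False)}
        if len(validated)
        else set()
    )
    rows = []
    for mid, gene in sorted(pred_pairs | val_pairs):
        in_p, in_v = (mid, gene) in pred_pairs, (mid, gene) in val_pairs
        evidence = "both" if (in_p and in_v) else "predicted" if in_p else "validated"
        n_sites = sum(1 for s in predicted if (s.mirna_id, s.utr_id) == (mid, gene))
        rows.append(dict(mirna_id=mid, gene_id=gene, evidence=evidence, n_sites=n_sites))
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "evidence", "n_sites"])


def bh_fdr(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone by
    construction, invariant to input order)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        prev = min(prev, p[i] * m / (rank + 1))
        q[i] = prev
    return q.tolist()


def enrich(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    fe_min: float = 1.5,
    fdr_max: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of the query in each gene set.

    p = P(X >= k) with X ~ Hypergeom(N, K, n); FE = (k/n)/(K/N).  Rows are
    sorted by (FDR, -FE, set id).  A query gene outside the universe is an
    error (listed), not silently dropped.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {stray}")
    if not query:
        raise ValueError("empty query")
    N, n = len(universe), len(query)
    rows = []
    for sid in sorted(gene_sets):
        members = gene_sets[sid] & universe
        K = len(members)
        k = len(query & members)
        fe = (k / n) / (K / N) if K else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append([sid, k, K, fe, p])
    fdrs = bh_fdr([r[4] for r in rows])
    out = [
        EnrichmentRow(set_id=sid, k=k, K=K, n=n, N=N, fold_enrichment=fe, p=p,
                      fdr=fdr, passed=bool(fe > fe_min and fdr < fdr_max))
        for (sid, k, K, fe, p), fdr in zip(rows, fdrs)
    ]
    out.sort(key=lambda r: (r.fdr, -r.fold_enrichment, r.set_id))
    return out
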