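"""Expression normalization, tissue summaries, TSS/cCRE evidence, and
tumor-vs-normal testing.

Counts are library-size normalized to RPM or (length-aware) TPM; per-tissue
medians and expression breadth summarize the normal-tissue panel; locus-level
transcription evidence comes from the nearest upstream TSS (strand-aware,
4 kb window) and nearby candidate cis-regulatory elements (20 kb window).
Differential expression between tumor and normal samples uses the
Mann-Whitney U test with the conventional star bands:
p in [0.01, 0.05] -> '*', [1e-4, 0.01) -> '**', < 1e-4 -> '***'.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Features x samples values plus sample metadata and a normalization tag."""

    values: pd.DataFrame
    meta: pd.DataFrame          # columns: sample, tissue, condition
    normalization: str = "raw"  # raw | RPM | TPM


@dataclass
class TSSAssociation:
    retromir_id: str
    tss_found: bool
    distance: int | None
    ccre_nearby: bool | None = None


def normalize(
    counts: pd.DataFrame, lengths: Mapping[str, float] | None, mode: str = "TPM"
) -> pd.DataFrame:
    """Reads-per-million or transcripts-per-million normalization.

    RPM = 1e6 * c / sum(c); TPM length-corrects first: 1e6 * (c/L) / sum(c/L).
    TPM columns sum to 1e6 (zero-depth samples become all-zero, with a
    warning).
    """
    if mode not in ("RPM", "TPM"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    x = counts.astype(float)
    if (x.values < 0).any():
        raise ValueError("negative counts")
    if mode == "TPM":
        if lengths is None:
            raise ValueError("TPM requires feature lengths")
        L = pd.Series({f: float(lengths[f]) for f in x.index})
        x = x.div(L, axis=0)
    depth = x.sum(axis=0)
    zero = depth == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-depth sample(s); columns left all-zero")
        depth = depth.replace(0, np.nan)
    out = 1e6 * x.div(depth, axis=1)
    out = out.fillna(0.0)
    out.attrs["normalization"] = mode
    return out


def summarize(values: pd.DataFrame, meta: pd.DataFrame, condition: str = "normal") -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature median per tissue and expression breadth.

    Breadth counts tissues whose median exceeds 0; only samples of the
    requested condition contribute.
    """
    m = meta[meta.condition == condition]
    medians = {}
    for tissue, grp in m.groupby("tissue", sort=True):
        medians[tissue] = values[grp["sample"]].median(axis=1)
    med = pd.DataFrame(medians)
    breadth = (med > 0).sum(axis=1)
    return med, breadth


def associate_tss(
    retromir_id: str,
    locus: GenomicInterval,
    tss_set: Sequence[GenomicInterval],
    window: int = 4000,
) -> TSSAssociation:
    """Nearest TSS upstream of the locus 5' end, same strand, within the
    window.  Upstream respects transcription orientation: positions before
    the start on '+', after the end on '-'."""
    five_prime = locus.start if locus.strand == "+" else locus.end - 1
    best: int | None = None
    for t in tss_set:
        if t.chrom != locus.chrom or (t.strand != "." and t.strand != locus.strand):
            continue
        pos = t.start
        dist = five_prime - pos if locus.strand == "+" else pos - five_prime
        if 0 <= dist <= window and (best is None or dist < best):
            best = dist
    return TSSAssociation(retromir_id=retromir_id, tss_found=best is not None, distance=best)


def associate_ccre(
    locus: GenomicInterval, ccres: Sequence[GenomicInterval], window_bp: int = 20000
) -> tuple[bool, int | None]:
    """Whether any cCRE lies within ``window_bp`` of the locus (strand
    ignored); returns (found, distance), distance 0 when overlapping."""
    best: int | None = None
    for c in ccres:
        if c.chrom != locus.chrom:
            continue
        if c.end > locus.start and c.start < locus.end:
            d = 0
        elif c.end <= locus.start:
            d = locus.start - c.end + 1
        else:
            d = c.start - locus.end + 1
        if d <= window_bp and (best is None or d < best):
            best = d
    return best is not None, best


def stars(p: float) -> str:
    """Significance stars: p<=0.05&>=0.01 '*', <0.01&>=1e-4 '**', <1e-4 '***'."""
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups are small (min n <= 8) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Two identical constant groups are a defined edge case
    (U = n1*n2/2, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def tumor_vs_normal(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    feature: str,
    cohort: str | None = None,
) -> tuple[float, float, str]:
    """Mann-Whitney test of one feature, tumor vs normal samples (optionally
    restricted to one cohort/tissue); returns (U, p, stars)."""
    m = meta if cohort is None else meta[meta.tissue == cohort]
    tum = m.loc[m.condition == "tumor", "sample"]
    nor = m.loc[m.condition == "normal", "sample"]
    u, p = mann_whitney(values.loc[feature, tum].values, values.loc[feature, nor].values)
    return u, p, stars(p)
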