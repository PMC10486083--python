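"""Conservation calls, age assignment, and selection-regime inference.

Conservation follows a strict identity rule (conserved iff pairwise identity
strictly exceeds 80%, terminal gaps excluded so 5' truncation is not
penalized).  Selection on retrocopy reading frames uses the Nei-Gojobori
(1986) counting method: per-codon enumeration of synonymous/nonsynonymous
sites, pathway-averaged difference counts for multi-hit codons, and the
Jukes-Cantor multiple-hit correction

    d = -3/4 * ln(1 - 4 p / 3).

Significance of omega = dN/dS against neutrality (omega = 1) comes from a
codon bootstrap rather than a likelihood-ratio test: codon columns are
resampled with replacement and the two-sided p-value is twice the fraction
of resamples falling on the far side of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .align import AlignmentResult, align_global

SPECIES_ORDER = ("human", "chimpanzee", "gorilla", "orangutan", "rhesus", "marmoset")

_STOPS = set(standard_dna_table.stop_codons)
_AA = dict(standard_dna_table.forward_table)
_BASES = "ACGT"


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _AA[codon]


# ------------------------------------------------------------ conservation

@dataclass
class ConservationCall:
    """Per-species identity/conservation of one retro-miR, plus its age."""

    retromir_id: str
    identity: dict[str, float] = field(default_factory=dict)  # absent species omitted
    conserved: dict[str, bool] = field(default_factory=dict)
    age: str | None = None


def call_conservation(
    retromir_id: str,
    retromir_seq: str,
    ortholog_panel: dict[str, str],
    threshold: float = 0.80,
    species_order: tuple[str, ...] = SPECIES_ORDER,
) -> ConservationCall:
    """Score a retro-miR against per-species ortholog sequences.

    ``conserved`` is strict: identity must be *greater than* the threshold.
    Species missing from the panel are recorded as absent (omitted).
    """
    call = ConservationCall(retromir_id)
    for sp in species_order:
        if sp == species_order[0] or sp not in ortholog_panel:
            continue
        res = align_global(retromir_seq, ortholog_panel[sp])
        ident = res.identity(exclude_end_gaps=True)
        call.identity[sp] = ident
        call.conserved[sp] = ident > threshold
    call.age = assign_age(call, species_order)
    return call


def assign_age(call: ConservationCall, species_order: tuple[str, ...] = SPECIES_ORDER) -> str:
    """Most distal taxon (along the ordered species list) in which the
    sequence is conserved.  The reference species itself always counts, so a
    sequence conserved nowhere else is labelled ``human-specific``; one
    conserved out to the last species is labelled ``all primates``."""
    distal = species_order[0]
    for sp in species_order[1:]:
        if call.conserved.get(sp, False):
            distal = sp
    if distal == species_order[0]:
        return f"{species_order[0]}-specific"
    if distal == species_order[-1]:
        return "all primates"
    return distal


# ------------------------------------------------------------ ORFs and codon alignment

def find_longest_orf(
    seq: str, six_frame: bool = False, min_codons: int = 20
) -> tuple[int, tuple[int, int], str] | None:
    """Longest ATG-to-stop open reading frame.

    Searches forward frames +1/+2/+3 (and the reverse strand with
    ``six_frame=True``, frames -1/-2/-3 reported with coordinates on the
    given sequence).  Ties go to the 5'-most start.  Returns
    ``(frame, (start, end), protein)`` with a half-open nt span including
    the stop codon, or None when no ORF reaches ``min_codons`` codons.
    """
    from .core import revcomp

    best: tuple[int, tuple[int, int], str] | None = None

    def scan(s: str, frame_label: int, reverse: bool) -> None:
        nonlocal best
        offset = abs(frame_label) - 1
        i = offset
        n = len(s)
        while i + 3 <= n:
            if s[i : i + 3] == "ATG":
                j = i
                protein = []
                while j + 3 <= n:
                    codon = s[j : j + 3]
                    if codon in _STOPS:
                        if len(protein) >= min_codons:
                            span = (i, j + 3)
                            if reverse:
                                span = (n - span[1], n - span[0])
                            cand = (frame_label, span, "".join(protein))
                            if best is None or len(cand[2]) > len(best[2]) or (
                                len(cand[2]) == len(best[2]) and cand[1][0] < best[1][0]
                            ):
                                best = cand
                        break
                    protein.append(_translate_codon(codon))
                    j += 3
                i = j + 3 if j > i else i + 3
            else:
                i += 3

    s = seq.upper().replace("U", "T")
    for f in (1, 2, 3):
        scan(s, f, reverse=False)
    if six_frame:
        rc = revcomp(s)
        for f in (1, 2, 3):
            scan(rc, -f, reverse=True)
    return best


def codon_align(
    protein_aln: AlignmentResult, cds1: str, cds2: str
) -> list[tuple[str, str]]:
    """Back-translate a protein alignment onto its source CDSs.

    Each aligned amino-acid column is mapped to its codon pair; gap columns
    are dropped.  The proteins must translate exactly from the CDSs.
    """
    cds1 = cds1.upper().replace("U", "T")
    cds2 = cds2.upper().replace("U", "T")
    pairs: list[tuple[str, str]] = []
    i1 = i2 = 0
    for col, (a, b) in enumerate(zip(protein_aln.query_aln, protein_aln.subject_aln)):
        c1 = c2 = None
        if a != "-":
            c1 = cds1[3 * i1 : 3 * i1 + 3]
            if len(c1) < 3 or _translate_codon(c1) != a:
                raise ValueError(
                    f"codon_align: CDS1 does not translate to aligned protein at column {col}"
                )
            i1 += 1
        if b != "-":
            c2 = cds2[3 * i2 : 3 * i2 + 3]
            if len(c2) < 3 or _translate_codon(c2) != b:
                raise ValueError(
                    f"codon_align: CDS2 does not translate to aligned protein at column {col}"
                )
            i2 += 1
        if c1 is not None and c2 is not None:
            pairs.append((c1, c2))
    return pairs


# ------------------------------------------------------------ NG86

@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.  S + N = 3 for every sense codon.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _translate_codon(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pairwise_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts between
    two sense codons (all orders of the differing positions, pathways through
    stop codons excluded when any stop-free pathway exists)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                via_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((via_stop, steps))
    usable = [steps for via, steps in paths if not via] or [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if b in _STOPS or a in _STOPS:
                nd += 1  # stop transitions (fallback pathways only) count nonsynonymous
            elif _translate_codon(a) == _translate_codon(b):
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


@dataclass
class SelectionResult:
    """dN/dS summary for one retrocopy reading frame."""

    retrocopy_id: str = ""
    orf: tuple[int, tuple[int, int], str] | None = None
    dN: float | None = None
    dS: float | None = None
    omega: float | None = None
    p_neutral: float | None = None
    regime: str = "NA"  # purifying | positive | neutral/NS | NA


def _per_codon_stats(codon_pairs: list[tuple[str, str]]) -> np.ndarray:
    """(n, 4) array of per-codon-pair [S_sites, N_sites, Sd, Nd]."""
    rows = []
    for c1, c2 in codon_pairs:
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        sd, nd = pairwise_differences(c1, c2)
        rows.append(((s1 + s2) / 2, (n1 + n2) / 2, sd, nd))
    return np.asarray(rows, dtype=float)


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _omega_from_stats(stats: np.ndarray) -> tuple[float | None, float | None, float | None]:
    S, N, Sd, Nd = stats.sum(axis=0)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc(pS), _jc(pN)
    if dS is None or dN is None:
        return dN, dS, None  # saturation
    if dS == 0.0:
        return dN, dS, None  # omega undefined
    return dN, dS, dN / dS


def dnds_ng86(codon_pairs: list[tuple[str, str]], retrocopy_id: str = "") -> SelectionResult:
    """Nei-Gojobori (1986) dN and dS with Jukes-Cantor correction.

    Requires at least 20 codon pairs.  omega is undefined (None) when dS = 0
    or when either proportion reaches the JC saturation bound of 3/4.
    """
    if len(codon_pairs) < 20:
        raise ValueError(f"dnds_ng86: need >= 20 codon pairs, got {len(codon_pairs)}")
    stats = _per_codon_stats(codon_pairs)
    dN, dS, omega = _omega_from_stats(stats)
    return SelectionResult(retrocopy_id=retrocopy_id, dN=dN, dS=dS, omega=omega,
                           regime="NA" if omega is None else "neutral/NS")


def test_neutrality(
    result: SelectionResult,
    codon_pairs: list[tuple[str, str]],
    n_boot: int = 1000,
    seed: int = 0,
) -> SelectionResult:
    """Codon-bootstrap test of omega = 1; fills p_neutral and regime.

    Resamples codon columns with replacement; the two-sided p-value is twice
    the fraction of resamples whose omega lands on the far side of 1 from
    the point estimate (resamples with dS = 0 but dN > 0 count as omega > 1;
    fully invariant resamples are dropped).
    """
    out = SelectionResult(**vars(result))
    if result.omega is None:
        out.regime = "NA"
        return out
    stats = _per_codon_stats(codon_pairs)
    rng = np.random.default_rng(seed)
    n = stats.shape[0]
    omegas = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        dN, dS, om = _omega_from_stats(stats[idx])
        if om is not None:
            omegas.append(om)
        elif dS == 0.0 and dN is not None and dN > 0:
            omegas.append(math.inf)
        # dN = dS = 0 or saturated: uninformative, dropped
    omegas = np.asarray(omegas)
    if omegas.size == 0:
        out.regime = "NA"
        return out
    if result.omega < 1:
        far = float(np.mean(omegas >= 1.0))
    else:
        far = float(np.mean(omegas <= 1.0))
    p = min(1.0, 2.0 * far)
    out.p_neutral = p
    if p <= 0.05 and result.omega < 1:
        out.regime = "purifying"
    elif p <= 0.05 and result.omega > 1:
        out.regime = "positive"
    else:
        out.regime = "neutral/NS"
    return out
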