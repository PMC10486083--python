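"""Hairpin assessment by base-pair maximization.

A deterministic Nussinov-style dynamic program stands in for thermodynamic
MFE folding: it maximizes the number of nested Watson-Crick + GU pairs with
a minimum hairpin loop, then a traceback with fixed tie-breaking yields one
structure.  ``assess_hairpin`` turns that structure into a yes/no stem-loop
call via three explicit thresholds (stem length, terminal loop size, paired
fraction) -- the criteria a curator would apply to a drawn fold.

Not modelled: free-energy parameters, pseudoknots, suboptimal ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import to_rna

#: Watson-Crick RNA pairs
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
#: canonical RNA pairs, GU wobble included.  Note that with wobble pairs the
#: maximal pair count is not reverse-complement symmetric (G.U maps to C.A).
PAIRS = WC_PAIRS | {("G", "U"), ("U", "G")}

_ALPHABET = set("ACGU")


@dataclass
class FoldResult:
    """One maximal-pairing nested structure and its summary metrics."""

    sequence: str
    dotbracket: str
    pairs: list[tuple[int, int]]
    n_pairs: int
    longest_helix: int
    loop_len: int
    paired_fraction: float


def _pair_matrix(seq: str, pairs=PAIRS) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    comp = np.zeros((len(seq), len(seq)), dtype=bool)
    for a, b in pairs:
        comp |= (arr[:, None] == a.encode()) & (arr[None, :] == b.encode())
    return comp


def fold_max_pairs(seq: str, min_loop: int = 3, allow_gu: bool = True) -> FoldResult:
    """Maximize nested base pairs (Nussinov DP) with hairpin loops >= min_loop.

    Traceback is deterministic: pairing (i, j) is preferred over dropping an
    end, dropping the left end over the right, and bifurcations split at the
    smallest split point.
    """
    rna = to_rna(seq)
    bad = set(rna) - _ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n = len(rna)
    if n < min_loop + 2:
        return FoldResult(rna, "." * n, [], 0, 0, 0, 0.0)

    can_pair = _pair_matrix(rna, PAIRS if allow_gu else WC_PAIRS)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i, j] over [i, j] inclusive
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = max(dp[i + 1, j], dp[i, j - 1])
            if can_pair[i, j]:
                best = max(best, dp[i + 1, j - 1] + 1)
            # bifurcation: max over k of dp[i, k] + dp[k+1, j]
            if span > 1:
                bif = int(np.max(dp[i, i : j] + dp[i + 1 : j + 1, j]))
                best = max(best, bif)
            dp[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1 or dp[i, j] == 0:
            continue
        if can_pair[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if dp[i, k] + dp[k + 1, j] == dp[i, j]:
                    stack.append((k + 1, j))
                    stack.append((i, k))
                    break

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    helix, loop = _helix_metrics(pairs)
    return FoldResult(rna, "".join(db), pairs, len(pairs), helix, loop, 2 * len(pairs) / n)


def _helix_metrics(pairs: list[tuple[int, int]], max_gap: int = 6) -> tuple[int, int]:
    """Longest stacked helix (pairs in one arm, internal loops <= max_gap nt
    allowed between segments) and the terminal-loop length of that helix."""
    if not pairs:
        return 0, 0
    # children[p] = outermost pairs directly nested inside p
    pairs = sorted(pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            roots.append(p)
        stack.append(p)

    # maximal perfectly stacked runs ("segments"); a gap junction of up to
    # max_gap nt may join two segments, but only when both sides hold >= 2
    # stacked pairs -- a ladder of isolated pairs is not a helix
    segments: list[list[tuple[int, int]]] = []
    seg_of: dict[tuple[int, int], int] = {}
    for p in pairs:
        if segments and segments[-1][-1] == (p[0] - 1, p[1] + 1):
            segments[-1].append(p)
        else:
            segments.append([p])
        seg_of[p] = len(segments) - 1

    # seg_next[s] = segment directly continuing s through an allowed junction
    seg_next: dict[int, int] = {}
    for si, seg in enumerate(segments):
        p = seg[-1]
        kids = children[p]
        if len(kids) != 1:
            continue
        c = kids[0]
        gap = (c[0] - p[0] - 1) + (p[1] - c[1] - 1)
        ci = seg_of[c]
        if gap == 0 or (gap <= max_gap and len(seg) >= 2 and len(segments[ci]) >= 2):
            seg_next[si] = ci

    chain_len: dict[int, int] = {}
    chain_tip: dict[int, int] = {}
    for si in range(len(segments) - 1, -1, -1):
        if si in seg_next:
            chain_len[si] = len(segments[si]) + chain_len[seg_next[si]]
            chain_tip[si] = chain_tip[seg_next[si]]
        else:
            chain_len[si] = len(segments[si])
            chain_tip[si] = si
    best = max(chain_len, key=lambda s: chain_len[s])
    tip_pair = segments[chain_tip[best]][-1]
    return chain_len[best], tip_pair[1] - tip_pair[0] - 1


def assess_hairpin(
    seq: str,
    min_stem: int = 18,
    max_loop: int = 40,
    min_paired_frac: float = 0.4,
    min_loop: int = 3,
) -> tuple[bool, FoldResult]:
    """Decide whether a sequence folds into a miRNA-like stem-loop.

    True iff the maximal-pairing fold has a helix of >= ``min_stem`` pairs
    (internal loops up to 6 nt allowed), a terminal loop <= ``max_loop`` nt,
    and a paired fraction >= ``min_paired_frac``.
    """
    if not 40 <= len(seq) <= 200:
        warnings.warn(
            f"assess_hairpin: length {len(seq)} outside the recommended 40-200 nt range",
            stacklevel=2,
        )
    fr = fold_max_pairs(seq, min_loop=min_loop)
    ok = (
        fr.longest_helix >= min_stem
        and fr.loop_len <= max_loop
        and fr.paired_fraction >= min_paired_frac
    )
    return ok, fr
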