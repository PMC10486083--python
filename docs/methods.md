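# Methods

This note records the models, conventions, parameter choices, and known
limitations behind `retromir`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open on named chromosomes; GTF and
GFF3 (1-based inclusive) are converted exactly once at the I/O boundary and
back on write.  Malformed lines fail with the file name and 1-based line
number.  Overlaps are strand-aware by default (a retro-miR and its host
retrocopy are expected to be co-oriented, since the miRNA rides on the mRNA
sense strand); unstranded features (`.`, used by repeats and cCREs) are
compatible with both strands, and `stranded=False` disables the check
because the strandedness of the original coordinate intersection is not
documented.

## Hairpin assessment

RNA secondary structure is assessed by base-pair maximization (Nussinov
dynamic programming) over Watson–Crick and GU pairs with hairpin loops of at
least 3 nt, instead of a thermodynamic minimum-free-energy fold.  This is a
deliberate trade: the kernel is deterministic, dependency-free, exactly
testable against exhaustive enumeration, and sufficient to discriminate
planted inverted repeats from background at this scale.  It does not produce
ΔG values, ensembles, or pseudoknots, and a maximal-pairing structure can
differ from the MFE structure for the same sequence.

The traceback is deterministic (pair the outer bases when optimal, else drop
the left end, else the right, else bifurcate at the smallest split).  A
structure is called a stem-loop when:

- the longest helix holds ≥ 18 pairs, where a helix is a chain of stacked
  pair runs; runs may be joined across internal loops of ≤ 6 nt, but only
  when both sides of the junction hold ≥ 2 stacked pairs (a ladder of
  isolated pairs joined by loops is not a helix — without this rule about a
  fifth of random 80-mers pass, with it about 2%);
- the terminal loop of that helix is ≤ 40 nt;
- at least 40% of bases are paired.

With GU wobble allowed the maximal pair count is not symmetric under reverse
complement (G·U maps to C·A); `allow_gu=False` restores the symmetry and is
used by the property test.

## Discovery and classification

Candidates are (precursor, retrocopy) pairs overlapping by ≥ 5 bp.  The
mobile-element exclusion is automated: a candidate whose precursor is ≥ 50%
covered by annotated repeats is flagged and written to a review table, never
silently dropped.  Folding confirmation tolerates up to 10% ambiguity
characters (replaced by non-pairing A); more is an error.

For classification the precursor plus up to 60 nt of retrocopy flank is
aligned locally (match +1, mismatch −1, gap open −2, extend −1) to the
spliced parental mRNA; the flanks anchor the placement even when the
precursor itself is heavily mutated (the de novo class).  Placement identity
is matches over precursor length *plus gap columns inside the precursor* —
with gap credit a scrambled precursor reaches the ~65% identity a longest
common subsequence provides and would pass the 60% placeability cutoff.
The placed span is projected through the exon chain to genomic blocks, and
the cascade is:

1. **EJ** — ≥ 2 blocks separated by ≥ 30 bp (a real intron, not an alignment
   artifact) *and* mature mismatches ≤ 1.  The mismatch condition matters:
   a de novo hairpin planted in a 3'UTR can legitimately straddle an exon
   junction, and structural evidence alone would mislabel it; exon-junction
   retro-miRs are near-exact copies of the junction-spanning region.
2. **R** — an annotated parental exonic miRNA overlaps the placed blocks and
   the mature has ≤ 1 mismatch ("exact copies" relaxed by one, since
   retroduplicated members may drift in the outer seed region).
3. **N** — mature mismatches ≥ 2 and the equivalent parental mRNA region
   fails the stem-loop call.

Everything else is reported as `unclassified` — a first-class category.

The DNA-duplication counter-screen aligns each gene's protein (BLOSUM62,
affine gaps −11/−1, local) against all six reading frames of the genome,
masking the gene's own locus so a co-optimal duplicate in the same frame is
not shadowed by the self-hit; a call requires score / self-score ≥ 0.7.  The
search is exhaustive over frames — correctness over speed at toy-genome
scale; it is not a seeded heuristic search and does not scale to mammalian
genomes.

## Conservation and selection

Conservation is computed on the precursor sequence against per-species
ortholog panels using global alignment identity with terminal gap columns
excluded (truncation is not divergence).  "Conserved" is strict: identity
must exceed 0.80.  Age is the most distal conserved taxon along
human → chimpanzee → gorilla → orangutan → rhesus → marmoset, with
human-only labelled `human-specific` and full-depth conservation
`all primates`.  Absent species are recorded as absent, not as 0 identity.

Selection inference replaces maximum-likelihood codon models with the
Nei–Gojobori (1986) counting method: per-codon synonymous site fractions by
enumeration of the nine single-nucleotide neighbours (changes to stop codons
count as nonsynonymous; S + N = 3 per sense codon, asserted over all 61),
pathway-averaged difference counts for multi-hit codons (pathways through
stop codons excluded when a stop-free pathway exists), and Jukes–Cantor
correction d = −¾ ln(1 − 4p/3), undefined at p ≥ ¾ (saturation → NA).
Significance against ω = 1 is a codon bootstrap (default 1000 resamples):
the two-sided p is twice the fraction of resamples on the far side of 1
from the point estimate; resamples with dS = 0 but dN > 0 count as ω > 1
and fully invariant resamples are dropped.  This is the package's largest
stated deviation from likelihood-ratio testing; the comparable output — the
purifying / positive / neutral-NS / NA regime label — is preserved.  ORF
search runs on the three forward frames by default (retrocopy orientation
is known); `six_frame=True` adds the reverse strand.

## Expression, targets, enrichment

TPM = 10⁶·(c/L)/Σ(c/L); RPM omits the length correction.  Zero-depth
samples normalize to all-zero columns with a warning.  Expression breadth
counts tissues whose per-tissue median exceeds 0.  TSS association looks
upstream of the precursor 5' end on the same strand within 4000 bp; cCRE
association is strand-blind within 20 kb (the window is exposed as a
parameter).  Tumor-vs-normal testing is a two-sided Mann–Whitney U — exact
when both groups are ≤ 8 and tie-free, otherwise the normal approximation
with tie and continuity corrections — with star bands
\* p ∈ [0.01, 0.05], \*\* p ∈ [10⁻⁴, 0.01), \*\*\* p < 10⁻⁴.

Seed sites: seed = mature positions 2–8; a core match is the reverse
complement of the seed in the UTR; an immediately-3' A makes it an 8mer-1a,
otherwise 7mer-m8 (the strongest type wins at a position; overlapping
matches are all reported).  Context++ scoring, 6mer and 3'-compensatory
sites are out of scope.  Validated interactions are merged by union.
Enrichment is the hypergeometric upper tail P(X ≥ k) with
FE = (k/n)/(K/N), BH-adjusted across sets; the default universe is all
genes carrying a UTR in the input.

## Survival signatures

The Cox partial likelihood uses Breslow tie handling and an L2 penalty
scaled by cohort size — the objective is ℓ(β) − n·λ‖β‖²/2 — so that
duplicating every patient leaves β̂ exactly invariant (with an unscaled
penalty it would not be).  Newton–Raphson with step-halving, convergence on
relative log-likelihood change < 10⁻⁸.  Inputs are standardized log1p
expressions.

The signature rule bootstraps the fit (default 100 resamples with
replacement) and keeps a feature when its coefficient sign is stable in
≥ 80% of resamples *and* its 99% bootstrap percentile interval excludes
zero.  Sign consistency alone is not a null-calibrated filter: a null
feature's bootstrap sign follows the sign of its full-sample noise estimate,
so consistency ≥ 0.8 occurs for roughly four in ten null features; the
interval condition restores the intended behaviour (mostly empty signatures
on null cohorts, while a ln 2 effect at n = 200 is retained essentially
always).  Scores are Σβᵢzᵢ; the cohort splits at the median score with ties
to the low group; arms are compared by the product-limit estimator and the
standard O−E log-rank test (df = 1).

## The synthetic-data generator

The generator emulates every input format the pipeline consumes and records
every planted fact in a truth ledger.  Defaults (the study conditions):
24 genes of 2–4 exons (5'UTR 60 nt ending in an in-frame stop so the
longest ORF is pinned to the CDS; CDS 120–180 codons; 3'UTR 220 nt; introns
80–300 nt; random gene strands), 15 retrocopies (4 R + 4 EJ + 4 N plants,
3 background, plus one repeat-decoy miRNA), point mutation rate 0 and no
truncation (so R/EJ copies are exact and truth scoring is exact), hairpins
of 24-bp stem + 8-nt A/C loop.  Retrocopy "insertion" appends to a
dedicated chromosome between random spacers, keeping all previously
assigned coordinates valid; insertion strands are random.

Class-specific construction: R parents carry an annotated exonic miRNA in
the 3'UTR; EJ parents have the hairpin written across a forced exon
junction 20–36 nt into the precursor (so it is split in the genome but
contiguous in the spliced mRNA, and deliberately *not* annotated in the
parent); N plants pick the 3'UTR window whose 3' arm is already most
complementary to its 5' arm and edit only the 3' arm (keeping the natural
loop) — the minimal mutational path to a hairpin, which is both the
realistic origin model and what keeps the planted precursor placeable on
its parent (~10–14 substitutions rather than ~22 for a random window).
Planted hairpins and parental windows are rejection-checked against the
assessor at plant time, so the generator's contracts hold by construction.

Ortholog panels draw a random age per retro-miR; species within the age get
divergence U(0.02, 0.10), the first species beyond it is present-but-
diverged (d = 0.30) with probability 0.5, the rest are absent.  Draws are
re-sampled (≤ 50 times) until the realized substitution fraction matches
the planted regime with margin (< 0.18 or > 0.22), so ledger semantics are
exact rather than probabilistic.  Retrocopy CDS orthologs evolve under a
planted ω regime (alternating 0.1 and 1.0; one proposal per codon position;
stop codons and the start codon protected) with 3% flank divergence — this
is what the pipeline's dN/dS stage consumes.

Expression: negative-binomial counts (var = μ + 0.3μ²) with per-feature
lognormal baselines, 70% tissue presence, a 4× lognormal-noised tumor fold
on six retro-miR matures, and one mature silent in all normal samples but
expressed in tumors.  Because TPM is compositional, the planted
overexpression slightly *depresses* the normalized values of unchanged
features in tumor samples — a genuine property of library-size
normalization, visible as significant down-shifts of some null features;
the type-I-error calibration uses fold = 1 throughout and is unaffected.
Survival: times ~ Exp(h₀·e^{βz}) with h₀ = 1/1000 per day, β = ln 2 on one
of five features, independent exponential censoring at ≈ 25%.  UTRs
(80 × 300 nt) are rejection-sampled to contain no seed core of *any*
retro-miR mature, then sites are planted (6 genes × 8mer-1a, 4 × 7mer-m8
for each of three matures) and re-scanned so ledger counts are exact; the
80-gene universe keeps the planted targets a minority, which is what makes
fold enrichment > 1.5 attainable for the planted pathway set.

What the generator does not emulate: indels in the default model (an indel
mode exists but is excluded from truth-scored runs), L1 insertion mechanics
(target-site duplications, poly-A tails), sequencing reads, batch effects,
and realistic genome scale.  Passing on synthetic data therefore
demonstrates the pipeline's internal correctness and calibration, not
performance on real genomes with repeat-rich contexts, paralogy, or
alignment ambiguity.

## Problem sizes

Default analyses run on the scales above: folding oracles on ≤ 12-mers
(10⁴ cases), NG86 brute-force checks on 50-codon pairs, regime recovery at
200 codons × 50 replicates with 1000-resample bootstraps, calibration at
500 (Mann–Whitney) and 200 (log-rank) replicates, and survival recovery on
20 cohorts of 200 patients — sizes at which every check completes in
seconds to a few minutes on one CPU while keeping the statistical targets
(3 SE bands, ≥ 90/95% recovery) meaningful.

## Determinism

Every stochastic component takes a seed or `numpy.random.Generator`; the
pipeline derives stage seeds from the config seed, reports contain no
timestamps, and identical configs produce byte-identical reports (the
config hash is embedded).  The hash covers inputs, parameters, seed and
output directory.
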