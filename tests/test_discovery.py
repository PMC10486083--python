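"""Candidate discovery, repeat exclusion, folding confirmation, and the
DNA-duplication counter-screen."""

import numpy as np
import pytest

from retromir.core import GenomicInterval, MiRNARecord, RetrocopyRecord, SeqRecordSet
from retromir.discovery import (
    confirm_hairpin,
    exclude_repeats,
    find_candidates,
    find_dna_duplications,
)


def mk_mirna(mid, start, end, chrom="chr1", strand="+"):
    return MiRNARecord(id=mid, precursor=GenomicInterval(chrom, start, end, strand), matures=[])


def mk_retro(rid, start, end, chrom="chr1", strand="+"):
    return RetrocopyRecord(id=rid, interval=GenomicInterval(chrom, start, end, strand),
                           parental_gene_id="g", parental_transcript_id="t",
                           sequence="A" * (end - start))


class TestFindCandidates:
    def test_overlap_threshold_boundary(self):
        m = mk_mirna("m", 1000, 1080)
        assert len(find_candidates([m], [mk_retro("r", 1075, 2000)])) == 1   # exactly 5
        assert len(find_candidates([m], [mk_retro("r", 1076, 2000)])) == 0   # 4 bp

    def test_contained_precursor_full_overlap(self):
        m = mk_mirna("m", 1000, 1080)
        c = find_candidates([m], [mk_retro("r", 900, 2000)])
        assert c[0].overlap_bp == 80

    def test_empty_inputs(self):
        assert find_candidates([], []) == []

    def test_matches_bruteforce_all_pairs(self, rng):
        mirnas = [mk_mirna(f"m{i}", s, s + int(rng.integers(60, 120)),
                           chrom=f"chr{int(rng.integers(1, 3))}")
                  for i, s in enumerate(rng.integers(0, 50000, size=300))]
        retros = [mk_retro(f"r{i}", s, s + int(rng.integers(300, 2000)),
                           chrom=f"chr{int(rng.integers(1, 3))}")
                  for i, s in enumerate(rng.integers(0, 50000, size=300))]
        got = {(c.mirna.id, c.retrocopy.id, c.overlap_bp)
               for c in find_candidates(mirnas, retros)}
        brute = set()
        for m in mirnas:
            for r in retros:
                if m.precursor.chrom != r.interval.chrom:
                    continue
                ov = min(m.precursor.end, r.interval.end) - max(m.precursor.start, r.interval.start)
                if ov >= 5:
                    brute.add((m.id, r.id, ov))
        assert got == brute

    def test_deterministic_order(self):
        ms = [mk_mirna("b", 100, 180), mk_mirna("a", 100, 180)]
        rs = [mk_retro("r", 0, 1000)]
        assert [c.mirna.id for c in find_candidates(ms, rs)] == ["a", "b"]


class TestExcludeRepeats:
    def cand(self):
        return find_candidates([mk_mirna("m", 100, 180)], [mk_retro("r", 0, 1000)])

    def test_majority_repeat_flagged(self):
        kept, review = exclude_repeats(self.cand(), [GenomicInterval("chr1", 120, 180, ".")])
        assert not kept and len(review) == 1 and review[0].repeat_overlap

    def test_boundary_exactly_half_flagged(self):
        kept, review = exclude_repeats(self.cand(), [GenomicInterval("chr1", 100, 140, ".")])
        assert len(review) == 1  # 40/80 >= 0.5

    def test_no_overlap_kept(self):
        kept, review = exclude_repeats(self.cand(), [GenomicInterval("chr1", 500, 600, ".")])
        assert len(kept) == 1 and not review

    def test_union_not_double_counted(self):
        reps = [GenomicInterval("chr1", 100, 130, "."), GenomicInterval("chr1", 110, 139, ".")]
        kept, review = exclude_repeats(self.cand(), reps)  # union covers 39 < 40
        assert len(kept) == 1


class TestConfirmHairpin:
    def test_planted_hairpin_confirmed(self, sim_default):
        from retromir.discovery import find_candidates

        cands = find_candidates(sim_default.retro_mirnas, sim_default.retrocopies)
        for c in cands:
            confirm_hairpin(c, sim_default.genome)
            assert c.hairpin_ok

    def test_random_sequences_usually_rejected(self, rng):
        genome = SeqRecordSet({"chr1": "".join(rng.choice(list("ACGT"), 200 * 90))})
        hits = 0
        n = 200
        for i in range(n):
            m = mk_mirna("m", i * 90, i * 90 + 80)
            c = find_candidates([m], [mk_retro("r", 0, 200 * 90)])[0]
            confirm_hairpin(c, genome)
            hits += c.hairpin_ok
        assert hits < 0.2 * n

    def test_too_many_ambiguous_chars_rejected(self):
        genome = SeqRecordSet({"chr1": "N" * 100})
        c = find_candidates([mk_mirna("m", 0, 80)], [mk_retro("r", 0, 100)])[0]
        with pytest.raises(ValueError, match="non-nucleotide"):
            confirm_hairpin(c, genome)


class TestDnaDuplications:
    @pytest.fixture()
    def dup_genome(self, rng):
        from retromir.simulate import _rand_sense_codons

        cds = "ATG" + _rand_sense_codons(rng, 60) + "TAA"
        spacer = lambda n: "".join(rng.choice(list("ACGT"), n))
        chrom = spacer(100) + cds + spacer(150) + cds + spacer(100)
        own = GenomicInterval("chr1", 100, 100 + len(cds), "+")
        from retromir.selection import find_longest_orf

        orf = find_longest_orf(cds, min_codons=20)
        return SeqRecordSet({"chr1": chrom}), {"g1": (orf[2], own)}, len(cds)

    def test_exact_copy_called_with_ratio_one(self, dup_genome):
        genome, prots, _ = dup_genome
        calls = find_dna_duplications(prots, genome)
        assert calls and max(c.score_ratio for c in calls) == pytest.approx(1.0)
        # the duplicate locus, not the gene's own
        assert all(c.locus.start >= 300 for c in calls)

    def test_no_copy_no_call(self, rng):
        from retromir.simulate import _rand_sense_codons
        from retromir.selection import find_longest_orf

        cds = "ATG" + _rand_sense_codons(rng, 60) + "TAA"
        chrom = "".join(rng.choice(list("ACGT"), 100)) + cds + "".join(rng.choice(list("ACGT"), 2000))
        genome = SeqRecordSet({"chr1": chrom})
        orf = find_longest_orf(cds, min_codons=20)
        prots = {"g1": (orf[2], GenomicInterval("chr1", 100, 100 + len(cds), "+"))}
        assert find_dna_duplications(prots, genome) == []

    def test_short_protein_skipped(self, dup_genome):
        genome, _, _ = dup_genome
        prots = {"tiny": ("MKV", GenomicInterval("chr1", 0, 9, "+"))}
        assert find_dna_duplications(prots, genome) == []
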