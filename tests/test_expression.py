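"""Normalization, tissue summaries, TSS/cCRE association, tumor-vs-normal."""

import numpy as np
import pandas as pd
import pytest

from retromir.core import GenomicInterval
from retromir.expression import (
    associate_ccre,
    associate_tss,
    mann_whitney,
    normalize,
    stars,
    summarize,
    tumor_vs_normal,
)


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestNormalize:
    def test_rpm_and_tpm_equal_lengths(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["a", "b"])
        tpm = normalize(counts, {"a": 50, "b": 50}, "TPM")
        assert tpm["s1"].tolist() == [1e5, 9e5]
        rpm = normalize(counts, None, "RPM")
        assert rpm["s1"].tolist() == [1e5, 9e5]

    def test_tpm_length_correction_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        tpm = normalize(counts, {"a": 100, "b": 200}, "TPM")
        assert tpm["s1"].values == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_tpm_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, size=(20, 5)),
                              index=[f"f{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(5)])
        lengths = {f"f{i}": int(l) for i, l in enumerate(rng.integers(50, 500, 20))}
        tpm = normalize(counts, lengths, "TPM")
        assert tpm.sum(axis=0).values == pytest.approx([1e6] * 5, rel=1e-6)

    def test_zero_depth_sample_warns_and_zeros(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero-depth"):
            rpm = normalize(counts, None, "RPM")
        assert rpm["s1"].tolist() == [0.0, 0.0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize(pd.DataFrame({"s": [-1]}, index=["a"]), None, "RPM")


class TestSummarize:
    def mk(self):
        vals = pd.DataFrame(
            {"t0_a": [1, 0, 0], "t0_b": [3, 0, 0], "t1_a": [0, 0, 4],
             "t1_b": [0, 0, 0], "t1_c": [0, 0, 0]},
            index=["x", "y", "z"],
        )
        meta = pd.DataFrame({
            "sample": vals.columns,
            "tissue": ["t0", "t0", "t1", "t1", "t1"],
            "condition": ["normal"] * 5,
        })
        return vals, meta

    def test_breadth_counts_tissues_with_positive_median(self):
        vals, meta = self.mk()
        med, breadth = summarize(vals, meta)
        assert breadth["x"] == 1      # expressed in t0 only
        assert breadth["y"] == 0      # all-zero feature
        # median of {0, 0, 4} is 0: tissue does not count
        assert med.loc["z", "t1"] == 0 and breadth["z"] == 0


class TestTSS:
    def test_upstream_within_window_found(self):
        a = associate_tss("m", iv(5000, 5060), [iv(1500, 1501)], window=4000)
        assert a.tss_found and a.distance == 3500

    def test_beyond_window_not_found(self):
        a = associate_tss("m", iv(5000, 5060), [iv(500, 501)], window=4000)
        assert not a.tss_found

    def test_minus_strand_mirror(self):
        a = associate_tss("m", iv(4940, 5000, strand="-"),
                          [iv(7999, 8000, strand="-")], window=4000)
        assert a.tss_found and a.distance == 3000

    def test_wrong_strand_ignored(self):
        a = associate_tss("m", iv(5000, 5060), [iv(4000, 4001, strand="-")])
        assert not a.tss_found

    def test_translation_invariance(self):
        a = associate_tss("m", iv(5000, 5060), [iv(1500, 1501)])
        shift = 12345
        b = associate_tss("m", iv(5000 + shift, 5060 + shift), [iv(1500 + shift, 1501 + shift)])
        assert (a.tss_found, a.distance) == (b.tss_found, b.distance)


class TestCCRE:
    def test_within_window(self):
        found, d = associate_ccre(iv(100000, 101000), [iv(89000, 89200)])
        assert found and d == pytest.approx(10801)

    def test_beyond_window(self):
        found, _ = associate_ccre(iv(100000, 101000), [iv(70000, 70200)])
        assert not found

    def test_overlap_distance_zero(self):
        found, d = associate_ccre(iv(100000, 101000), [iv(100500, 100600)])
        assert found and d == 0


class TestMannWhitney:
    def test_star_bands(self):
        assert stars(0.03) == "*"
        assert stars(0.05) == "*"
        assert stars(0.005) == "**"
        assert stars(1e-5) == "***"
        assert stars(0.2) == ""
        # band boundaries: 0.01 belongs to '*' (>= 0.01), 1e-4 to '**' (>= 0.0001)
        assert stars(0.01) == "*"
        assert stars(1e-4) == "**"

    def test_identical_groups_p_one(self):
        u, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)
        u, p = mann_whitney([5, 5, 5], [5, 5, 5])
        assert p == 1.0 and u == 4.5

    def test_u_matches_bruteforce_pair_counting(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(3, 9)))
            y = rng.normal(size=int(rng.integers(3, 9)))
            u, _ = mann_whitney(x, y)
            brute = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
            assert u == pytest.approx(brute)

    def test_separated_groups_significant(self, rng):
        x = rng.normal(5, 1, 30)
        y = rng.normal(0, 1, 30)
        _, p = mann_whitney(x, y)
        assert p < 1e-4

    def test_matrix_interface(self, sim_default):
        from retromir.simulate import SimConfig
        from retromir.expression import normalize as norm

        tpm = norm(sim_default.counts, dict(zip(sim_default.lengths.feature,
                                                sim_default.lengths.length)), "TPM")
        feat = sim_default.retro_mirnas[0].matures[0][0]
        u, p, st = tumor_vs_normal(tpm, sim_default.sample_meta, feat,
                                   cohort="cancer_cohort")
        assert p < 0.05 and st  # planted 4x overexpression is detected
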