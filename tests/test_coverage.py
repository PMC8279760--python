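"""Per-base coverage projection, bin profiles, region deltas and the ANOVA."""

import numpy as np
import pytest
from scipy import stats

from ribodelta._errors import (
    DegenerateInputError,
    InsufficientDataError,
    SegmentationMissingError,
    UndefinedProfileError,
)
from ribodelta.annotation import OrfSegmentation, build_transcript_model
from ribodelta.coverage import (
    CoverageVector,
    RegionDelta,
    bin_profile,
    compare_regions,
    coverage_from_bedgraph,
    coverage_from_sam,
    metagene_summary,
    passes_expression_filter,
    per_base_coverage,
    region_delta,
    region_fractions,
    select_3utr_biased,
    tukey_pair_p,
    utr3_log2_change,
)


def seg(tid, u5, cds, u3):
    return OrfSegmentation(tid, True, u5, cds, u3)


class TestPerBaseCoverage:
    def test_no_reads_all_zero(self, two_exon_plus):
        cov = per_base_coverage([], two_exon_plus)
        assert cov.depth.sum() == 0 and len(cov.depth) == 20

    def test_single_read_single_exon(self):
        m = build_transcript_model([("c", 0, 20, "+", "t", "g")])
        cov = per_base_coverage([[(0, 10)]], m)
        assert (cov.depth[:10] == 1).all() and (cov.depth[10:] == 0).all()

    def test_read_spanning_intron(self, two_exon_plus):
        """Genomic block [5,25) over exons [0,10),[20,30): spliced 5–14 covered."""
        cov = per_base_coverage([[(5, 25)]], two_exon_plus)
        expected = np.zeros(20, dtype=int)
        expected[5:15] = 1
        assert (cov.depth == expected).all()

    def test_minus_strand_projection(self, two_exon_minus):
        # genomic [25,30) is the transcript's first 5 spliced bases on '−'
        cov = per_base_coverage([[(25, 30)]], two_exon_minus)
        assert (cov.depth[:5] == 1).all() and cov.depth[5:].sum() == 0

    def test_sam_input(self, tmp_path, two_exon_plus):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100\n"
            "r1\t0\tchr1\t6\t60\t20M\t*\t0\t0\t*\t*\n"  # block [5,25)
            "r2\t4\tchr1\t0\t0\t*\t*\t0\t0\t*\t*\n"  # unmapped: ignored
        )
        covs = coverage_from_sam(str(sam), [two_exon_plus], "s1")
        expected = np.zeros(20, dtype=int)
        expected[5:15] = 1
        assert (covs["tx1"].depth == expected).all()

    def test_bedgraph_roundtrip(self, tmp_path, two_exon_plus):
        from ribodelta.coverage import write_bedgraph

        cov = per_base_coverage([[(5, 25)], [(0, 10)]], two_exon_plus)
        path = tmp_path / "c.bedgraph"
        with open(path, "w") as fh:
            write_bedgraph(cov, two_exon_plus, fh)
        back = coverage_from_bedgraph(str(path), two_exon_plus, "s")
        assert (back.depth == cov.depth).all()


class TestExpressionFilter:
    def test_boundary_inclusive(self):
        assert passes_expression_filter(CoverageVector("t", "s", np.ones(50)))

    def test_below_threshold(self):
        d = np.zeros(100)
        d[:99] = 1
        assert not passes_expression_filter(CoverageVector("t", "s", d))

    def test_mean_not_min(self):
        d = np.zeros(100)
        d[0] = 100
        assert passes_expression_filter(CoverageVector("t", "s", d))

    def test_zero_length(self):
        with pytest.raises(DegenerateInputError):
            passes_expression_filter(CoverageVector("t", "s", np.zeros(0)))


class TestBinProfile:
    def test_uniform(self):
        p = bin_profile(CoverageVector("t", "s", np.full(200, 3)))
        assert np.allclose(p.fractions, 0.01)

    def test_point_mass(self):
        d = np.zeros(100)
        d[0] = 10
        p = bin_profile(CoverageVector("t", "s", d))
        assert p.fractions[0] == 1.0 and p.fractions[1:].sum() == 0

    def test_floor_rule_L150(self):
        """L=150: bin widths alternate 1 and 2 under the floor rule."""
        p = bin_profile(CoverageVector("t", "s", np.ones(150)))
        widths = np.array(
            [np.floor((b + 1) * 1.5) - np.floor(b * 1.5) for b in range(100)]
        )
        assert np.allclose(p.fractions, widths / 150.0)
        assert abs(p.fractions.sum() - 1.0) < 1e-9

    def test_zero_depth_undefined(self):
        with pytest.raises(UndefinedProfileError):
            bin_profile(CoverageVector("t", "s", np.zeros(100)))

    def test_scaling_invariance_and_conservation(self, rng):
        for _ in range(50):
            L = int(rng.integers(5, 400))
            d = rng.integers(0, 20, size=L)
            if d.sum() == 0:
                d[0] = 1
            p1 = bin_profile(CoverageVector("t", "s", d))
            p7 = bin_profile(CoverageVector("t", "s", d * 7))
            assert abs(p1.fractions.sum() - 1.0) < 1e-9
            assert np.allclose(p1.fractions, p7.fractions)


class TestMetagene:
    def _profiles(self, arrays, sample_ids):
        return [
            bin_profile(CoverageVector(f"t{i}", sid, a))
            for sid, arrs in zip(sample_ids, arrays)
            for i, a in enumerate(arrs)
        ]

    def test_uniform_profiles_flat(self):
        arrays = [[np.full(200, 5)] * 3] * 4
        info = {f"s{i}": (f"a{i}", "control") for i in range(4)}
        profs = self._profiles(arrays, [f"s{i}" for i in range(4)])
        meta = metagene_summary(profs, info)["control"]
        assert np.allclose(meta.mean, 0.01) and np.allclose(meta.sem, 0.0)

    def test_single_animal_flagged(self):
        profs = self._profiles([[np.full(100, 2)]], ["s0"])
        meta = metagene_summary(profs, {"s0": ("a0", "mutant")})["mutant"]
        assert not meta.sem_defined and np.isnan(meta.sem).all()
        assert np.allclose(meta.mean, 0.01)

    def test_sem_matches_hand_formula(self, rng):
        """3 animals, one transcript each: SEM per bin = sd/√3."""
        arrays = [[rng.integers(1, 10, size=300)] for _ in range(3)]
        sids = ["s0", "s1", "s2"]
        info = {s: (f"animal{i}", "control") for i, s in enumerate(sids)}
        profs = self._profiles(arrays, sids)
        meta = metagene_summary(profs, info)["control"]
        stack = np.vstack([p.fractions for p in profs])
        assert np.allclose(meta.sem, stack.std(axis=0, ddof=1) / np.sqrt(3))
        assert meta.n_animals == 3


class TestRegionFractions:
    def test_proportional_to_length(self):
        s = seg("t", (0, 10), (10, 90), (90, 100))
        f = region_fractions(CoverageVector("t", "s", np.ones(100)), s)
        assert f == {"utr5": 0.1, "cds": 0.8, "utr3": 0.1}

    def test_all_depth_in_cds(self):
        s = seg("t", (0, 10), (10, 90), (90, 100))
        d = np.zeros(100)
        d[50] = 5
        f = region_fractions(CoverageVector("t", "s", d), s)
        assert f == {"utr5": 0.0, "cds": 1.0, "utr3": 0.0}

    def test_hand_sum(self):
        # depth 2 everywhere except utr3 where it is 1
        d = np.array([2, 2, 2, 2, 2, 2, 2, 2, 1, 1])
        s = seg("t", (0, 2), (2, 8), (8, 10))
        f = region_fractions(CoverageVector("t", "s", d), s)
        assert f == {"utr5": 4 / 18, "cds": 12 / 18, "utr3": 2 / 18}
        assert abs(sum(f.values()) - 1.0) < 1e-9

    def test_missing_segmentation(self):
        s = OrfSegmentation("t", False, None, None, None)
        with pytest.raises(SegmentationMissingError):
            region_fractions(CoverageVector("t", "s", np.ones(10)), s)


class TestRegionDelta:
    GENO = {"c1": "control", "c2": "control", "m1": "mutant", "m2": "mutant"}

    def test_identical_genotypes_zero(self):
        f = {"utr5": 0.1, "cds": 0.8, "utr3": 0.1}
        rd = region_delta({s: dict(f) for s in self.GENO}, self.GENO, "t")
        assert all(abs(v) < 1e-12 for v in rd.delta.values())

    def test_direct_subtraction(self):
        fr = {
            "c1": {"utr5": 0.1, "cds": 0.8, "utr3": 0.10},
            "m1": {"utr5": 0.125, "cds": 0.825, "utr3": 0.05},
        }
        rd = region_delta(fr, self.GENO, "t")
        assert abs(rd.delta["utr3"] - (-0.05)) < 1e-12

    def test_difference_of_means(self):
        fr = {
            "c1": {"utr5": 0.1, "cds": 0.8, "utr3": 0.1},
            "c2": {"utr5": 0.2, "cds": 0.7, "utr3": 0.1},
            "m1": {"utr5": 0.1, "cds": 0.85, "utr3": 0.05},
            "m2": {"utr5": 0.1, "cds": 0.87, "utr3": 0.03},
        }
        rd = region_delta(fr, self.GENO, "t")
        assert abs(rd.delta["utr3"] - (0.04 - 0.1)) < 1e-12
        assert abs(rd.delta["cds"] - (0.86 - 0.75)) < 1e-12

    def test_missing_genotype_excluded(self):
        fr = {"c1": {"utr5": 0.1, "cds": 0.8, "utr3": 0.1}}
        assert region_delta(fr, self.GENO, "t") is None


class TestCompareRegions:
    def _deltas(self, u5, cds, u3):
        return [
            RegionDelta(f"t{i}", {}, {}, {"utr5": a, "cds": b, "utr3": c})
            for i, (a, b, c) in enumerate(zip(u5, cds, u3))
        ]

    def test_identical_groups(self):
        vals = [0.01, -0.01, 0.02, 0.0, -0.02]
        res = compare_regions(self._deltas(vals, vals, vals))
        assert res.f_statistic < 1e-20
        assert all(p > 0.99 for p in res.tukey_p.values())

    def test_textbook_anova_arithmetic(self):
        """Hand-computed: groups (1,2,3), (2,3,4), (6,7,8) → F = 21, df (2,6)."""
        res = compare_regions(self._deltas([1, 2, 3], [2, 3, 4], [6, 7, 8]))
        assert abs(res.f_statistic - 21.0) < 1e-9
        assert abs(res.p_value - stats.f.sf(21.0, 2, 6)) < 1e-12

    def test_shifted_group_flagged(self, rng):
        n = 60
        u5 = rng.normal(0, 0.01, n)
        cds = rng.normal(0, 0.01, n)
        u3 = rng.normal(-0.1, 0.01, n)  # 10 SD shift
        res = compare_regions(self._deltas(u5, cds, u3))
        assert tukey_pair_p(res, "utr3", "utr5") < 0.001
        assert tukey_pair_p(res, "utr3", "cds") < 0.001
        assert tukey_pair_p(res, "utr5", "cds") > 0.01

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compare_regions(self._deltas([1], [2], [3]))


class TestSelect3UtrBiased:
    def test_selection_rules(self):
        down = {"a": -1.0, "b": -1.0, "c": -1.0, "d": -1.0}
        utr3 = {"a": -2.0, "b": -0.5, "c": -1.0}  # d missing: skipped
        assert select_3utr_biased(down, utr3) == ["a"]

    def test_utr3_log2_change_arithmetic(self):
        m_seg = seg("t", (0, 2), (2, 8), (8, 10))
        geno = {"c1": "control", "m1": "mutant"}
        covs = {
            "c1": CoverageVector("t", "c1", np.array([4] * 10)),
            "m1": CoverageVector("t", "m1", np.array([4] * 8 + [1, 1])),
        }
        # log2(1+1) − log2(4+1) on the 3'UTR mean depth
        expected = np.log2(2.0) - np.log2(5.0)
        assert abs(utr3_log2_change(covs, m_seg, geno) - expected) < 1e-12
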