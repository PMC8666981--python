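import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somacohort.cnv import (CopyNumberSegment, SamplePloidyProfile,
                            aneuploidy_score, classify_arm,
                            classify_gene_absolute, classify_gene_tcga,
                            gene_copy_number, infer_wgd, round_copy_number)
from somacohort.genome import ChromosomeArm, GeneLocus
from somacohort.simulate import CohortSimConfig, simulate_cohort
from somacohort import characterize_sample

from conftest import diploid_profile, make_segments


class TestRounding:
    @pytest.mark.parametrize("raw,expected", [
        (4.6, 5), (0.49, 0), (2.5, 3), (0.5, 1), (1.5, 2), (2.0, 2), (0.0, 0),
    ])
    def test_nearest_with_half_away_from_zero(self, raw, expected):
        assert round_copy_number(raw) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            round_copy_number(-0.1)


def _autosome_segments(build, major_by_chrom):
    segs = []
    for chrom in build.autosomes:
        major = major_by_chrom.get(chrom, 1.0)
        segs.append(CopyNumberSegment("s", chrom, 0, build.lengths[chrom],
                                      max(2.0, 2 * major), major))
    return segs


class TestWGD:
    def test_eleven_autosomes_at_major_two_is_wgd(self, toy):
        build, _, _ = toy
        high = {c: 2.0 for c in build.autosomes[:11]}
        assert infer_wgd(_autosome_segments(build, high), build) is True

    def test_ten_autosomes_is_not_wgd(self, toy):
        build, _, _ = toy
        high = {c: 2.0 for c in build.autosomes[:10]}
        assert infer_wgd(_autosome_segments(build, high), build) is False

    def test_half_bases_inclusive_and_threshold_strict(self, toy):
        """Exactly 50% of bases above 1.5 qualifies; exactly 1.5 does not."""
        build, _, _ = toy
        high = {c: 2.0 for c in build.autosomes[:10]}
        # the 11th autosome: exactly half its bases at major 1.6
        chrom = build.autosomes[10]
        L = build.lengths[chrom] // 2 * 2  # force an even length
        base = [s for s in _autosome_segments(build, high)
                if s.chromosome != chrom]
        half = [CopyNumberSegment("s", chrom, 0, L // 2, 3.2, 1.6),
                CopyNumberSegment("s", chrom, L // 2, L, 2.0, 1.0)]
        assert infer_wgd(base + half, build) is True
        # at exactly 1.5 the strict comparison fails
        at_bound = [CopyNumberSegment("s", chrom, 0, L // 2, 3.0, 1.5),
                    CopyNumberSegment("s", chrom, L // 2, L, 2.0, 1.0)]
        assert infer_wgd(base + at_bound, build) is False

    def test_no_autosomal_segments_is_error(self, toy):
        build, _, _ = toy
        segs = [CopyNumberSegment("s", "chrX", 0, 1000, 2.0, 1.0)]
        with pytest.raises(ValueError, match="cannot assess WGD"):
            infer_wgd(segs, build)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_monotone_in_major_allele(self, seed):
        """Raising any major-allele copy number never flips WGD true->false."""
        from somacohort import toy_genome

        build, _, _ = toy_genome(0.2)
        rng = np.random.default_rng(seed)
        segs = []
        for chrom in build.autosomes:
            major = float(rng.uniform(0.5, 2.5))
            segs.append(CopyNumberSegment("s", chrom, 0, build.lengths[chrom],
                                          2 * major, major))
        before = infer_wgd(segs, build)
        i = int(rng.integers(len(segs)))
        s = segs[i]
        bumped = CopyNumberSegment(s.sample, s.chromosome, s.start, s.end,
                                   s.copy_number + 2,
                                   s.major_allele_copy_number + 2)
        segs[i] = bumped
        after = infer_wgd(segs, build)
        assert not (before and not after)


class TestGeneCopyNumber:
    def test_fully_inside_single_segment(self):
        gene = GeneLocus("G", "chr1", 100, 200)
        segs = make_segments("s", [(0, 1000, 20.0, 10.0)])
        assert gene_copy_number(gene, segs) == 20

    def test_weighted_mean_across_segments(self):
        gene = GeneLocus("G", "chr1", 0, 100)
        segs = make_segments("s", [(0, 50, 4.6, 2.0), (50, 100, 5.2, 2.0)])
        assert gene_copy_number(gene, segs) == 5  # mean 4.9 -> 5

    def test_weighted_mean_three_quarters(self):
        gene = GeneLocus("G", "chr1", 0, 100)
        segs = make_segments("s", [(0, 75, 2.0, 1.0), (75, 100, 6.0, 3.0)])
        assert gene_copy_number(gene, segs) == 3  # mean 3.0

    def test_uncovered_gene_is_error(self):
        gene = GeneLocus("G", "chr2", 0, 100)
        segs = make_segments("s", [(0, 1000, 2.0, 1.0)], chromosome="chr1")
        with pytest.raises(ValueError, match="not covered"):
            gene_copy_number(gene, segs)


class TestGeneClassification:
    @pytest.mark.parametrize("cn,wgd,ploidy,expected", [
        (5, False, 2.0, "amplified"),   # diploid amp threshold
        (4, False, 2.0, "neutral"),
        (0, False, 2.0, "deleted"),     # diploid deletion only at zero
        (1, False, 2.0, "neutral"),
        (1, True, 4.0, "deleted"),      # 1 <= 4 - 3
        (2, True, 4.0, "neutral"),
        (7, True, 4.0, "neutral"),
        (8, True, 4.0, "amplified"),
        (1, True, 3.9, "neutral"),      # unrounded ploidy: 3.9 - 3 = 0.9 < 1
    ])
    def test_tcga_conditional(self, cn, wgd, ploidy, expected):
        profile = diploid_profile(ploidy=ploidy, wgd=wgd)
        assert classify_gene_tcga(cn, profile) == expected

    @pytest.mark.parametrize("cn,expected", [
        (0, "deleted"), (1, "deleted"), (2, "neutral"),
        (5, "neutral"), (6, "amplified"), (7, "amplified"),
    ])
    def test_absolute(self, cn, expected):
        assert classify_gene_absolute(cn) == expected

    def test_rule_families_differ_exactly_at_cn_1_and_5(self):
        """Diploid TCGA and absolute rules agree except at CN 1 and CN 5."""
        profile = diploid_profile()
        diff = {
            cn for cn in range(0, 12)
            if classify_gene_tcga(cn, profile) != classify_gene_absolute(cn)
        }
        assert diff == {1, 5}


def _arm(length=100, chrom="chr1"):
    return ChromosomeArm(chrom, "p", 0, length)


class TestArmClassification:
    def test_majority_gain_is_amplified(self):
        segs = make_segments("s", [(0, 60, 3.0), (60, 100, 2.0)])
        call = classify_arm(_arm(), segs, diploid_profile())
        assert call.status == "amplified"
        assert call.amplified_fraction == pytest.approx(0.6)

    def test_exactly_half_deleted_is_inclusive(self):
        segs = make_segments("s", [(0, 50, 1.0), (50, 100, 2.0)])
        call = classify_arm(_arm(), segs, diploid_profile())
        assert call.status == "deleted"
        assert call.deleted_fraction == pytest.approx(0.5)

    def test_rounded_ploidy_convention(self):
        """Ploidy 3.7 rounds to 4, so a whole arm at CN 3 is deleted."""
        segs = make_segments("s", [(0, 100, 3.0)])
        call = classify_arm(_arm(), segs, diploid_profile(ploidy=3.7))
        assert call.status == "deleted"
        assert call.deleted_fraction == pytest.approx(1.0)

    def test_uncovered_arm_neutral_with_warning(self):
        segs = make_segments("s", [(0, 100, 2.0)], chromosome="chr2")
        with pytest.warns(UserWarning, match="no covered bases"):
            call = classify_arm(_arm(), segs, diploid_profile())
        assert call.status == "neutral"

    def test_tie_precedence_deleted_wins(self):
        segs = make_segments("s", [(0, 50, 1.0), (50, 100, 3.0)])
        with pytest.warns(UserWarning, match="precedence"):
            call = classify_arm(_arm(), segs, diploid_profile())
        assert call.status == "deleted"

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_per_base_oracle(self, seed):
        """Segment-arithmetic calls equal a per-base brute-force expansion."""
        call, expected = _random_arm_case(seed)
        assert call.status == expected

    def test_diploid_flat_sample_is_silent(self, toy):
        build, arms, _ = toy
        segs = [CopyNumberSegment("s", c, 0, build.lengths[c], 2.0, 1.0)
                for c in build.chromosomes]
        profile = diploid_profile()
        calls = [classify_arm(a, segs, profile) for a in arms if a.callable]
        assert all(c.status == "neutral" for c in calls)
        assert aneuploidy_score(calls).score == 0


def _random_arm_case(seed):
    """One random small-arm instance plus its per-base oracle verdict."""
    rng = np.random.default_rng(seed)
    arm_len = int(rng.integers(10, 1000))
    arm = ChromosomeArm("chr1", "p", 0, arm_len)
    ploidy = float(rng.uniform(1.2, 4.8))
    profile = SamplePloidyProfile("s", 0.8, ploidy, ploidy > 3)
    n_seg = int(rng.integers(1, 11))
    cuts = np.sort(rng.choice(np.arange(1, arm_len), size=n_seg - 1,
                              replace=False)) if n_seg > 1 else np.array([], int)
    bounds = np.concatenate([[0], cuts, [arm_len]])
    segs = []
    per_base = np.full(arm_len, -1)
    for s, e in zip(bounds[:-1], bounds[1:]):
        if rng.random() < 0.15:  # coverage gap
            continue
        cn = float(rng.uniform(0, 6))
        segs.append(CopyNumberSegment("s", "chr1", int(s), int(e), cn, cn / 2))
        per_base[s:e] = round_copy_number(cn)
    if not segs:
        segs = [CopyNumberSegment("s", "chr1", 0, arm_len, 2.0, 1.0)]
        per_base[:] = 2
    covered = per_base >= 0
    p_int = round_copy_number(ploidy)
    del_frac = (per_base[covered] <= p_int - 1).mean()
    amp_frac = (per_base[covered] >= p_int + 1).mean()
    if del_frac >= 0.5:
        expected = "deleted"
    elif amp_frac >= 0.5:
        expected = "amplified"
    else:
        expected = "neutral"
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        call = classify_arm(arm, segs, profile)
    return call, expected


class TestAneuploidy:
    def test_counts_non_neutral_calls(self):
        from somacohort.cnv import ArmCNVCall

        calls = ([ArmCNVCall("s", f"a{i}", "amplified", 0, 1) for i in range(3)]
                 + [ArmCNVCall("s", f"d{i}", "deleted", 1, 0) for i in range(2)]
                 + [ArmCNVCall("s", f"n{i}", "neutral", 0, 0) for i in range(34)])
        score = aneuploidy_score(calls)
        assert score.score == 5
        assert set(score.altered_arms) == {"a0", "a1", "a2", "d0", "d1"}

    def test_toy_genome_has_39_callable_autosomal_arms(self, toy):
        _, arms, _ = toy
        callable_autosomal = [a for a in arms if a.callable
                              and a.chromosome not in ("chrX", "chrY")]
        assert len(callable_autosomal) == 39


class TestPlantedEventRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_egfr_focal_amplicon_always_recovered(self, seed):
        """A planted 20-copy EGFR amplicon is called amplified for every seed."""
        cfg = CohortSimConfig(seed=seed, n_young=4, n_old=2,
                              genome_scale_mb=0.2,
                              event_probs={"7p11_amp": (1.0, 1.0)})
        cohort = simulate_cohort(cfg)
        egfr = next(g for g in cohort.genes if g.symbol == "EGFR")
        for s in cohort.samples:
            cn = gene_copy_number(egfr, s.segments)
            assert cn == 20
            assert classify_gene_tcga(cn, s.profile) == "amplified"
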