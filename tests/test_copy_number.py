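import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_profile
from oracles import brute_force_segmentation_objective
from tumordiv import copy_number as cn
from tumordiv import synthetic


class TestSegmentation:
    def test_constant_profile_one_segment_per_chromosome(self):
        chrom = ["chr1"] * 10 + ["chr2"] * 10
        p = make_profile(np.zeros(20), chrom=chrom)
        seg = cn.segment_bins(p, gamma=15)
        assert seg.n_segments == 2
        assert list(seg.chrom) == ["chr1", "chr2"]

    def test_noise_free_step_gives_single_breakpoint(self, step_profile):
        seg = cn.segment_bins(step_profile, gamma=15)
        assert seg.n_segments == 2
        assert seg.first_bin.tolist() == [0, 20]
        assert np.allclose(seg.mean_log2, [0.0, 1.0])

    def test_multisample_mode_shares_breakpoints(self):
        rng = np.random.default_rng(0)
        base = np.zeros(40)
        with_step = np.r_[np.zeros(20), np.ones(20)]
        p1 = make_profile(with_step + rng.normal(0, 0.05, 40), sample_id="A")
        p2 = make_profile(base + rng.normal(0, 0.05, 40), sample_id="B")
        s1, s2 = cn.segment_bins([p1, p2], gamma=15)
        assert s1.first_bin.tolist() == s2.first_bin.tolist()
        assert 20 in s1.first_bin

    def test_mismatched_grids_rejected(self):
        p1 = make_profile(np.zeros(10))
        p2 = make_profile(np.zeros(12))
        with pytest.raises(ValueError, match="grid"):
            cn.segment_bins([p1, p2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dp_matches_exhaustive_enumeration(self, seed):
        """DP optimum equals brute force over all 2^(n-1) breakpoint subsets."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, 11) + np.r_[np.zeros(5), np.full(6, rng.uniform(1, 3))]
        p = make_profile(y)
        gamma = 15.0
        seg = cn.segment_bins(p, gamma=gamma)
        dp_obj = cn.penalized_sse(seg, gamma)
        scale = cn._noise_scale(y)
        brute = brute_force_segmentation_objective((y / scale)[None, :], gamma)
        assert dp_obj == pytest.approx(brute, rel=1e-9)

    def test_objective_beats_no_breakpoint_fit(self, step_profile):
        gamma = 15.0
        seg = cn.segment_bins(step_profile, gamma=gamma)
        flat = cn.SegmentProfile(
            sample_id=step_profile.sample_id,
            chrom=np.array(["chr1"], dtype=object),
            first_bin=[0], last_bin=[39],
            mean_log2=[step_profile.log2.mean()], n_bins=[40],
            profile=step_profile,
        )
        assert cn.penalized_sse(seg, gamma) <= cn.penalized_sse(flat, gamma)


class TestPurityPloidyFit:
    def test_manual_override_bypasses_search(self):
        p = make_profile(np.zeros(10))
        seg = cn.segment_bins(p)
        fit = cn.fit_purity_ploidy(seg, mode="cfdna", override=(0.07, 4.41))
        assert fit.purity == 0.07
        assert fit.ploidy == 4.41
        assert fit.manual_override

    def test_flat_profile_fits_diploid_with_zero_goodness(self):
        p = make_profile(np.zeros(20))
        seg = cn.segment_bins(p)
        fit = cn.fit_purity_ploidy(seg)
        assert fit.goodness == pytest.approx(0.0, abs=1e-10)
        assert abs(fit.ploidy - 2.0) <= cn.PSI_STEP
        assert fit.purity_unidentifiable

    def test_recovers_purity_from_noise_free_loss(self):
        """rho=0.6, psi=2, 30% of genome at CN 1."""
        rho = 0.6
        n = np.r_[np.full(30, 1), np.full(70, 2)]
        log2 = cn.expected_log2(n, rho, 2.0)
        p = make_profile(log2)
        seg = cn.segment_bins(p)
        fit = cn.fit_purity_ploidy(seg)
        assert abs(fit.purity - rho) <= cn.RHO_STEP
        assert abs(fit.ploidy - 2.0) <= cn.PSI_STEP

    def test_cfdna_grid_range_respected(self):
        n = np.r_[np.full(30, 1), np.full(70, 2)]
        p = make_profile(cn.expected_log2(n, 0.05, 2.0))
        seg = cn.segment_bins(p)
        fit = cn.fit_purity_ploidy(seg, mode="cfdna")
        assert 0.01 <= fit.purity <= 1.0
        assert 1.5 <= fit.ploidy <= 4.7

    def test_participant_joint_fit_noise_free_recovery(self, noise_free_cohort):
        cfg, profiles, truth = noise_free_cohort
        for pid, plist in profiles.items():
            segs = cn.segment_bins(plist, gamma=15)
            fits = cn.fit_participant(segs)
            for p, fit in zip(plist, fits):
                assert abs(fit.purity - truth.purity[(pid, p.sample_id)]) <= cn.RHO_STEP
                assert abs(fit.ploidy - truth.ploidy[(pid, p.sample_id)]) <= cn.PSI_STEP


class TestIntegerCN:
    @pytest.mark.parametrize(
        "log2,rho,psi,expected",
        [
            (0.0, 1.0, 2.0, 2),
            (np.log2(1.5 / 2), 0.5, 2.0, 1),
            (-8.0, 1.0, 2.0, 0),  # strongly negative clamps at zero
        ],
    )
    def test_inverse_mixture_equation(self, log2, rho, psi, expected):
        p = make_profile([log2] * 4)
        seg = cn.segment_bins(p)
        sample = cn.call_integer_cn(seg, cn.AbsoluteFit(rho, psi, 0.0))
        assert (sample.seg_cn == expected).all()
        assert (sample.bin_cn == expected).all()

    def test_round_trip_bin_cn_noise_free(self, noise_free_cohort):
        cfg, profiles, truth = noise_free_cohort
        for pid, plist in profiles.items():
            segs = cn.segment_bins(plist, gamma=15)
            fits = cn.fit_participant(segs)
            for p, s, f in zip(plist, segs, fits):
                sample = cn.call_integer_cn(s, f)
                np.testing.assert_array_equal(
                    sample.bin_cn, truth.bin_cn[(pid, p.sample_id)]
                )


class TestPGA:
    def _sample(self, bin_cn, ploidy=2.0, chrom=None):
        n = len(bin_cn)
        p = make_profile(np.zeros(n), chrom=chrom)
        seg = cn.SegmentProfile(
            sample_id="S", chrom=p.chrom[:1], first_bin=[0], last_bin=[n - 1],
            mean_log2=[0.0], n_bins=[n], profile=p,
        )
        s = cn.SampleCN(segments=seg, fit=cn.AbsoluteFit(1.0, ploidy, 0.0),
                        seg_cn=np.array([0]), bin_cn=np.asarray(bin_cn))
        return s

    def test_all_baseline_gives_zero(self):
        s = self._sample(np.full(100, 2))
        assert cn.compute_pga(s) == 0.0

    def test_fraction_off_baseline(self):
        s = self._sample(np.r_[np.full(20, 3), np.full(80, 2)])
        assert cn.compute_pga(s) == pytest.approx(0.2)

    def test_sex_bins_use_half_baseline(self):
        chrom = ["chr1"] * 50 + ["chrX"] * 50
        s = self._sample(np.r_[np.full(50, 2), np.full(50, 1)], chrom=chrom)
        assert cn.compute_pga(s) == 0.0

    def test_pga_monotone_in_off_baseline_bins(self):
        vals = []
        for k in (0, 10, 30, 60):
            s = self._sample(np.r_[np.full(k, 3), np.full(100 - k, 2)])
            vals.append(cn.compute_pga(s))
        assert vals == sorted(vals)


class TestFocalAmplifications:
    def _sample_with_segment(self, n_amp_bins, amp_height=3.0, n_total=200):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.1, n_total)
        y[50 : 50 + n_amp_bins] += amp_height
        p = make_profile(y)
        seg = cn.segment_bins(p, gamma=15)
        return cn.call_integer_cn(seg, cn.AbsoluteFit(1.0, 2.0, 0.0))

    @pytest.mark.parametrize("n_bins,called", [(4, True), (3, False), (25, False)])
    def test_bin_count_bounds_are_strict(self, n_bins, called):
        sample = self._sample_with_segment(n_bins)
        calls = cn.detect_focal_amplifications([sample])
        assert (len(calls) > 0) == called
        if called:
            assert calls.iloc[0]["n_bins"] == n_bins

    def test_zero_sd_profile_rejected(self):
        p = make_profile(np.zeros(30))
        seg = cn.segment_bins(p)
        sample = cn.call_integer_cn(seg, cn.AbsoluteFit(1.0, 2.0, 0.0))
        with pytest.raises(ValueError, match="sd"):
            cn.detect_focal_amplifications([sample])

    def test_oncogene_annotation(self):
        sample = self._sample_with_segment(4)
        genes = pd.DataFrame(
            [{"chrom": "chr1", "start": 50 * 500_000, "end": 55 * 500_000, "name": "MYC"}]
        )
        calls = cn.detect_focal_amplifications([sample], oncogene_regions=genes)
        assert calls.iloc[0]["genes"] == "MYC"


class TestArmStatus:
    def _sample(self, bin_cn):
        n = len(bin_cn)
        p = make_profile(np.zeros(n))
        seg = cn.SegmentProfile(
            sample_id="S", chrom=p.chrom[:1], first_bin=[0], last_bin=[n - 1],
            mean_log2=[0.0], n_bins=[n], profile=p,
        )
        return cn.SampleCN(segments=seg, fit=cn.AbsoluteFit(1.0, 2.0, 0.0),
                           seg_cn=np.array([2]), bin_cn=np.asarray(bin_cn))

    @pytest.mark.parametrize(
        "cns,expected",
        [
            (np.full(10, 3), "gain"),
            (np.full(10, 2), "neutral"),
            # even bin count with median 1.5 < 2
            (np.r_[np.full(5, 1), np.full(5, 2)], "loss"),
        ],
    )
    def test_median_vs_baseline(self, cns, expected):
        arm_table = pd.DataFrame([{"chrom": "chr1", "arm": "p", "first_bin": 0,
                                   "last_bin": len(cns) - 1}])
        out = cn.arm_status(self._sample(cns), arm_table)
        assert out.iloc[0]["status"] == expected


class TestFragmentFilter:
    def test_inclusive_bounds(self):
        df = pd.DataFrame({"insert_size": [89, 90, 120, 150, 151]})
        kept = cn.filter_fragment_sizes(df)
        assert kept["insert_size"].tolist() == [90, 120, 150]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        sizes = rng.integers(50, 250, 10)
        df = pd.DataFrame({"insert_size": sizes})
        kept = cn.filter_fragment_sizes(df)
        assert len(kept) == sum(1 for s in sizes if 90 <= s <= 150)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(-2, 2), min_size=6, max_size=20))
def test_segmentation_partitions_bins(vals):
    p = make_profile(np.array(vals))
    seg = cn.segment_bins(p, gamma=15)
    covered = []
    for a, b in zip(seg.first_bin, seg.last_bin):
        covered.extend(range(a, b + 1))
    assert covered == list(range(len(vals)))
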