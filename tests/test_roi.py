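"""ROI statistics, contrast metrics, protocol screening, temperature fit and
the paired t-test."""

import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ihmtquant as iq
from ihmtquant.errors import DegenerateFitError, EmptyRegionError, SelectionError
from ihmtquant.roi import AcquisitionResult, RegionStats
from ihmtquant.studydata import HISTOLOGY_PER_SAMPLE


def make_map(values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return iq.IhMTRMap(values=values, valid=np.asarray(valid, dtype=bool))


class TestRegionStats:
    def test_constant_region(self):
        values = np.full((4, 4), 7.5)
        mask = iq.RegionMask(np.ones((4, 4), dtype=int))
        st_ = iq.region_stats(make_map(values), mask, 1)
        assert st_.mean_ihmtr == 7.5
        assert st_.sd_ihmtr == 0.0
        assert st_.n_voxels == 16

    def test_two_voxel_region_hand_arithmetic(self):
        values = np.array([[8.0, 12.0], [99.0, 99.0]])
        labels = np.array([[2, 2], [0, 0]])
        st_ = iq.region_stats(make_map(values), iq.RegionMask(labels), 2)
        assert st_.mean_ihmtr == 10.0
        assert st_.sd_ihmtr == pytest.approx(math.sqrt(8.0))

    def test_matches_bruteforce_voxel_list(self, rng):
        values = rng.normal(10, 2, (12, 12))
        labels = rng.integers(0, 4, (12, 12))
        valid = rng.random((12, 12)) > 0.2
        ihmtr = make_map(np.where(valid, values, np.nan), valid)
        for label in (1, 2, 3):
            listed = [values[i, j] for i in range(12) for j in range(12)
                      if labels[i, j] == label and valid[i, j]]
            st_ = iq.region_stats(ihmtr, iq.RegionMask(labels), label)
            assert st_.mean_ihmtr == pytest.approx(statistics.fmean(listed))
            assert st_.sd_ihmtr == pytest.approx(statistics.stdev(listed))
            assert st_.n_voxels == len(listed)

    def test_empty_region_raises_and_names_label(self):
        values = np.ones((3, 3))
        with pytest.raises(EmptyRegionError, match="2"):
            iq.region_stats(make_map(values), iq.RegionMask(np.ones((3, 3), int)), 2)

    def test_exact_on_noiseless_phantom(self, noiseless_phantom):
        _, mtset, mask, truth = noiseless_phantom
        out = iq.compute_ihmtr(mtset)
        for label, want in [(1, 11.5), (2, 9.0), (3, 8.0)]:
            st_ = iq.region_stats(out, mask, label)
            assert st_.mean_ihmtr == pytest.approx(want, abs=1e-10)
            assert st_.sd_ihmtr == pytest.approx(0.0, abs=1e-10)


def rs(mean):
    return RegionStats(label=1, mean_ihmtr=mean, sd_ihmtr=0.0, n_voxels=10)


class TestContrasts:
    def test_hand_values(self):
        pair = iq.contrasts(rs(10), rs(8), rs(8))
        assert pair == (2.0, 2.0)

    def test_equal_means_zero(self):
        assert iq.contrasts(rs(9), rs(9), rs(9)) == (0.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(fr=st.floats(-20, 40), pmj=st.floats(-20, 40), myo=st.floats(-20, 40),
           shift=st.floats(-50, 50))
    def test_symmetric_and_shift_invariant(self, fr, pmj, myo, shift):
        a = iq.contrasts(rs(fr), rs(pmj), rs(myo))
        b = iq.contrasts(rs(fr + shift), rs(pmj + shift), rs(myo + shift))
        assert a.contrast_fr_myo == pytest.approx(b.contrast_fr_myo, abs=1e-9)
        assert a.contrast_fr_pmj == pytest.approx(b.contrast_fr_pmj, abs=1e-9)
        swapped = iq.contrasts(rs(pmj), rs(fr), rs(myo))
        assert swapped.contrast_fr_pmj == pytest.approx(a.contrast_fr_pmj)


def acq(name, fr, pmj, myo):
    proto = iq.ProtocolParams(name=name, pw_ms=1, dt_ms=1.1, pulses_per_burst=12,
                              n_bursts=32, btr_ms=48, df_khz=18)
    return AcquisitionResult(proto, rs(fr), rs(pmj), rs(myo))


class TestSelectProtocols:
    def test_single_survivor(self):
        acqs = [acq("lo", 2.0, 1.0, 1.0), acq("hi", 10.0, 7.0, 6.0)]
        ranked = iq.select_protocols(acqs, exclusion_threshold=5.0, k=1)
        assert len(ranked) == 1
        assert ranked[0].protocol.name == "hi"

    def test_dominating_acquisition_ranks_first_for_any_weights(self):
        # "dom" maximises the free-running mean and both contrasts
        acqs = [acq("a", 9.0, 7.5, 7.8), acq("b", 9.5, 8.0, 8.2),
                acq("dom", 11.0, 7.0, 7.5), acq("c", 10.0, 8.5, 8.6)]
        grid = [w for w in itertools.product([0, 0.5, 1, 2], repeat=3)
                if any(w)]
        for w in grid:
            ranked = iq.select_protocols(acqs, exclusion_threshold=0.0, k=4,
                                         weights=w)
            assert ranked[0].protocol.name == "dom", f"weights {w}"

    def test_duplicates_rank_adjacently(self):
        acqs = [acq("a", 9.0, 7.5, 7.8), acq("b", 10.0, 7.0, 7.6),
                acq("b2", 10.0, 7.0, 7.6), acq("c", 9.5, 8.5, 8.4)]
        ranked = iq.select_protocols(acqs, exclusion_threshold=0.0, k=4)
        names = [r.protocol.name for r in ranked]
        assert abs(names.index("b") - names.index("b2")) == 1

    def test_infinite_threshold_errors_with_advice(self):
        with pytest.raises(SelectionError, match="threshold"):
            iq.select_protocols([acq("a", 9.0, 7.0, 7.0)],
                                exclusion_threshold=float("inf"))

    def test_default_threshold_is_median_of_free_running_means(self):
        acqs = [acq(f"p{i}", fr, fr - 2, fr - 1)
                for i, fr in enumerate([4.0, 6.0, 8.0, 10.0, 12.0])]
        ranked = iq.select_protocols(acqs, k=5)
        kept = {r.protocol.name for r in ranked}
        assert kept == {"p2", "p3", "p4"}   # >= median (8.0)

    def test_score_components_reported(self):
        ranked = iq.select_protocols([acq("a", 9, 7, 7), acq("b", 11, 8, 9)],
                                     exclusion_threshold=0.0, k=2)
        top = ranked[0]
        assert top.score == pytest.approx(
            top.z_mean_fr + top.z_contrast_fr_myo + top.z_contrast_fr_pmj)


class TestTemperatureSensitivity:
    def test_two_point_line(self):
        fit = iq.temperature_sensitivity([(33.0, 9.0), (36.0, 9.87)])
        assert fit.slope_pct_per_c == pytest.approx(0.29)
        assert fit.intercept_pct == pytest.approx(9.0 - 0.29 * 33.0)

    def test_noisy_recovery_matches_closed_form_ols(self, rng):
        temps = np.linspace(33, 39, 15)
        values = 0.29 * temps - 0.5 + rng.normal(0, 0.1, temps.size)
        fit = iq.temperature_sensitivity(list(zip(temps, values)))
        # closed-form OLS oracle
        tbar, vbar = temps.mean(), values.mean()
        slope = ((temps - tbar) * (values - vbar)).sum() / ((temps - tbar) ** 2).sum()
        assert fit.slope_pct_per_c == pytest.approx(slope, abs=1e-12)
        assert fit.intercept_pct == pytest.approx(vbar - slope * tbar, abs=1e-12)

    def test_constant_values_give_zero_slope(self):
        fit = iq.temperature_sensitivity([(33, 9.0), (35, 9.0), (37, 9.0)])
        assert fit.slope_pct_per_c == 0.0

    def test_all_temperatures_equal_raises(self):
        with pytest.raises(DegenerateFitError):
            iq.temperature_sensitivity([(36.0, 9.0), (36.0, 10.0)])


class TestPairedTTest:
    def test_identical_pairs(self):
        res = iq.paired_t_test([(5, 5), (7, 7), (9, 9)])
        assert res.t == 0.0 and res.p == 1.0

    def test_hand_arithmetic_two_pairs(self):
        # differences {1, 3}: mean 2, sd sqrt(2), t = 2 / (sqrt(2)/sqrt(2)) = 2
        res = iq.paired_t_test([(2, 1), (6, 3)])
        assert res.t == pytest.approx(2.0)
        assert res.df == 1

    def test_published_collagen_pairs_agree_with_reference_implementation(self):
        pairs = list(zip(HISTOLOGY_PER_SAMPLE["total_collagen"]["free_running"],
                         HISTOLOGY_PER_SAMPLE["total_collagen"]["pmj"]))
        res = iq.paired_t_test(pairs)
        ref = sps.ttest_rel([a for a, _ in pairs], [b for _, b in pairs])
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == 4

    def test_direction_consistent_with_exhaustive_sign_permutation(self):
        pairs = list(zip(HISTOLOGY_PER_SAMPLE["total_collagen"]["free_running"],
                         HISTOLOGY_PER_SAMPLE["total_collagen"]["pmj"]))
        res = iq.paired_t_test(pairs)
        d = np.array([a - b for a, b in pairs])
        assert np.sign(res.t) == np.sign(d.mean())
        # exhaustive sign-flip permutation of the differences
        n = d.size
        t_obs = abs(res.t)
        count = 0
        for signs in itertools.product([1, -1], repeat=n):
            ds = d * np.array(signs)
            t_perm = ds.mean() / (ds.std(ddof=1) / math.sqrt(n))
            if abs(t_perm) >= t_obs - 1e-12:
                count += 1
        p_perm = count / 2 ** n
        # smallest achievable two-sided permutation p at n=5 agrees with a
        # strongly significant parametric result
        assert p_perm == pytest.approx(2 / 32)
        assert res.p < 0.01

    def test_zero_variance_nonzero_mean_flagged(self):
        res = iq.paired_t_test([(3, 1), (5, 3), (7, 5)])
        assert res.degenerate and res.p == 0.0 and math.isinf(res.t)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            iq.paired_t_test([(1, 2)])
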