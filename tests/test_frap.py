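"""FRAP candidate filtering, ROI arithmetic, normalization and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import punctakit as pk
from punctakit.frap import FrapTrace, punctum_masks_from_stack
from punctakit.imaging import GeometryWarning


def _punctum(pid, area, centroid):
    return pk.PunctumRecord(
        punctum_id=pid, cell_id=0, area=area, perimeter=1.0, circularity=1.0,
        roundness=1.0, solidity=1.0, aspect_ratio=1.0, centroid=centroid,
        integrated_density=0.0,
    )


class TestCandidateSelection:
    def test_bleach_fraction_filter(self):
        records = [
            _punctum(1, 10.0, (10.0, 10.0)),   # fraction 0.55 -> kept
            _punctum(2, 6.0, (100.0, 100.0)),  # fraction 0.92 -> rejected
        ]
        kept, reasons = pk.select_bleach_candidates(
            records, stimulation_roi_area=5.5, exclusion_radius=5.0
        )
        assert [r.punctum_id for r in kept] == [1]
        assert reasons[2] == ["bleach_fraction"]

    def test_boundary_fraction_kept_at_exactly_080(self):
        records = [_punctum(1, 10.0, (10.0, 10.0))]
        kept, _ = pk.select_bleach_candidates(
            records, stimulation_roi_area=8.0, exclusion_radius=1.0
        )
        assert len(kept) == 1

    def test_neighbor_exclusion(self):
        records = [
            _punctum(1, 10.0, (10.0, 10.0)),
            _punctum(2, 10.0, (12.0, 10.0)),  # 2 px away
            _punctum(3, 10.0, (60.0, 60.0)),
        ]
        kept, reasons = pk.select_bleach_candidates(
            records, stimulation_roi_area=5.0, exclusion_radius=5.0, pixel_size=1.0
        )
        assert [r.punctum_id for r in kept] == [3]
        assert reasons[1] == ["neighbor"] and reasons[2] == ["neighbor"]

    def test_size_band_filter(self):
        records = [_punctum(1, 30.0, (10.0, 10.0)), _punctum(2, 8.0, (80.0, 80.0))]
        kept, reasons = pk.select_bleach_candidates(
            records, stimulation_roi_area=5.0, exclusion_radius=5.0,
            size_band=(5.0, 20.0),
        )
        assert [r.punctum_id for r in kept] == [2]
        assert "size_band" in reasons[1]

    def test_empty_input(self):
        kept, reasons = pk.select_bleach_candidates([], stimulation_roi_area=5.0)
        assert kept == [] and reasons == {}


class TestBuildFrapRoi:
    def test_set_difference(self):
        pre = np.zeros((9, 9), bool)
        pre[2:7, 2:7] = True
        post = pre.copy()
        post[3:6, 3:6] = False
        roi = pk.build_frap_roi(pk.RoiMask(pre), pk.RoiMask(post))
        assert roi.n_pixels == 9
        expected = np.zeros((9, 9), bool)
        expected[3:6, 3:6] = True
        assert np.array_equal(roi.mask, expected)

    def test_post_superset_raises(self):
        pre = np.zeros((5, 5), bool)
        pre[1:3, 1:3] = True
        post = np.ones((5, 5), bool)
        with pytest.raises(ValueError, match="no bleached signal"):
            pk.build_frap_roi(pk.RoiMask(pre), pk.RoiMask(post))

    def test_disjoint_masks_warn_and_return_pre(self):
        pre = np.zeros((6, 6), bool)
        pre[:2, :2] = True
        post = np.zeros((6, 6), bool)
        post[4:, 4:] = True
        with pytest.warns(GeometryWarning):
            roi = pk.build_frap_roi(pk.RoiMask(pre), pk.RoiMask(post))
        assert np.array_equal(roi.mask, pre)


class TestExtractTrace:
    def test_direct_ratio(self):
        pixels = np.ones((6, 4, 4))
        frap = np.zeros((4, 4), bool)
        frap[:3, :3] = True  # 9 px
        pre = np.ones((4, 4), bool)  # 16 px
        stack = pk.ImageStack(
            pixels=pixels, timestamps=np.arange(6.0), pixel_size=1.0,
            bleach_frame_index=3,
        )
        trace = pk.extract_trace(stack, pk.RoiMask(frap), pk.RoiMask(pre))
        assert np.allclose(trace.raw_values, 9.0 / 16.0)
        assert trace.timestamps[3] == 0.0

    def test_identical_rois_uniform_stack_gives_ones(self):
        pixels = np.full((8, 5, 5), 3.0)
        roi = np.ones((5, 5), bool)
        stack = pk.ImageStack(
            pixels=pixels, timestamps=np.arange(8.0), pixel_size=1.0,
            bleach_frame_index=4,
        )
        trace = pk.extract_trace(stack, pk.RoiMask(roi), pk.RoiMask(roi))
        assert np.allclose(trace.raw_values, 1.0)

    def test_noiseless_stack_follows_model_curve(self, clean_stack):
        stack, truth = clean_stack
        pre, post = punctum_masks_from_stack(stack)
        roi = pk.build_frap_roi(pre, post)
        trace = pk.extract_trace(stack, roi, pre)
        norm = pk.normalize_trace(trace)
        expected = truth.mobile_fraction * (
            1.0 - np.exp(-norm.post_times / truth.half_time)
        )
        assert np.allclose(
            norm.normalized_values[norm.n_prebleach :], expected, atol=1e-6
        )

    def test_zero_denominator_raises(self):
        pixels = np.zeros((6, 4, 4))
        roi = np.ones((4, 4), bool)
        stack = pk.ImageStack(
            pixels=pixels, timestamps=np.arange(6.0), pixel_size=1.0,
            bleach_frame_index=3,
        )
        with pytest.raises(ValueError, match="zero pre-bleach"):
            pk.extract_trace(stack, pk.RoiMask(roi), pk.RoiMask(roi))


class TestNormalizeTrace:
    def test_two_anchor_affine_map(self):
        t = np.array([-8.0, -6.0, -4.0, -2.0, 0.0, 5.0, 10.0])
        raw = np.array([100.0, 102.0, 98.0, 101.0, 40.0, 70.0, 99.0])
        trace = FrapTrace(timestamps=t, raw_values=raw, n_prebleach=4)
        # pre mean = 100.25, F0 = 40: (70-40)/(100.25-40) = 0.4979...
        norm = pk.normalize_trace(trace)
        assert norm.normalized_values[5] == pytest.approx((70 - 40) / (100.25 - 40))
        assert norm.normalized_values[: 4].mean() == pytest.approx(1.0)
        assert norm.normalized_values[4] == 0.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = np.arange(-5.0, 20.0)
        raw = np.concatenate([np.full(5, 10.0), 4.0 + rng.random(20)])
        trace = FrapTrace(timestamps=t, raw_values=raw, n_prebleach=5)
        once = pk.normalize_trace(trace)
        twice = pk.normalize_trace(once)
        assert np.array_equal(once.normalized_values, twice.normalized_values)

    def test_no_contrast_raises(self):
        t = np.arange(-5.0, 5.0)
        trace = FrapTrace(timestamps=t, raw_values=np.ones(10), n_prebleach=5)
        with pytest.raises(ValueError, match="contrast"):
            pk.normalize_trace(trace)

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        noise=st.floats(0.0, 0.2),
        a=st.floats(0.05, 1.0),
    )
    def test_anchor_contract_holds_for_any_trace(self, seed, noise, a):
        """Pre-bleach mean exactly 1, first post value exactly 0."""
        truth = pk.FrapGroundTruth(
            mobile_fraction=a, half_time=30.0, noise_sd=noise, seed=seed
        )
        trace = pk.simulate_frap_trace(truth)
        norm = pk.normalize_trace(trace)
        pre = norm.normalized_values[: norm.n_prebleach]
        assert abs(pre.mean() - 1.0) < 1e-12
        assert norm.normalized_values[norm.n_prebleach] == 0.0


class TestFitRecovery:
    def _trace(self, a, tau, noise=0.0, seed=0):
        truth = pk.FrapGroundTruth(
            mobile_fraction=a, half_time=tau, noise_sd=noise, seed=seed
        )
        return pk.normalize_trace(pk.simulate_frap_trace(truth))

    def test_exact_recovery_on_noiseless_trace(self):
        fit = pk.fit_recovery(self._trace(0.7, 60.0))
        assert fit.converged
        assert fit.mobile_fraction == pytest.approx(0.7, abs=1e-3)
        assert fit.half_time == pytest.approx(60.0, rel=1e-3)
        assert fit.rss < 1e-10

    def test_flat_trace_flagged_unidentifiable(self):
        t = np.arange(-10.0, 100.0, 2.0)
        raw = np.concatenate([np.ones(5), np.zeros(len(t) - 5)])
        # inject bleach contrast for normalization, then flat at 0
        trace = FrapTrace(timestamps=t, raw_values=raw + 0.001, n_prebleach=5)
        norm = pk.normalize_trace(trace)
        fit = pk.fit_recovery(norm)
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)
        assert fit.identifiability_flag

    def test_t_half_ln2_reporting(self):
        fit = pk.fit_recovery(self._trace(0.8, 100.0))
        assert fit.t_half_ln2 == pytest.approx(100.0 * np.log(2), rel=1e-3)

    def test_monotonicity_in_true_tau(self):
        taus = [10.0, 30.0, 60.0, 120.0]
        fitted = [pk.fit_recovery(self._trace(0.6, tau)).half_time for tau in taus]
        assert all(a < b for a, b in zip(fitted, fitted[1:]))

    def test_model_self_consistency(self):
        """The fitted model evaluated at its own parameters reproduces a
        noiseless generator trace."""
        trace = self._trace(0.45, 35.0)
        fit = pk.fit_recovery(trace)
        t = trace.post_times
        model = fit.mobile_fraction * (1 - np.exp(-t / fit.half_time))
        rss = np.sum((trace.normalized_values[trace.n_prebleach :] - model) ** 2)
        assert rss < 1e-10

    def test_noisy_recovery_median_errors(self):
        errs_a, errs_tau = [], []
        for seed in range(50):
            fit = pk.fit_recovery(self._trace(0.6, 60.0, noise=0.02, seed=seed))
            errs_a.append(abs(fit.mobile_fraction - 0.6))
            errs_tau.append(abs(fit.half_time - 60.0) / 60.0)
        assert np.median(errs_a) <= 0.05
        assert np.median(errs_tau) <= 0.10


class TestSummarize:
    def _fit(self, a, tau, converged=True, group=None):
        return pk.FrapFit(
            mobile_fraction=a, half_time=tau, rss=0.0, converged=converged,
            group=group,
        )

    def test_mean_and_sem(self):
        table = pk.summarize_frap(
            [self._fit(0.5, 30.0), self._fit(0.7, 50.0)], groups=["g", "g"]
        )
        row = table.iloc[0]
        assert row["mobile_fraction_mean"] == pytest.approx(0.6)
        assert row["mobile_fraction_sem"] == pytest.approx(0.1)

    def test_single_fit_sem_missing(self):
        table = pk.summarize_frap([self._fit(0.5, 30.0)], groups=["g"])
        assert np.isnan(table.iloc[0]["mobile_fraction_sem"])

    def test_nonconverged_excluded_and_counted(self):
        table = pk.summarize_frap(
            [self._fit(0.5, 30.0), self._fit(9.0, 1e9, converged=False)],
            groups=["g", "g"],
        )
        assert table.iloc[0]["n"] == 1 and table.iloc[0]["n_excluded"] == 1
        assert table.iloc[0]["tau_mean_s"] == pytest.approx(30.0)

    def test_group_tau_ordering_reproduced(self):
        """Three simulated condensate groups with τ₁ < τ₂ = τ₃ keep that
        ordering in the summary (fast-recovering group stays fastest)."""
        rng_seeds = range(6)
        fits, groups = [], []
        for offset, (g, tau) in enumerate(
            (("g1", 20.0), ("g2", 60.0), ("g3", 60.0))
        ):
            for seed in rng_seeds:
                truth = pk.FrapGroundTruth(
                    mobile_fraction=0.7, half_time=tau, noise_sd=0.02,
                    seed=seed + 1000 * offset,
                )
                trace = pk.normalize_trace(pk.simulate_frap_trace(truth))
                fits.append(pk.fit_recovery(trace))
                groups.append(g)
        table = pk.summarize_frap(fits, groups=groups).set_index("group")
        assert table.loc["g1", "tau_mean_s"] < table.loc["g2", "tau_mean_s"]
        assert table.loc["g1", "tau_mean_s"] < table.loc["g3", "tau_mean_s"]
        assert table.loc["g2", "tau_mean_s"] == pytest.approx(
            table.loc["g3", "tau_mean_s"], rel=0.25
        )
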