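import numpy as np
import pytest

from srtmkit.cohort import (
    CohortConfig,
    ConditionSpec,
    KineticTruth,
    ReferenceParams,
    RegionSpec,
    noise_sigma,
    simulate_cohort,
    simulate_covariates,
    simulate_reference_tac,
    simulate_target_tac,
    write_cohort,
    read_scan_table,
)
from srtmkit.kinetics import fit_srtm, frame_average
from srtmkit.schedule import make_frame_schedule


class TestReferenceCurve:
    def test_zero_amplitude_gives_zero_curve(self):
        t, y = simulate_reference_tac(ReferenceParams(peak_amplitude=0.0))
        np.testing.assert_array_equal(y, 0.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ReferenceParams(peak_amplitude=-1.0)

    def test_peak_falls_at_configured_time(self):
        for tp in (2.0, 4.0, 8.0):
            t, y = simulate_reference_tac(ReferenceParams(peak_time=tp), fine_dt=0.05)
            assert abs(t[np.argmax(y)] - tp) <= 0.05
        assert y[0] == 0.0 and np.all(y >= 0)

    def test_grid_refinement_changes_frame_averages_below_0p1_percent(self, schedule):
        t1, y1 = simulate_reference_tac(fine_dt=0.05)
        t2, y2 = simulate_reference_tac(fine_dt=0.025)
        f1 = frame_average(t1, y1, schedule)
        f2 = frame_average(t2, y2, schedule)
        assert np.max(np.abs(f1 - f2) / f2) < 1e-3


class TestTargetTac:
    def test_unit_r1_zero_bp_collapses_to_reference(self, schedule, ref_fine):
        truth = KineticTruth(r1=1.0, k2=0.3, bp_nd=0.0)
        tac = simulate_target_tac(truth, ref_fine, schedule, noise_scale=0.0)
        t, y = ref_fine
        np.testing.assert_allclose(tac.activity, frame_average(t, y, schedule), rtol=1e-10)

    def test_forward_fit_round_trip(self, schedule, ref_fine):
        truth = KineticTruth(r1=1.0, k2=0.3, bp_nd=2.5)
        tac = simulate_target_tac(truth, ref_fine, schedule, noise_scale=0.0)
        fit = fit_srtm(tac, ref_fine)
        assert fit.bp_nd == pytest.approx(2.5, abs=1e-3)

    def test_noise_scale_doubles_residual_magnitude(self, schedule, ref_fine):
        truth = KineticTruth(1.0, 0.3, 2.5)
        clean = simulate_target_tac(truth, ref_fine, schedule, 0.0).activity
        resid = {}
        for ns in (0.02, 0.04):
            mags = []
            for seed in range(100):
                noisy = simulate_target_tac(truth, ref_fine, schedule, ns, rng=seed)
                mags.append(np.mean(np.abs(noisy.activity - clean)))
            resid[ns] = np.mean(mags)
        assert resid[0.04] / resid[0.02] == pytest.approx(2.0, rel=0.1)

    def test_noise_variance_scales_inversely_with_duration(self, schedule):
        sig = noise_sigma(np.full(schedule.n_frames, 10.0), schedule, 0.05,
                          decay_lambda=0.0)
        var = sig**2
        np.testing.assert_allclose(var * schedule.duration, var[0] * schedule.duration[0])

    def test_schedule_past_reference_support_rejected(self, ref_fine):
        long_sched = make_frame_schedule([(1, 200.0)])
        with pytest.raises(ValueError):
            simulate_target_tac(KineticTruth(1.0, 0.3, 1.0), ref_fine, long_sched)

    def test_two_tissue_mode_differs_but_is_close(self, schedule, ref_fine):
        truth = KineticTruth(1.0, 0.3, 2.5)
        srtm = simulate_target_tac(truth, ref_fine, schedule, forward_model="srtm")
        ttc = simulate_target_tac(truth, ref_fine, schedule, forward_model="2tc")
        assert not np.allclose(srtm.activity, ttc.activity)
        # same truth, same scale of curve
        assert ttc.activity.max() == pytest.approx(srtm.activity.max(), rel=0.5)


class TestCohort:
    def test_noise_free_pipeline_returns_true_delta_bp(self):
        """SDs=0, ΔBP_true=20%: post BP is generated at 0.8 x baseline and
        the noise-free fit chain returns 20% within 0.1 points."""
        from srtmkit.kinetics import fine_from_frames

        cfg = CohortConfig(
            n_subjects=1, seed=0, noise_scale=0.0, recenter=True,
            regions={"striatum": RegionSpec(2.5, 42.6)},
            conditions={"MP+LPS": ConditionSpec(20.0, 0.0)},
        )
        cohort = simulate_cohort(cfg)
        assert cohort.subjects[0].delta_bp_true["MP+LPS"] == 20.0
        base = next(s for s in cohort.scans if s.scan_type == "baseline")
        post = next(s for s in cohort.scans if s.scan_type == "post")
        bps = {}
        for scan in (base, post):
            ref = fine_from_frames(scan.tacs["cerebellum"])
            bps[scan.scan_type] = fit_srtm(scan.tacs["striatum"], ref).bp_nd
        recovered = 100.0 * (bps["baseline"] - bps["post"]) / bps["baseline"]
        assert recovered == pytest.approx(20.0, abs=0.1)

    def test_same_seed_gives_identical_datasets(self):
        cfg = CohortConfig(n_subjects=2, seed=42)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for sa, sb in zip(a.scans, b.scans):
            for reg in sa.tacs:
                np.testing.assert_array_equal(sa.tacs[reg].activity, sb.tacs[reg].activity)
        for ca, cb in zip(a.covariates, b.covariates):
            np.testing.assert_array_equal(ca.poms_fatigue, cb.poms_fatigue)

    def test_recentring_pins_sample_mean_exactly(self):
        cfg = CohortConfig(
            n_subjects=8, seed=7, recenter=True,
            conditions={"MP+LPS": ConditionSpec(17.1, 3.6)},
        )
        cohort = simulate_cohort(cfg)
        draws = [s.delta_bp_true["MP+LPS"] for s in cohort.subjects]
        assert np.mean(draws) == pytest.approx(17.1, abs=1e-12)
        assert np.std(draws) > 0  # still a spread of subject truths

    def test_crossover_half_lps_first(self):
        cfg = CohortConfig(n_subjects=8, seed=3)
        cohort = simulate_cohort(cfg)
        lps_first = sum(
            1 for order in cohort.condition_order.values() if order[0] == "MP+LPS"
        )
        assert lps_first == 4

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(conditions={"MP+saline": ConditionSpec(5.0, 1.0)})

    def test_roundtrip_through_tsv(self, tmp_path):
        cfg = CohortConfig(n_subjects=1, seed=1,
                           regions={"striatum": RegionSpec(2.5, 42.6)})
        cohort = simulate_cohort(cfg)
        manifest = write_cohort(cohort, tmp_path)
        entry = manifest["scans"][0]
        tacs = read_scan_table(tmp_path / entry["file"])
        orig = cohort.scans[0].tacs
        np.testing.assert_array_equal(tacs["striatum"].activity, orig["striatum"].activity)
        assert set(tacs) == {"striatum", "cerebellum"}


class TestCovariates:
    def test_placebo_cytokines_stay_at_baseline(self):
        cov = simulate_covariates("sub-01", "MP+PBO", 0)
        assert cov.cytokines["TNFa"].max() < 5.0
        assert cov.cytokines["IL6"].max() < 10.0

    def test_lps_tnf_peaks_before_il6(self):
        for seed in range(5):
            cov = simulate_covariates("sub-01", "MP+LPS", seed)
            t = cov.cytokine_times
            assert t[np.argmax(cov.cytokines["TNFa"])] < t[np.argmax(cov.cytokines["IL6"])]

    def test_mp_absent_without_methylphenidate(self):
        cov = simulate_covariates("sub-01", "LPS", 0)
        assert cov.mp_ng_ml.size == 0
        cov2 = simulate_covariates("sub-01", "MP+LPS", 0)
        np.testing.assert_array_equal(cov2.mp_times, [30.0, 90.0, 150.0])

    def test_poms_integers_in_range(self):
        for seed in range(20):
            for cond in ("MP+LPS", "MP+PBO", "LPS"):
                cov = simulate_covariates("s", cond, seed)
                assert np.issubdtype(cov.poms_fatigue.dtype, np.integer)
                assert cov.poms_fatigue.min() >= 0 and cov.poms_fatigue.max() <= 4

    def test_mp_level_independent_of_true_delta_bp(self):
        rng = np.random.default_rng(123)
        mp, dbp = [], []
        for _ in range(1000):
            cov = simulate_covariates("s", "MP+LPS", rng)
            mp.append(cov.mp_ng_ml.mean())
            dbp.append(rng.normal(17.1, 3.6))  # truth drawn separately by design
        assert abs(np.corrcoef(mp, dbp)[0, 1]) < 0.1

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            simulate_covariates("s", "TNF-blocker", 0)
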