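"""Generators: phantoms, activity days, treadmill sessions, cohorts."""

from datetime import datetime

import numpy as np
import pytest

from discload.actigraphy import epoch_mad, epoch_series, treadmill_summary
from discload.synthgen import (
    Bout,
    BoutSchedule,
    CalibrationMap,
    CohortDesign,
    DEFAULT_CALIBRATION,
    PhantomSpec,
    RegionSpec,
    default_phantom_spec,
    make_activity_day,
    make_cohort,
    make_histogram_cohort,
    make_phantom,
    make_treadmill_session,
)


class TestMakePhantom:
    def test_noiseless_pixel_value_is_closed_form_decay(self):
        """Region T2=60, S0=1000 at TE=15.75 ms -> 1000*exp(-15.75/60)."""
        reg = RegionSpec("disc_nucleus", "ellipse", (10, 10), (6, 3), 1000.0, 60.0)
        spec = PhantomSpec((20, 20), 1, 0.366, 4.5, (reg,))
        stack, truth = make_phantom(spec)
        inside = truth.mask(0)
        assert stack.images[0][inside][0] == pytest.approx(1000 * np.exp(-15.75 / 60.0))
        tes = stack.echo_times_ms
        expected = 1000.0 * np.exp(-tes / 60.0)
        for e in range(tes.size):
            assert np.allclose(stack.images[e][inside], expected[e])
            assert np.allclose(stack.images[e][0][~inside[0]], 0.0)

    def test_same_seed_bit_identical(self):
        spec = default_phantom_spec(noise_sd=15.0, seed=11, n_slices=2)
        s1, _ = make_phantom(spec)
        s2, _ = make_phantom(spec)
        assert np.array_equal(s1.images, s2.images)
        s3, _ = make_phantom(default_phantom_spec(noise_sd=15.0, seed=12, n_slices=2))
        assert not np.array_equal(s1.images, s3.images)

    def test_rician_background_mean_is_rayleigh(self):
        """S0=0 background under Rician noise has mean sd*sqrt(pi/2)."""
        spec = PhantomSpec((128, 128), 1, 1.0, 1.0, (), noise_sd=10.0,
                           noise_model="rician", seed=3)
        stack, _ = make_phantom(spec)
        assert stack.images.mean() == pytest.approx(10.0 * np.sqrt(np.pi / 2), rel=0.02)

    def test_overlap_raises_naming_labels(self):
        a = RegionSpec("vertebra", "rectangle", (10, 10), (5, 5), 1000.0, 50.0, name="v0")
        b = RegionSpec("disc_nucleus", "ellipse", (12, 12), (5, 3), 1000.0, 120.0, name="n0")
        with pytest.raises(ValueError, match="n0.*collides.*v0"):
            make_phantom(PhantomSpec((24, 24), 1, 0.366, 4.5, (a, b)))

    def test_masks_exactly_delineate_primitives(self):
        reg = RegionSpec("vertebra", "rectangle", (10.0, 10.0), (4.0, 3.0), 500.0, 50.0)
        spec = PhantomSpec((21, 21), 1, 1.0, 1.0, (reg,))
        _, truth = make_phantom(spec)
        rows, cols = np.indices((21, 21), dtype=float)
        oracle = (np.abs(cols - 10.0) <= 4.0) & (np.abs(rows - 10.0) <= 3.0)
        assert np.array_equal(truth.mask(0)[0], oracle)

    def test_default_phantom_regions_are_disjoint_and_complete(self):
        stack, truth = make_phantom(default_phantom_spec(n_slices=1))
        assert len(truth.regions) == 19  # 7 vertebrae + 6 x (annulus + nucleus)
        for label in ("disc_nucleus", "disc_annulus", "vertebra"):
            assert truth.label_mask(label).any()

    def test_bright_background_rejected(self):
        bg = RegionSpec("background", "rectangle", (5, 5), (2, 2), 100.0, 50.0)
        with pytest.raises(ValueError, match="noise floor"):
            PhantomSpec((10, 10), 1, 1.0, 1.0, (bg,), noise_sd=1.0)


class TestMakeActivityDay:
    def test_all_day_nonwear_stays_under_detector_threshold(self, day_start):
        sched = BoutSchedule((Bout("nonwear", 86400.0),), day_start, fs_hz=10.0)
        rec = make_activity_day(sched, seed=4)
        res = rec.resultant()
        per_hour = res.reshape(24, -1)
        assert np.all(per_hour.std(axis=1, ddof=0) < 0.024 / 2)  # 2x margin

    def test_wear_bouts_exceed_threshold_with_margin(self, day_start):
        for activity in ("rest", "sit"):
            sched = BoutSchedule((Bout(activity, 3600.0),), day_start, fs_hz=10.0)
            res = make_activity_day(sched, seed=4).resultant()
            assert res.std(ddof=0) > 2 * 0.024

    def test_walk_at_2ms_lands_in_the_calibrated_band(self, day_start):
        """5-s epoch MADs of 2 m/s ambulation sit inside [0.44, 0.59] g."""
        sched = BoutSchedule((Bout("walk", 600.0, 2.0),), day_start, fs_hz=100.0)
        rec = make_activity_day(sched, seed=9)
        _, mads = epoch_mad(rec.resultant(), 100.0)
        assert np.all(mads >= 0.44) and np.all(mads <= 0.59)

    @pytest.mark.parametrize("seed", range(5))
    def test_mad_monotone_in_speed(self, seed, day_start):
        speeds = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
        means = []
        for v in speeds:
            sched = BoutSchedule((Bout("walk" if v < 2 else "run", 120.0, v),),
                                 day_start, fs_hz=100.0)
            rec = make_activity_day(sched, seed=seed)
            _, mads = epoch_mad(rec.resultant(), 100.0)
            means.append(mads.mean())
        assert np.all(np.diff(means) > 0)

    def test_speed_outside_calibration_raises(self, day_start):
        sched = BoutSchedule((Bout("run", 60.0, 5.0),), day_start)
        with pytest.raises(ValueError, match="outside calibration range"):
            make_activity_day(sched)

    def test_signal_respects_device_range(self, day_start):
        sched = BoutSchedule((Bout("jump", 600.0),), day_start, fs_hz=100.0)
        rec = make_activity_day(sched, seed=2)
        assert np.abs(rec.xyz).max() <= 6.0

    def test_schedule_over_24h_rejected(self, day_start):
        with pytest.raises(ValueError, match="24 h"):
            BoutSchedule((Bout("sit", 86401.0),), day_start)

    def test_seeded_determinism(self, day_start):
        sched = BoutSchedule((Bout("walk", 60.0, 1.5), Bout("sit", 60.0)), day_start)
        r1 = make_activity_day(sched, seed=7)
        r2 = make_activity_day(sched, seed=7)
        assert np.array_equal(r1.xyz, r2.xyz)


class TestCalibrationMap:
    def test_band_anchors(self):
        """2 m/s mid-band, 1.5 m/s below 0.44 g, 2.5 m/s above 0.59 g."""
        c = DEFAULT_CALIBRATION
        assert 0.44 < c.target_mad(2.0) < 0.59
        assert c.target_mad(1.5) < 0.44
        assert c.target_mad(2.5) > 0.59

    def test_monotone_and_roundtrip(self):
        c = DEFAULT_CALIBRATION
        speeds = np.linspace(0.5, 3.5, 13)
        mads = [c.target_mad(v) for v in speeds]
        assert np.all(np.diff(mads) > 0)
        assert CalibrationMap.from_dict(c.to_dict()) == c


class TestMakeTreadmillSession:
    def test_default_protocol_has_seven_70s_stages(self):
        sess = make_treadmill_session(seed=1)
        assert len(sess.stages) == 7
        for _, start, end in sess.stages:
            assert end - start == pytest.approx(70.0)

    def test_trimmed_stage_yields_twelve_epochs(self):
        sess = make_treadmill_session(seed=1)
        out = treadmill_summary(sess.recording, sess.stages)
        assert all(s["n_epochs"] == 12 for s in out)

    def test_jump_stage_exceeds_running_band(self):
        """Jump epoch MADs sit above the fastest running stage's MADs."""
        sess = make_treadmill_session(include_jumps=True, seed=3)
        out = treadmill_summary(sess.recording, sess.stages)
        run_top = max(s["mean_mad_g"] for s in out[:-1])
        assert out[-1]["stage"] == "jump"
        assert out[-1]["mean_mad_g"] > run_top


class TestMakeCohort:
    def test_study_scale_design_has_79_rows(self):
        cohort = make_cohort(CohortDesign(group_sizes=(24, 30, 25), seed=5))
        assert len(cohort.table) == 79
        assert cohort.table.group.value_counts()["jogger"] == 30

    def test_same_seed_identical_cohort(self):
        d = CohortDesign(seed=8)
        assert make_cohort(d).table.equals(make_cohort(d).table)

    def test_planted_effects_set_group_means(self):
        d = CohortDesign(group_sizes=(400, 400, 400),
                         t2_effects={"no-sport": 0.0, "jogger": 0.10, "long-distance": 0.20},
                         seed=2)
        t = make_cohort(d).table
        ref = t[t.group == "no-sport"].nucleus_t2_ms.mean()
        assert t[t.group == "jogger"].nucleus_t2_ms.mean() / ref == pytest.approx(1.10, abs=0.02)
        assert t[t.group == "long-distance"].nucleus_t2_ms.mean() / ref == pytest.approx(1.20, abs=0.02)

    def test_impossible_effect_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            CohortDesign(t2_effects={"no-sport": 0.0, "jogger": -1.5, "long-distance": 0.1})

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            CohortDesign(group_sizes=(1, 5, 5))

    def test_subject_days_are_reproducible_and_wearable(self):
        d = CohortDesign(group_sizes=(2, 2, 2), n_days=1, fs_hz=10.0, seed=3)
        cohort = make_cohort(d)
        r1 = cohort.recording_for("S000", 0)
        r2 = cohort.recording_for("S000", 0)
        assert np.array_equal(r1.xyz, r2.xyz)
        es = epoch_series(r1)
        wear_hours = es.wear.sum() * es.epoch_s / 3600.0
        assert wear_hours >= 10.0  # generated days satisfy the valid-day rule


class TestMakeHistogramCohort:
    def test_shapes_and_determinism(self):
        c1, o1, edges = make_histogram_cohort(n_subjects=20, seed=6)
        c2, o2, _ = make_histogram_cohort(n_subjects=20, seed=6)
        assert c1.shape == (20, 98) and o1.shape == (20,)
        assert np.array_equal(c1, c2) and np.array_equal(o1, o2)

    def test_null_outcome_independent_of_band(self):
        counts, outcome, _ = make_histogram_cohort(n_subjects=4000, assoc=0.0, seed=1)
        band_mean = np.log(counts[:, 40:56]).mean(axis=1)
        r = np.corrcoef(band_mean, outcome)[0, 1]
        assert abs(r) < 0.05

    def test_planted_band_correlates_with_outcome(self):
        counts, outcome, _ = make_histogram_cohort(n_subjects=4000, assoc=0.8, seed=1)
        band_mean = np.log(counts[:, 40:56]).mean(axis=1)
        out_r = np.corrcoef(np.log(counts[:, 10]), outcome)[0, 1]
        band_r = np.corrcoef(band_mean, outcome)[0, 1]
        assert band_r > 0.5 and abs(out_r) < 0.1
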