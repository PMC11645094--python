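"""Synthetic cohort generator: counts, determinism, physics, null model."""

import numpy as np
import pytest
from pydantic import ValidationError

from fatlat import synthio as sio


@pytest.fixture(scope="module")
def participant():
    return sio.ParticipantMeta(
        id="B00", group="B", mass=68.2, height=1.755,
        sets_per_exercise={ex: 3 for ex in sio.EXERCISES},
        random_effect={"amplitude": 1.0, "duration": 1.0})


class TestValidation:
    def test_negative_fatigue_field_rejected(self):
        with pytest.raises(ValidationError, match=">= 0"):
            sio.FatigueProfile(amplitude_drift=-0.1)

    def test_group_a_must_have_single_set(self):
        with pytest.raises(ValidationError, match="1 set"):
            sio.ParticipantMeta(id="A0", group="A", mass=70, height=1.7,
                                sets_per_exercise={"Squat": 3},
                                random_effect={})

    def test_group_b_needs_at_least_two_sets(self):
        with pytest.raises(ValidationError, match=">= 2"):
            sio.ParticipantMeta(id="B0", group="B", mass=70, height=1.7,
                                sets_per_exercise={"Squat": 1},
                                random_effect={})

    def test_zero_sets_range_rejected(self):
        with pytest.raises(ValidationError):
            sio.GeneratorConfig(sets_range=(0, 0))

    def test_unknown_exercise_rejected(self):
        with pytest.raises(ValueError, match="unknown exercise"):
            sio.generate_repetition_named = sio.generate_repetition(
                participant=sio.ParticipantMeta(
                    id="x", group="A", mass=70, height=1.7,
                    sets_per_exercise={}, random_effect={}),
                exercise="Situp", fatigue_fraction=0.0, seed=1)


class TestCohortGeneration:
    def test_repetition_count_one_b_participant_three_sets(self):
        cfg = sio.GeneratorConfig(n_group_a=0, n_group_b=1, sets_range=(3, 3), seed=7)
        manifest, reps = sio.generate_cohort(cfg)
        assert len(reps) == 3 * 10 * 4  # sets x reps x exercises

    def test_group_a_counts(self):
        cfg = sio.GeneratorConfig(n_group_a=2, n_group_b=0, seed=1)
        _, reps = sio.generate_cohort(cfg)
        assert len(reps) == 2 * 4 * 10

    def test_determinism_same_seed_identical_streams(self):
        cfg = sio.GeneratorConfig(n_group_a=1, n_group_b=1, sets_range=(2, 4), seed=3)
        _, r1 = sio.generate_cohort(cfg)
        _, r2 = sio.generate_cohort(cfg)
        assert r1.keys() == r2.keys()
        for k in r1:
            np.testing.assert_array_equal(r1[k].board_forces, r2[k].board_forces)
            for s in sio.SENSORS:
                np.testing.assert_array_equal(r1[k].imu_acc[s], r2[k].imu_acc[s])

    def test_different_seed_differs(self):
        a = sio.generate_cohort(sio.GeneratorConfig(n_group_a=1, n_group_b=0, seed=1))[1]
        b = sio.generate_cohort(sio.GeneratorConfig(n_group_a=1, n_group_b=0, seed=2))[1]
        k = next(iter(a))
        assert not np.array_equal(a[k].board_forces, b[k].board_forces)

    def test_board_forces_nonnegative_and_rates_recorded(self, participant):
        rep = sio.generate_repetition(participant, "Squat", 0.5, seed=5,
                                      profile=sio.DEFAULT_FATIGUE)
        assert (rep.board_forces >= 0).all()
        assert rep.board_rate == 30.0 and rep.imu_rate == 60.0


class TestPhysics:
    def test_static_stance_total_force_matches_weight(self, participant):
        board = sio.generate_static_stance(participant, duration=4.0, seed=2,
                                           noise_scale=0.0)
        total = board.sum(axis=1)
        assert abs(total.mean() - participant.mass * sio.GRAVITY) \
            < 0.01 * participant.mass * sio.GRAVITY

    def test_repetition_mean_grf_near_body_weight(self, participant):
        rep = sio.generate_repetition(participant, "Squat", 0.0, seed=2,
                                      noise_scale=0.0)
        total = rep.board_forces.sum(axis=1)
        assert abs(total.mean() - participant.mass * sio.GRAVITY) \
            < 0.05 * participant.mass * sio.GRAVITY

    def test_amplitude_drift_scales_template(self, participant):
        profile = sio.FatigueProfile(amplitude_drift=0.2)
        kw = dict(profile=profile, noise_scale=0.0)
        r0 = sio.generate_repetition(participant, "Squat", 0.0, seed=3, **kw)
        r1 = sio.generate_repetition(participant, "Squat", 1.0, seed=3, **kw)
        g0 = np.abs(r0.imu_gyro["hip"]).max()
        g1 = np.abs(r1.imu_gyro["hip"]).max()
        assert g1 / g0 == pytest.approx(1.2, rel=1e-3)

    def test_mirror_lunges(self):
        p = np.linspace(0, 1, 200, endpoint=False)
        left = sio.exercise_template("LungeLeft", p)
        right = sio.exercise_template("LungeRight", p)
        np.testing.assert_allclose(left["cop"][0], right["cop"][0])
        np.testing.assert_allclose(left["cop"][1], -right["cop"][1])
        np.testing.assert_allclose(left["grf"], right["grf"])
        # arms swap and mediolateral acceleration negates
        np.testing.assert_allclose(left["acc"]["forearm_l"][1],
                                   -right["acc"]["forearm_r"][1])
        np.testing.assert_allclose(left["acc"]["forearm_l"][0],
                                   right["acc"]["forearm_r"][0])
        # angular rate is a pseudovector: x and z components negate
        np.testing.assert_allclose(left["gyro"]["hip"][0], -right["gyro"]["hip"][0])
        np.testing.assert_allclose(left["gyro"]["hip"][1], right["gyro"]["hip"][1])


class TestFatigueInjection:
    @staticmethod
    def _stat_across_fractions(participant, profile, stat):
        vals = []
        for phi in (0.0, 0.5, 1.0):
            reps = [sio.generate_repetition(participant, "Squat", phi, seed=100 + i,
                                            profile=profile)
                    for i in range(12)]
            vals.append(np.mean([stat(r) for r in reps]))
        return vals

    def test_amplitude_drift_monotone_in_peak_amplitude(self, participant):
        vals = self._stat_across_fractions(
            participant, sio.FatigueProfile(amplitude_drift=0.5),
            lambda r: np.abs(r.imu_gyro["hip"]).max())
        assert vals[0] < vals[1] < vals[2]

    def test_noise_growth_monotone_in_residual_sd(self, participant):
        def high_freq_sd(r):
            x = r.imu_acc["hip"][:, 0]
            return np.diff(x).std()
        vals = self._stat_across_fractions(
            participant, sio.FatigueProfile(noise_growth=1.5), high_freq_sd)
        assert vals[0] < vals[1] < vals[2]

    def test_sway_growth_monotone_in_cop_dispersion(self, participant):
        from fatlat.preprocess import derive_grf_cop

        def cop_sd(r):
            gc = derive_grf_cop(r.board_forces, participant.mass)
            return gc[:, 1:].std()
        vals = self._stat_across_fractions(
            participant, sio.FatigueProfile(sway_growth=3.0), cop_sd)
        assert vals[0] < vals[1] < vals[2]

    def test_null_profile_stationary_across_sets(self, participant):
        """All-zero profile: set statistics exchangeable across fractions."""
        def mean_amp(r):
            return np.abs(r.imu_acc["hip"]).mean()
        null = sio.FatigueProfile()
        a = [mean_amp(sio.generate_repetition(participant, "Squat", 0.0, seed=i, profile=null))
             for i in range(20)]
        b = [mean_amp(sio.generate_repetition(participant, "Squat", 1.0, seed=1000 + i, profile=null))
             for i in range(20)]
        # permutation test on the mean difference at alpha = 0.01
        rng = np.random.default_rng(0)
        obs = abs(np.mean(a) - np.mean(b))
        pooled = np.array(a + b)
        count = sum(
            abs(np.mean(perm[:20]) - np.mean(perm[20:])) >= obs
            for perm in (rng.permutation(pooled) for _ in range(500)))
        assert (count + 1) / 501 > 0.01


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    cfg = sio.GeneratorConfig(n_group_a=1, n_group_b=1, sets_range=(2, 2), seed=9)
    manifest, reps = sio.generate_cohort(cfg)
    d = tmp_path_factory.mktemp("cohort")
    sio.write_cohort(manifest, reps, d)
    return d, manifest, reps


class TestCohortIO:

    def test_round_trip_lossless(self, written):
        d, manifest, reps = written
        cohort = sio.read_cohort(d)
        key = ("B00", "Squat", 0, 0)
        r0, r1 = reps[key], cohort.get(*key)
        assert np.abs(r0.board_forces - r1.board_forces).max() == 0.0
        for s in sio.SENSORS:
            assert np.abs(r0.imu_acc[s] - r1.imu_acc[s]).max() == 0.0

    def test_missing_file_names_key(self, written, tmp_path):
        d, manifest, reps = written
        import shutil
        broken = tmp_path / "broken"
        shutil.copytree(d, broken)
        victim = next(broken.glob("data/*/Squat/set0_rep3.csv"))
        victim.unlink()
        with pytest.raises(sio.MissingFileError, match="set0_rep3"):
            sio.read_cohort(broken)

    def test_duplicate_key_rejected(self, written):
        _, manifest, _ = written
        rec = manifest.records[0]
        with pytest.raises(ValueError, match="duplicate"):
            sio.CohortManifest(master_seed=0, participants=manifest.participants,
                               records=[rec, rec])

    def test_unknown_repetition_key(self, written):
        d, _, _ = written
        cohort = sio.read_cohort(d)
        with pytest.raises(KeyError):
            cohort.get("Z99", "Squat", 0, 0)
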