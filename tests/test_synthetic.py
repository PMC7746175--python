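import numpy as np
import pytest

from cervinet.kinematics import segment_repetitions, summarize_movement
from cervinet.nfhas import MOVEMENTS, nfhas_score
from cervinet.preprocessing import build_target
from cervinet.synthetic import (
    BASELINE_TYPE_PROPORTIONS,
    RecoveryModelSpec,
    SyntheticConfig,
    default_recovery_spec,
    default_severity_profiles,
    generate_cohort,
    generate_trace,
    read_cohort,
    write_cohort,
)


class TestSeverityProfiles:
    def test_rom_and_speed_non_increasing_cv_non_decreasing(self):
        profiles = default_severity_profiles()
        for m in MOVEMENTS:
            roms = [p.mean_rom_by_movement[m] for p in profiles]
            speeds = [p.mean_speed_by_movement[m] for p in profiles]
            cvs = [p.mean_cv_by_movement[m] for p in profiles]
            assert roms == sorted(roms, reverse=True)
            assert speeds == sorted(speeds, reverse=True)
            assert cvs == sorted(cvs)

    def test_speed_ordering_rotation_fe_lateral(self):
        for p in default_severity_profiles():
            s = p.mean_speed_by_movement
            assert s["Lrt"] >= s["F"] >= s["Llb"]
            assert s["Rrt"] >= s["E"] >= s["Rlb"]


class TestGenerateTrace:
    def test_deterministic_given_seed(self):
        prof = default_severity_profiles()[1]
        t1 = generate_trace("F", prof, seed=3)
        t2 = generate_trace("F", prof, seed=3)
        np.testing.assert_array_equal(t1.angle, t2.angle)
        np.testing.assert_array_equal(t1.time, t2.time)

    def test_different_seeds_differ(self):
        prof = default_severity_profiles()[1]
        assert not np.array_equal(
            generate_trace("F", prof, seed=1).angle,
            generate_trace("F", prof, seed=2).angle,
        )

    def test_no_amplitude_jitter_gives_zero_cv(self):
        from dataclasses import replace

        prof = default_severity_profiles()[2]
        prof0 = replace(
            prof,
            mean_cv_by_movement={m: 1e-9 for m in MOVEMENTS},
        )
        trace = generate_trace("F", prof0, seed=0, period_jitter=0.0)
        reps = segment_repetitions(trace)
        s = summarize_movement(reps, "F", 55.0)
        assert s.cv == pytest.approx(0.0, abs=0.05)

    def test_invalid_duration_rejected(self):
        prof = default_severity_profiles()[0]
        with pytest.raises(ValueError):
            generate_trace("F", prof, duration=0.0)

    def test_round_trip_recovers_profile_rom_and_speed(self):
        # aggregate >= 200 repetitions across seeds; kinematics must land
        # within 5% of the generating profile
        prof = default_severity_profiles()[2]
        roms, speeds = [], []
        for seed in range(12):
            trace = generate_trace("Lrt", prof, seed=seed)
            for r in segment_repetitions(trace):
                roms.append(r.rom)
                speeds.append(r.peak_speed)
        assert len(roms) >= 200
        assert np.mean(roms) == pytest.approx(
            prof.mean_rom_by_movement["Lrt"], rel=0.05
        )
        assert np.mean(speeds) == pytest.approx(
            prof.mean_speed_by_movement["Lrt"], rel=0.05
        )


class TestGenerateCohort:
    def test_type_counts_within_binomial_tolerance(self):
        n = 1000
        cohort = generate_cohort(SyntheticConfig(n_patients=n, seed=0))
        counts = np.bincount(cohort.severity_types, minlength=6)[1:]
        for k, p in enumerate(BASELINE_TYPE_PROPORTIONS):
            tol = 3.0 * np.sqrt(n * p * (1 - p))
            assert abs(counts[k] - n * p) <= tol

    def test_no_noise_change_equals_model_output(self):
        spec = default_recovery_spec(noise_sd=0.0)
        cohort = generate_cohort(SyntheticConfig(n_patients=40, seed=1, recovery=spec))
        np.testing.assert_allclose(cohort.true_change, cohort.noiseless_change)

    def test_deterministic_given_seed(self):
        c1 = generate_cohort(SyntheticConfig(n_patients=10, seed=5))
        c2 = generate_cohort(SyntheticConfig(n_patients=10, seed=5))
        np.testing.assert_array_equal(c1.true_change, c2.true_change)
        np.testing.assert_array_equal(
            c1.baseline[3].raw_features(), c2.baseline[3].raw_features()
        )

    def test_patient_streams_independent_of_cohort_size(self):
        # counter-based substreams: patient i is identical whether 10 or 30
        # patients are generated
        c_small = generate_cohort(SyntheticConfig(n_patients=10, seed=5))
        c_large = generate_cohort(SyntheticConfig(n_patients=30, seed=5))
        np.testing.assert_array_equal(
            c_small.baseline[7].raw_features(), c_large.baseline[7].raw_features()
        )

    def test_target_reconstructed_from_records(self):
        cohort = generate_cohort(SyntheticConfig(n_patients=30, seed=2))
        targets = [
            build_target(b, f, nfhas_score)
            for b, f in zip(cohort.baseline, cohort.followup)
        ]
        np.testing.assert_allclose(targets, cohort.true_change, atol=1e-9)

    def test_followup_nfhas_within_bounds_under_saturation(self):
        cohort = generate_cohort(SyntheticConfig(n_patients=200, seed=3))
        assert (cohort.nfhas_followup >= -1e-9).all()
        assert (cohort.nfhas_followup <= 100.0 + 1e-9).all()

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            RecoveryModelSpec(
                coefficients=tuple([0.0] * 18),
                group_proportions=(0.5, 0.5, 0.5, 0.0, 0.0),
            )


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(SyntheticConfig(n_patients=1500, seed=11))


class TestEmpiricalStructure:
    def test_rom_monotone_and_cv_monotone_across_types(self, big_cohort):
        cohort = big_cohort
        raw = np.vstack([r.raw_features() for r in cohort.baseline])
        types = cohort.severity_types
        for j, m in enumerate(MOVEMENTS):
            rom_means = [raw[types == k, j].mean() for k in range(1, 6)]
            cv_means = [raw[types == k, 6 + j].mean() for k in range(1, 6)]
            se = max(raw[:, j].std() / np.sqrt(min((types == k).sum() for k in range(1, 6))), 1e-9)
            for a, b in zip(rom_means, rom_means[1:]):
                assert b <= a + 3 * se
            for a, b in zip(cv_means, cv_means[1:]):
                assert b >= a - 3 * se

    def test_speed_ordering_within_each_type(self, big_cohort):
        cohort = big_cohort
        raw = np.vstack([r.raw_features() for r in cohort.baseline])
        types = cohort.severity_types
        idx = {m: 12 + i for i, m in enumerate(MOVEMENTS)}
        for k in range(1, 6):
            sel = types == k
            rot = raw[sel][:, [idx["Lrt"], idx["Rrt"]]].mean()
            fe = raw[sel][:, [idx["F"], idx["E"]]].mean()
            lat = raw[sel][:, [idx["Llb"], idx["Rlb"]]].mean()
            assert rot >= fe >= lat


def test_cohort_disk_round_trip(tmp_path):
    cohort = generate_cohort(SyntheticConfig(n_patients=8, seed=4))
    write_cohort(cohort, tmp_path)
    baseline, followup, sidecar = read_cohort(tmp_path)
    assert len(baseline) == len(followup) == 8
    np.testing.assert_allclose(sidecar["true_change"], cohort.true_change)
    assert sidecar["config"]["seed"] == 4
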