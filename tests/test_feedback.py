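"""Feedback maps, baseline comparison, control magnitude, directional gains."""

import numpy as np
import pytest

import stablegait as sg
from conftest import synthetic_deviation_set


class TestErrorMapExact:
    def test_exact_linear_gains_and_r2(self):
        dev = synthetic_deviation_set(gains=(0.0, 0.4, 0.0, 0.0))
        fit = sg.fit_error_map(dev, 0.5)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.gain_for("body:y") == pytest.approx(0.4, abs=1e-10)
        assert fit.gain_for("body:x") == pytest.approx(0.0, abs=1e-10)

    def test_multichannel_exact_gains(self):
        gains = (0.2, -0.3, 0.1, 0.05)
        dev = synthetic_deviation_set(gains=gains)
        fit = sg.fit_error_map(dev, 0.5)
        np.testing.assert_allclose(fit.gains, gains, atol=1e-10)

    def test_independent_response_r2_near_inflation_level(self):
        # with dP independent of dQ, in-sample R^2 ~ N/(n-1)
        rng = np.random.default_rng(0)
        dev = synthetic_deviation_set(n=400, gains=(0, 0, 0, 0), noise=1.0)
        fit = sg.fit_error_map(dev, 0.5)
        n, N = 400, 4
        assert fit.r2 < 5 * (N / (n - 1)) + 0.02
        # permutation oracle: shuffling the response gives the same level
        r2s = []
        for _ in range(20):
            d2 = synthetic_deviation_set(n=400, gains=(0, 0, 0, 0), noise=1.0)
            d2.dP = d2.dP[rng.permutation(400)]
            r2s.append(sg.fit_error_map(d2, 0.5).r2)
        assert abs(fit.r2 - np.mean(r2s)) < 0.03

    def test_sample_size_precondition(self):
        dev = synthetic_deviation_set(n=20)
        with pytest.raises(ValueError, match="need n >="):
            sg.fit_error_map(dev, 0.5)

    def test_scaling_equivariance(self):
        # scaling all lateral coordinates by s leaves R^2 unchanged
        dev1 = synthetic_deviation_set(gains=(0.1, 0.4, 0.0, 0.2))
        dev2 = synthetic_deviation_set(gains=(0.1, 0.4, 0.0, 0.2))
        s = 3.7
        dev2.dP = dev2.dP * s
        dev2.dQ = dev2.dQ * s
        f1 = sg.fit_error_map(dev1, 0.5)
        f2 = sg.fit_error_map(dev2, 0.5)
        assert f2.r2 == pytest.approx(f1.r2, abs=1e-10)
        np.testing.assert_allclose(f2.gains, f1.gains, atol=1e-8)
        assert f2.intercept == pytest.approx(s * f1.intercept, abs=1e-8)


class TestBaselineMap:
    def test_duplicate_foot_channels_trigger_ridge(self):
        dev = synthetic_deviation_set()
        dev.dQt[:, :, 2] = dev.dQt[:, :, 0]  # exact collinearity
        fit = sg.fit_baseline_map(dev, 0.5)
        assert fit.ridge
        assert np.all(np.isfinite(fit.gains))

    def test_baseline_r2_approaches_one_at_contact(self, feedback_cohort):
        # at phi -> 1 the foot is at its placement, so the foot-kinematics
        # model explains nearly all placement variance
        dev = feedback_cohort["dev"].for_leg("left")
        for animal in dev.index["animal_id"].unique()[:2]:
            da = dev.for_animal(animal)
            fit = sg.fit_baseline_map(da, 1.0)
            assert fit.r2 > 0.9

    def test_gain_recovery_at_swing_onset(self, feedback_cohort):
        dev = feedback_cohort["dev"].for_leg("left")
        sw = feedback_cohort["dev"].phi_swing["left"]
        g = feedback_cohort["params"].gain
        gains = [sg.fit_error_map(dev.for_animal(a), sw).gain_for("body:y")
                 for a in sorted(dev.index["animal_id"].unique())]
        gains = np.asarray(gains)
        sem = gains.std(ddof=1) / np.sqrt(len(gains))
        assert abs(gains.mean() - g) <= max(3 * sem, 0.03)


class TestR2PhaseProfile:
    def test_body_model_wins_before_swing_onset(self, feedback_cohort):
        comp = sg.r2_phase_profile(feedback_cohort["dev"], leg="left",
                                   min_animals_ks=4)
        pre = ((comp.phase_grid < comp.swing_onset_phase)
               & (comp.phase_grid >= 0.1))
        med_body, _, _ = comp.median_iqr("body")
        med_base, _, _ = comp.median_iqr("baseline")
        assert np.all(med_body[pre] > med_base[pre])
        assert (comp.ks_p[pre] < 0.05).mean() > 0.5

    def test_null_profile_statistically_indistinct(self, null_cohort):
        comp = sg.r2_phase_profile(null_cohort["dev"], leg="left",
                                   min_animals_ks=4)
        assert (comp.ks_p < 0.05).mean() <= 0.15

    def test_identical_samples_give_p_one(self):
        comp = sg.ModelComparison(
            phase_grid=np.linspace(0, 1, 5), direction="lateral",
            leg="left", animals=list("abcde"),
            r2_body=np.tile(np.linspace(0.1, 0.5, 5), (5, 1)),
            r2_baseline=np.tile(np.linspace(0.1, 0.5, 5), (5, 1)),
            ks_stat=None, ks_p=None, swing_onset_phase=0.6)
        mags = sg.control_magnitude(comp)
        np.testing.assert_allclose(mags, 0.0, atol=1e-12)

    def test_few_animals_skips_ks(self, feedback_cohort):
        comp = sg.r2_phase_profile(feedback_cohort["dev"], leg="left",
                                   min_animals_ks=10)
        assert comp.ks_p is None


class TestControlMagnitude:
    def test_monotone_in_gain(self, biped_profile):
        mags = {}
        for g in (0.2, 0.6):
            p = sg.WalkerParams(profile=biped_profile, seed=21, gain=g)
            sims = sg.simulate_individuals(p, 4, 200.0)
            cycles = sg.process_bouts([s.bout for s in sims], biped_profile)
            dev = sg.compute_deviations(cycles)
            comp = sg.r2_phase_profile(dev, leg="left", min_animals_ks=4)
            mags[g] = float(np.median(sg.control_magnitude(comp)))
        assert mags[0.6] > mags[0.2] > 0.0


class TestDirectionalGains:
    def test_symmetric_gains_similar(self, feedback_cohort):
        dev = feedback_cohort["dev"]
        sw = dev.phi_swing["left"]
        out = sg.directional_gains(dev, sw, "left")
        d = out["comparison"]["d"]
        assert abs(d) < 1.2
        diff = np.abs(out["medial"].mean() - out["lateral"].mean())
        assert diff < 0.08

    def test_asymmetric_gains_recovered(self, biped_profile):
        p = sg.WalkerParams(profile=biped_profile, seed=22,
                            medial_gain=0.2, lateral_gain=0.6)
        sims = sg.simulate_individuals(p, 5, 300.0)
        cycles = sg.process_bouts([s.bout for s in sims], biped_profile)
        dev = sg.compute_deviations(cycles)
        out = sg.directional_gains(dev, dev.phi_swing["left"], "left")
        assert np.all(out["lateral"] > out["medial"])
        assert out["comparison"]["d"] > 0.8
        assert out["comparison"]["p"] < 0.05

    def test_one_signed_errors_exclude_animal(self):
        dev = synthetic_deviation_set(n=100)
        # force all lateral errors to one side of the reference foot
        dev.dQ[:, :, 1] = np.abs(dev.dQ[:, :, 1])
        dev.index["reference_side"] = 1.0
        out = sg.directional_gains(dev, 0.5, "left")
        assert out["animals"] == []
        assert "comparison" not in out
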