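"""Straightness, alignment, contact detection, segmentation, normalization."""

import numpy as np
import pytest

import stablegait as sg
from stablegait.gait_processing import (_heading_series, align_heading,
                                        detect_contacts, phase_normalize,
                                        segment_cycles, select_straight_bouts,
                                        spatial_normalize)


def _turning_bout(profile, fr=50.0):
    """Straight for 6 s, then a 90 degree turn, then straight for 6 s."""
    n = int(12 * fr)
    t = np.arange(n) / fr
    heading = np.where(t < 6.0, 0.0, np.pi / 2)
    # short transition to avoid a perfect corner
    ramp = (t - 5.8) / 0.4
    heading = np.where((t >= 5.8) & (t < 6.2), np.pi / 2 * np.clip(ramp, 0, 1),
                       heading)
    v = 1.0
    body = np.cumsum(
        np.column_stack([np.cos(heading), np.sin(heading)]) * v / fr, axis=0)
    osc = 0.1 * np.sin(2 * np.pi * 2.0 * t)
    positions = {"body": body}
    for leg in profile.leg_labels:
        sign = 1.0 if "left" in leg else -1.0
        positions[leg] = body + np.column_stack([osc, 0.05 * sign
                                                 * np.ones(n)])
    return sg.TrajectoryBout(bout_id="turn", species=profile, t=t,
                             positions=positions)


class TestStraightness:
    def test_straight_simulated_bout_kept_whole(self, clean_sim):
        out = select_straight_bouts([clean_sim.bout])
        assert len(out) == 1
        assert out[0].n_frames == clean_sim.bout.n_frames

    def test_turn_excised_into_two_segments(self, biped_profile):
        out = select_straight_bouts([_turning_bout(biped_profile)])
        assert len(out) == 2
        for seg in out:
            heading = _heading_series(seg)
            assert np.ptp(heading) <= np.deg2rad(
                biped_profile.straightness_threshold) + 0.15

    def test_returned_segments_respect_threshold(self, biped_profile):
        # property: heading range of every surviving segment stays bounded
        p = sg.WalkerParams(profile=biped_profile, seed=6, heading_rate=0.05)
        bout = sg.simulate_walker(p, 120.0).bout
        for seg in select_straight_bouts([bout]):
            rng = np.ptp(_heading_series(seg))
            assert rng <= np.deg2rad(
                biped_profile.straightness_threshold) + 0.15


class TestAlignHeading:
    def test_already_aligned_is_identity(self, clean_sim):
        aligned = align_heading(clean_sim.bout)
        assert abs(aligned.meta["heading_rotation_rad"]) < 0.02

    def test_minus_y_travel_rotated_to_plus_x(self, biped_profile):
        bout = clean_simulated(biped_profile)
        aligned = align_heading(bout)
        disp = (aligned.positions["body"][-1] - aligned.positions["body"][0])
        assert disp[0] > 0
        assert abs(disp[1]) < 0.05 * abs(disp[0])

    def test_pairwise_distances_preserved(self, clean_sim):
        aligned = align_heading(clean_sim.bout)
        p, q = clean_sim.bout.positions, aligned.positions
        for a in ("body", "left"):
            for b in ("right",):
                d0 = np.linalg.norm(p[a] - p[b], axis=1)
                d1 = np.linalg.norm(q[a] - q[b], axis=1)
                assert np.max(np.abs(d0 - d1)) < 1e-10

    def test_zero_displacement_errors(self, biped_profile):
        n = 100
        t = np.arange(n) / 50.0
        positions = {m: np.zeros((n, 2)) for m in biped_profile.markers}
        bout = sg.TrajectoryBout(bout_id="still", species=biped_profile,
                                 t=t, positions=positions)
        with pytest.raises(ValueError, match="displacement"):
            align_heading(bout)


def clean_simulated(profile):
    """A bout rendered along -y (rotate a straight +x bout by -90 deg)."""
    p = sg.WalkerParams(profile=profile, seed=8, sigma_obs=0.0)
    bout = sg.simulate_walker(p, 40.0).bout
    rot = np.array([[0.0, 1.0], [-1.0, 0.0]])  # +x -> -y
    bout.positions = {m: xy @ rot.T for m, xy in bout.positions.items()}
    return bout


class TestDetectContacts:
    def test_extrema_onsets_match_truth(self, clean_sim):
        aligned = align_heading(clean_sim.bout)
        for leg in ("left", "right"):
            det = detect_contacts(aligned, leg, method="extrema")
            truth = clean_sim.truth_contacts[leg]
            truth_on = np.array([e.onset_index for e in truth])
            errs = [np.min(np.abs(truth_on - c.onset_index)) for c in det]
            assert np.max(errs) <= 2

    def test_methods_agree_on_event_count(self, clean_sim):
        aligned = align_heading(clean_sim.bout)
        n_e = len(detect_contacts(aligned, "left", method="extrema"))
        n_v = len(detect_contacts(aligned, "left",
                                  method="velocity_threshold"))
        assert abs(n_e - n_v) <= max(2, int(0.02 * n_e))

    def test_constant_displacement_yields_empty(self, biped_profile):
        n = 500
        t = np.arange(n) / 50.0
        body = np.column_stack([t, np.zeros(n)])
        positions = {"body": body}
        for leg in biped_profile.leg_labels:
            positions[leg] = body + [0.1, 0.0]  # no stepping
        bout = sg.TrajectoryBout(bout_id="glide", species=biped_profile,
                                 t=t, positions=positions)
        assert detect_contacts(bout, "left") == []


class TestSegmentation:
    def test_fencepost_cycle_count(self, clean_sim, biped_profile):
        aligned = align_heading(clean_sim.bout)
        contacts = {leg: detect_contacts(aligned, leg)[:5]
                    for leg in biped_profile.leg_labels}
        cycles = segment_cycles(aligned, contacts, biped_profile)
        for leg in biped_profile.leg_labels:
            assert sum(c.leg == leg for c in cycles) == 4

    def test_vhat_matches_commanded_speed(self, biped_profile):
        p = sg.WalkerParams(profile=biped_profile, seed=9, v_sd=0.0,
                            sigma_obs=0.0)
        sim = sg.simulate_walker(p, 60.0)
        cycles = sg.process_bouts([sim.bout], biped_profile)
        v = np.array([c.v_hat for c in cycles])
        assert np.median(v) == pytest.approx(p.v_mean, rel=0.02)

    def test_termination_based_segmentation_similar_count(self, clean_sim,
                                                          biped_profile):
        aligned = align_heading(clean_sim.bout)
        contacts = {leg: detect_contacts(aligned, leg)
                    for leg in biped_profile.leg_labels}
        c_on = segment_cycles(aligned, contacts, biped_profile)
        c_off = segment_cycles(aligned, contacts, biped_profile,
                               use_terminations=True)
        for leg in biped_profile.leg_labels:
            n_on = sum(c.leg == leg for c in c_on)
            n_off = sum(c.leg == leg for c in c_off)
            assert abs(n_on - n_off) <= 1


class TestPhaseNormalize:
    def _raw_cycles(self, sim, profile):
        aligned = align_heading(sim.bout)
        contacts = {leg: detect_contacts(aligned, leg)
                    for leg in profile.leg_labels}
        return segment_cycles(aligned, contacts, profile), contacts

    def test_output_shape_contract(self, clean_sim, biped_profile):
        raw, _ = self._raw_cycles(clean_sim, biped_profile)
        for M in (20, 100):
            cyc = phase_normalize(raw[3], M=M)
            assert cyc.Q.shape == (M, 4)
            assert cyc.Q_tilde.shape == (M, 4)

    def test_linear_in_time_exact_in_phase(self, biped_profile):
        # signals linear in time stay exactly linear on the phase grid
        from stablegait.gait_processing import GaitCycle
        n = 200
        t = np.arange(n) / biped_profile.frame_rate
        positions = {}
        for k, m in enumerate(biped_profile.markers):
            positions[m] = np.column_stack([1.3 * t + k, -0.4 * t + 2 * k])
        bout = sg.TrajectoryBout(bout_id="lin", species=biped_profile,
                                 t=t, positions=positions)
        raw = GaitCycle(
            leg="left", animal_id="a", bout_id="lin", cycle_index=0,
            v_hat=1.3, duration=float(t[150] - t[20]),
            phase_grid=np.empty(0), Q=np.empty((0, 0)), Q_channels=(),
            Q_tilde=np.empty((0, 0)), placement=np.zeros(2),
            contact_time=float(t[20]),
            meta={"i0": 20, "i1": 150, "bout": bout})
        cyc = phase_normalize(raw, M=33)
        for col, slope in ((0, 1.3), (1, -0.4)):
            ch = cyc.Q[:, col]
            fitted = np.polyval(np.polyfit(cyc.phase_grid, ch, 1),
                                cyc.phase_grid)
            assert np.max(np.abs(ch - fitted)) < 1e-9
        # velocities of a linear signal are the constant slope
        np.testing.assert_allclose(cyc.Q[:, 2], 1.3, atol=1e-9)

    def test_short_cycle_dropped(self, clean_sim, biped_profile):
        raw, _ = self._raw_cycles(clean_sim, biped_profile)
        raw[0].meta["i1"] = raw[0].meta["i0"] + 2
        assert phase_normalize(raw[0]) is None


class TestSpatialNormalize:
    def test_translation_invariance(self, biped_profile):
        p = sg.WalkerParams(profile=biped_profile, seed=11, sigma_obs=0.0)
        sim = sg.simulate_walker(p, 60.0)
        shifted = sim.bout.copy()
        for m in shifted.positions:
            shifted.positions[m] = shifted.positions[m] + [10.0, -3.0]
        c0 = sg.process_bouts([sim.bout], biped_profile)
        c1 = sg.process_bouts([shifted], biped_profile)
        assert len(c0) == len(c1)
        p0 = np.array([c.placement for c in c0])
        p1 = np.array([c.placement for c in c1])
        np.testing.assert_allclose(p0, p1, atol=1e-9)

    def test_biped_reference_is_contralateral(self, feedback_cohort):
        for c in feedback_cohort["cycles"][:50]:
            assert c.reference_leg == ("right" if c.leg == "left" else "left")

    def test_step_width_magnitude(self, clean_sim, biped_profile):
        cycles = sg.process_bouts([clean_sim.bout], biped_profile)
        widths = np.array([abs(c.placement[1]) for c in cycles])
        # nominal width 0.12, small deviations around it
        assert np.median(widths) == pytest.approx(0.12, abs=0.02)


class TestFullChainFidelity:
    def test_recovered_placement_deviations_match_truth(self, clean_sim,
                                                        biped_profile):
        params = clean_sim.params
        cycles = sg.process_bouts([clean_sim.bout], biped_profile)
        n_truth = sum(len(v) - 1 for v in clean_sim.truth_contacts.values())
        assert len(cycles) >= 0.99 * n_truth
        dev = sg.compute_deviations(cycles)
        d = dev.for_leg("left")
        truth = clean_sim.truth_placement_dev["left"]
        t_on = np.array([c["t_on"]
                         for c in clean_sim.plan.contacts["left"]])
        end_t = (d.index["contact_time"] + d.index["duration"]).to_numpy()
        ix = np.array([int(np.argmin(np.abs(t_on - et))) for et in end_t])
        resid = d.dP[:, 1] - truth[ix]
        resid -= resid.mean()
        assert np.max(np.abs(resid)) < 3 * params.sigma_foot
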