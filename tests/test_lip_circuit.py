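"""LIP maps, head-centered readout, remapping feedback, and ablations."""

import numpy as np
import pytest

from helpers import FAR, fixation_state

from lipstab import AblationConfig, Simulator, make_trajectory
from lipstab.oculomotor import TrialSchedule, schedule_events


class TestAblationConfig:
    def test_rejects_unknown_variant(self):
        with pytest.raises(Exception):
            AblationConfig(variant="feedforward")

    def test_labels(self):
        assert AblationConfig().label() == "full"
        assert AblationConfig(remapping_feedback=False).label() == "no_remap"
        assert AblationConfig(corollary_discharge=False).label() == "no_cd"
        assert AblationConfig(variant="lateral").label() == "lateral"


class TestDriveXbPc:
    def test_zero_retina_means_zero_drive(self, circuit):
        d = circuit.drive_xb_pc(np.zeros(40), np.ones(40))
        assert np.all(d == 0.0)

    def test_single_blob_at_intersection(self, cfg, circuit):
        state = fixation_state(cfg, circuit, stimulus=0.0, eye=0.0)
        rates = state.lip.xb_pc.rates
        i, j = np.unravel_index(np.argmax(rates), rates.shape)
        g = circuit.grid
        assert abs(g.centers[i]) <= g.spacing  # retinal 0
        assert abs(g.centers[j]) <= g.spacing  # eye 0
        # exactly one connected region above 10% of the max
        mask = rates > 0.1 * rates.max()
        from scipy import ndimage
        _, n_blobs = ndimage.label(mask)
        assert n_blobs == 1

    def test_blob_tracks_stimulus_by_one_grid_step(self, cfg, circuit):
        g = circuit.grid
        a = fixation_state(cfg, circuit, stimulus=g.centers[20]).lip.xb_pc.rates
        b = fixation_state(cfg, circuit, stimulus=g.centers[21]).lip.xb_pc.rates
        ia = np.unravel_index(np.argmax(a), a.shape)
        ib = np.unravel_index(np.argmax(b), b.shape)
        assert ib[0] - ia[0] == 1 and ib[1] == ia[1]


class TestDriveXbCd:
    def test_visual_row_without_cd(self, circuit):
        xr = np.zeros(40)
        xr[21] = 1.0
        d = circuit.drive_xb_cd(xr, np.zeros(40), np.zeros(79),
                                AblationConfig())
        # no anticipatory signal: every column identical, purely visual
        assert d.max() > 0
        np.testing.assert_allclose(d, d[:, :1] @ np.ones((1, 40)))

    def test_feedback_gated_off(self, circuit):
        xr = np.zeros(40)
        fef = np.zeros(40)
        fef[23] = 1.0
        xh = np.ones(79)
        d_off = circuit.drive_xb_cd(xr, fef, xh,
                                    AblationConfig(remapping_feedback=False))
        assert np.all(d_off == 0.0)  # no visual input, feedback disabled
        d_on = circuit.drive_xb_cd(xr, fef, xh, AblationConfig())
        assert d_on.max() > 0.0

    def test_feedback_peaks_at_diagonal_intersection(self, cfg, circuit):
        # brute-force oracle: the feedback term is k_fb * sat(xh[l+m]) * fef_k(m)
        xr = np.zeros(40)
        fef = np.zeros(40)
        fef[23] = 1.0
        xh = np.zeros(79)
        xh[39] = 1.0
        d = circuit.drive_xb_cd(xr, fef, xh, AblationConfig())
        cols = circuit.Wfef @ fef
        x0 = cfg.lip.fb_sat
        expected = np.empty((40, 40))
        for l in range(40):
            for m in range(40):
                expected[l, m] = (cfg.lip.k_fb * x0
                                  * np.tanh(xh[l + m] / x0) * cols[m])
        np.testing.assert_allclose(d, expected, atol=1e-12)
        l_star, m_star = np.unravel_index(np.argmax(d), d.shape)
        assert m_star == 23 and l_star + m_star == 39


class TestDriveXh:
    def test_zero_maps_zero_drive(self, circuit):
        assert np.all(circuit.drive_xh(np.zeros((40, 40)),
                                       np.zeros((40, 40))) == 0.0)

    def test_single_unit_maps_to_diagonal_bin(self, circuit):
        m = np.zeros((40, 40))
        m[12, 7] = 1.0
        d = circuit.drive_xh(m, np.zeros((40, 40)))
        assert np.argmax(d) == 19  # l + m

    def test_head_centered_invariance_of_diagonal(self, circuit):
        a = np.zeros((40, 40))
        a[12, 7] = 1.0
        b = np.zeros((40, 40))
        b[13, 6] = 1.0
        da = circuit.drive_xh(a, np.zeros((40, 40)))
        db = circuit.drive_xh(b, np.zeros((40, 40)))
        np.testing.assert_allclose(da, db)  # same diagonal, same drive
        both = circuit.drive_xh(a + b, np.zeros((40, 40)))
        np.testing.assert_allclose(both, da + db)

    def test_shape_mismatch_rejected(self, circuit):
        with pytest.raises(ValueError):
            circuit.drive_xh(np.zeros((40, 40)), np.zeros((39, 40)))


class TestLateralVariant:
    def test_requires_lateral_flag(self, circuit):
        with pytest.raises(ValueError):
            circuit.lateral_variant_drive(np.zeros((40, 40)), np.zeros(40),
                                          AblationConfig(), np.zeros(40))

    def test_stateless_diagonal_input(self, cfg, circuit):
        ab = AblationConfig(variant="lateral")
        fef = np.zeros(40)
        fef[23] = 1.0
        blob = np.zeros((40, 40))
        blob[19, 20] = 1.0
        with_input = circuit.lateral_variant_drive(blob, fef, ab, np.zeros(40))
        assert with_input.max() > 0
        # zeroing the LIP(PC) map removes the diagonal input immediately
        without = circuit.lateral_variant_drive(np.zeros((40, 40)), fef, ab,
                                                np.zeros(40))
        assert np.all(without == 0.0)


class TestStepLip:
    def test_zero_in_zero_out(self, cfg, circuit):
        sim = Simulator(cfg, AblationConfig(), circuit)
        sacc = make_trajectory(8.0, FAR, cfg.oculomotor)
        sched = TrialSchedule(saccade=sacc, segments=[], t_end=50.0)
        state = sim.run(sched)
        assert np.all(state.lip.xb_pc.rates == 0.0)
        assert np.all(state.lip.xb_cd.rates == 0.0)
        assert np.all(state.lip.xh.rates == 0.0)

    def test_steady_state_matches_drive(self, cfg, circuit):
        # after 25 tau the map rates equal their drives within 5%
        state = fixation_state(cfg, circuit, stimulus=0.0, duration=250.0)
        d_pc = circuit.drive_xb_pc(state.xr.rates, state.xe_pc.rates)
        r = state.lip.xb_pc.rates
        mask = d_pc > 0.1 * d_pc.max()
        assert np.all(np.abs(r[mask] - d_pc[mask]) <= 0.05 * d_pc[mask])

    def test_synchronous_update_uses_previous_state(self, cfg, circuit):
        # a stimulus switched on at t influences xr after one step, xb maps
        # only after two, and xh only after three
        sim = Simulator(cfg, AblationConfig(), circuit)
        sacc = make_trajectory(8.0, FAR, cfg.oculomotor)
        sched = TrialSchedule(saccade=sacc,
                              segments=[(0.0, 100.0, 0.0, 1.0)], t_end=10.0)
        state = sim.reset(sched)
        sim.step()
        assert state.xr.rates.max() > 0
        assert state.lip.xb_pc.rates.max() == 0
        sim.step()
        assert state.lip.xb_pc.rates.max() > 0
        assert state.lip.xh.rates.max() == 0
        sim.step()
        assert state.lip.xh.rates.max() > 0


class TestHeadCenteredInvariance:
    def test_xh_peak_invariant_across_eye_positions(self, cfg, circuit):
        # same head-centered stimulus, eyes at -12, 0, +12 deg: the
        # head-centered peak bin must agree within one bin
        def peak(eye):
            state = fixation_state(cfg, circuit, stimulus=4.0, eye=eye)
            return int(np.argmax(state.lip.xh.rates))

        center = peak(0.0)
        assert abs(peak(-12.0) - center) <= 1
        assert abs(peak(12.0) - center) <= 1


class TestRemappingGating:
    def _frf_feedback_response(self, cfg, circuit, cd_on):
        # stimulus in the future RF around saccade onset; the tracked cell
        # (RF at -14 deg retinal) responds only through the CD-gated feedback
        ab = AblationConfig(corollary_discharge=cd_on)
        sacc = make_trajectory(14.0, 700.0, cfg.oculomotor)
        sched = schedule_events(cfg, sacc, "remap", flash_time=620.0,
                                flash_position=0.0)
        sim = Simulator(cfg, ab, circuit)
        row = circuit.grid.index_of(-14.0)
        col = circuit.grid.index_of(14.0 - cfg.oculomotor.undershoot_mean)
        peak = 0.0

        def track(state):
            nonlocal peak
            if state.t <= sacc.onset:  # pre-saccadic response only
                peak = max(peak, state.lip.xb_cd.rates[row, col])
            return state.t > sacc.onset

        sim.run(sched, callback=track)
        return peak

    def test_cd_gates_the_predictive_response(self, cfg, circuit):
        with_cd = self._frf_feedback_response(cfg, circuit, cd_on=True)
        without = self._frf_feedback_response(cfg, circuit, cd_on=False)
        # without CD only the far tail of the classical RF remains
        assert without < 0.05 * with_cd
        assert with_cd > 0.05


class TestLoopStabilization:
    def _transition_time(self, cfg, circuit, feedback):
        """50%-crossing time of the head-centered pattern transition from the
        pre-displacement to the post-displacement representation, measured by
        projecting xh(t) onto the (post - pre) pattern difference."""
        ab = AblationConfig(remapping_feedback=feedback)
        sacc = make_trajectory(8.0, 600.0, cfg.oculomotor,
                               executed=8.0 - cfg.oculomotor.undershoot_mean)
        sched = schedule_events(cfg, sacc, "ssd", displacement=4.0)
        sim = Simulator(cfg, ab, circuit)
        t_disp = sacc.onset + cfg.ssd.displacement_delay
        profiles = []

        def track(state):
            if state.t >= t_disp:
                profiles.append((state.t, state.lip.xh.rates.copy()))
            return state.t > t_disp + 250.0

        sim.run(sched, callback=track)
        t0, pre = profiles[0]
        _, post = profiles[-1]
        u = post - pre
        s = np.array([((x - pre) @ u) / (u @ u) for _, x in profiles])
        return profiles[int(np.argmax(s >= 0.5))][0] - t0

    def test_feedback_slows_transition_to_displaced_position(self, cfg, circuit):
        slow = self._transition_time(cfg, circuit, feedback=True)
        fast = self._transition_time(cfg, circuit, feedback=False)
        assert slow > fast
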