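"""Template matching, Poisson spiking, competition, and accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipstab import (DecisionRunner, accumulate, accumulation_start,
                     build_templates, compete, default_config,
                     make_trajectory, poissonize, split_evidence,
                     template_match)
from lipstab.decision_readout import DecisionTrace, TemplateBank


@pytest.fixture(scope="module")
def bank(cfg, circuit):
    return build_templates(cfg, 8.0, "intermediate", circuit)


class TestAccumulationStart:
    def test_peri_saccadic_rule(self, cfg):
        sacc = make_trajectory(8.0, 500.0, cfg.oculomotor)  # offset 544.6
        start = accumulation_start(sacc, 530.0, cfg)
        assert start == pytest.approx(sacc.offset + 28.0)

    def test_post_saccadic_rule(self, cfg):
        sacc = make_trajectory(8.0, 500.0, cfg.oculomotor)
        assert accumulation_start(sacc, 780.0, cfg) == pytest.approx(840.0)

    def test_boundary_counts_as_post_saccadic(self, cfg):
        sacc = make_trajectory(8.0, 500.0, cfg.oculomotor)
        start = accumulation_start(sacc, sacc.offset, cfg)
        assert start == pytest.approx(sacc.offset + 60.0)


class TestTemplateBank:
    def test_lattice_step_is_half_degree(self, bank):
        np.testing.assert_allclose(np.diff(bank.positions), 0.5)
        assert 8.0 in bank.positions

    def test_templates_non_negative(self, bank):
        assert np.all(bank.templates >= 0.0)

    def test_self_match_peaks_at_stimulus_position(self, cfg, circuit, bank):
        # feed the bank a decision input generated for a stimulus at 10 deg;
        # the best-matching template must be at (or next to) 10 deg
        from helpers import fixation_state
        state = fixation_state(cfg, circuit, stimulus=10.0, eye=8.0)
        m = template_match(circuit.decision_input(state), bank)
        best = bank.positions[np.argmax(m)]
        assert abs(best - 10.0) <= 0.5

    def test_match_scale_in_poisson_range(self, cfg, circuit, bank):
        from helpers import fixation_state
        state = fixation_state(cfg, circuit, stimulus=8.0, eye=8.0)
        m = template_match(circuit.decision_input(state), bank)
        assert 0.3 <= m.max() <= 1.0

    def test_zero_input_zero_match(self, bank):
        assert np.all(template_match(np.zeros(79), bank) == 0.0)

    def test_length_mismatch_rejected(self, bank):
        with pytest.raises(ValueError):
            template_match(np.zeros(12), bank)

    def test_cached_by_config(self, cfg, circuit):
        a = build_templates(cfg, 8.0, "intermediate", circuit)
        b = build_templates(cfg, 8.0, "intermediate", circuit)
        assert a is b


class TestPoissonize:
    def test_zero_rate_never_spikes(self, rng):
        assert poissonize(0.0, rng) == 0.0

    def test_saturated_rate_always_spikes(self, rng):
        assert poissonize(1.0, rng, bins=50) == 1.0
        assert poissonize(2.3, rng, bins=50) == 1.0

    def test_half_rate_bernoulli_mean(self, rng):
        vals = [poissonize(0.5, rng) for _ in range(500)]  # 10^4 draws
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_unbiased_on_rate_grid(self, rng):
        # E[poissonize(m)] = min(m, 1) on m in {0, 0.1, ..., 1.2}, 3 SE
        for m in np.arange(0.0, 1.21, 0.1):
            n = 400 * 20
            vals = [poissonize(m, rng) for _ in range(400)]
            p = min(m, 1.0)
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(np.mean(vals) - p) <= max(3 * se, 1e-9)


class TestSplitEvidence:
    POS = np.arange(6.0, 10.5, 0.5)

    def test_border_bin_feeds_both(self):
        m = np.zeros(len(self.POS))
        m[self.POS == 8.0] = 2.0
        m[self.POS == 7.5] = 1.0
        m[self.POS == 8.5] = 3.0
        m_f, m_b = split_evidence(m, self.POS, 8.0)
        assert (m_f, m_b) == (5.0, 3.0)

    def test_all_mass_at_border(self):
        m = np.where(self.POS == 8.0, 4.0, 0.0)
        m_f, m_b = split_evidence(m, self.POS, 8.0)
        assert m_f == m_b == 4.0

    def test_mass_strictly_above_border(self):
        m = np.where(self.POS > 8.0, 1.0, 0.0)
        m_f, m_b = split_evidence(m, self.POS, 8.0)
        assert m_b == 0.0 and m_f == m[self.POS > 8.0].sum()

    def test_off_lattice_border_snaps(self):
        m = np.ones(len(self.POS))
        m_f, m_b = split_evidence(m, self.POS, 8.1)
        assert m_f == m[self.POS >= 8.0].sum()


class TestCompete:
    @pytest.mark.parametrize("mf, mb, expected", [
        (0.5, 0.5, (0.0, 0.0)),
        (0.6, 0.2, (0.4, -0.4)),
        (0.7, 0.0, (0.7, -0.7)),
    ])
    def test_hand_values(self, mf, mb, expected):
        assert compete(mf, mb) == pytest.approx(expected)

    @given(mf=st.floats(0, 100), mb=st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, mf, mb):
        f, b = compete(mf, mb)
        assert f + b == pytest.approx(0.0, abs=1e-9)
        assert f == pytest.approx(mf - mb)


class TestAccumulate:
    def test_closed_form_crossing_time(self, cfg):
        # constant drive 0.2, threshold 0.3, baseline 0.1, tau 50 ms:
        # crossing at (0.3 - 0.1) * 50 / 0.2 = 50 ms
        local = default_config()
        local.decision.d_thresh = 0.3
        trace = DecisionTrace(c_pre=8.0)
        while trace.outcome is None:
            accumulate(trace, 0.2, -0.2, 1.0, local)
        assert trace.decision_time == pytest.approx(50.0)
        assert trace.outcome == "forward"

    def test_weak_drive_times_out_with_larger_accumulator(self, cfg):
        local = default_config()
        local.decision.d_thresh = 0.9
        trace = DecisionTrace(c_pre=8.0)
        for _ in range(100):
            accumulate(trace, 0.05, -0.05, 1.0, local)
        assert trace.outcome is None  # threshold never reached
        assert trace.d_f[-1] == pytest.approx(0.2)
        assert trace.d_b[-1] == 0.0  # floored at zero
        assert trace.d_f[-1] > trace.d_b[-1]

    def test_threshold_monotonicity(self):
        # raising the threshold never decreases the decision time
        times = []
        for thresh in (0.3, 0.6, 0.9):
            local = default_config()
            local.decision.d_thresh = thresh
            trace = DecisionTrace(c_pre=8.0)
            t = 0
            while trace.outcome is None and t < 1000:
                accumulate(trace, 0.25, -0.25, 1.0, local)
                t += 1
            times.append(trace.decision_time)
        assert times == sorted(times)


class TestRunnerUnbiasedness:
    def test_symmetric_input_gives_even_odds(self, cfg):
        # symmetric decision input centered exactly on the border: the
        # forward rate over 400 seeded trials must lie in the binomial
        # 99% CI around 0.5
        positions = np.arange(6.0, 10.5, 0.5)
        templates = np.stack([
            np.exp(-((positions - c) ** 2) / 2.0) for c in positions
        ])
        bank = TemplateBank(positions=positions, templates=templates,
                            scale=0.5 / (templates[0] @ templates[0]))
        i_dp = np.exp(-((positions - 8.0) ** 2) / 2.0)
        wins = 0
        master = np.random.SeedSequence(2024)
        for child in master.spawn(400):
            runner = DecisionRunner(bank, 8.0, cfg,
                                    np.random.default_rng(child))
            while not runner.update(i_dp, 1.0):
                pass
            wins += runner.trace.outcome == "forward"
        # 99% binomial CI around p = 0.5 at n = 400: 0.5 +/- 2.576 * 0.025
        assert abs(wins / 400 - 0.5) <= 2.576 * 0.025

    def test_timeout_and_trace_bookkeeping(self, cfg):
        positions = np.arange(6.0, 10.5, 0.5)
        bank = TemplateBank(positions=positions,
                            templates=np.zeros((len(positions), len(positions))),
                            scale=1.0)
        runner = DecisionRunner(bank, 8.0, cfg, np.random.default_rng(0))
        steps = 0
        while not runner.update(np.zeros(len(positions)), 1.0):
            steps += 1
        assert steps + 1 == cfg.decision.timeout
        assert runner.trace.timed_out
        assert runner.trace.outcome in ("forward", "backward")  # coin flip
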