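"""Timer, sizers, and the event-driven cycle simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chlamycycle.cycle_model import (
    CycleParams,
    LightSchedule,
    accrue_timer,
    commitment_check,
    mitotic_sizer,
    simulate_cycle,
    simulate_lineage,
)
from chlamycycle.growth_kinetics import growth_rate


class TestLightSchedule:
    def test_validation(self):
        with pytest.raises(ValueError):
            LightSchedule([(1.0, 2.0, 100.0)])  # must start at 0
        with pytest.raises(ValueError):
            LightSchedule([(0.0, 1.0, 100.0), (2.0, 3.0, 100.0)])  # gap
        with pytest.raises(ValueError):
            LightSchedule([(0.0, 1.0, -5.0)])  # negative PAR

    def test_condition_labels(self):
        assert LightSchedule.LL(200).condition_label() == "LL"
        assert LightSchedule.LD(200, 5.0).condition_label() == "LD"
        assert LightSchedule.LDL(200, 5.0, 9.0).condition_label() == "LDL"
        assert LightSchedule.L1L2(200, 5.0, 100).condition_label() == "L1L2"

    def test_json_round_trip(self):
        s = LightSchedule.LDL(200, 5.0, 9.0)
        assert LightSchedule.from_json(s.to_json()).segments == s.segments

    def test_dark_duration(self):
        s = LightSchedule.LDL(200, 5.0, 9.0)
        assert s.dark_duration(0.0, 20.0) == pytest.approx(4.0)
        assert s.dark_duration(6.0, 7.0) == pytest.approx(1.0)


class TestCommitmentCheck:
    @pytest.mark.parametrize(
        "v,v0,expected",
        [(160.0, 80.0, True), (159.0, 80.0, False), (87.0, 69.0, False)],
    )
    def test_doubling_gate(self, v, v0, expected):
        assert commitment_check(v, v0) is expected

    def test_shrunk_volume_rejected(self):
        with pytest.raises(ValueError):
            commitment_check(60.0, 80.0)


class TestMitoticSizer:
    @pytest.mark.parametrize(
        "ratio,expected", [(2.5, 2), (3.5, 4), (1.5, 0), (2.0, 2), (2.9, 4)]
    )
    def test_daughter_number_bands(self, ratio, expected):
        assert mitotic_sizer(ratio) == expected

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            mitotic_sizer(0.0)

    @settings(derandomize=True, max_examples=300)
    @given(ratio=st.floats(0.01, 10.0), seed=st.integers(0, 2**16))
    def test_never_odd_even_in_stochastic_band_mode(self, ratio, seed):
        """Asymmetric division (1 or 3 daughters) never occurs."""
        p = CycleParams(stochastic_bands=True)
        n = mitotic_sizer(ratio, p, rng=np.random.default_rng(seed))
        assert n in (0, 2, 4)


class TestAccrueTimer:
    def test_matches_ln_volume_ratio_before_commitment(self, noiseless_params):
        """Pre-commitment the timer is indistinguishable from a sizer."""
        sched = LightSchedule.LL(200)
        mu = growth_rate(200)
        t = 0.5 * math.log(2) / mu  # half-way to commitment
        assert accrue_timer(sched, noiseless_params, t) == pytest.approx(mu * t, rel=1e-12)

    def test_pauses_in_darkness_before_commitment(self, noiseless_params):
        mu = growth_rate(200)
        t_off = math.log(1.5) / mu
        sched = LightSchedule.LDL(200, t_off, t_off + 9.0)
        s_before = accrue_timer(sched, noiseless_params, t_off)
        s_during = accrue_timer(sched, noiseless_params, t_off + 5.0)
        assert s_during == pytest.approx(s_before, rel=1e-12)

    def test_continues_in_darkness_after_commitment(self, noiseless_params):
        mu = growth_rate(200)
        t_off = math.log(3.0) / mu  # committed before light-off
        sched = LightSchedule.LD(200, t_off)
        s = accrue_timer(sched, noiseless_params, t_off + 2.0)
        assert s == pytest.approx(mu * (t_off + 2.0), rel=1e-12)


class TestSimulateCycle:
    @settings(derandomize=True, max_examples=50)
    @given(par=st.floats(5.0, 400.0))
    def test_timer_identity_under_continuous_light(self, par):
        """Noiseless LL: mu * T equals the timer threshold for every PAR."""
        p = CycleParams(cv_mu=0, cv_threshold=0, cv_measurement=0, v0_cv=0)
        res = simulate_cycle(LightSchedule.LL(par), p, v0=80.0)
        mu = growth_rate(par)
        assert res.t_division_entry == pytest.approx(p.timer_threshold / mu, rel=1e-12)
        assert res.ratio_final == pytest.approx(math.exp(p.timer_threshold), rel=1e-12)
        assert res.division_number == 4

    def test_final_ratio_is_4_1(self, noiseless_params):
        res = simulate_cycle(LightSchedule.LL(200), noiseless_params, v0=80.0)
        assert round(res.ratio_final, 1) == 4.1

    def test_ld_entry_depends_only_on_light_rate(self, noiseless_params):
        """Committed LD cells divide at T = threshold/mu regardless of when
        the light went out."""
        mu = growth_rate(200)
        entries = []
        for ratio_off in (2.2, 2.8, 3.5, 4.0):
            sched = LightSchedule.LD(200, math.log(ratio_off) / mu)
            res = simulate_cycle(sched, noiseless_params, v0=80.0)
            entries.append(res.t_division_entry)
        expected = noiseless_params.timer_threshold / mu
        assert entries == pytest.approx([expected] * 4, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(t_dark=st.floats(0.5, 24.0))
    def test_dark_interval_before_commitment_only_shifts_entry(self, t_dark):
        """LDL with an uncommitted dark interval: entry shifts by exactly the
        dark duration and nothing else changes."""
        p = CycleParams(cv_mu=0, cv_threshold=0, cv_measurement=0, v0_cv=0)
        mu = growth_rate(200)
        t_off = math.log(1.5) / mu
        base = simulate_cycle(LightSchedule.LL(200), p, v0=80.0)
        res = simulate_cycle(
            LightSchedule.LDL(200, t_off, t_off + t_dark), p, v0=80.0
        )
        assert res.t_division_entry == pytest.approx(
            base.t_division_entry + t_dark, rel=1e-9
        )
        assert res.ratio_final == pytest.approx(base.ratio_final, rel=1e-9)
        assert res.division_number == base.division_number

    def test_uncommitted_cell_arrests_in_darkness(self, noiseless_params):
        """Light off at V/V0 = 1.5: no division within 48 h of darkness."""
        mu = growth_rate(200)
        t_off = math.log(1.5) / mu
        res = simulate_cycle(
            LightSchedule.LD(200, t_off), noiseless_params, v0=80.0,
            t_max=t_off + 48.0,
        )
        assert res.t_division_entry is None
        assert res.division_number == 0
        assert not res.committed
        assert res.ratio_final == pytest.approx(1.5, rel=1e-12)

    def test_no_growth_at_compensation_par(self, noiseless_params):
        res = simulate_cycle(
            LightSchedule.LL(0.2), noiseless_params, v0=80.0, t_max=100.0
        )
        assert res.ratio_final == pytest.approx(1.0)
        assert res.division_number == 0

    def test_mass_partition_and_subphases(self, noiseless_params):
        res = simulate_cycle(LightSchedule.LL(100), noiseless_params, v0=80.0)
        assert sum(res.daughter_volumes) == pytest.approx(res.v_final, abs=0.0)
        assert len(res.daughter_volumes) == res.division_number
        durations = np.diff(res.subphase_times)
        expected = [
            noiseless_params.subphase_durations[k]
            for k in ("shrinkage", "rotation", "first_mitosis",
                      "second_mitosis", "mitosis_completion")
        ]
        assert durations == pytest.approx(expected)

    def test_division_phase_duration_independent_of_par(self, noiseless_params):
        spans = []
        for par in (10, 40, 200):
            res = simulate_cycle(LightSchedule.LL(par), noiseless_params, v0=80.0)
            spans.append(res.subphase_times[-1] - res.subphase_times[0])
        assert spans[0] == pytest.approx(spans[1]) == pytest.approx(spans[2])

    def test_seeded_run_is_reproducible(self, default_params):
        a = simulate_cycle(LightSchedule.LL(200), default_params, 80.0, rng_seed=7)
        b = simulate_cycle(LightSchedule.LL(200), default_params, 80.0, rng_seed=7)
        assert a.t_division_entry == b.t_division_entry
        assert a.v_final == b.v_final


class TestSimulateLineage:
    def test_quarter_rule_daughter_volume(self, noiseless_params):
        """Mother final volume 277 -> each of 4 daughters starts at 69.25."""
        mu = growth_rate(200)
        v0 = 277.0 / math.exp(noiseless_params.timer_threshold)
        lineage = simulate_lineage(
            LightSchedule.LL(200), noiseless_params, generations=2, v0=v0
        )
        assert lineage[0].v_final == pytest.approx(277.0, rel=1e-12)
        assert lineage[0].division_number == 4
        assert lineage[1].v_initial == pytest.approx(69.25, rel=1e-12)

    def test_binary_split_halves(self, noiseless_params):
        # force one fission by entering division right at ratio 2.5:
        # light off when committed so the final ratio lands in the 2-daughter band
        mu = growth_rate(200)
        sched = LightSchedule.LD(200, math.log(2.5) / mu)
        res = simulate_cycle(sched, noiseless_params, v0=80.0)
        assert res.division_number == 2
        assert res.daughter_volumes == pytest.approx([100.0, 100.0])

    def test_noiseless_lineage_is_stationary_in_muT(self, noiseless_params):
        lineage = simulate_lineage(
            LightSchedule.LL(200), noiseless_params, generations=3, v0=80.0
        )
        products = [r.mu_initial_light * r.t_division_entry for r in lineage]
        assert products == pytest.approx([products[0]] * 3, rel=1e-12)

    def test_lineage_truncates_without_division(self, noiseless_params):
        mu = growth_rate(200)
        sched = LightSchedule.LD(200, math.log(1.5) / mu)
        lineage = simulate_lineage(
            sched, noiseless_params, generations=3, v0=80.0, t_max=30.0
        )
        assert len(lineage) == 1
        assert lineage[0].division_number == 0
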