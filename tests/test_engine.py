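"""Stochastic engine: propensities, SSA statistics, switch and division."""

import math

import numpy as np
import pytest

from chemoton import build_preset, run
from chemoton.engine import (
    DeadlockError,
    SimState,
    apply_switch_rules,
    division_step,
    food_step,
    propensity,
    ssa_step,
)
from chemoton.model import DIVISION, GROWTH, ReactionDef, build_basic_chemoton
from chemoton.model import ChemotonParams

from conftest import micro_spec


def _state(spec, counts, phase=GROWTH, time=0.0):
    base = spec.default_initial_counts()
    base.update(counts)
    return SimState(time=time, counts=base, phase=phase)


class TestPropensity:
    def test_printed_rate_law(self):
        """k1 * |A1| * |X| with the published constants and amounts."""
        spec = build_preset("fig2a")  # X unclamped in influx mode
        r = spec.reactions[0]
        assert r.format() == "A1 + X -> A2"
        st = _state(spec, {"A1": 200, "X": 200})
        assert propensity(r, st, spec) == pytest.approx(2.0 * 200 * 200)

    def test_zero_count_reactant(self, fig2c_spec):
        r = fig2c_spec.reactions[0]
        st = _state(fig2c_spec, {"A1": 0})
        assert propensity(r, st, fig2c_spec) == 0.0

    def test_clamped_species_contributes_clamp_value(self, fig2c_spec):
        r = fig2c_spec.reactions[0]  # A1 + X -> A2, X clamped at 10
        st = _state(fig2c_spec, {"A1": 5, "X": 0})
        assert propensity(r, st, fig2c_spec) == pytest.approx(2.0 * 5 * 10)

    def test_growth_gated_reaction_frozen_in_division(self, fig2c_spec):
        r = fig2c_spec.reactions[0]
        st = _state(fig2c_spec, {"A1": 100}, phase=DIVISION)
        assert propensity(r, st, fig2c_spec) == 0.0

    def test_insufficient_copies_for_stoichiometry(self, fig2c_spec):
        rev = next(
            r for r in fig2c_spec.reactions if r.reactants == (("A1", 2),)
        )
        st = _state(fig2c_spec, {"A1": 1})
        assert propensity(rev, st, fig2c_spec) == 0.0


class TestSsaStep:
    def test_waiting_time_mean(self, rng):
        """Single channel with total propensity 5 -> exponential mean 0.2."""
        spec = micro_spec(
            [ReactionDef((("A", 1),), (("B", 1),), 0.1)], {"A": 50}
        )
        st = _state(spec, {"A": 50})
        n = 10_000
        taus = np.array(
            [ssa_step(st, spec, rng)[0].time for _ in range(n)]
        )
        se = 0.2 / math.sqrt(n)  # exponential: sd == mean
        assert abs(taus.mean() - 0.2) < 3 * se

    def test_channel_selection_frequency(self, rng):
        """Propensities 3:1 -> first channel chosen with frequency 3/4."""
        spec = micro_spec(
            [
                ReactionDef((("A", 1),), (("B", 1),), 3.0),
                ReactionDef((("A", 1),), (("C", 1),), 1.0),
            ],
            {"A": 1},
        )
        st = _state(spec, {"A": 1})
        n = 10_000
        hits = sum(
            ssa_step(st, spec, rng)[0].detail == "A -> B" for _ in range(n)
        )
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_deadlock_signal(self):
        spec = micro_spec([ReactionDef((("A", 1),), (("B", 1),), 1.0)], {})
        st = _state(spec, {"A": 0})
        with pytest.raises(DeadlockError):
            ssa_step(st, spec, np.random.default_rng(0))


class TestSwitchRules:
    def test_growth_to_division_at_critical(self, fig2c_spec):
        st = _state(fig2c_spec, {"Tm": 200})
        new, ev = apply_switch_rules(st, fig2c_spec)
        assert new.phase == DIVISION and ev.kind == "phase_change"

    def test_division_to_growth_at_half(self, fig2c_spec):
        st = _state(fig2c_spec, {"Tm": 100}, phase=DIVISION)
        new, ev = apply_switch_rules(st, fig2c_spec)
        assert new.phase == GROWTH and "Division->Growth" in ev.detail

    def test_no_transition_between_thresholds(self, fig2c_spec):
        st = _state(fig2c_spec, {"Tm": 150})
        new, ev = apply_switch_rules(st, fig2c_spec)
        assert new.phase == GROWTH and ev is None
        st_d = _state(fig2c_spec, {"Tm": 150}, phase=DIVISION)
        new, ev = apply_switch_rules(st_d, fig2c_spec)
        assert new.phase == DIVISION and ev is None


class TestDivisionStep:
    def test_membrane_only_halves_exactly(self, fig2c_spec, rng):
        st = _state(fig2c_spec, {"Tm": 200}, phase=DIVISION)
        # clear everything else
        for k in st.counts:
            if k not in ("Tm", "X"):
                st.counts[k] = 0
        deletions = 0
        while True:
            st, ev = apply_switch_rules(st, fig2c_spec)
            if st.phase == GROWTH:
                break
            _ev, st = division_step(st, fig2c_spec, rng)
            deletions += 1
        assert st.counts["Tm"] == 100 and deletions == 100

    def test_zero_count_species_never_deleted(self, fig2c_spec, rng):
        st = _state(fig2c_spec, {"Tm": 150, "A1": 5}, phase=DIVISION)
        for _ in range(40):
            _ev, st = division_step(st, fig2c_spec, rng)
        assert all(c >= 0 for c in st.counts.values())

    def test_clamped_food_not_deleted(self, fig2c_spec, rng):
        st = _state(fig2c_spec, {"Tm": 150}, phase=DIVISION)
        for _ in range(30):
            _ev, st = division_step(st, fig2c_spec, rng)
        assert st.counts["X"] == 10


class TestFoodStep:
    def test_influx_interarrival_mean(self, rng):
        """Influx rate 10 -> exponential inter-arrival mean 0.1."""
        spec = build_preset("fig2a")
        st = _state(spec, {"X": 0})
        n = 10_000
        taus = np.array([food_step(st, spec, rng)[0].time for _ in range(n)])
        se = 0.1 / math.sqrt(n)
        assert abs(taus.mean() - 0.1) < 3 * se

    def test_constant_count_has_no_food_event(self, fig2c_spec, rng):
        st = _state(fig2c_spec, {})
        assert food_step(st, fig2c_spec, rng) is None

    def test_gated_influx_blocked_while_food_present(self, rng):
        import dataclasses

        from chemoton import get_preset
        from chemoton.model import build_basic_chemoton

        p = get_preset("fig2a")
        spec = build_basic_chemoton(
            dataclasses.replace(p.params, food_mode="gated_influx")
        )
        st = _state(spec, {"X": 3})
        assert food_step(st, spec, rng) is None
        st.counts["X"] = 0
        ev, _new = food_step(st, spec, rng)
        assert ev.kind == "influx"


class TestRun:
    def test_ten_complete_cycles(self, fig2c_traj):
        """Ten divisions -> strictly alternating phase changes, starting
        with Growth->Division and ending with Division->Growth."""
        assert fig2c_traj.n_divisions == 10
        froms = fig2c_traj.pc_from
        assert froms.size == 20
        assert np.array_equal(froms, np.tile([0, 1], 10))
        assert np.all(np.diff(fig2c_traj.pc_times) >= 0)

    def test_exact_post_division_membrane(self, fig2c_traj):
        assert np.all(fig2c_traj.pc_tm[fig2c_traj.pc_from == 1] == 100)

    def test_growth_phase_membrane_ceiling(self, fig2c_traj):
        tm = fig2c_traj.species_series("Tm")
        growth = fig2c_traj.phases == 0
        assert tm[growth].max() <= 200
        assert np.all(fig2c_traj.pc_tm[fig2c_traj.pc_from == 0] == 200)

    def test_clamped_species_constant(self, fig2c_traj):
        assert np.all(fig2c_traj.species_series("X") == 10)

    def test_counts_never_negative(self, fig2c_traj):
        assert fig2c_traj.counts.min() >= 0

    def test_max_time_zero_gives_initial_sample_only(self, fig2c_spec):
        traj = run(fig2c_spec, seed=1, max_time=0.0)
        assert traj.times.size == 1 and traj.times[0] == 0.0
        assert traj.counts[0, traj.spec.species_index("A1")] == 200

    def test_bit_identical_reruns(self, fig2c_spec):
        a = run(fig2c_spec, seed=42, max_divisions=3, sample_interval=0.01)
        b = run(fig2c_spec, seed=42, max_divisions=3, sample_interval=0.01)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.pc_times, b.pc_times)
        assert np.array_equal(a.pc_counts, b.pc_counts)

    def test_seeds_differ(self, fig2c_spec):
        a = run(fig2c_spec, seed=1, max_divisions=3, sample_interval=0.01)
        b = run(fig2c_spec, seed=2, max_divisions=3, sample_interval=0.01)
        assert not np.array_equal(a.times, b.times)

    def test_deadlock_reported_with_final_state(self):
        spec = micro_spec(
            [ReactionDef((("A", 1),), (("B", 1),), 1.0)], {"A": 5}
        )
        traj = run(spec, seed=1, max_time=100.0, sample_interval=1000.0)
        assert traj.stop_reason == "deadlock"
        assert traj.counts[-1, spec.species_index("B")] == 5

    def test_phase_boundary_channel_separation(self, fig2c_spec):
        """No chemistry fires during Division, no deletion during Growth."""
        traj = run(
            fig2c_spec,
            seed=5,
            max_divisions=3,
            sample_interval=0.01,
            record_events=True,
        )
        # reconstruct the phase at each event time from the change log
        changes = [(t, f) for t, f in zip(traj.pc_times, traj.pc_from)]
        for ev in traj.events:
            if ev.kind == "phase_change":
                continue
            phase = 0
            for t, frm in changes:
                if t < ev.time:  # the triggering event precedes the switch
                    phase = 1 - frm
            if ev.kind == "reaction":
                assert phase == 0
            elif ev.kind == "deletion":
                assert phase == 1

    def test_self_regulation(self, fig2c_spec):
        """Perturbing initial counts by +-50% leaves the settled per-cycle
        maxima (cycles 6-15) within 20% in median — the system finds its
        typical amounts regardless of where it starts."""
        from chemoton.analysis import detect_cycles

        def cycle_maxima(traj):
            cyc = detect_cycles(traj)[5:15]
            return {
                n: float(np.median([c.species_max[n] for c in cyc]))
                for n in traj.species
            }

        base = run(fig2c_spec, seed=11, max_divisions=16, sample_interval=0.01)
        mb = cycle_maxima(base)
        for fac, seed in ((0.5, 12), (1.5, 13)):
            init = {"A1": int(200 * fac), "pV0": int(20 * fac), "Tm": int(10 * fac)}
            pert = run(
                fig2c_spec,
                seed=seed,
                max_divisions=16,
                sample_interval=0.01,
                initial_counts=init,
            )
            mp = cycle_maxima(pert)
            rels = [
                abs(mp[n] - mb[n]) / mb[n] for n in mb if mb[n] >= 10
            ]
            assert float(np.median(rels)) < 0.20
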