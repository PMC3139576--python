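"""Phase-gated Gillespie simulation of chemoton networks.

The engine implements the direct stochastic simulation algorithm (SSA) with
full propensity recomputation per step — the network is small (a few dozen
channels), so the direct method is both fast enough and easy to verify.
Three kinds of channels compete, depending on the cell-cycle phase:

* **Growth**: every chemical reaction whose phase gate admits Growth, plus
  the food-influx channel (``influx`` / ``gated_influx`` modes);
* **Division**: one first-order deletion channel per non-clamped species
  (propensity ``deletion_factor * count``), plus the influx channel.  All
  chemoton chemistry freezes.

Phase changes are deterministic and instantaneous: Growth→Division when the
membrane count reaches the critical value, Division→Growth when it falls to
half of it — so the post-division membrane count is exact while every other
species is halved only in expectation.

The inner loop is a single function compiled with numba when available and
executed as plain Python otherwise; both paths consume identical uniform
draws (waiting times are inverted from uniforms explicitly), so a trajectory
is reproducible given ``(spec, seed, stop condition)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    DIVISION,
    GROWTH,
    ModelSpec,
    ReactionDef,
    validate_model,
)

__all__ = [
    "SimState",
    "EventRecord",
    "Trajectory",
    "DeadlockError",
    "CompiledNetwork",
    "compile_network",
    "propensity",
    "ssa_step",
    "apply_switch_rules",
    "division_step",
    "food_step",
    "run",
]

_PHASE_CODE = {GROWTH: 0, DIVISION: 1}
_PHASE_NAME = {0: GROWTH, 1: DIVISION}
_GATE_CODE = {"always": 0, "growth_only": 1, "division_only": 2}

# sample buffer rows per kernel chunk; the wrapper resumes on overflow
_CHUNK_SAMPLES = 200_000
_CHUNK_PHASE_CHANGES = 4_096
_CHUNK_EVENTS = 1_000_000


class DeadlockError(RuntimeError):
    """No channel has positive propensity; the system cannot advance."""


@dataclass
class SimState:
    """Instantaneous simulator state: clock, integer counts and phase."""

    time: float
    counts: dict[str, int]
    phase: str = GROWTH

    def copy(self) -> "SimState":
        return SimState(self.time, dict(self.counts), self.phase)


@dataclass(frozen=True)
class EventRecord:
    """One logged event: a reaction firing, a deletion, an influx arrival or
    a phase change."""

    time: float
    kind: str  # reaction | deletion | influx | phase_change
    detail: str


@dataclass
class Trajectory:
    """A sampled stochastic trajectory plus its phase-change log.

    ``times``/``counts``/``phases`` hold fixed-interval samples; every phase
    change is additionally recorded at its exact event time with a full
    count snapshot (``pc_*`` arrays), so division start/end states are never
    lost to sampling resolution.
    """

    spec: ModelSpec
    seed: int
    times: np.ndarray  # (T,) float64
    counts: np.ndarray  # (T, S) int64
    phases: np.ndarray  # (T,) int8; 0 = Growth, 1 = Division
    pc_times: np.ndarray  # (K,) float64
    pc_from: np.ndarray  # (K,) int8 — phase before the change
    pc_tm: np.ndarray  # (K,) int64 — membrane count at the change
    pc_counts: np.ndarray  # (K, S) int64 — full snapshot at the change
    n_divisions: int
    stop_reason: str  # stop_condition | deadlock
    sample_interval: float
    events: list[EventRecord] = field(default_factory=list)

    @property
    def species(self) -> tuple[str, ...]:
        return self.spec.species_names

    def phase_changes(self) -> list[EventRecord]:
        out = []
        for t, f in zip(self.pc_times, self.pc_from):
            frm = _PHASE_NAME[int(f)]
            to = _PHASE_NAME[1 - int(f)]
            out.append(EventRecord(float(t), "phase_change", f"{frm}->{to}"))
        return out

    def species_series(self, name: str) -> np.ndarray:
        return self.counts[:, self.spec.species_index(name)]

    def to_frame(self):
        """Samples as a pandas DataFrame with derived subsystem totals."""
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "time", self.times)
        df.insert(1, "phase", [_PHASE_NAME[int(p)] for p in self.phases])
        a_cols = [s.name for s in self.spec.species if s.role == "metabolite"]
        df["sum_A"] = df[a_cols].sum(axis=1)
        for lad in self.spec.ladders:
            df[f"sum_p{lad.label}"] = df[list(lad.members())].sum(axis=1)
        return df


# ---------------------------------------------------------------------------
# Network compilation (shared with the ODE oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompiledNetwork:
    """Array form of a ModelSpec for the simulation kernels.

    Net count changes of clamped species are zeroed so clamps hold by
    construction; clamped species still enter propensities via their counts,
    which are set to the clamp value and never touched.
    """

    names: tuple[str, ...]
    counts0: np.ndarray  # (S,) int64 initial counts (clamps applied)
    clamped: np.ndarray  # (S,) bool
    react_idx: np.ndarray  # (R, MR) int64, -1 padded
    react_sto: np.ndarray  # (R, MR) int64
    net_idx: np.ndarray  # (R, MN) int64, -1 padded
    net_delta: np.ndarray  # (R, MN) int64
    rates: np.ndarray  # (R,) float64
    gates: np.ndarray  # (R,) int8
    tm_idx: int
    x_idx: int
    critical: int
    half: int
    food_mode: int  # 0 constant_count, 1 influx, 2 gated_influx
    influx_rate: float
    del_factor: float
    deletable: np.ndarray  # (S,) float64 0/1 mask


def compile_network(
    spec: ModelSpec, initial_counts: dict[str, int] | None = None
) -> CompiledNetwork:
    names = spec.species_names
    index = {n: i for i, n in enumerate(names)}
    S = len(names)
    clamped = np.array([s.clamped for s in spec.species], dtype=bool)
    counts = spec.default_initial_counts()
    if initial_counts:
        for k, v in initial_counts.items():
            if k not in index:
                raise KeyError(f"unknown species {k!r} in initial counts")
            if not spec.species[index[k]].clamped:
                counts[k] = int(v)
    counts0 = np.array([counts[n] for n in names], dtype=np.int64)

    R = len(spec.reactions)
    mr = max(sum(1 for _ in r.reactants) for r in spec.reactions)
    react_idx = -np.ones((R, mr), dtype=np.int64)
    react_sto = np.zeros((R, mr), dtype=np.int64)
    net_rows: list[dict[int, int]] = []
    for ri, r in enumerate(spec.reactions):
        net: dict[int, int] = {}
        for k, (sp, c) in enumerate(r.reactants):
            react_idx[ri, k] = index[sp]
            react_sto[ri, k] = c
            net[index[sp]] = net.get(index[sp], 0) - c
        for sp, c in r.products:
            net[index[sp]] = net.get(index[sp], 0) + c
        net = {i: d for i, d in net.items() if d != 0 and not clamped[i]}
        net_rows.append(net)
    mn = max(1, max(len(n) for n in net_rows))
    net_idx = -np.ones((R, mn), dtype=np.int64)
    net_delta = np.zeros((R, mn), dtype=np.int64)
    for ri, net in enumerate(net_rows):
        for k, (i, d) in enumerate(sorted(net.items())):
            net_idx[ri, k] = i
            net_delta[ri, k] = d
    rates = np.array([r.rate_constant for r in spec.reactions], dtype=np.float64)
    gates = np.array(
        [_GATE_CODE[r.phase_gate] for r in spec.reactions], dtype=np.int8
    )
    p = spec.params
    food_mode = {"constant_count": 0, "influx": 1, "gated_influx": 2}[p.food_mode]
    deletable = (~clamped).astype(np.float64)
    return CompiledNetwork(
        names=names,
        counts0=counts0,
        clamped=clamped,
        react_idx=react_idx,
        react_sto=react_sto,
        net_idx=net_idx,
        net_delta=net_delta,
        rates=rates,
        gates=gates,
        tm_idx=index[spec.membrane_count_species],
        x_idx=index["X"] if "X" in index else 0,
        critical=p.critical_Tm,
        half=p.critical_Tm // 2,
        food_mode=food_mode,
        influx_rate=p.influx_rate,
        del_factor=p.deletion_factor,
        deletable=deletable,
    )


# ---------------------------------------------------------------------------
# Reference (per-call) operations
# ---------------------------------------------------------------------------


def propensity(reaction: ReactionDef, state: SimState, spec: ModelSpec) -> float:
    """Mass-action propensity of one channel in the current state.

    Raw-count convention: ``k * prod(count^stoich)`` (one factor per
    stoichiometric unit, no combinatorial correction), zero when any
    reactant count is below its stoichiometry or the phase gate excludes
    the current phase.
    """
    gate = reaction.phase_gate
    if gate == "growth_only" and state.phase != GROWTH:
        return 0.0
    if gate == "division_only" and state.phase != DIVISION:
        return 0.0
    a = reaction.rate_constant
    for sp, sto in reaction.reactants:
        c = state.counts.get(sp, 0)
        sdef = spec.get_species(sp)
        if sdef.clamped:
            c = sdef.clamp_value
        if c < sto:
            return 0.0
        a *= float(c) ** sto
    return a


def _apply_reaction(state: SimState, reaction: ReactionDef, spec: ModelSpec) -> None:
    for sp, c in reaction.reactants:
        if not spec.get_species(sp).clamped:
            state.counts[sp] -= c
    for sp, c in reaction.products:
        if not spec.get_species(sp).clamped:
            state.counts[sp] = state.counts.get(sp, 0) + c


def ssa_step(
    state: SimState, spec: ModelSpec, rng: np.random.Generator
) -> tuple[EventRecord, SimState]:
    """One direct-method SSA step over the phase-active reaction channels.

    Waiting time is exponential in the total propensity; the channel is
    chosen with probability proportional to its propensity.  Raises
    :class:`DeadlockError` when no channel can fire.
    """
    props = [propensity(r, state, spec) for r in spec.reactions]
    total = float(sum(props))
    if total <= 0.0:
        raise DeadlockError("no active reaction channel has positive propensity")
    tau = -math.log(1.0 - rng.random()) / total
    pick = rng.random() * total
    acc = 0.0
    chosen = len(props) - 1
    for i, a in enumerate(props):
        acc += a
        if pick < acc:
            chosen = i
            break
    new = state.copy()
    new.time += tau
    _apply_reaction(new, spec.reactions[chosen], spec)
    return EventRecord(new.time, "reaction", spec.reactions[chosen].name), new


def apply_switch_rules(
    state: SimState, spec: ModelSpec
) -> tuple[SimState, EventRecord | None]:
    """Fire at most one deterministic phase transition at the current time."""
    tm = spec.membrane_count_species
    count = state.counts.get(tm, 0)
    p = spec.params
    if state.phase == GROWTH and count >= p.critical_Tm:
        new = state.copy()
        new.phase = DIVISION
        return new, EventRecord(state.time, "phase_change", f"{GROWTH}->{DIVISION}")
    if state.phase == DIVISION and count <= p.critical_Tm // 2:
        new = state.copy()
        new.phase = GROWTH
        return new, EventRecord(state.time, "phase_change", f"{DIVISION}->{GROWTH}")
    return state, None


def division_step(
    state: SimState, spec: ModelSpec, rng: np.random.Generator
) -> tuple[EventRecord, SimState]:
    """One deletion event of the division protocol.

    Every non-clamped species (the membrane count included) carries a
    first-order deletion channel of propensity ``deletion_factor * count``;
    the winner loses exactly one molecule.
    """
    if state.phase != DIVISION:
        raise ValueError("division_step requires the Division phase")
    f = spec.params.deletion_factor
    names = [s.name for s in spec.species if not s.clamped]
    props = [f * state.counts.get(n, 0) for n in names]
    total = float(sum(props))
    if total <= 0.0:
        raise DeadlockError("nothing left to delete during division")
    tau = -math.log(1.0 - rng.random()) / total
    pick = rng.random() * total
    acc = 0.0
    chosen = len(names) - 1
    for i, a in enumerate(props):
        acc += a
        if pick < acc:
            chosen = i
            break
    new = state.copy()
    new.time += tau
    new.counts[names[chosen]] -= 1
    return EventRecord(new.time, "deletion", names[chosen]), new


def food_step(
    state: SimState, spec: ModelSpec, rng: np.random.Generator
) -> tuple[EventRecord, SimState] | None:
    """One food-influx arrival (``influx``/``gated_influx`` modes only).

    Returns ``None`` when the channel cannot fire (constant-count mode, or a
    gated channel with food still present).
    """
    p = spec.params
    if p.food_mode == "constant_count":
        return None
    if p.food_mode == "gated_influx" and state.counts.get("X", 0) != 0:
        return None
    tau = -math.log(1.0 - rng.random()) / p.influx_rate
    new = state.copy()
    new.time += tau
    new.counts["X"] = new.counts.get("X", 0) + 1
    return EventRecord(new.time, "influx", "X"), new


# ---------------------------------------------------------------------------
# Simulation kernel (numba-compiled when available)
# ---------------------------------------------------------------------------


def _sim_core(
    counts,
    t,
    phase,
    ndiv,
    nev,
    next_sample,
    react_idx,
    react_sto,
    net_idx,
    net_delta,
    rates,
    gates,
    tm_idx,
    critical,
    half,
    food_mode,
    influx_rate,
    x_idx,
    del_factor,
    deletable,
    dt,
    max_time,
    max_divisions,
    max_events,
    samp_t,
    samp_c,
    samp_ph,
    pc_t,
    pc_from,
    pc_tm,
    pc_counts,
    ev_t,
    ev_kind,
    ev_detail,
    record_events,
    seed,
    do_seed,
):
    # status: 0 stop reached, 1 buffers full (resume), 2 deadlock
    if do_seed:
        np.random.seed(seed)
    R = rates.shape[0]
    S = counts.shape[0]
    a = np.zeros(R + S + 1)
    ns = 0
    npc = 0
    nel = 0
    samp_cap = samp_t.shape[0]
    pc_cap = pc_t.shape[0]
    ev_cap = ev_t.shape[0]
    status = 0
    while True:
        if max_divisions >= 0 and ndiv >= max_divisions:
            break
        if max_events >= 0 and nev >= max_events:
            break
        if t >= max_time:
            break
        if ns >= samp_cap or npc >= pc_cap or (record_events and nel >= ev_cap):
            status = 1
            break
        # propensities
        total = 0.0
        for r in range(R):
            g = gates[r]
            active = (g == 0) or (phase == 0 and g == 1) or (phase == 1 and g == 2)
            p = 0.0
            if active:
                p = rates[r]
                for k in range(react_idx.shape[1]):
                    idx = react_idx[r, k]
                    if idx < 0:
                        break
                    sto = react_sto[r, k]
                    c = counts[idx]
                    if c < sto:
                        p = 0.0
                        break
                    for _q in range(sto):
                        p *= c
            a[r] = p
            total += p
        for s in range(S):
            p = 0.0
            if phase == 1:
                p = del_factor * counts[s] * deletable[s]
            a[R + s] = p
            total += p
        p = 0.0
        if food_mode == 1:
            p = influx_rate
        elif food_mode == 2 and counts[x_idx] == 0:
            p = influx_rate
        a[R + S] = p
        total += p
        if total <= 0.0:
            status = 2
            break
        u = np.random.random()
        tau = -np.log(1.0 - u) / total
        t_next = t + tau
        if next_sample <= max_time and next_sample <= t_next:
            # record the pre-event state at the sampling instant and redraw
            # (valid by memorylessness of the exponential waiting time)
            t = next_sample
            samp_t[ns] = t
            for s in range(S):
                samp_c[ns, s] = counts[s]
            samp_ph[ns] = phase
            ns += 1
            next_sample += dt
            continue
        if t_next > max_time:
            t = max_time
            break
        t = t_next
        pick = np.random.random() * total
        acc = 0.0
        chosen = R + S
        for i in range(R + S + 1):
            acc += a[i]
            if pick < acc:
                chosen = i
                break
        if chosen < R:
            for k in range(net_idx.shape[1]):
                idx = net_idx[chosen, k]
                if idx < 0:
                    break
                counts[idx] += net_delta[chosen, k]
            kind = 0
            detail = chosen
        elif chosen < R + S:
            counts[chosen - R] -= 1
            kind = 1
            detail = chosen - R
        else:
            counts[x_idx] += 1
            kind = 2
            detail = x_idx
        nev += 1
        if record_events and nel < ev_cap:
            ev_t[nel] = t
            ev_kind[nel] = kind
            ev_detail[nel] = detail
            nel += 1
        # deterministic two-state switch
        if phase == 0 and counts[tm_idx] >= critical:
            phase = 1
            pc_t[npc] = t
            pc_from[npc] = 0
            pc_tm[npc] = counts[tm_idx]
            for s in range(S):
                pc_counts[npc, s] = counts[s]
            npc += 1
        elif phase == 1 and counts[tm_idx] <= half:
            phase = 0
            ndiv += 1
            pc_t[npc] = t
            pc_from[npc] = 1
            pc_tm[npc] = counts[tm_idx]
            for s in range(S):
                pc_counts[npc, s] = counts[s]
            npc += 1
    return t, phase, ndiv, nev, ns, npc, nel, status, next_sample


try:  # compiled fast path; the plain-Python function is the fallback
    import numba as _numba

    _sim_core_fast = _numba.njit(cache=True)(_sim_core)
except Exception:  # pragma: no cover - numba is a declared dependency
    _sim_core_fast = _sim_core


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run(
    spec: ModelSpec,
    *,
    seed: int,
    max_time: float | None = None,
    max_divisions: int | None = None,
    max_events: int | None = None,
    sample_interval: float = 0.1,
    record_events: bool = False,
    initial_counts: dict[str, int] | None = None,
) -> Trajectory:
    """Simulate ``spec`` until a stop condition and return the trajectory.

    Exactly reproducible: identical ``(spec, seed, stop, sample_interval)``
    yield identical trajectories.  ``initial_counts`` overrides the model's
    defaults for non-clamped species.  At least one stop condition is
    required; a deadlocked system terminates early with
    ``stop_reason == "deadlock"`` and the final state in the last sample.
    """
    problems = validate_model(spec)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    if max_time is None and max_divisions is None and max_events is None:
        raise ValueError("at least one stop condition is required")
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    net = compile_network(spec, initial_counts)
    counts = net.counts0.copy()
    S = counts.shape[0]

    t = 0.0
    phase = 0
    # initial switch check (e.g. starting at/above the critical count)
    if counts[net.tm_idx] >= net.critical:
        phase = 1

    mt = math.inf if max_time is None else float(max_time)
    md = -1 if max_divisions is None else int(max_divisions)
    me = -1 if max_events is None else int(max_events)

    all_t = [np.array([t])]
    all_c = [counts.copy()[None, :]]
    all_p = [np.array([phase], dtype=np.int8)]
    pcs_t: list[np.ndarray] = []
    pcs_from: list[np.ndarray] = []
    pcs_tm: list[np.ndarray] = []
    pcs_counts: list[np.ndarray] = []
    events: list[EventRecord] = []

    ndiv = 0
    nev = 0
    next_sample = sample_interval
    do_seed = True
    stop_reason = "stop_condition"
    ev_cap = _CHUNK_EVENTS if record_events else 1
    while True:
        samp_t = np.empty(_CHUNK_SAMPLES)
        samp_c = np.empty((_CHUNK_SAMPLES, S), dtype=np.int64)
        samp_ph = np.empty(_CHUNK_SAMPLES, dtype=np.int8)
        pc_t = np.empty(_CHUNK_PHASE_CHANGES)
        pc_from = np.empty(_CHUNK_PHASE_CHANGES, dtype=np.int8)
        pc_tm = np.empty(_CHUNK_PHASE_CHANGES, dtype=np.int64)
        pc_counts = np.empty((_CHUNK_PHASE_CHANGES, S), dtype=np.int64)
        ev_t = np.empty(ev_cap)
        ev_kind = np.empty(ev_cap, dtype=np.int8)
        ev_detail = np.empty(ev_cap, dtype=np.int64)
        t, phase, ndiv, nev, ns, npc, nel, status, next_sample = _sim_core_fast(
            counts,
            t,
            phase,
            ndiv,
            nev,
            next_sample,
            net.react_idx,
            net.react_sto,
            net.net_idx,
            net.net_delta,
            net.rates,
            net.gates,
            net.tm_idx,
            net.critical,
            net.half,
            net.food_mode,
            net.influx_rate,
            net.x_idx,
            net.del_factor,
            net.deletable,
            float(sample_interval),
            mt,
            md,
            me,
            samp_t,
            samp_c,
            samp_ph,
            pc_t,
            pc_from,
            pc_tm,
            pc_counts,
            ev_t,
            ev_kind,
            ev_detail,
            record_events,
            int(seed) & 0x7FFFFFFF,
            do_seed,
        )
        do_seed = False
        if ns:
            all_t.append(samp_t[:ns].copy())
            all_c.append(samp_c[:ns].copy())
            all_p.append(samp_ph[:ns].copy())
        if npc:
            pcs_t.append(pc_t[:npc].copy())
            pcs_from.append(pc_from[:npc].copy())
            pcs_tm.append(pc_tm[:npc].copy())
            pcs_counts.append(pc_counts[:npc].copy())
        if record_events and nel:
            kinds = ("reaction", "deletion", "influx")
            for i in range(nel):
                k = kinds[int(ev_kind[i])]
                if k == "reaction":
                    detail = spec.reactions[int(ev_detail[i])].name
                else:
                    detail = net.names[int(ev_detail[i])]
                events.append(EventRecord(float(ev_t[i]), k, detail))
        if status == 1:
            continue
        if status == 2:
            stop_reason = "deadlock"
        # record the final state at termination (unless already sampled there)
        last_t = all_t[-1][-1] if all_t[-1].size else -1.0
        if t > last_t:
            all_t.append(np.array([t]))
            all_c.append(counts.copy()[None, :])
            all_p.append(np.array([phase], dtype=np.int8))
        break

    def _cat(parts, dtype=None):
        if not parts:
            return np.empty((0,), dtype=dtype or float)
        return np.concatenate(parts)

    traj = Trajectory(
        spec=spec,
        seed=int(seed),
        times=_cat(all_t),
        counts=np.concatenate(all_c) if all_c else np.empty((0, S), dtype=np.int64),
        phases=_cat(all_p, np.int8),
        pc_times=_cat(pcs_t),
        pc_from=_cat(pcs_from, np.int8),
        pc_tm=_cat(pcs_tm, np.int64),
        pc_counts=(
            np.concatenate(pcs_counts)
            if pcs_counts
            else np.empty((0, S), dtype=np.int64)
        ),
        n_divisions=int(ndiv),
        stop_reason=stop_reason,
        sample_interval=float(sample_interval),
        events=events,
    )
    if record_events:
        traj.events = sorted(
            events + traj.phase_changes(), key=lambda e: e.time
        )
    else:
        traj.events = traj.phase_changes()
    return traj
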