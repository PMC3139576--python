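# Methods

## Model structure

The simulator works on explicit reaction networks (`ModelSpec`): species
with roles, elementary mass-action reactions, one or two template ladders,
and the two switch rules of the cell-cycle controller. Reversible
reactions are represented as forward/backward elementary pairs. Propensities
follow the raw-count convention `k · Π count^stoich` (one factor per
stoichiometric unit, no combinatorial `n(n−1)/2` correction); a channel is
disabled whenever a reactant count falls below its stoichiometry, which
only matters for the `2·A1 → Am` reverse step. Time is dimensionless; all
constants share that base.

### Metabolic cycle

The canonical five-member cycle is

```
A1 + X ⇌ A2          (k = 2.0, k′ = 0.1)
A2  →  A3 (+ Y)      waste release; reverse omitted (see below)
A3  ⇌  A4 + V        monomer release (U in the double model)
A4  ⇌  A5 + T′       membrane-precursor release
A5  ⇌  2·A1          cycle closure, doubling the seed metabolite
```

Only the first forward/backward pair is pinned by the published constants;
every other forward constant defaults to 2.0 and every reverse to 0.1
(uniform generalization of the single printed pair; all individually
configurable). Waste `Y` is declared but discarded by default
(`track_waste=True` stores it inertly); no reaction consumes it, so the
reverse of the `Y`-releasing step is never emitted.

For cycle sizes `m ≠ 5`, extra metabolites are inserted into the
food-assimilation segment at the front of the cycle: each added step is
`A_i + X ⇌ A_{i+1}`, and the three byproduct-releasing steps stay at fixed
distance from the closure step (positions `m−3`, `m−2`, `m−1`). This
placement was a genuinely open design choice; we also implemented
proportional rescaling of the release positions and found it inflates the
time-averaged metabolite total roughly four-fold for `m = 12`, destroying
the observed near-identity of small and large cycles, whereas the
fixed-distance placement reproduces it (the residual effect is a ~1%
*decrease* for `m = 12`, resolvable only with long, many-seed averages).
Positions remain overridable via `ChemotonParams.byproduct_steps`. For
`m < 5` the release steps collide and are merged into non-elementary steps
with a warning; the resulting 3-member cycle behaves almost identically to
the 5-member one (period medians within 10%).

### Template ladders

A ladder of half-length `n` (default 6) has stage species `pX(0) … pX(n−1)`.
Default kinetics are two-step: association `pX(i) + X ⇌ pX(i)·X`
(`k6`, `k6r`) followed by irreversible condensation `pX(i)·X → pX(i+1) + R`
(`k7`); the terminal condensation yields `2·pX(0) + R`. A `one_step` mode
(single constant `k7`) is available for comparison. Two constants per
ladder are published (`k6`, `k7` = 1 in the reference experiments, with
`k_W7 ∈ {1, 10, 100}`); the dissociation constant `k6r` defaults to the
uniform reverse 0.1. Bound complexes count toward a template's total copy
number by default (they are part of the template subsystem); an exclusion
flag supports comparison with one-step runs.

### Membrane

`R + T′ → T` (`k_mem = 2.0`) followed by incorporation. The incorporation
kinetics are not published; the default is membrane-autocatalytic,
`T + T_m → 2·T_m` with propensity `k_inc·|T|·|T_m|` (`k_inc = 1.0`), which
makes the boundary subsystem autocatalytic like the other two. A
first-order variant (`membrane_autocatalytic=False`, propensity
`k_inc·|T|`) is provided; neither is asserted canonical. Because
incorporation is fast in either reading, the choice does not measurably
change cycle structure.

### Cell-cycle switch and division

The two-state switch is deterministic and instantaneous: Growth→Division
when `|T_m| ≥ critical_Tm`, Division→Growth when `|T_m| ≤ critical_Tm/2`.
Triggers are implemented as threshold crossings rather than equalities
(equivalent under ±1 updates, robust otherwise). During Division every
chemical reaction freezes and each non-clamped species — bound complexes
and `T` included — carries a first-order deletion channel with propensity
`deletion_factor · count`, simulated by the same SSA mechanics. Division
ends exactly at `critical_Tm/2` membrane molecules, so the membrane
halving is deterministic while all other species halve in expectation
(verified: pooled survival fractions over 200 divisions lie within
[0.45, 0.55] for all well-populated species). `deletion_factor` defaults
to 10.0; the two-template experiments use 0.1 (100× slower removal, as in
the corresponding published runs — outcome-neutral because the endpoint is
exact).

### Food supply

Three modes: `constant_count` (X clamped — it enters propensities at its
clamp value but is never consumed), `influx` (a channel of constant
propensity `influx_rate` adds one X per firing, active in both phases),
and `gated_influx` (the literal reading of the published event: the
channel is active only while `|X| = 0`). The experiment presets with
influx use the ungated mode, following the prose ("constantly added") and
the captions; the gated mode is available via `--gated-influx` or the
config.

## Engine

Gillespie direct method with full propensity recomputation per event — the
networks have only a few dozen channels, so the simpler variant is both
fast and easy to verify against closed forms. The inner loop is one
function compiled with numba (pure-Python fallback executes the same code
and consumes the same uniform draws: exponential waiting times are
inverted from uniforms explicitly, so trajectories are reproducible given
`(model, seed, stop condition)` regardless of backend). Fixed-interval
state sampling is implemented as a pseudo-event: if the next sample
instant precedes the next reaction, the state is recorded there and the
waiting time redrawn — statistically exact by memorylessness. Every phase
change is additionally logged at its exact time with a full count
snapshot, so division start/end states are independent of the sampling
resolution. Full event logging is available (`record_events=True`) but off
by default.

Deadlock (total propensity zero) terminates the run cleanly with the final
state recorded and `stop_reason="deadlock"`, distinct from normal stop
conditions (max time / divisions / events).

## Deterministic oracle

`ode_oracle` translates any `ModelSpec` into mass-action ODEs with the
same constants and phase gating; counts are used directly as continuous
amounts (no volume conversion), and clamped species have zero derivative.
Integration uses LSODA with `rtol = atol = 1e−8`. Division is idealized as
instantaneous halving of all non-clamped amounts when the membrane amount
crosses the critical value (terminal event detection). The deterministic
basic model settles into clockwork cycles (successive periods differ by
<1% after the first five; the period converges to ≈5.78 under the
constant-food reference conditions). Validation uses non-dividing
subnetworks (`A + X ⇌ B`): the SSA ensemble mean tracks the ODE within
three standard errors, the stationary mean matches the detailed-balance
fixed point `B/A = k·X/k′`, and rescaling counts ×10 with bimolecular
constants ÷10 shrinks single-run deviations from the ODE (thermodynamic
limit). The `|X|=0`-gated influx has no continuous analogue and is
rejected by the integrator.

## Analysis conventions

Cycles are delimited by Division→Growth events (the trajectory start seeds
the first cycle); the trailing incomplete cycle is dropped. Analyses
discard a transient of 3 completed divisions by default — initial amounts
are arbitrary and the system self-regulates to its typical levels
(perturbing initial counts by ±50% changes settled per-cycle maxima by
<20% in median). Coexistence requires both template totals strictly
positive at every post-burn-in sample; the minimum fraction statistic is
`min(ΣpV, ΣpW)/(ΣpV+ΣpW)` minimized over samples. Persistence is monotone
non-decreasing in the burn-in (a longer burn-in only removes
constraints).

Monte-Carlo regression bounds used in tests (template-load agreement 15%,
period CV 0.25, symmetric-share band [0.35, 0.65], m3-vs-m5 period medians
10%) are repository thresholds for qualitative published claims, not
published numbers.

## Problem sizes

Test and acceptance runs use desk-scale protocols: 5–20 divisions per
run, 3–10 seeds for qualitative claims, 100-run ensembles for mean
agreement, 200 divisions for halving statistics, and 40 seeds × 20
divisions for the ~1% metabolic-size effect, which smaller protocols
cannot resolve in either direction.

## Known limitations

* The slow template in the 100:1 polymerization-rate experiment is
  marginally viable: six condensations at `k7 = 1` bound its per-copy
  doubling time (≥6 time units) against a ~10-unit cell period, so its
  self-regulated load is only ~10–30 copies and drifts to extinction in
  roughly 5% of 10-division runs (extinction can only occur at a division,
  since growth-phase totals are non-decreasing). Single published
  trajectories showing coexistence are consistent with this rate; the
  unpublished precursor-exchange constants (`kV`, `kVr`) set the stiffness
  of the stabilizing feedback and hence this margin.
* Membrane geometry, osmotic pressure, volume and surface variables are
  outside scope; division is triggered purely by the membrane count.
* Heteropolymers, mutation and template evolution are not modelled; the
  polycondensation threshold of classical chemoton formulations is
  deliberately omitted (it is unnecessary for growth–division cycling).
* The generator emulates well-mixed mass-action kinetics with clamped
  environments; real protocell chemistries have crowding, spatial
  structure and fluctuating food, none of which these tests probe.
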