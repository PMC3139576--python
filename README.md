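# chemoton

Stochastic simulation of the **chemoton** — Gánti's minimal model of a
living cell — including the extension in which two template replicators
with different polymerization rates compete inside one protocell.

## The model

A chemoton couples three autocatalytic subsystems through fixed
stoichiometry:

* **Metabolism** `A1 … Am`: an autocatalytic cycle that consumes food `X`
  (`A1 + X ⇌ A2`, rate `k1·|A1|·|X|`), releases waste `Y`, a template
  monomer `V` (or its precursor `U`), and a membrane precursor `T′`, and
  closes with `Am ⇌ 2·A1`, doubling the seed metabolite once per turn.
* **Template polymerization** `pV(0) … pV(n−1)`: a double-stranded
  homopolymer grows by single monomer incorporations
  (`pV(i) + V → pV(i+1) + R`), each releasing a condensation byproduct `R`;
  the *n*-th incorporation splits the duplex into two `pV(0)` copies.
* **Membrane**: `R + T′ → T`, and incorporation of `T` into the boundary
  increments the membrane count `T_m`.

All reactions are simulated exactly with the Gillespie direct method
(mass-action propensities on raw molecule counts, dimensionless time).
A deterministic two-state switch controls the cell cycle: when `T_m`
reaches a critical value the cell enters a **Division** phase in which all
chemistry freezes and every non-clamped species is deleted at a common
per-capita rate until `T_m` reaches exactly half the critical count — so
the membrane halving is exact while every other species halves only in
expectation.

In the double-template variant the monomers `V` and `W` share a precursor
`U` (`U + Z1 ⇌ V`, `U + Z2 ⇌ W`, with `Z1`, `Z2` clamped). Because all
subsystems are stoichiometrically coupled, the two template cycles coexist
across division cycles even when one polymerizes 10–100× faster — a
compartment-level escape from Eigen's paradox.

A mass-action ODE counterpart of any model (same constants, counts used as
continuous amounts, division idealized as instantaneous halving) serves as
an oracle for validating the stochastic engine's mean behaviour.

## Worked example

```python
from chemoton import build_preset, run, detect_cycles
import numpy as np

spec = build_preset("fig2c")          # basic chemoton, X clamped at 10
traj = run(spec, seed=1, max_divisions=10, sample_interval=0.01)
cycles = detect_cycles(traj)
periods = [c.period for c in cycles]
print(f"divisions completed : {traj.n_divisions}")
print(f"membrane count after each division: "
      f"{sorted(set(traj.pc_tm[traj.pc_from == 1].tolist()))}")
print(f"period mean (cycles 4-10): {np.mean(periods[3:]):.2f}")
```

prints

```
divisions completed : 10
membrane count after each division: [100]
period mean (cycles 4-10): 7.07
```

The run starts from 200 `A1`, 20 `pV(0)` and 10 `T_m` with the division
threshold at 200: the cell grows, divides when `T_m` hits 200, and every
division leaves exactly 100 membrane molecules; after a short transient the
cycle period settles (clockwork-like oscillations). The same API drives the
two-template experiments:

```python
from chemoton import coexistence_metrics
traj = run(build_preset("fig3r3"), seed=1, max_divisions=10, sample_interval=0.05)
rep = coexistence_metrics(traj)
print(rep.persisted, rep.n_species_persisting,
      round(rep.totals["V"].mean(), 1), round(rep.totals["W"].mean(), 1))
# True 2 20.6 73.1
```

Here `pW` polymerizes 100× faster than `pV` (`k_W7 = 100`), yet both
templates persist across ten divisions — the shared precursor and the
periodic fission keep the slow template in the population.

## Command line

```sh
chemoton list-presets
chemoton simulate --preset fig3r3 --seed 1 --stop-divisions 10 --out out/
chemoton analyze --traj out/fig3r3_seed1.tsv --events out/fig3r3_seed1_events.tsv --preset fig3r3
chemoton compare --preset-a fig5m5 --preset-b fig5m12 --json-summary
chemoton export-model --preset fig2c
```

Presets transcribe the published run conditions (figure-panel initial
amounts, clamps, thresholds and rate constants); configs are YAML files
that round-trip through `save_config`/`load_config`.

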