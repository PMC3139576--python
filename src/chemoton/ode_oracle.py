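"""Deterministic mass-action counterpart of a chemoton network.

Used to validate the stochastic engine's mean behaviour: the same species,
reactions, rate constants and phase gating are translated into ordinary
differential equations, with molecule *counts* used directly as continuous
amounts (the rate functions operate on cardinalities, so no volume
conversion is applied and constants are shared exactly).

Cell division has a deterministic idealization here: when the membrane
amount reaches the critical value, every non-clamped amount is halved
instantaneously — the limit of the stochastic deletion protocol in which
every species halves in expectation while the membrane count halves
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import DIVISION, GROWTH, ModelSpec
from .engine import CompiledNetwork, compile_network

__all__ = ["OdeSystem", "OdeResult", "build_ode", "ode_rhs", "integrate"]


@dataclass(frozen=True)
class OdeSystem:
    """Precompiled derivative map for one model and phase."""

    spec: ModelSpec
    net: CompiledNetwork

    def rhs(self, amounts: np.ndarray, phase: str = GROWTH) -> np.ndarray:
        """Mass-action derivatives; clamped species have zero derivative.

        During Division only division-gated chemistry is active (the default
        networks have none) — the stochastic deletion protocol itself has no
        deterministic analogue beyond the halving rule applied by
        :func:`integrate`.
        """
        n = self.net
        phase_code = 0 if phase == GROWTH else 1
        y = np.asarray(amounts, dtype=float)
        yc = np.maximum(y, 0.0)
        dy = np.zeros_like(y)
        R = n.rates.shape[0]
        for r in range(R):
            g = n.gates[r]
            active = (
                g == 0
                or (phase_code == 0 and g == 1)
                or (phase_code == 1 and g == 2)
            )
            if not active:
                continue
            v = n.rates[r]
            for k in range(n.react_idx.shape[1]):
                idx = n.react_idx[r, k]
                if idx < 0:
                    break
                v *= yc[idx] ** n.react_sto[r, k]
            for k in range(n.net_idx.shape[1]):
                idx = n.net_idx[r, k]
                if idx < 0:
                    break
                dy[idx] += n.net_delta[r, k] * v
        if n.food_mode == 1:  # constant-rate influx; the |X|=0 gate is
            dy[n.x_idx] += n.influx_rate  # discontinuous and not modelled here
        dy[n.clamped] = 0.0
        return dy


@dataclass
class OdeResult:
    """Deterministic trajectory (phase is Growth except at halving instants)."""

    times: np.ndarray  # (T,)
    amounts: np.ndarray  # (T, S)
    species: tuple[str, ...]
    division_times: np.ndarray  # (K,)
    success: bool
    message: str

    def periods(self) -> np.ndarray:
        return np.diff(self.division_times)

    def series(self, name: str) -> np.ndarray:
        return self.amounts[:, self.species.index(name)]


def build_ode(spec: ModelSpec) -> OdeSystem:
    return OdeSystem(spec=spec, net=compile_network(spec))


def ode_rhs(
    spec: ModelSpec, amounts: np.ndarray | dict[str, float], phase: str = GROWTH
) -> np.ndarray:
    """Derivative vector at ``amounts`` (array in species order, or a dict)."""
    sys = build_ode(spec)
    if isinstance(amounts, dict):
        y = np.zeros(len(sys.net.names))
        for k, v in amounts.items():
            y[spec.species_index(k)] = v
        y[sys.net.clamped] = sys.net.counts0[sys.net.clamped]
    else:
        y = np.asarray(amounts, dtype=float)
    return sys.rhs(y, phase)


def integrate(
    spec: ModelSpec,
    t_span: tuple[float, float],
    initial_amounts: dict[str, float] | np.ndarray | None = None,
    *,
    division_protocol: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    max_divisions: int | None = None,
    method: str = "LSODA",
) -> OdeResult:
    """Integrate the deterministic system, optionally with halving divisions.

    With ``division_protocol`` on, integration stops whenever the membrane
    amount crosses the critical value from below, all non-clamped amounts
    are halved, and integration resumes — producing the deterministic
    clockwork cell cycle.  Stiff-capable by default (LSODA, atol 1e-8).
    """
    if spec.params.food_mode == "gated_influx":
        raise ValueError(
            "gated_influx has no continuous analogue; use influx or constant_count"
        )
    sys = build_ode(spec)
    n = sys.net
    if initial_amounts is None:
        y = n.counts0.astype(float)
    elif isinstance(initial_amounts, dict):
        y = n.counts0.astype(float)
        y[~n.clamped] = 0.0
        for k, v in initial_amounts.items():
            idx = spec.species_index(k)
            if not n.clamped[idx]:
                y[idx] = float(v)
    else:
        y = np.asarray(initial_amounts, dtype=float).copy()
        y[n.clamped] = n.counts0[n.clamped]

    def rhs(_t: float, yy: np.ndarray) -> np.ndarray:
        return sys.rhs(yy, GROWTH)

    def hit_critical(_t: float, yy: np.ndarray) -> float:
        return yy[n.tm_idx] - n.critical

    hit_critical.terminal = True  # type: ignore[attr-defined]
    hit_critical.direction = 1  # type: ignore[attr-defined]

    t0, t_end = float(t_span[0]), float(t_span[1])
    times = [np.array([t0])]
    amounts = [y.copy()[None, :]]
    division_times: list[float] = []
    t = t0
    success = True
    message = "completed"
    while t < t_end:
        sol = solve_ivp(
            rhs,
            (t, t_end),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            events=[hit_critical] if division_protocol else None,
            dense_output=False,
        )
        if sol.t.size > 1:
            times.append(sol.t[1:])
            amounts.append(sol.y.T[1:])
        if sol.status < 0:
            success = False
            message = f"integration failed at t={sol.t[-1]:.6g}: {sol.message}"
            break
        if division_protocol and sol.status == 1 and sol.t_events[0].size:
            t = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            division_times.append(t)
            y[~n.clamped] *= 0.5
            times.append(np.array([t]))
            amounts.append(y.copy()[None, :])
            if max_divisions is not None and len(division_times) >= max_divisions:
                message = "max_divisions reached"
                break
            continue
        t = float(sol.t[-1])
        y = sol.y[:, -1].copy()
        if sol.status == 0:
            break
    return OdeResult(
        times=np.concatenate(times),
        amounts=np.concatenate(amounts),
        species=n.names,
        division_times=np.asarray(division_times),
        success=success,
        message=message,
    )
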