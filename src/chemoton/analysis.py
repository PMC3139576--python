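"""Trajectory analysis: cell-cycle structure, template totals, coexistence.

These are the quantities a chemoton study actually reports: per-cycle
periods and extrema, total polymer load per template subsystem
(``sum(pV_i)``, ``sum(pW_j)``), and whether two competing templates both
persist across division cycles.  All operations are pure functions of the
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory

__all__ = [
    "CycleRecord",
    "CoexistenceReport",
    "detect_cycles",
    "template_totals",
    "coexistence_metrics",
    "compare_template_load",
    "metabolic_size_comparison",
    "default_burn_in",
    "plot_trajectory",
]


@dataclass(frozen=True)
class CycleRecord:
    """One completed cell cycle.

    ``period`` is the time between this cycle's division end and the
    previous one's (the trajectory start for the first cycle).
    """

    index: int
    growth_start: float
    division_start: float
    division_end: float
    period: float
    species_max: dict[str, int]
    species_min: dict[str, int]


@dataclass
class CoexistenceReport:
    """Verdict on two-template persistence.

    ``min_fraction`` is the minimum over post-burn-in samples of
    ``min(V_total, W_total) / (V_total + W_total)`` (0.5 = perfectly
    balanced, 0 = one template absent at some sample); ``persisted``
    requires both totals positive at every post-burn-in sample.
    """

    times: np.ndarray
    totals: dict[str, np.ndarray]
    burn_in: float
    min_fraction: float
    persisted: bool
    n_species_persisting: int


def default_burn_in(traj: Trajectory, n_divisions: int = 3) -> float:
    """Time of the ``n_divisions``-th completed division (0 if fewer).

    Initial counts are arbitrary, so analyses discard the transient before
    the system settles onto its cycle.
    """
    ends = traj.pc_times[traj.pc_from == 1]
    if ends.size >= n_divisions:
        return float(ends[n_divisions - 1])
    return float(traj.times[0]) if traj.times.size else 0.0


def detect_cycles(traj: Trajectory) -> list[CycleRecord]:
    """Split a trajectory into completed cell cycles.

    A cycle runs from one Division→Growth event (or the trajectory start)
    to the next Division→Growth event; the trailing incomplete cycle is
    dropped.  Returns one record per completed division.
    """
    starts = traj.pc_times[traj.pc_from == 0]  # Growth -> Division
    ends = traj.pc_times[traj.pc_from == 1]  # Division -> Growth
    if ends.size == 0:
        return []
    t0 = float(traj.times[0]) if traj.times.size else 0.0
    boundaries = np.concatenate([[t0], ends])
    records: list[CycleRecord] = []
    names = traj.species
    for i in range(ends.size):
        lo, hi = float(boundaries[i]), float(boundaries[i + 1])
        within = starts[(starts > lo) & (starts <= hi)]
        division_start = float(within[-1]) if within.size else hi
        mask = (traj.times >= lo) & (traj.times <= hi)
        if mask.any():
            sub = traj.counts[mask]
            smax = dict(zip(names, sub.max(axis=0).tolist()))
            smin = dict(zip(names, sub.min(axis=0).tolist()))
        else:
            smax, smin = {}, {}
        records.append(
            CycleRecord(
                index=i,
                growth_start=lo,
                division_start=division_start,
                division_end=hi,
                period=hi - lo,
                species_max=smax,
                species_min=smin,
            )
        )
    return records


def template_totals(
    traj: Trajectory, label: str, include_complexes: bool = True
) -> np.ndarray:
    """Per-sample total copy number of one template subsystem.

    Sums all polymerization-stage species of the ladder and, in two-step
    mode, the monomer-bound complexes (they belong to the template
    subsystem; exclude them to compare against one-step runs).
    """
    lad = traj.spec.ladder(label)
    cols = [traj.spec.species_index(s) for s in lad.members(include_complexes)]
    return traj.counts[:, cols].sum(axis=1)


def metabolite_totals(traj: Trajectory) -> np.ndarray:
    """Per-sample total metabolite count ``sum(A_i)``."""
    cols = [
        i for i, s in enumerate(traj.spec.species) if s.role == "metabolite"
    ]
    return traj.counts[:, cols].sum(axis=1)


def coexistence_metrics(
    traj: Trajectory,
    burn_in: float | None = None,
    include_complexes: bool = True,
) -> CoexistenceReport:
    """Evaluate two-template coexistence on a double-template trajectory.

    ``burn_in`` defaults to the time of the third completed division;
    persistence is evaluated strictly after it.
    """
    if len(traj.spec.ladders) != 2:
        raise ValueError("coexistence metrics require a double-template model")
    if burn_in is None:
        burn_in = default_burn_in(traj)
    labels = [lad.label for lad in traj.spec.ladders]
    totals = {
        lab: template_totals(traj, lab, include_complexes) for lab in labels
    }
    mask = traj.times > burn_in
    a = totals[labels[0]][mask].astype(float)
    b = totals[labels[1]][mask].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(a + b > 0, np.minimum(a, b) / (a + b), 0.0)
    min_fraction = float(frac.min()) if frac.size else 0.0
    persisted = bool(frac.size) and bool(np.all((a > 0) & (b > 0)))
    n_persist = 0
    if mask.any():
        n_persist = int(sum(1 for lab in labels if totals[lab][mask][-1] > 0))
    return CoexistenceReport(
        times=traj.times[mask],
        totals={lab: totals[lab][mask] for lab in labels},
        burn_in=float(burn_in),
        min_fraction=min_fraction,
        persisted=persisted,
        n_species_persisting=n_persist,
    )


def compare_template_load(
    basic_traj: Trajectory,
    double_traj: Trajectory,
    burn_in: float | None = None,
) -> float:
    """Relative difference of time-averaged template load, double vs basic.

    The claim under test: with matched metabolism and division threshold,
    the combined polymer load of two templates sharing a precursor equals
    the single-template load of the basic model.  Returns
    ``|mean(V+W, double) - mean(V, basic)| / mean(V, basic)`` over
    post-burn-in samples.
    """
    if len(basic_traj.spec.ladders) != 1:
        raise ValueError("first trajectory must come from the basic model")
    pb, pd = basic_traj.spec.params, double_traj.spec.params
    if pb.critical_Tm != pd.critical_Tm or pb.m != pd.m or pb.n != pd.n:
        raise ValueError("trajectories have mismatched parameterizations")
    bb = default_burn_in(basic_traj) if burn_in is None else burn_in
    bd = default_burn_in(double_traj) if burn_in is None else burn_in
    vb = template_totals(basic_traj, basic_traj.spec.ladders[0].label)
    mask_b = basic_traj.times > bb
    mean_basic = float(vb[mask_b].mean()) if mask_b.any() else 0.0
    mask_d = double_traj.times > bd
    tot_d = sum(
        template_totals(double_traj, lad.label)
        for lad in double_traj.spec.ladders
    )
    mean_double = float(tot_d[mask_d].mean()) if mask_d.any() else 0.0
    if mean_basic == 0.0:
        raise ValueError("basic-model template load is zero after burn-in")
    return abs(mean_double - mean_basic) / mean_basic


def metabolic_size_comparison(
    traj_small: Trajectory,
    traj_large: Trajectory,
    burn_in: float | None = None,
) -> dict[str, float]:
    """Compare time-averaged total metabolite load across cycle sizes.

    A longer metabolic cycle (more intermediates after the membrane
    precursor is released) reaches the division threshold with slightly
    fewer metabolite molecules in total, so the expected ordering is
    ``mean_large <= mean_small``.
    """
    ps, pl = traj_small.spec.params, traj_large.spec.params
    if ps.n != pl.n or ps.critical_Tm != pl.critical_Tm:
        raise ValueError("non-metabolic parameters differ between runs")
    out: dict[str, float] = {}
    means = []
    for key, traj in (("small", traj_small), ("large", traj_large)):
        b = default_burn_in(traj) if burn_in is None else burn_in
        mask = traj.times > b
        tot = metabolite_totals(traj)
        mean = float(tot[mask].mean()) if mask.any() else 0.0
        out[f"mean_sum_A_{key}"] = mean
        out[f"m_{key}"] = float(traj.spec.params.m)
        means.append(mean)
    small, large = means
    out["relative_difference"] = (
        abs(large - small) / small if small else float("nan")
    )
    out["ordering_holds"] = float(large <= small)
    return out


def plot_trajectory(traj: Trajectory, species: list[str] | None = None, ax=None):
    """Quick time-series plot with division phases shaded (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(9, 4))
    df = traj.to_frame()
    if species is None:
        species = [c for c in df.columns if c.startswith("sum_")]
    for sp in species:
        ax.plot(df["time"], df[sp], label=sp, lw=0.8)
    in_div = df["phase"].to_numpy() == "Division"
    if in_div.any():
        t = df["time"].to_numpy()
        ax.fill_between(
            t, 0, df[species].to_numpy().max(), where=in_div, alpha=0.15,
            color="grey", step="post", label="Division",
        )
    ax.set_xlabel("time (dimensionless)")
    ax.set_ylabel("molecule count")
    ax.legend(fontsize=8)
    return ax
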