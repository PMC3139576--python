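"""Configuration files, trajectory I/O and batch experiment running.

Configs are YAML with a schema string; they round-trip losslessly through
:func:`save_config` / :func:`load_config`.  Trajectories are written as
tab-delimited text with ``#``-prefixed metadata headers so a run can be
re-analyzed without re-simulating.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .analysis import (
    coexistence_metrics,
    default_burn_in,
    detect_cycles,
    metabolite_totals,
    template_totals,
)
from .engine import Trajectory, run
from .model import (
    ChemotonParams,
    LadderParams,
    ModelSpec,
    build_basic_chemoton,
    build_double_template_chemoton,
    validate_model,
)
from .presets import Preset, get_preset

__all__ = [
    "SCHEMA",
    "ConfigError",
    "RunOptions",
    "params_to_dict",
    "params_from_dict",
    "save_config",
    "load_config",
    "preset_config",
    "write_trajectory",
    "write_events",
    "read_trajectory",
    "run_summary",
    "write_summary",
    "run_experiment",
]

SCHEMA = "chemoton-config/1"


class ConfigError(ValueError):
    """A config file failed to parse or validate; ``problems`` lists all
    violations found."""

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = problems or []
        detail = "".join(f"\n  - {p}" for p in self.problems)
        super().__init__(message + detail)


@dataclass(frozen=True)
class RunOptions:
    """Engine options that are not part of the chemical model."""

    seed: int = 1
    max_divisions: int | None = 10
    max_time: float | None = None
    max_events: int | None = None
    sample_interval: float = 0.01
    record_events: bool = False


def params_to_dict(params: ChemotonParams) -> dict:
    d = dataclasses.asdict(params)
    d["ladders"] = [dataclasses.asdict(l) for l in params.ladders]
    for key in ("metabolic_forward", "metabolic_reverse"):
        if d[key] is not None:
            d[key] = list(d[key])
    return d


def params_from_dict(d: dict) -> ChemotonParams:
    d = dict(d)
    ladders = tuple(LadderParams(**l) for l in d.pop("ladders", []))
    if not ladders:
        ladders = (LadderParams("V"),)
    for key in ("metabolic_forward", "metabolic_reverse"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    known = {f.name for f in dataclasses.fields(ChemotonParams)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError("unknown parameter keys", sorted(unknown))
    return ChemotonParams(ladders=ladders, **d)


def save_config(
    path: str | Path, model: str, params: ChemotonParams, options: RunOptions
) -> None:
    doc = {
        "schema": SCHEMA,
        "model": model,
        "params": params_to_dict(params),
        "run": dataclasses.asdict(options),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def preset_config(preset: Preset) -> dict:
    """A preset rendered as a config document (round-trips losslessly)."""
    return {
        "schema": SCHEMA,
        "model": preset.model,
        "params": params_to_dict(preset.params),
        "run": dataclasses.asdict(
            RunOptions(
                seed=preset.default_seed,
                max_divisions=preset.stop_divisions,
                sample_interval=preset.sample_interval,
            )
        ),
    }


def load_config(path: str | Path) -> tuple[ModelSpec, RunOptions]:
    """Load and fully validate a config file.

    Raises :class:`ConfigError` with every violation found (never a
    partially built spec).
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a config mapping (empty file?)")
    if doc.get("schema") != SCHEMA:
        raise ConfigError(
            f"{path}: missing or unsupported schema (expected {SCHEMA!r})"
        )
    model = doc.get("model")
    if model not in ("basic", "double"):
        raise ConfigError(f"{path}: model must be 'basic' or 'double'")
    params = params_from_dict(doc.get("params") or {})
    try:
        if model == "double":
            spec = build_double_template_chemoton(params)
        else:
            spec = build_basic_chemoton(params)
    except ValueError as exc:
        raise ConfigError(f"{path}: invalid parameters", [str(exc)]) from exc
    problems = validate_model(spec)
    if problems:
        raise ConfigError(f"{path}: model validation failed", problems)
    run_d = dict(doc.get("run") or {})
    known = {f.name for f in dataclasses.fields(RunOptions)}
    unknown = set(run_d) - known
    if unknown:
        raise ConfigError(f"{path}: unknown run options", sorted(unknown))
    return spec, RunOptions(**run_d)


# ---------------------------------------------------------------------------
# Trajectory text format
# ---------------------------------------------------------------------------

_PHASES = ("Growth", "Division")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Tab-delimited samples: time, phase, every species, subsystem totals."""
    names = list(traj.species)
    a_cols = [
        i for i, s in enumerate(traj.spec.species) if s.role == "metabolite"
    ]
    sums = {"sum_A": traj.counts[:, a_cols].sum(axis=1)}
    for lad in traj.spec.ladders:
        sums[f"sum_p{lad.label}"] = template_totals(traj, lad.label)
    with open(path, "w") as fh:
        fh.write("# chemoton-trajectory/1\n")
        fh.write(f"# model: {'double' if len(traj.spec.ladders) == 2 else 'basic'}\n")
        fh.write(f"# seed: {traj.seed}\n")
        fh.write(f"# n_divisions: {traj.n_divisions}\n")
        fh.write(f"# stop_reason: {traj.stop_reason}\n")
        fh.write(f"# sample_interval: {traj.sample_interval:.10g}\n")
        fh.write("time\tphase\t" + "\t".join(names + list(sums)) + "\n")
        for i in range(traj.times.size):
            row = [f"{traj.times[i]:.10g}", _PHASES[int(traj.phases[i])]]
            row += [str(int(c)) for c in traj.counts[i]]
            row += [str(int(sums[k][i])) for k in sums]
            fh.write("\t".join(row) + "\n")


def write_events(traj: Trajectory, path: str | Path) -> None:
    """Phase-change log with full count snapshots at each transition."""
    names = list(traj.species)
    with open(path, "w") as fh:
        fh.write("# chemoton-events/1\n")
        fh.write("time\tfrom_phase\tto_phase\tTm\t" + "\t".join(names) + "\n")
        for i in range(traj.pc_times.size):
            frm = _PHASES[int(traj.pc_from[i])]
            to = _PHASES[1 - int(traj.pc_from[i])]
            row = [f"{traj.pc_times[i]:.10g}", frm, to, str(int(traj.pc_tm[i]))]
            row += [str(int(c)) for c in traj.pc_counts[i]]
            fh.write("\t".join(row) + "\n")


def read_trajectory(
    traj_path: str | Path, events_path: str | Path, spec: ModelSpec
) -> Trajectory:
    """Rebuild a Trajectory from its two text files (for re-analysis)."""
    import pandas as pd

    meta: dict[str, str] = {}
    with open(traj_path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
        else:
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    names = list(spec.species_names)
    ev = pd.read_csv(events_path, sep="\t", comment="#")
    return Trajectory(
        spec=spec,
        seed=int(meta.get("seed", 0)),
        times=df["time"].to_numpy(float),
        counts=df[names].to_numpy(np.int64),
        phases=np.array(
            [0 if p == "Growth" else 1 for p in df["phase"]], dtype=np.int8
        ),
        pc_times=ev["time"].to_numpy(float),
        pc_from=np.array(
            [0 if p == "Growth" else 1 for p in ev["from_phase"]], dtype=np.int8
        ),
        pc_tm=ev["Tm"].to_numpy(np.int64),
        pc_counts=ev[names].to_numpy(np.int64)
        if all(n in ev.columns for n in names)
        else np.zeros((len(ev), len(names)), dtype=np.int64),
        n_divisions=int(meta.get("n_divisions", 0)),
        stop_reason=meta.get("stop_reason", "stop_condition"),
        sample_interval=float(meta.get("sample_interval", 0.0) or 0.0),
    )


# ---------------------------------------------------------------------------
# Summaries and batch experiments
# ---------------------------------------------------------------------------


def run_summary(traj: Trajectory, burn_in: float | None = None) -> dict:
    """Single-row scientific summary of one run."""
    b = default_burn_in(traj) if burn_in is None else burn_in
    cycles = detect_cycles(traj)
    settled = [c for c in cycles if c.division_end > b]
    periods = np.array([c.period for c in settled])
    mask = traj.times > b
    out: dict[str, object] = {
        "seed": traj.seed,
        "n_divisions": traj.n_divisions,
        "stop_reason": traj.stop_reason,
        "final_time": round(float(traj.times[-1]), 6) if traj.times.size else 0.0,
        "burn_in": round(float(b), 6),
        "n_cycles_analyzed": len(settled),
        "period_mean": round(float(periods.mean()), 6) if periods.size else float("nan"),
        "period_cv": (
            round(float(periods.std() / periods.mean()), 6)
            if periods.size > 1 and periods.mean() > 0
            else float("nan")
        ),
        "mean_sum_A": (
            round(float(metabolite_totals(traj)[mask].mean()), 4)
            if mask.any()
            else float("nan")
        ),
    }
    for lad in traj.spec.ladders:
        tot = template_totals(traj, lad.label)
        out[f"mean_sum_p{lad.label}"] = (
            round(float(tot[mask].mean()), 4) if mask.any() else float("nan")
        )
    if len(traj.spec.ladders) == 2:
        rep = coexistence_metrics(traj, burn_in=b)
        out["min_fraction"] = round(rep.min_fraction, 6)
        out["persisted"] = rep.persisted
        out["n_species_persisting"] = rep.n_species_persisting
    return out


def write_summary(rows: list[dict], path: str | Path) -> None:
    keys: list[str] = []
    for r in rows:
        for k in r:
            if k not in keys:
                keys.append(k)
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(k, "")) for k in keys) + "\n")


def run_experiment(
    source: str | tuple[ModelSpec, RunOptions],
    seeds: list[int],
    out_dir: str | Path,
    *,
    stop_divisions: int | None = None,
    max_time: float | None = None,
    sample_interval: float | None = None,
    label: str | None = None,
) -> list[dict]:
    """Run one configuration under several seeds and write all outputs.

    ``source`` is a preset name or a ``(ModelSpec, RunOptions)`` pair.
    Writes per-seed trajectory, event and summary files plus an aggregate
    summary table; deterministic (byte-identical on re-invocation) for a
    fixed seed list.
    """
    if isinstance(source, str):
        preset = get_preset(source)
        spec = preset.build()
        opts = RunOptions(
            seed=preset.default_seed,
            max_divisions=preset.stop_divisions,
            sample_interval=preset.sample_interval,
        )
        name = label or preset.name
    else:
        spec, opts = source
        name = label or "run"
    if stop_divisions is not None:
        opts = dataclasses.replace(opts, max_divisions=stop_divisions, max_time=None)
    if max_time is not None:
        opts = dataclasses.replace(opts, max_time=max_time)
    if sample_interval is not None:
        opts = dataclasses.replace(opts, sample_interval=sample_interval)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for seed in seeds:
        traj = run(
            spec,
            seed=seed,
            max_time=opts.max_time,
            max_divisions=opts.max_divisions,
            max_events=opts.max_events,
            sample_interval=opts.sample_interval,
        )
        write_trajectory(traj, out / f"{name}_seed{seed}.tsv")
        write_events(traj, out / f"{name}_seed{seed}_events.tsv")
        row = run_summary(traj)
        write_summary([row], out / f"{name}_seed{seed}_summary.tsv")
        rows.append(row)
    write_summary(rows, out / f"{name}_aggregate.tsv")
    return rows
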