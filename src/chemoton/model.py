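"""Reaction-network builders for the chemoton minimal-cell model.

The chemoton is Gánti's minimal model of a living cell: three autocatalytic
subsystems coupled stoichiometrically —

* a **metabolic cycle** ``A1 … Am`` that consumes food ``X``, releases waste
  ``Y``, a template monomer (``V``, or the precursor ``U`` in the
  double-template variant), a membrane precursor ``Tp`` (T′), and doubles its
  seed metabolite ``A1`` once per turn;
* a **template polymerization cycle**: a double-stranded homopolymer whose
  stages ``pV(0) … pV(n-1)`` accumulate monomers one at a time, releasing a
  condensation byproduct ``R`` per incorporation; the n-th incorporation
  splits the duplex into two ``pV(0)`` copies (template autocatalysis);
* a **membrane subsystem**: ``R + Tp -> T`` followed by incorporation of
  ``T`` into the boundary, incrementing the membrane count ``Tm``.

Because every subsystem feeds the others through fixed stoichiometry, the
system grows as a whole; crossing a critical ``Tm`` triggers division.

The double-template variant adds a second homopolymer ``pW`` whose monomer
``W`` shares a common precursor ``U`` with ``V``; partitioning of ``U`` is
controlled by clamped food species ``Z1``/``Z2`` and the reversible
constants ``kV/kVr`` and ``kW/kWr``.

This module only *describes* networks (:class:`ModelSpec`); stochastic
simulation lives in :mod:`chemoton.engine` and the deterministic counterpart
in :mod:`chemoton.ode_oracle`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GROWTH",
    "DIVISION",
    "ROLES",
    "SpeciesDef",
    "ReactionDef",
    "LadderParams",
    "PolymerLadder",
    "SwitchRule",
    "ChemotonParams",
    "ModelSpec",
    "build_basic_chemoton",
    "build_double_template_chemoton",
    "extend_metabolic_cycle",
    "validate_model",
    "ladder_closure",
    "producible_species",
]

GROWTH = "Growth"
DIVISION = "Division"

#: Recognised species roles.
ROLES = frozenset(
    {
        "metabolite",
        "food",
        "waste",
        "monomer-precursor",
        "monomer",
        "polymer-stage",
        "polymer-monomer-complex",
        "condensation-byproduct",
        "membrane-precursor",
        "membrane-unit",
        "membrane-count",
        "phase-signal",
    }
)

_GATES = ("growth_only", "division_only", "always")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species.

    ``clamped`` species are held at ``clamp_value`` for the whole run: they
    enter propensities with that constant count but are never produced,
    consumed or deleted (a constant outside-world concentration).
    """

    name: str
    role: str
    clamped: bool = False
    clamp_value: int = 0


@dataclass(frozen=True)
class ReactionDef:
    """An elementary mass-action reaction channel.

    The propensity is ``rate_constant * prod(count(reactant)^stoich)`` — raw
    counts, one factor per stoichiometric unit.  ``phase_gate`` restricts the
    channel to a cell-cycle phase; every chemical reaction of the chemoton is
    ``growth_only`` (all of them freeze while the cell divides).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float
    phase_gate: str = "growth_only"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", self.format())

    def format(self) -> str:
        def side(terms: tuple[tuple[str, int], ...]) -> str:
            if not terms:
                return "0"
            return " + ".join(s if c == 1 else f"{c} {s}" for s, c in terms)

        return f"{side(self.reactants)} -> {side(self.products)}"


@dataclass(frozen=True)
class LadderParams:
    """Kinetic configuration of one template polymerization cycle.

    ``k6``/``k6r`` are the monomer association/dissociation constants and
    ``k7`` the condensation (polymerization) constant.  In ``two_step`` mode
    each incorporation is ``pX(i) + X <-> pX(i)·X`` followed by
    ``pX(i)·X -> pX(i+1) + R``; ``one_step`` collapses it to
    ``pX(i) + X -> pX(i+1) + R`` at ``k7``.
    """

    label: str = "V"
    k6: float = 1.0
    k6r: float = 0.1
    k7: float = 1.0
    mode: str = "two_step"


@dataclass(frozen=True)
class PolymerLadder:
    """A built template ladder: stage species plus (two-step) complexes."""

    label: str
    monomer: str
    n: int
    stages: tuple[str, ...]
    complexes: tuple[str, ...]
    mode: str
    k6: float
    k6r: float
    k7: float

    def members(self, include_complexes: bool = True) -> tuple[str, ...]:
        """All species belonging to this template subsystem."""
        return self.stages + (self.complexes if include_complexes else ())


@dataclass(frozen=True)
class SwitchRule:
    """One arm of the deterministic two-state Growth/Division switch."""

    from_phase: str
    to_phase: str
    trigger_species: str
    trigger_comparison: str  # "reaches_or_exceeds" | "reaches_or_falls_to"
    threshold: int


@dataclass(frozen=True)
class ChemotonParams:
    """Full parameterization of a chemoton network.

    All rate constants live on the same dimensionless time base as the
    simulation clock.  ``metabolic_forward``/``metabolic_reverse`` give one
    constant per cycle step (length ``m``); ``None`` means the defaults
    2.0 / 0.1 for every step (the printed exemplar step ``A1 + X <-> A2``
    generalized uniformly).
    """

    m: int = 5
    n: int = 6
    metabolic_forward: tuple[float, ...] | None = None
    metabolic_reverse: tuple[float, ...] | None = None
    ladders: tuple[LadderParams, ...] = (LadderParams("V"),)
    # precursor branching (double-template model only)
    kV: float = 2.0
    kVr: float = 0.1
    kW: float = 2.0
    kWr: float = 0.1
    z1_clamp: int = 10
    z2_clamp: int = 10
    # membrane chemistry
    k_mem: float = 2.0
    k_inc: float = 1.0
    membrane_autocatalytic: bool = True
    # division
    critical_Tm: int = 200
    deletion_factor: float = 10.0
    # food supply
    food_mode: str = "constant_count"  # constant_count | influx | gated_influx
    x_clamp: int = 10
    influx_rate: float = 10.0
    # bookkeeping
    track_waste: bool = False
    #: explicit cycle positions of the (Y, monomer, Tp)-releasing steps;
    #: None places the release block just before the doubling step
    byproduct_steps: tuple[int, int, int] | None = None
    initial_counts: dict[str, int] = field(default_factory=dict)

    def metabolic_constants(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        kf = self.metabolic_forward or tuple(2.0 for _ in range(self.m))
        kr = self.metabolic_reverse or tuple(0.1 for _ in range(self.m))
        return tuple(kf), tuple(kr)


@dataclass(frozen=True)
class ModelSpec:
    """A complete phase-gated reaction network plus its parameters."""

    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    ladders: tuple[PolymerLadder, ...]
    switches: tuple[SwitchRule, ...]
    params: ChemotonParams

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def get_species(self, name: str) -> SpeciesDef:
        return self.species[self.species_index(name)]

    def ladder(self, label: str) -> PolymerLadder:
        for lad in self.ladders:
            if lad.label == label:
                return lad
        raise KeyError(f"no ladder labelled {label!r}")

    @property
    def membrane_count_species(self) -> str:
        for s in self.species:
            if s.role == "membrane-count":
                return s.name
        raise ValueError("model has no membrane-count species")

    def reaction_listing(self) -> str:
        """Human-readable one-reaction-per-line listing for diffing."""
        lines = [
            f"{r.format()} @ {r.rate_constant:g} [{r.phase_gate}]"
            for r in self.reactions
        ]
        return "\n".join(lines)

    def default_initial_counts(self) -> dict[str, int]:
        """Initial counts: clamps, then user-specified overrides."""
        counts = {s.name: 0 for s in self.species}
        for s in self.species:
            if s.clamped:
                counts[s.name] = s.clamp_value
        for name, c in self.params.initial_counts.items():
            if name in counts and not self.get_species(name).clamped:
                counts[name] = int(c)
        return counts


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _byproduct_positions(
    m: int, explicit: tuple[int, int, int] | None = None
) -> tuple[dict[int, list[str]], bool]:
    """Cycle positions of the Y-, monomer- and Tp-releasing steps.

    For the canonical 5-member cycle these are steps 2, 3 and 4 — the last
    three steps before the cycle-closing doubling.  Larger cycles keep the
    release block at that position and insert the extra metabolites into the
    food-assimilation segment at the front (each added step feeds on ``X``
    and the previous metabolite): positions ``m-3``, ``m-2``, ``m-1``.
    Rescaling the positions proportionally instead inflates the metabolite
    pools upstream of the monomer-releasing step several-fold, which is
    inconsistent with the near-identical behaviour of small and large
    cycles; see the methods note.  Returns ``(position -> byproduct slots,
    merged)`` where ``merged`` flags that distinct byproducts collapsed onto
    one (non-elementary) step, as happens for ``m < 5``.
    """
    if explicit is not None:
        y, v, tp = explicit
        if not all(2 <= p <= m - 1 for p in (y, v, tp)):
            raise ValueError(
                f"byproduct_steps must lie in [2, {m - 1}] for m={m}, got {explicit}"
            )
    else:
        y = min(max(2, m - 3), m - 1)
        v = min(max(y, m - 2), m - 1)
        tp = min(max(v, m - 1), m - 1)
    slots: dict[int, list[str]] = {}
    slots.setdefault(y, []).append("Y")
    slots.setdefault(v, []).append("monomer")
    slots.setdefault(tp, []).append("Tp")
    merged = len({y, v, tp}) < 3
    return slots, merged


def _check_params(params: ChemotonParams, n_ladders: int) -> None:
    if params.m < 3:
        raise ValueError(f"metabolic cycle size m must be >= 3, got {params.m}")
    if params.n < 2:
        raise ValueError(f"template half-length n must be >= 2, got {params.n}")
    if len(params.ladders) != n_ladders:
        raise ValueError(
            f"expected {n_ladders} ladder configuration(s), got {len(params.ladders)}"
        )
    if params.critical_Tm <= 0 or params.critical_Tm % 2:
        raise ValueError(
            f"critical_Tm must be a positive even integer, got {params.critical_Tm}"
        )
    kf, kr = params.metabolic_constants()
    if len(kf) != params.m or len(kr) != params.m:
        raise ValueError("metabolic constant tuples must have length m")
    consts = list(kf) + list(kr) + [params.k_mem, params.k_inc, params.deletion_factor]
    for lad in params.ladders:
        consts += [lad.k6, lad.k6r, lad.k7]
        if lad.mode not in ("one_step", "two_step"):
            raise ValueError(f"unknown ladder mode {lad.mode!r}")
    if n_ladders == 2:
        consts += [params.kV, params.kVr, params.kW, params.kWr]
    if params.food_mode not in ("constant_count", "influx", "gated_influx"):
        raise ValueError(f"unknown food_mode {params.food_mode!r}")
    if params.food_mode != "constant_count":
        consts.append(params.influx_rate)
    if any(k <= 0 for k in consts):
        raise ValueError("all rate constants must be strictly positive")


def _ladder_network(
    lad: LadderParams, n: int
) -> tuple[PolymerLadder, list[SpeciesDef], list[ReactionDef]]:
    mono = lad.label
    stages = tuple(f"p{mono}{i}" for i in range(n))
    species = [SpeciesDef(s, "polymer-stage") for s in stages]
    complexes: tuple[str, ...] = ()
    reactions: list[ReactionDef] = []
    if lad.mode == "two_step":
        complexes = tuple(f"p{mono}{i}_{mono}" for i in range(n))
        species += [SpeciesDef(c, "polymer-monomer-complex") for c in complexes]
        for i in range(n):
            reactions.append(
                ReactionDef(((stages[i], 1), (mono, 1)), ((complexes[i], 1),), lad.k6)
            )
            reactions.append(
                ReactionDef(((complexes[i], 1),), ((stages[i], 1), (mono, 1)), lad.k6r)
            )
            if i < n - 1:
                prod: tuple[tuple[str, int], ...] = ((stages[i + 1], 1), ("R", 1))
            else:  # terminal incorporation: the duplex splits in two
                prod = ((stages[0], 2), ("R", 1))
            reactions.append(ReactionDef(((complexes[i], 1),), prod, lad.k7))
    else:
        for i in range(n):
            if i < n - 1:
                prod = ((stages[i + 1], 1), ("R", 1))
            else:
                prod = ((stages[0], 2), ("R", 1))
            reactions.append(
                ReactionDef(((stages[i], 1), (mono, 1)), prod, lad.k7)
            )
    built = PolymerLadder(
        label=lad.label,
        monomer=mono,
        n=n,
        stages=stages,
        complexes=complexes,
        mode=lad.mode,
        k6=lad.k6,
        k6r=lad.k6r,
        k7=lad.k7,
    )
    return built, species, reactions


def _build(params: ChemotonParams, double: bool) -> ModelSpec:
    """Shared assembly for the basic and double-template networks."""
    _check_params(params, 2 if double else 1)
    m = params.m
    kf, kr = params.metabolic_constants()
    monomer_release = "U" if double else "V"

    species: list[SpeciesDef] = [
        SpeciesDef(f"A{i + 1}", "metabolite") for i in range(m)
    ]
    x_clamped = params.food_mode == "constant_count"
    species.append(SpeciesDef("X", "food", clamped=x_clamped, clamp_value=params.x_clamp))
    species.append(SpeciesDef("Y", "waste"))
    if double:
        species.append(SpeciesDef("U", "monomer-precursor"))
        species.append(SpeciesDef("Z1", "food", clamped=True, clamp_value=params.z1_clamp))
        species.append(SpeciesDef("Z2", "food", clamped=True, clamp_value=params.z2_clamp))
    for lad in params.ladders:
        species.append(SpeciesDef(lad.label, "monomer"))
    species += [
        SpeciesDef("Tp", "membrane-precursor"),
        SpeciesDef("T", "membrane-unit"),
        SpeciesDef("R", "condensation-byproduct"),
        SpeciesDef("Tm", "membrane-count"),
    ]

    reactions: list[ReactionDef] = []

    # -- metabolic cycle -------------------------------------------------
    slots, merged = _byproduct_positions(m, params.byproduct_steps)
    if merged:
        warnings.warn(
            f"m={m}: byproduct-releasing steps coincide; the cycle contains "
            "merged, non-elementary reaction steps",
            stacklevel=3,
        )
    for j in range(1, m):  # steps A_j -> A_{j+1}
        a, b = f"A{j}", f"A{j + 1}"
        byp = [monomer_release if s == "monomer" else s for s in slots.get(j, [])]
        if byp:
            prods: list[tuple[str, int]] = [(b, 1)]
            prods += [(s, 1) for s in byp if s != "Y" or params.track_waste]
            reactions.append(ReactionDef(((a, 1),), tuple(prods), kf[j - 1]))
            # reverse: consumes the released byproducts except waste Y
            # (reverses through Y are disabled: Y is discarded)
            if "Y" not in byp:
                rev_react = tuple([(b, 1)] + [(s, 1) for s in byp])
                reactions.append(ReactionDef(rev_react, ((a, 1),), kr[j - 1]))
        else:
            reactions.append(ReactionDef(((a, 1), ("X", 1)), ((b, 1),), kf[j - 1]))
            reactions.append(ReactionDef(((b, 1),), ((a, 1), ("X", 1)), kr[j - 1]))
    # final step doubles the seed metabolite: A_m <-> 2 A1
    reactions.append(ReactionDef(((f"A{m}", 1),), (("A1", 2),), kf[m - 1]))
    reactions.append(ReactionDef((("A1", 2),), ((f"A{m}", 1),), kr[m - 1]))

    # -- precursor branching (double model) ------------------------------
    if double:
        lv, lw = params.ladders
        reactions.append(ReactionDef((("U", 1), ("Z1", 1)), ((lv.label, 1),), params.kV))
        reactions.append(ReactionDef(((lv.label, 1),), (("U", 1), ("Z1", 1)), params.kVr))
        reactions.append(ReactionDef((("U", 1), ("Z2", 1)), ((lw.label, 1),), params.kW))
        reactions.append(ReactionDef(((lw.label, 1),), (("U", 1), ("Z2", 1)), params.kWr))

    # -- template ladders ------------------------------------------------
    ladders: list[PolymerLadder] = []
    for lad in params.ladders:
        built, sp, rx = _ladder_network(lad, params.n)
        ladders.append(built)
        species += sp
        reactions += rx

    # -- membrane chemistry ----------------------------------------------
    reactions.append(ReactionDef((("R", 1), ("Tp", 1)), (("T", 1),), params.k_mem))
    if params.membrane_autocatalytic:
        # incorporation catalysed by the existing boundary: T + Tm -> 2 Tm
        reactions.append(ReactionDef((("T", 1), ("Tm", 1)), (("Tm", 2),), params.k_inc))
    else:
        reactions.append(ReactionDef((("T", 1),), (("Tm", 1),), params.k_inc))

    switches = (
        SwitchRule(GROWTH, DIVISION, "Tm", "reaches_or_exceeds", params.critical_Tm),
        SwitchRule(DIVISION, GROWTH, "Tm", "reaches_or_falls_to", params.critical_Tm // 2),
    )
    return ModelSpec(
        species=tuple(species),
        reactions=tuple(reactions),
        ladders=tuple(ladders),
        switches=switches,
        params=params,
    )


def build_basic_chemoton(params: ChemotonParams) -> ModelSpec:
    """Build the single-template chemoton.

    Metabolism releases the template monomer ``V`` directly; there is no
    precursor ``U`` and no ``Z1``/``Z2`` food species.
    """
    return _build(params, double=False)


def build_double_template_chemoton(params: ChemotonParams) -> ModelSpec:
    """Build the chemoton with two competing template cycles.

    Metabolism releases the common precursor ``U``; the reversible branching
    ``U + Z1 <-> V`` and ``U + Z2 <-> W`` (with ``Z1``, ``Z2`` clamped)
    partitions it between the two ladders.
    """
    if len(params.ladders) != 2:
        raise ValueError("double-template model requires exactly two ladder configurations")
    return _build(params, double=True)


def extend_metabolic_cycle(spec: ModelSpec, m_new: int) -> ModelSpec:
    """Rebuild ``spec`` with an ``m_new``-member metabolic cycle.

    Added interior steps are ``A_i + X <-> A_{i+1}``; the byproduct-releasing
    steps keep their relative positions in the cycle, and the final step still
    doubles ``A1``.  ``m_new == m`` returns ``spec`` unchanged.
    """
    if m_new < 3:
        raise ValueError(f"m_new must be >= 3, got {m_new}")
    if m_new == spec.params.m:
        return spec
    kf = spec.params.metabolic_forward
    kr = spec.params.metabolic_reverse
    bp = spec.params.byproduct_steps
    params = dataclasses.replace(
        spec.params,
        m=m_new,
        # custom per-step constants and positions cannot be carried across a resize
        metabolic_forward=kf if kf is not None and len(kf) == m_new else None,
        metabolic_reverse=kr if kr is not None and len(kr) == m_new else None,
        byproduct_steps=bp if bp and all(2 <= p <= m_new - 1 for p in bp) else None,
    )
    return _build(params, double=len(spec.ladders) == 2)


# ---------------------------------------------------------------------------
# Validation & structural checks
# ---------------------------------------------------------------------------


def validate_model(spec: ModelSpec) -> list[str]:
    """Return a list of invariant violations (empty when the spec is sound).

    Violations are data, not exceptions: each entry names the offending
    species, reaction or parameter.
    """
    v: list[str] = []
    names = [s.name for s in spec.species]
    declared = set(names)
    if len(declared) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        v.append(f"duplicate species names: {', '.join(dupes)}")
    for s in spec.species:
        if s.role not in ROLES:
            v.append(f"species {s.name}: unknown role {s.role!r}")
        if s.clamped and s.clamp_value < 0:
            v.append(f"species {s.name}: negative clamp_value")
    counters = [s.name for s in spec.species if s.role == "membrane-count"]
    if len(counters) != 1:
        v.append(
            f"exactly one membrane-count species required, found {len(counters)}"
        )
    for r in spec.reactions:
        for sp, c in r.reactants + r.products:
            if sp not in declared:
                v.append(f"reaction '{r.name}': undeclared species {sp}")
            if not isinstance(c, int) or c <= 0:
                v.append(f"reaction '{r.name}': non-positive stoichiometry for {sp}")
        if r.rate_constant <= 0:
            v.append(f"reaction '{r.name}': non-positive rate constant")
        if r.phase_gate not in _GATES:
            v.append(f"reaction '{r.name}': unknown phase_gate {r.phase_gate!r}")
    for lad in spec.ladders:
        if len(lad.stages) != lad.n:
            v.append(f"ladder {lad.label}: expected {lad.n} stages, found {len(lad.stages)}")
        if lad.mode == "two_step" and len(lad.complexes) != lad.n:
            v.append(f"ladder {lad.label}: two_step mode requires {lad.n} complex species")
        for sp in lad.members():
            if sp not in declared:
                v.append(f"ladder {lad.label}: undeclared species {sp}")
    p = spec.params
    if p.critical_Tm % 2 or p.critical_Tm <= 0:
        v.append("critical_Tm must be even and positive")
    if counters:
        tm = counters[0]
        up = [
            s
            for s in spec.switches
            if s.from_phase == GROWTH and s.to_phase == DIVISION
        ]
        down = [
            s
            for s in spec.switches
            if s.from_phase == DIVISION and s.to_phase == GROWTH
        ]
        if not (
            len(up) == 1
            and up[0].trigger_species == tm
            and up[0].threshold == p.critical_Tm
        ):
            v.append("missing or wrong Growth->Division switch on the membrane count")
        if not (
            len(down) == 1
            and down[0].trigger_species == tm
            and down[0].threshold == p.critical_Tm // 2
        ):
            v.append("missing or wrong Division->Growth switch on the membrane count")
        for s in spec.switches:
            if s.trigger_species not in declared:
                v.append(f"switch: undeclared trigger species {s.trigger_species}")
    n_lad = len(spec.ladders)
    if n_lad == 1 and {"U", "Z1", "Z2"} & declared:
        v.append("basic model must not contain U/Z1/Z2")
    if n_lad == 2 and not {"U", "Z1", "Z2"} <= declared:
        v.append("double-template model requires U, Z1 and Z2")
    if n_lad not in (1, 2):
        v.append(f"model must have 1 or 2 ladders, found {n_lad}")
    return v


def ladder_closure(spec: ModelSpec, label: str) -> dict[str, int]:
    """Symbolic stoichiometric walk of one template cycle.

    Starting from a single copy of stage 0 (with unlimited monomer), follow
    the built reactions through successive incorporations until the terminal
    split, and report how many monomers were incorporated, how many stage-0
    copies the walk ends with, and how many condensation byproducts ``R``
    were released.  For a sound ladder of half-length ``n`` this is exactly
    ``n`` incorporations, 2 copies and ``n`` byproducts.
    """
    lad = spec.ladder(label)
    by_reactants = {tuple(sorted(s for s, _ in r.reactants)): r for r in spec.reactions}
    incorporations = 0
    released_R = 0
    current = lad.stages[0]
    while True:
        if current in lad.stages:
            if lad.mode == "two_step":
                assoc = by_reactants.get(tuple(sorted((current, lad.monomer))))
                if assoc is None:
                    raise ValueError(f"ladder {label}: no association step from {current}")
                (nxt,) = [s for s, _ in assoc.products]
                current = nxt
                continue
            step = by_reactants.get(tuple(sorted((current, lad.monomer))))
        else:  # a bound complex: find its condensation step (not dissociation)
            cands = [
                r
                for r in spec.reactions
                if r.reactants == ((current, 1),)
                and any(s == "R" for s, _ in r.products)
            ]
            step = cands[0] if cands else None
        if step is None:
            raise ValueError(f"ladder {label}: walk stuck at {current}")
        incorporations += 1
        released_R += sum(c for s, c in step.products if s == "R")
        stage_prods = [(s, c) for s, c in step.products if s in lad.stages]
        (stage, copies) = stage_prods[0]
        if stage == lad.stages[0]:
            return {
                "incorporations": incorporations,
                "stage0_copies": copies,
                "byproducts_released": released_R,
            }
        current = stage


def producible_species(
    spec: ModelSpec, sources: Iterable[str] | None = None
) -> set[str]:
    """Species reachable from ``sources`` on the reaction hypergraph.

    A reaction becomes firable once all its reactants are available; its
    products then become available.  Default sources are the seed metabolite,
    the food species, every ladder's stage 0, the membrane count and all
    clamped species.
    """
    if sources is None:
        src = {"A1", "X", "Tm"}
        src.update(lad.stages[0] for lad in spec.ladders)
        src.update(s.name for s in spec.species if s.clamped)
    else:
        src = set(sources)
    avail = set(src)
    changed = True
    while changed:
        changed = False
        for r in spec.reactions:
            if all(s in avail for s, _ in r.reactants):
                for s, _ in r.products:
                    if s not in avail:
                        avail.add(s)
                        changed = True
    return avail
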