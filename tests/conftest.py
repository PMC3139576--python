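"""Shared fixtures: presets, micro-networks and cached trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from chemoton import build_preset, run
from chemoton.model import (
    DIVISION,
    GROWTH,
    ChemotonParams,
    LadderParams,
    ModelSpec,
    ReactionDef,
    SpeciesDef,
    SwitchRule,
    build_basic_chemoton,
)
from chemoton.model import _ladder_network


def micro_spec(
    reactions: list[ReactionDef],
    counts: dict[str, int],
    extra_species: list[SpeciesDef] | None = None,
    critical_Tm: int = 1_000_000,
    **param_overrides,
) -> ModelSpec:
    """A minimal valid model around an arbitrary reaction set.

    Adds the structural species a spec must carry (membrane count, an inert
    template ladder) so subnetworks like ``A + X <-> B`` can be simulated
    and integrated in isolation without any division ever triggering.
    """
    species: list[SpeciesDef] = [
        SpeciesDef("A", "metabolite"),
        SpeciesDef("B", "metabolite"),
        SpeciesDef("C", "metabolite"),
        SpeciesDef(
            "X", "food", clamped=param_overrides.pop("x_clamped", True),
            clamp_value=param_overrides.pop("x_clamp", 10),
        ),
        SpeciesDef("V", "monomer"),
        SpeciesDef("R", "condensation-byproduct"),
        SpeciesDef("Tm", "membrane-count"),
    ]
    lad, lad_species, lad_rx = _ladder_network(LadderParams("V"), 2)
    species += lad_species
    if extra_species:
        species += extra_species
    params = ChemotonParams(
        n=2,
        ladders=(LadderParams("V"),),
        critical_Tm=critical_Tm,
        initial_counts=dict(counts),
        **param_overrides,
    )
    switches = (
        SwitchRule(GROWTH, DIVISION, "Tm", "reaches_or_exceeds", critical_Tm),
        SwitchRule(DIVISION, GROWTH, "Tm", "reaches_or_falls_to", critical_Tm // 2),
    )
    return ModelSpec(
        species=tuple(species),
        reactions=tuple(reactions) + tuple(lad_rx),
        ladders=(lad,),
        switches=switches,
        params=params,
    )


def closed_pair_spec(
    k: float = 2.0, kr: float = 0.1, x_clamp: int = 10, n_total: int = 50
) -> ModelSpec:
    """``A + X <-> B`` with clamped X: the canonical oracle subnetwork."""
    rx = [
        ReactionDef((("A", 1), ("X", 1)), (("B", 1),), k),
        ReactionDef((("B", 1),), (("A", 1), ("X", 1)), kr),
    ]
    return micro_spec(rx, {"A": n_total}, x_clamp=x_clamp)


def matched_basic_params() -> ChemotonParams:
    """Basic-model parameters matched to the double-template experiments
    (same metabolism, membrane, division threshold and food as fig3)."""
    return ChemotonParams(
        m=5,
        n=6,
        ladders=(LadderParams("V", k6=1.0, k6r=0.1, k7=1.0),),
        critical_Tm=1000,
        deletion_factor=0.1,
        food_mode="constant_count",
        x_clamp=20,
        initial_counts={"A1": 100, "pV0": 200, "Tm": 100},
    )


@pytest.fixture(scope="session")
def fig2c_spec():
    return build_preset("fig2c")


@pytest.fixture(scope="session")
def fig2c_traj(fig2c_spec):
    """One 10-division reference run of the basic model."""
    return run(fig2c_spec, seed=1, max_divisions=10, sample_interval=0.01)


@pytest.fixture(scope="session")
def fig3r1_traj():
    return run(
        build_preset("fig3r1"), seed=1, max_divisions=10, sample_interval=0.05
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
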