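"""Shipped parameterizations of the published simulation experiments.

Each preset transcribes the run conditions of one figure panel family:

* ``fig2a``/``fig2b``/``fig2c`` — the basic chemoton under three food
  regimes (slow influx, fast influx, constant food count);
* ``fig3r1``..``fig3r3`` — the double-template chemoton with constant food
  and polymerization-rate ratios ``k_W7/k_V7`` of 1, 10 and 100;
* ``fig4r1``..``fig4r3`` — the same ratios with food supplied by a slow
  influx instead of a clamp;
* ``fig5m5``/``fig5m12`` — the basic chemoton with a 5- versus 12-member
  metabolic cycle.

Presets fix the study conditions (initial amounts, clamps, thresholds,
kinetic constants); the seed and stop condition are run options.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import (
    ChemotonParams,
    LadderParams,
    ModelSpec,
    build_basic_chemoton,
    build_double_template_chemoton,
)

__all__ = ["Preset", "PRESETS", "get_preset", "build_preset", "list_presets"]


@dataclass(frozen=True)
class Preset:
    """A named, fully specified experiment configuration."""

    name: str
    description: str
    model: str  # "basic" | "double"
    params: ChemotonParams
    stop_divisions: int = 10
    sample_interval: float = 0.01
    default_seed: int = 1

    def build(self) -> ModelSpec:
        if self.model == "double":
            return build_double_template_chemoton(self.params)
        return build_basic_chemoton(self.params)


def _fig2_params(**overrides) -> ChemotonParams:
    base = ChemotonParams(
        m=5,
        n=6,
        ladders=(LadderParams("V", k6=1.0, k6r=0.1, k7=1.0),),
        critical_Tm=200,
        deletion_factor=10.0,
        initial_counts={"A1": 200, "pV0": 20, "Tm": 10},
    )
    return replace(base, **overrides)


def _fig3_params(kW7: float, **overrides) -> ChemotonParams:
    base = ChemotonParams(
        m=5,
        n=6,
        ladders=(
            LadderParams("V", k6=1.0, k6r=0.1, k7=1.0),
            LadderParams("W", k6=1.0, k6r=0.1, k7=kW7),
        ),
        critical_Tm=1000,
        # removal during division runs 100x slower than in the basic runs;
        # the outcome is unaffected since the halving endpoint is exact
        deletion_factor=0.1,
        food_mode="constant_count",
        x_clamp=20,
        z1_clamp=10,
        z2_clamp=10,
        initial_counts={"A1": 100, "pV0": 100, "pW0": 100, "Tm": 100},
    )
    return replace(base, **overrides)


PRESETS: dict[str, Preset] = {}


def _register(p: Preset) -> None:
    PRESETS[p.name] = p


_register(
    Preset(
        "fig2a",
        "Basic chemoton; X starts at 200 and is added at a low constant rate (10).",
        "basic",
        _fig2_params(
            food_mode="influx",
            influx_rate=10.0,
            initial_counts={"A1": 200, "pV0": 20, "Tm": 10, "X": 200},
        ),
        stop_divisions=10,
        sample_interval=0.02,
    )
)
_register(
    Preset(
        "fig2b",
        "Basic chemoton; influx rate of X increased to 200.",
        "basic",
        _fig2_params(
            food_mode="influx",
            influx_rate=200.0,
            initial_counts={"A1": 200, "pV0": 20, "Tm": 10, "X": 200},
        ),
        stop_divisions=10,
        sample_interval=0.01,
    )
)
_register(
    Preset(
        "fig2c",
        "Basic chemoton; X clamped at 10 (stable outside world); critical Tm 200.",
        "basic",
        _fig2_params(food_mode="constant_count", x_clamp=10),
        stop_divisions=10,
        sample_interval=0.01,
    )
)
_register(
    Preset(
        "fig3r1",
        "Double-template chemoton, constant X (20); identical polymerization "
        "rates k_V7 = k_W7 = 1; critical Tm 1000.",
        "double",
        _fig3_params(kW7=1.0),
        stop_divisions=10,
        sample_interval=0.05,
    )
)
_register(
    Preset(
        "fig3r2",
        "Double-template chemoton, constant X; k_W7 = 10, k_V7 = 1.",
        "double",
        _fig3_params(kW7=10.0),
        stop_divisions=10,
        sample_interval=0.05,
    )
)
_register(
    Preset(
        "fig3r3",
        "Double-template chemoton, constant X; k_W7 = 100, k_V7 = 1.",
        "double",
        _fig3_params(kW7=100.0),
        stop_divisions=10,
        sample_interval=0.05,
    )
)
for _i, _kw7 in ((1, 1.0), (2, 10.0), (3, 100.0)):
    _register(
        Preset(
            f"fig4r{_i}",
            f"Double-template chemoton, X influx 10 (initial 100); k_W7 = {_kw7:g}.",
            "double",
            _fig3_params(
                kW7=_kw7,
                food_mode="influx",
                influx_rate=10.0,
                initial_counts={
                    "A1": 100,
                    "pV0": 100,
                    "pW0": 100,
                    "Tm": 100,
                    "X": 100,
                },
            ),
            stop_divisions=6,
            sample_interval=0.5,
        )
    )
_register(
    Preset(
        "fig5m5",
        "Basic chemoton with the canonical 5-member metabolic cycle.",
        "basic",
        _fig2_params(food_mode="constant_count", x_clamp=10),
        stop_divisions=10,
        sample_interval=0.01,
    )
)
_register(
    Preset(
        "fig5m12",
        "Basic chemoton with a 12-member metabolic cycle (extra steps feed "
        "on X and the previous metabolite).",
        "basic",
        _fig2_params(m=12, food_mode="constant_count", x_clamp=10),
        stop_divisions=10,
        sample_interval=0.01,
    )
)


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def build_preset(name: str) -> ModelSpec:
    """Build the ModelSpec for a named preset."""
    return get_preset(name).build()


def list_presets() -> list[str]:
    return sorted(PRESETS)
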