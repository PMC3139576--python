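"""Network builders: structure, stoichiometry, validation."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoton.model import (
    ChemotonParams,
    LadderParams,
    ReactionDef,
    build_basic_chemoton,
    build_double_template_chemoton,
    extend_metabolic_cycle,
    ladder_closure,
    producible_species,
    validate_model,
)


def _double_params(kW7=1.0, **over):
    base = ChemotonParams(
        ladders=(
            LadderParams("V", k6=1.0, k6r=0.1, k7=1.0),
            LadderParams("W", k6=1.0, k6r=0.1, k7=kW7),
        ),
        critical_Tm=1000,
    )
    return dataclasses.replace(base, **over)


class TestBasicBuilder:
    def test_default_ladder_has_six_stages(self):
        spec = build_basic_chemoton(ChemotonParams(n=6))
        lad = spec.ladder("V")
        assert lad.stages == ("pV0", "pV1", "pV2", "pV3", "pV4", "pV5")
        assert len(lad.complexes) == 6

    @pytest.mark.parametrize("mode", ["one_step", "two_step"])
    def test_minimal_ladder_terminal_split(self, mode):
        # n=2: the incorporation from the last stage yields two stage-0 copies
        spec = build_basic_chemoton(
            ChemotonParams(n=2, ladders=(LadderParams("V", mode=mode),))
        )
        terminal = [
            r
            for r in spec.reactions
            if ("pV0", 2) in r.products and ("R", 1) in r.products
        ]
        assert len(terminal) == 1
        reactant_names = {s for s, _ in terminal[0].reactants}
        if mode == "one_step":
            assert reactant_names == {"pV1", "V"}
        else:
            assert reactant_names == {"pV1_V"}

    def test_species_count_m5_n6_two_step(self):
        # 5 metabolites + {X, Y, V, Tp, T, R, Tm} + 6 stages + 6 complexes
        spec = build_basic_chemoton(ChemotonParams(m=5, n=6))
        assert len(spec.species_names) == 24

    def test_metabolic_cycle_shape(self):
        spec = build_basic_chemoton(ChemotonParams())
        listing = spec.reaction_listing()
        assert "A1 + X -> A2 @ 2" in listing
        assert "A2 -> A1 + X @ 0.1" in listing
        assert "A5 -> 2 A1" in listing  # final step doubles the seed metabolite
        # V is released by metabolism directly (no precursor in basic model)
        assert any(
            ("V", 1) in r.products and r.reactants[0][0].startswith("A")
            for r in spec.reactions
        )
        assert "U" not in spec.species_names

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="m must be"):
            build_basic_chemoton(ChemotonParams(m=2))
        with pytest.raises(ValueError, match="n must be"):
            build_basic_chemoton(ChemotonParams(n=1))
        with pytest.raises(ValueError, match="even"):
            build_basic_chemoton(ChemotonParams(critical_Tm=999))
        with pytest.raises(ValueError, match="positive"):
            build_basic_chemoton(
                ChemotonParams(ladders=(LadderParams("V", k7=-1.0),))
            )

    def test_builder_determinism(self):
        p = ChemotonParams()
        assert build_basic_chemoton(p) == build_basic_chemoton(p)


class TestDoubleBuilder:
    def test_symmetric_rates_top_row(self):
        spec = build_double_template_chemoton(_double_params(kW7=1.0))
        lv, lw = spec.ladder("V"), spec.ladder("W")
        assert (lv.k6, lv.k6r, lv.k7) == (lw.k6, lw.k6r, lw.k7)

    def test_bottom_row_hundredfold_w(self):
        spec = build_double_template_chemoton(_double_params(kW7=100.0))
        assert spec.ladder("W").k7 == 100.0
        assert spec.ladder("V").k7 == 1.0

    def test_precursor_branching_present(self):
        spec = build_double_template_chemoton(_double_params())
        assert {"U", "Z1", "Z2"} <= set(spec.species_names)
        # metabolism releases U, not V
        assert any(
            ("U", 1) in r.products and r.reactants[0][0].startswith("A")
            for r in spec.reactions
        )
        listing = spec.reaction_listing()
        assert "U + Z1 -> V" in listing and "U + Z2 -> W" in listing
        assert spec.get_species("Z1").clamped and spec.get_species("Z2").clamped

    def test_relabel_symmetry(self):
        """With equal clamps and constants the model is V<->W symmetric."""
        spec = build_double_template_chemoton(_double_params())
        swap = (
            spec.reaction_listing()
            .replace("V", "\x01")
            .replace("W", "V")
            .replace("\x01", "W")
            .replace("Z1", "\x02")
            .replace("Z2", "Z1")
            .replace("\x02", "Z2")
        )
        assert sorted(swap.splitlines()) == sorted(
            spec.reaction_listing().splitlines()
        )

    def test_requires_two_ladders(self):
        with pytest.raises(ValueError, match="two ladder"):
            build_double_template_chemoton(ChemotonParams())


class TestExtendCycle:
    def test_grow_to_twelve(self):
        spec5 = build_basic_chemoton(ChemotonParams(m=5))
        spec12 = extend_metabolic_cycle(spec5, 12)
        mets5 = [s for s in spec5.species if s.role == "metabolite"]
        mets12 = [s for s in spec12.species if s.role == "metabolite"]
        assert len(mets12) - len(mets5) == 7
        x_steps = lambda s: [
            r
            for r in s.reactions
            if any(sp == "X" for sp, _ in r.reactants)
            and r.reactants[0][0].startswith("A")
        ]
        assert len(x_steps(spec12)) - len(x_steps(spec5)) == 7
        # reversible: each X-consuming step has its reverse
        for r in x_steps(spec12):
            assert any(
                rr.reactants == tuple((s, c) for s, c in r.products)
                and rr.products == r.reactants
                for rr in spec12.reactions
            )
        assert "A12 -> 2 A1" in spec12.reaction_listing()

    def test_identity(self):
        spec = build_basic_chemoton(ChemotonParams(m=5))
        assert extend_metabolic_cycle(spec, 5) is spec

    def test_shrink_to_three_warns_and_merges(self):
        spec = build_basic_chemoton(ChemotonParams(m=5))
        with pytest.warns(UserWarning, match="non-elementary"):
            spec3 = extend_metabolic_cycle(spec, 3)
        assert sum(1 for s in spec3.species if s.role == "metabolite") == 3
        merged = [
            r
            for r in spec3.reactions
            if ("V", 1) in r.products and ("Tp", 1) in r.products
        ]
        assert len(merged) == 1

    def test_below_minimum_rejected(self):
        spec = build_basic_chemoton(ChemotonParams())
        with pytest.raises(ValueError):
            extend_metabolic_cycle(spec, 2)


class TestValidation:
    def test_valid_specs_clean(self):
        assert validate_model(build_basic_chemoton(ChemotonParams())) == []
        assert validate_model(build_double_template_chemoton(_double_params())) == []

    def test_undeclared_species_named(self):
        spec = build_basic_chemoton(ChemotonParams())
        bad = dataclasses.replace(
            spec,
            reactions=spec.reactions
            + (ReactionDef((("Q", 1),), (("A1", 1),), 1.0),),
        )
        assert any("Q" in v for v in validate_model(bad))

    def test_odd_critical_reported(self):
        spec = build_basic_chemoton(ChemotonParams())
        bad = dataclasses.replace(
            spec, params=dataclasses.replace(spec.params, critical_Tm=999)
        )
        assert any("even" in v for v in validate_model(bad))


class TestStoichiometricWalks:
    @settings(deadline=None, max_examples=12, derandomize=True)
    @given(
        n=st.integers(min_value=2, max_value=9),
        mode=st.sampled_from(["one_step", "two_step"]),
    )
    def test_ladder_closure(self, n, mode):
        """One stage-0 duplex incorporates exactly n monomers, splits into
        two stage-0 copies and releases n condensation byproducts."""
        spec = build_basic_chemoton(
            ChemotonParams(n=n, ladders=(LadderParams("V", mode=mode),))
        )
        walk = ladder_closure(spec, "V")
        assert walk == {
            "incorporations": n,
            "stage0_copies": 2,
            "byproducts_released": n,
        }

    @pytest.mark.parametrize(
        "spec",
        [
            build_basic_chemoton(ChemotonParams()),
            build_double_template_chemoton(_double_params()),
        ],
        ids=["basic", "double"],
    )
    def test_all_species_producible(self, spec):
        """Every non-clamped, non-food species is reachable from the seed
        set {A1, X, stage-0 duplexes, Tm} on the reaction hypergraph."""
        reach = producible_species(spec)
        needed = {
            s.name
            for s in spec.species
            if not s.clamped and s.role not in ("food", "waste")
        }
        missing = needed - reach
        # Y is only produced when waste tracking is enabled
        assert not missing, f"unreachable species: {sorted(missing)}"

    def test_waste_tracking_flag(self):
        quiet = build_basic_chemoton(ChemotonParams())
        noisy = build_basic_chemoton(ChemotonParams(track_waste=True))
        produces_y = lambda s: any(
            ("Y", 1) in r.products for r in s.reactions
        )
        assert not produces_y(quiet) and produces_y(noisy)
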