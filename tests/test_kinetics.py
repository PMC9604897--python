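"""Rate-law generation: forms, limits, monotonicity, rendering."""

import random

import pytest
import sympy as sp

from pleurosim import (
    Model,
    Modifier,
    ModifierMode,
    Reaction,
    assign_all,
    assign_rate_law,
    render_expression,
)
from pleurosim.core import Compartment, CompartmentKind, Species, SpeciesRole
from pleurosim.kinetics import parse_content_mathml

CAT, ACT, INH = ModifierMode.catalyst, ModifierMode.activator, ModifierMode.inhibitor


def _rx(reactants=(), products=(("p", 1),), modifiers=()):
    return Reaction("re1", "test", reactants=reactants, products=products, modifiers=modifiers)


def test_pure_mass_action_value():
    law = assign_rate_law(_rx(reactants=(("s", 1),)))
    assert law.evaluate({"s": 0.5}) == pytest.approx(0.5)


def test_inhibitor_at_ki_halves_the_rate():
    law = assign_rate_law(_rx(reactants=(("s", 1),), modifiers=(Modifier("i", INH),)))
    assert law.evaluate({"s": 0.5, "i": 1.0}) == pytest.approx(0.25)


def test_stoichiometry_enters_as_exponent():
    law = assign_rate_law(_rx(reactants=(("s", 2),)))
    assert law.evaluate({"s": 3.0}) == pytest.approx(9.0)


def test_source_reaction_rate_is_modifier_product():
    law = assign_rate_law(_rx(modifiers=(Modifier("e", CAT),)))
    assert law.evaluate({"e": 1.7}) == pytest.approx(1.7)


def test_re6_law_couples_catalyst_and_inhibitor(fruiting_model, fruiting_laws):
    law = fruiting_laws["re6"]
    expected = sp.sympify(
        "k_re6 * mycelium_aggregation * hydrophobin"
        " * KI_re6_pofst_protein / (KI_re6_pofst_protein + pofst_protein)"
    )
    assert sp.simplify(law.expression - expected) == 0


def test_michaelis_menten_form_and_preconditions():
    rx = _rx(reactants=(("s", 1),), modifiers=(Modifier("e", CAT),))
    law = assign_rate_law(rx, form="mm")
    # v = Vmax*E*S/(Km+S) with defaults 1: 1*2*1/(1+1) = 1
    assert law.evaluate({"s": 1.0, "e": 2.0}) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        assign_rate_law(_rx(reactants=(("a", 1), ("b", 1)),
                            modifiers=(Modifier("e", CAT),)), form="mm")
    with pytest.raises(ValueError):
        assign_rate_law(_rx(reactants=(("a", 1),)), form="mm")


def test_parameter_overrides_by_name_and_family():
    rx = _rx(reactants=(("s", 1),))
    assert assign_rate_law(rx, defaults={"k": 2.5}).evaluate({"s": 1.0}) == pytest.approx(2.5)
    assert assign_rate_law(rx, defaults={"k_re1": 3.0}).evaluate({"s": 1.0}) == pytest.approx(3.0)


def test_assign_all_is_total(fruiting_model, fruiting_laws):
    assert set(fruiting_laws) == {r.id for r in fruiting_model.reactions}
    assert len(fruiting_laws) == 39


def test_assign_all_on_empty_model():
    assert assign_all(Model(id="empty")) == {}


def test_mm_policy_upgrades_single_substrate_catalysed_reactions(fruiting_model):
    laws = assign_all(fruiting_model, policy="mm_enzymes")
    assert laws["re6"].form == "mm"       # one substrate + catalyst
    assert laws["re37"].form == "gma"     # two substrates stay mass action


def _random_reaction(rng):
    n_react = rng.randint(0, 2)
    reactants = tuple((f"s{i}", rng.randint(1, 2)) for i in range(n_react))
    mods = []
    for j in range(rng.randint(0, 3)):
        mode = rng.choice([CAT, ACT, INH])
        mods.append(Modifier(f"m{j}", mode))
    products = (("prod", 1),) if (n_react == 0 or rng.random() < 0.8) else ()
    return Reaction("reX", "rand", reactants=reactants, products=products,
                    modifiers=tuple(mods))


def test_random_laws_are_finite_nonnegative_and_monotone():
    """1000 random evaluations: v >= 0, increasing in substrates/catalysts/
    activators, decreasing in inhibitors (finite differences)."""
    rng = random.Random(42)
    checked = 0
    while checked < 1000:
        rx = _random_reaction(rng)
        if not rx.reactants and not rx.products:
            continue
        law = assign_rate_law(rx)
        names = sorted(law.symbols - set(law.parameters))
        state = {n: rng.uniform(0.0, 5.0) for n in names}
        v = law.evaluate(state)
        assert v >= 0.0 and v < float("inf")
        for m in rx.modifiers:
            bumped = dict(state)
            bumped[m.species] = state[m.species] + 0.1
            dv = law.evaluate(bumped) - v
            if m.mode is INH:
                assert dv <= 1e-12
            else:
                assert dv >= -1e-12
        for sid, _ in rx.reactants:
            bumped = dict(state)
            bumped[sid] = state[sid] + 0.1
            assert law.evaluate(bumped) - v >= -1e-12
        checked += 1


def test_modifier_factor_limits():
    act = assign_rate_law(_rx(reactants=(("s", 1),), modifiers=(Modifier("a", ACT),)))
    inh = assign_rate_law(_rx(reactants=(("s", 1),), modifiers=(Modifier("i", INH),)))
    assert act.evaluate({"s": 1.0, "a": 1e9}) == pytest.approx(1.0, rel=1e-6)
    assert act.evaluate({"s": 1.0, "a": 0.0}) == 0.0
    assert inh.evaluate({"s": 1.0, "i": 0.0}) == pytest.approx(1.0)
    # no modifiers: reduces to pure mass action
    plain = assign_rate_law(_rx(reactants=(("s", 1),)))
    assert plain.expression == sp.Symbol("k_re1") * sp.Symbol("s")


def test_text_rendering_is_parseable_and_equivalent():
    law = assign_rate_law(_rx(reactants=(("substrate", 1),)))
    text = render_expression(law, "text")
    assert sp.simplify(sp.sympify(text) - law.expression) == 0


def test_mathml_rendering_roundtrips_numerically():
    rng = random.Random(7)
    rx = _rx(reactants=(("s", 2),),
             modifiers=(Modifier("e", CAT), Modifier("a", ACT), Modifier("i", INH)))
    law = assign_rate_law(rx)
    doc = render_expression(law, "mathml")
    back = parse_content_mathml(doc)
    for _ in range(10):
        state = {n: rng.uniform(0.1, 4.0) for n in ("s", "e", "a", "i")}
        state.update(law.parameters)
        expected = law.evaluate({k: v for k, v in state.items() if k in ("s", "e", "a", "i")})
        got = float(back.subs({sp.Symbol(k): v for k, v in state.items()}))
        assert got == pytest.approx(expected, abs=1e-9)
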