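"""ODE integration, initial-condition scheme and scans."""

import numpy as np
import pytest

from pleurosim import (
    Model,
    SimulationSettings,
    SyntheticConfig,
    assign_all,
    default_initial_conditions,
    generate_model,
    integrate,
    scan_initial,
)
from pleurosim.core import Compartment, CompartmentKind, Reaction, Species, SpeciesRole


def _decay_model():
    return Model(
        id="decay",
        compartments=[Compartment("fungal_cell", "cell", CompartmentKind.fungal_cell)],
        species=[
            Species("a", "A", SpeciesRole.simple_molecule, "fungal_cell", initial_amount=1.0),
            Species("b", "B", SpeciesRole.simple_molecule, "fungal_cell", initial_amount=0.0),
        ],
        reactions=[Reaction("re1", "a to b", reactants=(("a", 1),), products=(("b", 1),))],
    )


def test_role_defaults_follow_the_initial_value_scheme(fruiting_model):
    ics = default_initial_conditions(fruiting_model)
    assert ics["olya6_gene"] == 0.5
    assert ics["olya6_mrna"] == 1.0
    assert ics["pleurotolysin"] == 2.0
    assert ics["powc1_fad_complex"] == 2.0
    assert ics["pinhead_formation"] == 2.5
    assert ics["fad"] == 0.5
    assert ics["membrane_receptor"] == 0.5


def test_explicit_initial_amount_overrides_role_default():
    model = _decay_model()
    assert default_initial_conditions(model) == {"a": 1.0, "b": 0.0}


def test_empty_model_has_empty_initial_conditions():
    assert default_initial_conditions(Model(id="empty")) == {}


def test_two_species_decay_matches_closed_form():
    model = _decay_model()
    laws = assign_all(model)
    traj = integrate(model, laws, settings=SimulationSettings(t_end=1.0, n_points=11))
    assert traj.terminal("a") == pytest.approx(np.exp(-1.0), abs=1e-6)
    total = traj.amounts["a"] + traj.amounts["b"]
    assert np.allclose(total, 1.0, atol=1e-7)


def test_zero_rate_constants_freeze_the_state(fruiting_model):
    laws = assign_all(fruiting_model, defaults={"k": 0.0})
    traj = integrate(fruiting_model, laws, settings=SimulationSettings(t_end=2.0, n_points=20))
    ics = default_initial_conditions(fruiting_model)
    for sid, series in traj.amounts.items():
        assert np.allclose(series, ics[sid], atol=1e-9)


def test_constant_species_are_held_fixed(fruiting_model, fruiting_laws):
    traj = integrate(fruiting_model, fruiting_laws,
                     settings=SimulationSettings(t_end=5.0, n_points=50))
    assert np.allclose(traj.amounts["blue_light"], traj.amounts["blue_light"][0])
    assert np.allclose(traj.amounts["humidity"], traj.amounts["humidity"][0])


def test_trajectory_is_finite_nonnegative_on_curated_model(fruiting_model, fruiting_laws):
    traj = integrate(fruiting_model, fruiting_laws)
    for series in traj.amounts.values():
        assert np.isfinite(series).all()
        assert (series >= 0).all()


def test_halving_tolerances_barely_moves_terminal_values(fruiting_model, fruiting_laws):
    tight = SimulationSettings(rtol=5e-9, atol=5e-11)
    a = integrate(fruiting_model, fruiting_laws)
    b = integrate(fruiting_model, fruiting_laws, settings=tight)
    for sid in a.amounts:
        ref = max(abs(a.terminal(sid)), 1.0)
        assert abs(a.terminal(sid) - b.terminal(sid)) / ref < 1e-5


def test_closed_mass_action_subsystem_conserves_total():
    model = Model(
        id="cycle",
        compartments=[Compartment("fungal_cell", "cell", CompartmentKind.fungal_cell)],
        species=[
            Species(s, s.upper(), SpeciesRole.simple_molecule, "fungal_cell",
                    initial_amount=x)
            for s, x in (("a", 2.0), ("b", 0.5), ("c", 0.0))
        ],
        reactions=[
            Reaction("re1", "a-b", reactants=(("a", 1),), products=(("b", 1),)),
            Reaction("re2", "b-c", reactants=(("b", 1),), products=(("c", 1),)),
            Reaction("re3", "c-a", reactants=(("c", 1),), products=(("a", 1),)),
        ],
    )
    laws = assign_all(model)
    settings = SimulationSettings(t_end=20.0)
    traj = integrate(model, laws, settings=settings)
    total = traj.amounts["a"] + traj.amounts["b"] + traj.amounts["c"]
    assert np.allclose(total, 2.5, atol=10 * settings.rtol * 2.5)


def test_unknown_species_in_ics_or_scan_is_rejected(fruiting_model, fruiting_laws):
    with pytest.raises(KeyError):
        integrate(fruiting_model, fruiting_laws, ics={"nope": 1.0})
    with pytest.raises(KeyError):
        scan_initial(fruiting_model, fruiting_laws, "nope", [0, 1], "pinhead_formation")
    with pytest.raises(KeyError):
        scan_initial(fruiting_model, fruiting_laws, "hydrophobin", [0, 1], "nope")


def test_scan_grid_validation(fruiting_model, fruiting_laws):
    with pytest.raises(ValueError):
        scan_initial(fruiting_model, fruiting_laws, "hydrophobin", [], "pinhead_formation")
    with pytest.raises(ValueError):
        scan_initial(fruiting_model, fruiting_laws, "hydrophobin", [-1.0], "pinhead_formation")


def test_scan_records_one_terminal_value_per_grid_point(fruiting_model, fruiting_laws):
    settings = SimulationSettings(t_end=2.0, n_points=20)
    dr = scan_initial(fruiting_model, fruiting_laws, "hydrophobin", [0.0, 1.0],
                      "pinhead_formation", settings)
    assert dr.grid.shape == dr.terminal.shape == (2,)
    assert np.isfinite(dr.terminal).all()


@pytest.mark.parametrize("seed", range(0, 25, 5))
def test_synthetic_models_simulate_to_t_end(seed):
    model = generate_model(SyntheticConfig(n_genes=2, n_extra_molecules=4,
                                           n_phenotypes=1, seed=seed))
    laws = assign_all(model)
    traj = integrate(model, laws, settings=SimulationSettings(t_end=5.0, n_points=30))
    for series in traj.amounts.values():
        assert np.isfinite(series).all()
        assert (series >= 0).all()
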