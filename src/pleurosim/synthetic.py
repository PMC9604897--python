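"""Seeded random generators for structurally realistic regulatory models.

:func:`generate_model` emulates the architecture of the curated fruiting
network without copying it: per-gene central-dogma chains
(gene -> mRNA -> protein), a pool of interconverting small molecules,
proteins attached to conversion reactions as catalysts or inhibitors, and
phenotype sink species each fed by at least one reaction path.  Initial
amounts fall in the 0.5-2.5 arbitrary-unit range via the role defaults.

:func:`generate_graph` produces uniform random simple directed graphs
(optionally bipartite) as oracle fodder for the topology metrics.

Both are pure functions of their configuration: the seed is explicit and
no global random state is touched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import (
    Compartment,
    CompartmentKind,
    Model,
    Modifier,
    ModifierMode,
    Reaction,
    Species,
    SpeciesRole,
    require_valid,
)
from .netanalysis import DirectedGraph, GraphEdge, GraphNode


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 11
    n_extra_molecules: int = 8
    n_phenotypes: int = 2
    cross_link_probability: float = 0.3
    inhibitor_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_extra_molecules < 0:
            raise ValueError("counts must be non-negative")
        if self.n_phenotypes < 1:
            raise ValueError("need at least one phenotype")
        for p in (self.cross_link_probability, self.inhibitor_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


_COMPARTMENTS = [
    Compartment("environment", "environment", CompartmentKind.environment),
    Compartment("fungal_cell", "fungal cell", CompartmentKind.fungal_cell),
    Compartment("mitochondria", "mitochondria", CompartmentKind.mitochondria),
    Compartment("substrate", "substrate", CompartmentKind.substrate),
]


def generate_model(config: SyntheticConfig) -> Model:
    """Random regulatory model; identical output for identical config."""
    rng = random.Random(config.seed)
    species: list[Species] = []
    reactions: list[Reaction] = []
    rid = iter(f"re{i}" for i in range(1, 10_000))

    proteins: list[str] = []
    for i in range(1, config.n_genes + 1):
        g, m, p = f"gene{i}", f"mrna{i}", f"protein{i}"
        species += [
            Species(g, f"gene {i}", SpeciesRole.gene, "fungal_cell"),
            Species(m, f"mRNA {i}", SpeciesRole.mrna, "fungal_cell"),
            Species(p, f"protein {i}", SpeciesRole.protein, "fungal_cell"),
        ]
        reactions.append(
            Reaction(next(rid), f"transcription {i}", reactants=((g, 1),), products=((m, 1),))
        )
        reactions.append(
            Reaction(next(rid), f"translation {i}", reactants=((m, 1),), products=((p, 1),))
        )
        proteins.append(p)

    molecules = [f"mol{j}" for j in range(1, config.n_extra_molecules + 1)]
    comps = ["fungal_cell", "mitochondria", "substrate"]
    for j, mol in enumerate(molecules):
        species.append(
            Species(mol, f"molecule {j + 1}", SpeciesRole.simple_molecule, rng.choice(comps))
        )

    conversions: list[Reaction] = []
    # a chain through the molecule pool keeps it connected ...
    for a, b in zip(molecules, molecules[1:]):
        conversions.append(
            Reaction(next(rid), f"{a} to {b}", reactants=((a, 1),), products=((b, 1),))
        )
    # ... plus random cross-links
    for a in molecules:
        for b in molecules:
            if a != b and rng.random() < config.cross_link_probability:
                conversions.append(
                    Reaction(next(rid), f"{a} to {b} (link)", reactants=((a, 1),), products=((b, 1),))
                )

    phenotypes = [f"phenotype{k}" for k in range(1, config.n_phenotypes + 1)]
    for k, ph in enumerate(phenotypes):
        species.append(Species(ph, f"phenotype {k + 1}", SpeciesRole.phenotype, "fungal_cell"))
        # every phenotype sink is fed by at least one reaction path
        if molecules:
            src = rng.choice(molecules)
            conversions.append(
                Reaction(next(rid), f"{src} drives {ph}", reactants=((src, 1),), products=((ph, 1),))
            )
        else:
            conversions.append(Reaction(next(rid), f"{ph} formation", products=((ph, 1),)))

    # attach proteins to conversion reactions as catalysts or inhibitors
    decorated: list[Reaction] = []
    for r in conversions:
        decorated.append(r)
    for p in proteins:
        if not decorated:
            break
        target_idx = rng.randrange(len(decorated))
        target = decorated[target_idx]
        if p in target.reactant_ids() or p in target.modifier_ids():
            continue
        mode = (
            ModifierMode.inhibitor
            if rng.random() < config.inhibitor_fraction
            else ModifierMode.catalyst
        )
        decorated[target_idx] = Reaction(
            target.id,
            target.name,
            target.reactants,
            target.products,
            target.modifiers + (Modifier(p, mode),),
            target.reversible,
            target.annotation,
        )

    model = Model(
        id=f"synthetic_seed{config.seed}",
        name="synthetic regulatory model",
        compartments=list(_COMPARTMENTS),
        species=species,
        reactions=reactions + decorated,
    )
    require_valid(model)
    return model


def generate_graph(
    n_nodes: int, n_edges: int, seed: int = 0, bipartite: bool = False
) -> DirectedGraph:
    """Uniform random simple directed graph on ``n_nodes`` labelled nodes.

    With ``bipartite=True`` nodes alternate species/reaction kinds and
    edges only cross the two classes (hence no triangles and clustering
    coefficient 0).  Raises ``ValueError`` for an infeasible edge count.
    """
    rng = random.Random(seed)
    if bipartite:
        kinds = ["species" if i % 2 == 0 else "reaction" for i in range(n_nodes)]
    else:
        kinds = ["species"] * n_nodes
    ids = [f"n{i}" for i in range(n_nodes)]
    pairs = [
        (ids[i], ids[j])
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and (not bipartite or kinds[i] != kinds[j])
    ]
    if n_edges > len(pairs):
        raise ValueError(f"cannot place {n_edges} edges among {n_nodes} nodes")
    chosen = rng.sample(pairs, n_edges)
    chosen.sort()
    return DirectedGraph(
        nodes=[GraphNode(ids[i], kinds[i], ids[i]) for i in range(n_nodes)],
        edges=[GraphEdge(a, b, "link") for a, b in chosen],
    )
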