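"""Core model schema: compartments, species, reactions and validation.

The in-memory representation mirrors a small, well-defined subset of an
SBML Level 2 model: a set of compartments, a set of typed species (the
type — gene, mRNA, protein, complex, simple molecule, receptor or
phenotype — drives default initial amounts and kinetic roles downstream),
and a set of irreversible reactions with reactant/product stoichiometries
and modifier species acting as catalysts, activators or inhibitors.

Validation never raises: broken invariants are returned as
:class:`Violation` records so a caller (or the CLI) can report every
problem at once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence


class CompartmentKind(str, Enum):
    environment = "environment"
    fungal_cell = "fungal_cell"
    mitochondria = "mitochondria"
    substrate = "substrate"
    other = "other"


class SpeciesRole(str, Enum):
    gene = "gene"
    mrna = "mRNA"
    protein = "protein"
    complex = "complex"
    simple_molecule = "simple_molecule"
    receptor = "receptor"
    phenotype = "phenotype"


class ModifierMode(str, Enum):
    catalyst = "catalyst"
    activator = "activator"
    inhibitor = "inhibitor"


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str
    kind: CompartmentKind = CompartmentKind.other


@dataclass(frozen=True)
class Species:
    id: str
    name: str
    role: SpeciesRole
    compartment: str
    #: explicit initial amount in arbitrary concentration units; ``None``
    #: defers to the per-role default applied by the simulator.
    initial_amount: Optional[float] = None
    #: constant species (environmental stimuli such as blue light or
    #: humidity) are boundary conditions: the integrator holds them fixed.
    constant: bool = False


@dataclass(frozen=True)
class Modifier:
    species: str
    mode: ModifierMode


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str
    reactants: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[Modifier, ...] = ()
    reversible: bool = False
    annotation: str = ""

    def __post_init__(self) -> None:
        # Normalise lists passed by callers into hashable tuples.
        object.__setattr__(self, "reactants", tuple((s, int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(n)) for s, n in self.products))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))

    def reactant_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.reactants)

    def product_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.products)

    def modifier_ids(self) -> tuple[str, ...]:
        return tuple(m.species for m in self.modifiers)


@dataclass
class Model:
    id: str
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    name: str = ""

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def species_ids(self) -> set[str]:
        return {s.id for s in self.species}

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            name=self.name,
            compartments=list(self.compartments),
            species=list(self.species),
            reactions=list(self.reactions),
        )


@dataclass(frozen=True)
class Violation:
    """One broken invariant: the offending element and the rule it breaks."""

    element: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.element}: {self.message}"


@dataclass(frozen=True)
class CompositionSummary:
    """Counts of model elements by role.

    ``proteins`` counts roles ``protein`` and ``complex`` together (a bound
    protein complex is still a protein-class node); ``simple_molecules``
    counts ``simple_molecule`` and ``receptor`` together.  Under those
    groupings the role counts sum to the total species count.
    """

    compartments: int
    species: int
    genes: int
    mrna: int
    proteins: int
    simple_molecules: int
    phenotypes: int
    reactions: int

    def as_dict(self) -> dict[str, int]:
        return {
            "compartments": self.compartments,
            "species": self.species,
            "genes": self.genes,
            "mrna": self.mrna,
            "proteins": self.proteins,
            "simple_molecules": self.simple_molecules,
            "phenotypes": self.phenotypes,
            "reactions": self.reactions,
        }


#: Compartment ids whose kind is pinned when present (the four curated
#: compartments of the fruiting model).
_CANONICAL_COMPARTMENTS = {
    "environment": CompartmentKind.environment,
    "fungal_cell": CompartmentKind.fungal_cell,
    "mitochondria": CompartmentKind.mitochondria,
    "substrate": CompartmentKind.substrate,
}


def validate_model(model: Model) -> list[Violation]:
    """Check every schema invariant; return one record per breach.

    An empty list means the model is valid.  Violations are data, not
    exceptions, so all problems are reported in a single pass.
    """
    out: list[Violation] = []

    seen: Counter[str] = Counter()
    for element in (*model.compartments, *model.species, *model.reactions):
        seen[element.id] += 1
    for ident, n in seen.items():
        if n > 1:
            out.append(Violation(ident, "unique-id", f"identifier used {n} times"))

    comp_ids = {c.id for c in model.compartments}
    for c in model.compartments:
        pinned = _CANONICAL_COMPARTMENTS.get(c.id)
        if pinned is not None and c.kind is not pinned:
            out.append(
                Violation(c.id, "compartment-kind", f"kind {c.kind.value!r} does not match canonical name")
            )

    sp_ids = set()
    for s in model.species:
        sp_ids.add(s.id)
        if s.compartment not in comp_ids:
            out.append(
                Violation(s.id, "dangling-compartment", f"compartment {s.compartment!r} is not defined")
            )
        if s.initial_amount is not None and s.initial_amount < 0:
            out.append(
                Violation(s.id, "negative-amount", f"initial amount {s.initial_amount} is negative")
            )

    for r in model.reactions:
        if not r.reactants and not r.products:
            out.append(Violation(r.id, "empty-reaction", "no reactants and no products"))
        for sid, stoich in (*r.reactants, *r.products):
            if sid not in sp_ids:
                out.append(Violation(r.id, "dangling-species", f"species {sid!r} is not defined"))
            if stoich <= 0:
                out.append(Violation(r.id, "bad-stoichiometry", f"{sid}: stoichiometry {stoich} <= 0"))
        for m in r.modifiers:
            if m.species not in sp_ids:
                out.append(Violation(r.id, "dangling-species", f"modifier {m.species!r} is not defined"))
        overlap = set(r.reactant_ids()) & set(r.modifier_ids())
        for sid in sorted(overlap):
            out.append(
                Violation(r.id, "reactant-modifier-overlap", f"{sid} is both reactant and modifier")
            )

    return out


class InvalidModelError(ValueError):
    """Raised by operations that require a valid model."""

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in violations[:5])
        more = "" if len(violations) <= 5 else f" (+{len(violations) - 5} more)"
        super().__init__(f"model is invalid: {lines}{more}")


def require_valid(model: Model) -> None:
    violations = validate_model(model)
    if violations:
        raise InvalidModelError(violations)


def composition_summary(model: Model) -> CompositionSummary:
    """Count model elements by role (the printed composition line).

    Deterministic and invariant under reordering of species or reactions.
    """
    require_valid(model)
    roles = Counter(s.role for s in model.species)
    return CompositionSummary(
        compartments=len(model.compartments),
        species=len(model.species),
        genes=roles[SpeciesRole.gene],
        mrna=roles[SpeciesRole.mrna],
        proteins=roles[SpeciesRole.protein] + roles[SpeciesRole.complex],
        simple_molecules=roles[SpeciesRole.simple_molecule] + roles[SpeciesRole.receptor],
        phenotypes=roles[SpeciesRole.phenotype],
        reactions=len(model.reactions),
    )
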