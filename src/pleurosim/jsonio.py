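"""JSON model dialect: a plain, documented serialization of the schema.

Schema (version 1)::

    {
      "format": "pleurosim-model", "version": 1,
      "id": ..., "name": ...,
      "compartments": [{"id", "name", "kind"}],
      "species": [{"id", "name", "role", "compartment",
                   "initial_amount" (optional), "constant" (optional)}],
      "reactions": [{"id", "name",
                     "reactants": [[species, stoichiometry], ...],
                     "products": [...],
                     "modifiers": [{"species", "mode"}, ...],
                     "reversible" (optional), "annotation" (optional)}]
    }

The mapping is lossless: ``model_from_dict(model_to_dict(m)) == m``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

from .core import (
    Compartment,
    CompartmentKind,
    Model,
    Modifier,
    ModifierMode,
    Reaction,
    Species,
    SpeciesRole,
)

FORMAT = "pleurosim-model"
VERSION = 1


def model_to_dict(model: Model) -> dict[str, Any]:
    out: dict[str, Any] = {
        "format": FORMAT,
        "version": VERSION,
        "id": model.id,
        "name": model.name,
        "compartments": [
            {"id": c.id, "name": c.name, "kind": c.kind.value} for c in model.compartments
        ],
        "species": [],
        "reactions": [],
    }
    for s in model.species:
        d: dict[str, Any] = {
            "id": s.id, "name": s.name, "role": s.role.value, "compartment": s.compartment,
        }
        if s.initial_amount is not None:
            d["initial_amount"] = s.initial_amount
        if s.constant:
            d["constant"] = True
        out["species"].append(d)
    for r in model.reactions:
        d = {
            "id": r.id,
            "name": r.name,
            "reactants": [[sid, n] for sid, n in r.reactants],
            "products": [[sid, n] for sid, n in r.products],
            "modifiers": [{"species": m.species, "mode": m.mode.value} for m in r.modifiers],
        }
        if r.reversible:
            d["reversible"] = True
        if r.annotation:
            d["annotation"] = r.annotation
        out["reactions"].append(d)
    return out


def model_from_dict(data: dict[str, Any]) -> Model:
    if data.get("format") != FORMAT:
        raise ValueError(f"not a {FORMAT} document")
    return Model(
        id=data["id"],
        name=data.get("name", ""),
        compartments=[
            Compartment(c["id"], c["name"], CompartmentKind(c["kind"]))
            for c in data["compartments"]
        ],
        species=[
            Species(
                id=s["id"], name=s["name"], role=SpeciesRole(s["role"]),
                compartment=s["compartment"],
                initial_amount=s.get("initial_amount"),
                constant=s.get("constant", False),
            )
            for s in data["species"]
        ],
        reactions=[
            Reaction(
                id=r["id"], name=r["name"],
                reactants=tuple((sid, n) for sid, n in r.get("reactants", [])),
                products=tuple((sid, n) for sid, n in r.get("products", [])),
                modifiers=tuple(
                    Modifier(m["species"], ModifierMode(m["mode"]))
                    for m in r.get("modifiers", [])
                ),
                reversible=r.get("reversible", False),
                annotation=r.get("annotation", ""),
            )
            for r in data["reactions"]
        ],
    )


def write_json(model: Model, path: Union[str, Path, None] = None) -> str:
    text = json.dumps(model_to_dict(model), indent=1, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_json(source: Union[str, Path]) -> Model:
    text = source if isinstance(source, str) and source.lstrip().startswith("{") else Path(source).read_text()
    return model_from_dict(json.loads(text))
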