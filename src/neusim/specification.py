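"""High-level model specification: populations, connections, mechanisms.

The specification is the user-facing description of a network model. It can
be given as

* a bare equation string (or list of strings) — wrapped into a single
  population named ``pop1``;
* a :class:`Specification` built programmatically;
* a JSON document (see :func:`load_spec`) with top-level keys
  ``populations``, ``connections`` and ``mechanisms``.

``standardize`` normalizes any of these into a validated Specification; the
model builder then flattens it into one ODE system.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import library
from .equations import EquationSet, parse_equations
from .errors import ModelError

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "Specification",
    "standardize",
    "load_spec",
    "save_spec",
]

_POP_FIELDS = {"name", "size", "equations", "mechanisms", "mechanism_list", "parameters"}
_CON_FIELDS = {"source", "target", "mechanisms", "mechanism_list", "parameters"}
_TOP_FIELDS = {"populations", "connections", "mechanisms"}


@dataclass
class PopulationSpec:
    """One population: a set of identical units sharing equations."""

    name: str = "pop1"
    size: int = 1
    equations: object = ""  # str | list[str] | EquationSet | library pop name
    mechanism_list: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


@dataclass
class ConnectionSpec:
    """Directed connection source -> target via connection mechanisms."""

    source: str = ""
    target: str = ""
    mechanism_list: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass
class Specification:
    populations: list = field(default_factory=list)
    connections: list = field(default_factory=list)
    mechanisms: dict = field(default_factory=dict)  # inline name -> EquationSet|str

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    def connection(self, source: str, target: str) -> ConnectionSpec:
        for c in self.connections:
            if c.source == source and c.target == target:
                return c
        raise KeyError(f"no connection {source}->{target}")

    def copy(self) -> "Specification":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------


def standardize(spec_input) -> Specification:
    """Normalize user input into a validated Specification.

    Bare equation text becomes a single population named ``pop1`` of size 1
    (a declared parameter ``N`` sets the size instead). Already-standard
    specifications pass through unchanged (idempotent up to deep copy).
    """
    if isinstance(spec_input, Specification):
        spec = spec_input.copy()
    elif isinstance(spec_input, (str, list, tuple)):
        spec = Specification(populations=[PopulationSpec(equations=spec_input)])
    elif isinstance(spec_input, dict):
        spec = _from_dict(spec_input)
    else:
        raise TypeError(
            "specification must be a string, list of strings, dict, or "
            f"Specification (got {type(spec_input).__name__})"
        )

    seen = set()
    for pop in spec.populations:
        if not isinstance(pop, PopulationSpec):
            raise TypeError("populations must contain PopulationSpec objects")
        pop.name = pop.name or "pop1"
        if pop.name in seen:
            raise ModelError(f"duplicate population name {pop.name!r}")
        seen.add(pop.name)
    for pop in spec.populations:
        _resolve_population(pop)
        if int(pop.size) < 1:
            raise ModelError(f"population {pop.name!r}: size must be >= 1")
        pop.size = int(pop.size)
        _check_parameter_arrays(pop.parameters, pop.size, f"population {pop.name!r}")

    for con in spec.connections:
        if not isinstance(con, ConnectionSpec):
            raise TypeError("connections must contain ConnectionSpec objects")
        for end in (con.source, con.target):
            if end not in seen:
                raise ModelError(
                    f"connection {con.label!r} references unknown population {end!r}"
                )
        con.mechanism_list = list(con.mechanism_list)
        con.parameters = dict(con.parameters)
    return spec


def _resolve_population(pop: PopulationSpec) -> None:
    """Resolve equations to an EquationSet; fold in directives and defaults."""
    eqs = pop.equations
    if isinstance(eqs, str) and library.find_population(eqs.strip()) is not None:
        eqs = library.instantiate(eqs.strip(), size=pop.size)
    if isinstance(eqs, (str, list, tuple)):
        eqs = parse_equations(eqs, strict=False, name=pop.name)
    if not isinstance(eqs, EquationSet):
        raise TypeError(
            f"population {pop.name!r}: equations must be text, an EquationSet, "
            "or a library population name"
        )
    pop.equations = eqs
    # a 'mechanisms' directive inside the equations extends the list
    merged = list(eqs.mechanism_list) + [
        m for m in pop.mechanism_list if m not in eqs.mechanism_list
    ]
    pop.mechanism_list = merged
    for key, value in getattr(eqs, "mech_overrides", {}).items():
        pop.parameters.setdefault(key, value)
    # equations may set the population size through a parameter N
    if "N" in eqs.parameters and (pop.size is None or pop.size == 1):
        pop.size = int(eqs.parameters["N"])
    pop.size = int(pop.size or 1)
    pop.parameters = dict(pop.parameters)


def _check_parameter_arrays(params: dict, size: int, where: str) -> None:
    for name, value in params.items():
        if name == "netcon":
            continue  # checked against (target, source) shape by the builder
        if isinstance(value, (list, tuple)):
            if len(value) != size and not any(
                isinstance(v, (list, tuple)) for v in value
            ):
                raise ModelError(
                    f"{where}: parameter {name!r} has length {len(value)}, "
                    f"expected the population size {size}"
                )


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------


def _from_dict(doc: dict) -> Specification:
    unknown = set(doc) - _TOP_FIELDS
    if unknown:
        raise ModelError(f"unknown specification fields: {sorted(unknown)}")
    spec = Specification()
    for p in doc.get("populations", []):
        bad = set(p) - _POP_FIELDS
        if bad:
            raise ModelError(f"unknown population fields: {sorted(bad)}")
        spec.populations.append(
            PopulationSpec(
                name=p.get("name", "pop1"),
                size=p.get("size", 1),
                equations=p.get("equations", ""),
                mechanism_list=list(p.get("mechanisms", p.get("mechanism_list", []))),
                parameters=dict(p.get("parameters", {})),
            )
        )
    for c in doc.get("connections", []):
        bad = set(c) - _CON_FIELDS
        if bad:
            raise ModelError(f"unknown connection fields: {sorted(bad)}")
        spec.connections.append(
            ConnectionSpec(
                source=c.get("source", ""),
                target=c.get("target", ""),
                mechanism_list=list(c.get("mechanisms", c.get("mechanism_list", []))),
                parameters=dict(c.get("parameters", {})),
            )
        )
    spec.mechanisms = dict(doc.get("mechanisms", {}))
    return spec


def to_dict(spec: Specification) -> dict:
    from .equations import serialize

    def _eqs(e):
        return serialize(e) if isinstance(e, EquationSet) else e

    doc = {
        "populations": [
            {
                "name": p.name,
                "size": p.size,
                "equations": _eqs(p.equations),
                "mechanisms": list(p.mechanism_list),
                "parameters": dict(p.parameters),
            }
            for p in spec.populations
        ]
    }
    if spec.connections:
        doc["connections"] = [
            {
                "source": c.source,
                "target": c.target,
                "mechanisms": list(c.mechanism_list),
                "parameters": dict(c.parameters),
            }
            for c in spec.connections
        ]
    if spec.mechanisms:
        doc["mechanisms"] = {k: _eqs(v) for k, v in spec.mechanisms.items()}
    return doc


def load_spec(path) -> Specification:
    """Read a specification from a JSON file and standardize it."""
    doc = json.loads(Path(path).read_text())
    return standardize(doc)


def save_spec(spec: Specification, path) -> None:
    Path(path).write_text(json.dumps(to_dict(spec), indent=2) + "\n")
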