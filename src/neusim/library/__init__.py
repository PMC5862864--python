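"""Prepackaged model-object library.

Ships reusable model objects as plain-text dialect files:

* ``mechanisms/*.mech`` — input sources (noise, poisson, stim), intrinsic ion
  currents (iNa, iK, iNaF, iKDR, iM) and connection mechanisms (iAMPA,
  iGABAa, iGABAb, iNMDA, iGAP, iCOM);
* ``populations/*.pop``  — complete neuron models (HH, Izh, LIF) given as
  equations plus an optional intrinsic mechanism list.

Every ionic mechanism contributes through the ``@current +=`` linker, so
arbitrary subsets compose into a single voltage equation. File headers carry
the citation for the kinetics used; the first comment line is exposed via
:func:`list_objects`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from ..equations import EquationSet, parse_equations, parse_mechanism_file
from ..errors import ModelError

__all__ = [
    "LibraryEntry",
    "LibraryIndex",
    "library_paths",
    "list_objects",
    "instantiate",
    "find_mechanism",
    "find_population",
]

_ROOT = Path(__file__).parent
KINDS = ("input", "intrinsic", "connection", "population")


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    kind: str  # input | intrinsic | connection | population
    path: Path
    citation: str


class LibraryIndex(dict):
    """Mapping name -> LibraryEntry with stable alphabetical iteration."""

    def __iter__(self):
        return iter(sorted(dict.keys(self), key=str.lower))

    def items(self):
        return [(k, self[k]) for k in self]

    def names(self):
        return list(self)


def library_paths():
    """Directories scanned for ``.mech`` and ``.pop`` files."""
    return [_ROOT / "mechanisms", _ROOT / "populations"]


def _read_header(path: Path):
    kind = None
    citation = ""
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line.startswith(("%", "#")):
            break
        body = line.lstrip("%# ").strip()
        m = re.match(r"kind:\s*(\w+)", body)
        if m:
            kind = m.group(1)
        elif not citation:
            citation = body
    return kind, citation


def _scan(extra_paths=()) -> LibraryIndex:
    idx = LibraryIndex()
    dirs = [Path(d) for d in extra_paths] + library_paths()
    for d in dirs:
        if not d.is_dir():
            continue
        for p in sorted(d.iterdir()):
            if p.suffix not in (".mech", ".pop"):
                continue
            if p.stem in idx:  # extra paths shadow the packaged library
                continue
            kind, citation = _read_header(p)
            if kind is None:
                kind = "population" if p.suffix == ".pop" else "intrinsic"
            if kind not in KINDS:
                raise ModelError(f"{p.name}: unknown object kind {kind!r}")
            idx[p.stem] = LibraryEntry(p.stem, kind, p, citation)
    return idx


def list_objects(kind: str | None = None, extra_paths=()) -> LibraryIndex:
    """Index of packaged model objects, optionally filtered by kind.

    ``kind`` is one of ``input``, ``intrinsic``, ``connection``,
    ``population`` (or None for everything).
    """
    if kind is not None and kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {KINDS}")
    idx = _scan(extra_paths)
    if kind is None:
        return idx
    out = LibraryIndex()
    for name in idx:
        if idx[name].kind == kind:
            out[name] = idx[name]
    return out


def find_mechanism(name: str, extra_paths=()) -> Path | None:
    for d in [Path(d) for d in extra_paths] + [_ROOT / "mechanisms"]:
        p = Path(d) / f"{name}.mech"
        if p.exists():
            return p
    return None


def find_population(name: str, extra_paths=()) -> Path | None:
    for d in [Path(d) for d in extra_paths] + [_ROOT / "populations"]:
        p = Path(d) / f"{name}.pop"
        if p.exists():
            return p
    return None


def instantiate(name: str, size: int = 1, overrides: dict | None = None,
                mechanisms=()) -> EquationSet:
    """Load a library object with parameter overrides applied.

    For a population entry the returned EquationSet carries the population's
    intrinsic mechanism list (extended by ``mechanisms``); parameter
    overrides naming a parameter of a listed mechanism are kept as
    population-level overrides (the model builder pushes them down by name).
    Overriding a name that exists nowhere raises.
    """
    overrides = dict(overrides or {})
    idx = _scan()
    if name not in idx:
        raise KeyError(f"no library object named {name!r}")
    entry = idx[name]
    if entry.kind == "population":
        eqs = parse_equations(entry.path.read_text(), strict=False, name=name)
    else:
        eqs = parse_mechanism_file(entry.path)
    eqs.mechanism_list = list(eqs.mechanism_list) + list(mechanisms)

    # names overridable at this level: own parameters + those of listed mechs
    mech_params: dict[str, list[str]] = {}
    for m in eqs.mechanism_list:
        mp = find_mechanism(m)
        if mp is None:
            raise ModelError(f"mechanism {m!r} not found in library")
        for p in parse_mechanism_file(mp).parameters:
            mech_params.setdefault(p, []).append(m)

    mech_overrides: dict = {}
    eqs.mech_overrides = mech_overrides
    for key, value in overrides.items():
        if key in eqs.parameters:
            eqs.parameters[key] = value
        elif key in mech_params:
            # kept as an override; the model builder pushes it down to the
            # declaring mechanism(s) by name
            mech_overrides[key] = value
        elif key == "size":
            continue
        else:
            raise KeyError(
                f"{name!r} has no parameter {key!r} (not in the object or "
                "its mechanisms)"
            )
    if size is not None and int(size) < 1:
        raise ValueError("population size must be >= 1")
    return eqs
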