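"""Flatten a Specification into a single ODE system (the FlatModel).

The flattening step mirrors how modular neural models are composed in the
field: every object (population or mechanism instance) gets a namespace
prefix joined with ``_`` (state ``m`` of mechanism ``Na`` in population
``pop1`` becomes ``pop1_Na_m``); mechanism contributions are then spliced
into host equations by *linkers* — ``@``-prefixed placeholders paired with
compound-assignment statements such as ``@current += INa``. After
substitution no ``@`` token remains and the model is a plain system of ODEs,
functions, conditionals and parameters with globally unique names, ready for
numerical integration.

Connection mechanisms (source -> target) additionally see the reserved
symbols ``netcon`` (a target x source connectivity matrix, all-to-all ones
by default), ``N_pre``/``N_post`` (population sizes), ``<name>_pre`` /
``<name>_post`` (source/target symbols, e.g. ``V_pre``) and
``tspike_pre``/``tspike_post`` (ring buffers of recent spike times).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _expr, library
from ._expr import Bin, Name, Num, Un, parse_expr, ser
from .equations import (
    Conditional,
    EquationSet,
    Monitor,
    RESERVED_NAMES,
    parse_equations,
    parse_mechanism_file,
)
from .errors import ModelError
from .specification import Specification, standardize

__all__ = ["FlatModel", "PopulationInfo", "qualify", "link", "build"]


@dataclass
class PopulationInfo:
    name: str
    size: int
    voltage_state: str | None  # fully-qualified name of the spiking state
    spike_threshold: float | None  # None -> solver default


@dataclass
class FlatModel:
    """Fully namespaced, linked, single system of equations."""

    parameters: dict = field(default_factory=dict)
    fixed_variables: dict = field(default_factory=dict)
    functions: dict = field(default_factory=dict)  # fq -> (resolved args, body)
    odes: dict = field(default_factory=dict)
    ics: dict = field(default_factory=dict)
    conditionals: list = field(default_factory=list)
    monitors: list = field(default_factory=list)  # Monitor with fq names
    state_layout: dict = field(default_factory=dict)  # fq state -> (pop, size)
    namespace_table: dict = field(default_factory=dict)  # (path, local) -> fq
    populations: list = field(default_factory=list)  # PopulationInfo, spec order
    spike_buffers: dict = field(default_factory=dict)  # pop name -> buffer length
    warnings: list = field(default_factory=list)

    def canonical_text(self) -> str:
        parts = []
        for nm, v in self.parameters.items():
            parts.append(f"{nm}={np.asarray(v).tolist()!r}")
        for nm, e in self.fixed_variables.items():
            parts.append(f"{nm}:={e}")
        for nm, (args, body) in self.functions.items():
            parts.append(f"{nm}({','.join(args)})={body}")
        for st, rhs in self.odes.items():
            parts.append(f"d{st}/dt={rhs};{st}(0)={self.ics.get(st, '0')}")
        for c in self.conditionals:
            acts = ";".join(f"{t}={e}" for t, e in c.actions)
            parts.append(f"if({c.condition})({acts})")
        for p in self.populations:
            parts.append(f"pop:{p.name}[{p.size}]@{p.voltage_state}")
        return "\n".join(parts)

    def hash(self) -> str:
        return hashlib.md5(self.canonical_text().encode()).hexdigest()

    def population(self, name: str) -> PopulationInfo:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population {name!r}")


# ---------------------------------------------------------------------------
# qualify
# ---------------------------------------------------------------------------


def qualify(object_path, local_name, table: dict | None = None) -> str:
    """Join an object path and a local name into a fully-qualified name.

    ``(['pop1','Na'],'m') -> 'pop1_Na_m'``. If a table is supplied, the
    mapping is recorded and a collision (two distinct (path, local) keys
    producing one qualified name) raises ModelError.
    """
    for tok in list(object_path) + [local_name]:
        if not tok or not tok[0].isalpha() and tok[0] != "_":
            raise ModelError(f"invalid identifier {tok!r} in namespace path")
    fq = "_".join(list(object_path) + [local_name])
    if table is not None:
        key = (tuple(object_path), local_name)
        for other_key, other_fq in table.items():
            if other_fq == fq and other_key != key:
                raise ModelError(
                    f"namespace collision: {other_key} and {key} both map to {fq!r}"
                )
        table[key] = fq
    return fq


# ---------------------------------------------------------------------------
# Flattener
# ---------------------------------------------------------------------------


class _Object:
    """One namespaced object: the population master or a mechanism instance."""

    def __init__(self, path, eqs: EquationSet, host: str, size: int,
                 source: str | None = None):
        self.path = list(path)  # e.g. ['E'] or ['E','iNa'] or ['E','I','iGABAa']
        self.eqs = eqs
        self.host = host  # host (target) population name
        self.source = source  # source population name for connection mechanisms
        self.size = size  # size of this object's state arrays
        self.mapping: dict[str, str] = {}


class _Flattener:
    def __init__(self, spec: Specification, mech_paths=(), spike_buffer_len=1):
        self.spec = spec
        self.mech_paths = list(mech_paths)
        self.K = int(spike_buffer_len)
        self.model = FlatModel()
        self.objects: list[_Object] = []
        self.by_pop: dict[str, list[_Object]] = {}
        self.pop_master: dict[str, _Object] = {}
        self.pop_size: dict[str, int] = {}

    # -- mechanism loading -------------------------------------------------
    def load_mechanism(self, name: str) -> EquationSet:
        inline = self.spec.mechanisms or {}
        if name in inline:
            m = inline[name]
            if isinstance(m, EquationSet):
                return m.copy()
            eqs = parse_equations(m, strict=False, name=name)
            if not eqs.linkers and not eqs.odes:
                raise ModelError(f"empty mechanism: {name}")
            return eqs
        path = library.find_mechanism(name, self.mech_paths)
        if path is None:
            raise ModelError(f"mechanism {name!r} not found (searched inline "
                             f"definitions, {self.mech_paths} and the library)")
        return parse_mechanism_file(path)

    # -- main --------------------------------------------------------------
    def run(self) -> FlatModel:
        spec, model = self.spec, self.model

        for pop in spec.populations:
            eqs = pop.equations.copy()
            self.pop_size[pop.name] = pop.size
            master = _Object([pop.name], eqs, pop.name, pop.size)
            self.pop_master[pop.name] = master
            self.by_pop[pop.name] = [master]
            self.objects.append(master)

            unmatched = dict(pop.parameters)
            self._apply_overrides(eqs, unmatched)
            for mname in pop.mechanism_list:
                meqs = self.load_mechanism(mname)
                self._apply_overrides(meqs, unmatched)
                obj = _Object([pop.name, mname], meqs, pop.name, pop.size)
                self.by_pop[pop.name].append(obj)
                self.objects.append(obj)
            if unmatched:
                raise ModelError(
                    f"population {pop.name!r}: parameter override(s) "
                    f"{sorted(unmatched)} match no declared parameter"
                )

        for con in spec.connections:
            nt, ns = self.pop_size[con.target], self.pop_size[con.source]
            unmatched = {k: v for k, v in con.parameters.items() if k != "netcon"}
            for mname in con.mechanism_list:
                meqs = self.load_mechanism(mname)
                self._apply_overrides(meqs, unmatched)
                obj = _Object([con.target, con.source, mname], meqs,
                              con.target, ns, source=con.source)
                obj.netcon = self._netcon_for(con, nt, ns)
                self.by_pop[con.target].append(obj)
                self.objects.append(obj)
            if unmatched:
                raise ModelError(
                    f"connection {con.label!r}: parameter override(s) "
                    f"{sorted(unmatched)} match no declared parameter"
                )

        for obj in self.objects:
            self._build_mapping(obj)
        for obj in self.objects:
            self._rename(obj)
        for pname in self.by_pop:
            self._resolve_linkers(pname)
        self._assemble()
        self._finalize_populations()
        self._resolution_check()
        return model

    # -- overrides ---------------------------------------------------------
    @staticmethod
    def _apply_overrides(eqs: EquationSet, pending: dict) -> None:
        for key in list(pending):
            if key in eqs.parameters:
                v = pending.pop(key)
                eqs.parameters[key] = (
                    list(v) if isinstance(v, (list, tuple, np.ndarray)) else float(v)
                )

    def _netcon_for(self, con, nt, ns):
        val = con.parameters.get("netcon")
        if val is None:
            return np.ones((nt, ns))
        try:
            import scipy.sparse as sp

            if sp.issparse(val):
                val = val.toarray()  # storage hint only; evaluate dense
        except ImportError:  # pragma: no cover
            pass
        arr = np.asarray(val, dtype=float)
        if arr.shape != (nt, ns):
            raise ModelError(
                f"connection {con.label!r}: connectivity matrix has shape "
                f"{arr.shape}, expected (target, source) = {(nt, ns)}"
            )
        return arr

    # -- namespacing -------------------------------------------------------
    def _build_mapping(self, obj: _Object) -> None:
        tbl = self.model.namespace_table
        m = obj.mapping
        for local in obj.eqs.declared_names():
            m[local] = qualify(obj.path, local, tbl)
        is_mech = len(obj.path) > 1
        if not is_mech:
            if self._uses(obj.eqs, "N"):
                m["N"] = self._size_param(obj.host)
            return
        # function formals not declared locally resolve like externals, so a
        # bare reference to the function can be expanded with global names
        formals = {
            a
            for args, _ in obj.eqs.functions.values()
            for a in args
            if a not in obj.eqs.declared_names() and a not in ("t", "dt", "pi")
        }
        for ext in sorted(obj.eqs.externals | self._used_reserved(obj.eqs) | formals):
            if ext == "N":
                m["N"] = self._size_param(obj.source or obj.host)
            elif ext == "N_pre":
                self._require_conn(obj, ext)
                m["N_pre"] = self._size_param(obj.source)
            elif ext == "N_post":
                self._require_conn(obj, ext)
                m["N_post"] = self._size_param(obj.host)
            elif ext == "netcon":
                self._require_conn(obj, ext)
                m["netcon"] = qualify(obj.path, "netcon", tbl)
            elif ext == "tspike_pre":
                self._require_conn(obj, ext)
                m["tspike_pre"] = self._spike_buffer(obj.source)
            elif ext == "tspike_post":
                m["tspike_post"] = self._spike_buffer(obj.host)
            elif ext.endswith("_pre") and obj.source is not None:
                base = self._resolve_in_pop(obj.source, ext[: -len("_pre")], obj, ext)
                m[ext] = qualify([obj.source], base)
            elif ext.endswith("_post") and obj.source is not None:
                base = self._resolve_in_pop(obj.host, ext[: -len("_post")], obj, ext)
                m[ext] = qualify([obj.host], base)
            else:
                base = self._resolve_in_pop(obj.host, ext, obj, ext, required=False)
                if base is not None:
                    m[ext] = qualify([obj.host], base)
                # else: left untouched; the final resolution check reports it

    def _resolve_in_pop(self, pop: str, base: str, obj, ext: str,
                        required: bool = True) -> str | None:
        """Resolve a mechanism external against a population's symbols.

        Exact name first; the conventional voltage aliases 'v'/'V'/'X' fall
        back to the population's principal (first-declared) state variable,
        so library mechanisms written with lowercase ``v`` attach to hosts
        that call their voltage ``V`` (and vice versa).
        """
        master = self.pop_master[pop]
        declared = master.eqs.declared_names()
        if base in declared:
            return base
        if base in ("v", "V", "X"):
            swapped = base.swapcase()
            if swapped in declared:
                return swapped
            first = next(iter(master.eqs.odes), None)
            if first is not None:
                return first
        if required:
            raise ModelError(
                f"{'_'.join(obj.path)}: {ext!r} refers to {base!r}, which "
                f"population {pop!r} does not declare"
            )
        return None

    def _uses(self, eqs: EquationSet, name: str) -> bool:
        return any(
            name in _expr.free_names(parse_expr(e)) for e in _iter_exprs(eqs)
        )

    @staticmethod
    def _used_reserved(eqs: EquationSet) -> set:
        used = set()
        for e in _iter_exprs(eqs):
            used |= _expr.free_names(parse_expr(e)) & RESERVED_NAMES
        return used

    def _require_conn(self, obj, ext):
        if obj.source is None:
            raise ModelError(
                f"{'_'.join(obj.path)}: reserved name {ext!r} is only available "
                "inside connection mechanisms"
            )

    def _size_param(self, pop: str) -> str:
        fq = f"{pop}_N"
        self.model.parameters.setdefault(fq, float(self.pop_size[pop]))
        return fq

    def _spike_buffer(self, pop: str) -> str:
        self.model.spike_buffers[pop] = max(self.model.spike_buffers.get(pop, 1),
                                            self.K)
        return f"_tspike_{pop}"

    def _rename(self, obj: _Object) -> None:
        e = obj.eqs
        m = obj.mapping

        def rn(expr_text, exclude=()):
            mm = {k: v for k, v in m.items() if k not in exclude}
            return ser(_expr.rename(parse_expr(expr_text), mm))

        e.parameters = {m[k]: v for k, v in e.parameters.items()}
        e.fixed_variables = {m[k]: rn(v) for k, v in e.fixed_variables.items()}
        e.functions = {
            m[k]: (tuple(m.get(a, a) for a in args), rn(body))
            for k, (args, body) in e.functions.items()
        }
        e.odes = {m[k]: rn(v) for k, v in e.odes.items()}
        e.ics = {m[k]: rn(v) for k, v in e.ics.items()}
        e.conditionals = [
            Conditional(rn(c.condition), [(m.get(t, t), rn(a)) for t, a in c.actions])
            for c in e.conditionals
        ]
        e.monitors = [
            Monitor(m.get(mon.name, mon.name), mon.kind, mon.threshold)
            for mon in e.monitors
        ]
        e.linkers = [
            type(lk)(lk.linker_name, lk.operator, m.get(lk.payload, lk.payload))
            for lk in e.linkers
        ]
        if getattr(obj, "netcon", None) is not None and "netcon" in m:
            e.parameters[m["netcon"]] = obj.netcon

    # -- linker substitution -------------------------------------------------
    def _resolve_linkers(self, pop: str) -> None:
        objs = self.by_pop[pop]
        contributions: dict[str, list] = {}
        for obj in objs:
            for lk in obj.eqs.linkers:
                contributions.setdefault(lk.linker_name, []).append(
                    (lk.operator, lk.payload)
                )

        used: set[str] = set()
        for obj in objs:
            for e in _iter_exprs(obj.eqs):
                used |= _expr.linker_names(parse_expr(e))

        mapping: dict[str, object] = {}
        for name in used:
            mapping[name] = self._combine(name, contributions.get(name, []))
        for name, contribs in contributions.items():
            if name not in used:
                self.model.warnings.append(
                    f"population {pop!r}: linker {name!r} has contributions "
                    f"({len(contribs)}) but appears in no host equation"
                )

        for obj in objs:
            e = obj.eqs

            def sub(expr_text):
                return ser(_expr.replace_linkers(parse_expr(expr_text), mapping))

            e.fixed_variables = {k: sub(v) for k, v in e.fixed_variables.items()}
            e.functions = {k: (args, sub(b)) for k, (args, b) in e.functions.items()}
            e.odes = {k: sub(v) for k, v in e.odes.items()}
            e.ics = {k: sub(v) for k, v in e.ics.items()}
            e.conditionals = [
                Conditional(sub(c.condition), [(t, sub(a)) for t, a in c.actions])
                for c in e.conditionals
            ]
            e.linkers = []

    @staticmethod
    def _combine(linker: str, contribs: list):
        if not contribs:
            return Num("0")  # additive identity: placeholder with no terms
        node = None
        eq_seen = False
        for op, payload in contribs:
            p = Name(payload)
            if op == "=":
                if eq_seen:
                    raise ModelError(
                        f"linker {linker!r}: '=' used by two contributions "
                        "(ambiguous overwrite)"
                    )
                eq_seen = True
                node = p
            elif op == "+=":
                node = p if node is None else Bin("+", node, p)
            elif op == "-=":
                node = Un("-", p) if node is None else Bin("-", node, p)
            elif op == "*=":
                node = p if node is None else Bin("*", node, p)
        return node

    # -- assembly ------------------------------------------------------------
    def _assemble(self) -> None:
        md = self.model
        for obj in self.objects:
            e = obj.eqs
            for k, v in e.parameters.items():
                if isinstance(v, (list, tuple)):
                    arr = np.asarray(v, dtype=float)
                    if arr.ndim == 1 and obj.source is None and len(arr) != obj.size:
                        raise ModelError(
                            f"parameter {k!r}: array length {len(arr)} does not "
                            f"match population size {obj.size}"
                        )
                    md.parameters[k] = arr
                else:
                    md.parameters[k] = float(v) if not isinstance(v, np.ndarray) else v
            md.fixed_variables.update(e.fixed_variables)
            md.functions.update(e.functions)
            for st, rhs in e.odes.items():
                md.odes[st] = rhs
                md.state_layout[st] = (
                    obj.source if obj.source is not None else obj.host,
                    obj.size,
                )
            md.ics.update(e.ics)
            md.conditionals.extend(e.conditionals)
            md.monitors.extend(e.monitors)
        for st in md.odes:
            md.ics.setdefault(st, "0")

    def _finalize_populations(self) -> None:
        md = self.model
        for pop in self.spec.populations:
            master = self.pop_master[pop.name]
            vstate = next(iter(master.eqs.odes), None)
            thr = None
            for mon in master.eqs.monitors:
                if mon.kind == "spikes":
                    vstate = mon.name
                    thr = mon.threshold
            md.populations.append(
                PopulationInfo(pop.name, pop.size, vstate, thr)
            )

    # -- final checks ----------------------------------------------------------
    def _resolution_check(self) -> None:
        md = self.model
        known = (
            set(md.parameters)
            | set(md.fixed_variables)
            | set(md.functions)
            | set(md.odes)
            | {f"_tspike_{p}" for p in md.spike_buffers}
        )
        fn_arity = {k: len(args) for k, (args, _) in md.functions.items()}

        def check(expr_text, local=(), where=""):
            node = parse_expr(expr_text)
            if _expr.linker_names(node):
                raise ModelError(
                    f"unresolved linker {sorted(_expr.linker_names(node))} "
                    f"in {where}: {expr_text!r}"
                )
            free = _expr.free_names(node) - set(local)
            missing = free - known
            if missing:
                raise ModelError(
                    f"unresolved identifier {sorted(missing)[0]!r} in {where}: "
                    f"{expr_text!r}"
                )

        for k, v in md.fixed_variables.items():
            check(v, where=f"fixed variable {k}")
        for k, (args, body) in md.functions.items():
            check(body, local=args, where=f"function {k}")
        for st, rhs in md.odes.items():
            check(rhs, where=f"d{st}/dt")
            check(md.ics[st], where=f"{st}(0)")
        for c in md.conditionals:
            check(c.condition, where="conditional")
            for t, a in c.actions:
                if t not in md.odes and t not in md.parameters:
                    raise ModelError(
                        f"conditional action target {t!r} is not a state or "
                        "parameter of the flattened model"
                    )
                check(a, where="conditional action")


def _iter_exprs(eqs: EquationSet):
    yield from eqs.fixed_variables.values()
    for args, body in eqs.functions.values():
        yield body
    yield from eqs.odes.values()
    yield from eqs.ics.values()
    for c in eqs.conditionals:
        yield c.condition
        for _, a in c.actions:
            yield a


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def build(spec_input, mech_paths=(), spike_buffer_len: int = 1) -> FlatModel:
    """Flatten a specification (any accepted form) into a FlatModel."""
    spec = standardize(spec_input)
    return _Flattener(spec, mech_paths, spike_buffer_len).run()


def link(population_eqns, mechanism_sets, population_name: str = "pop1") -> EquationSet:
    """Merge a population's equations with its mechanisms' (namespaced,
    linker-substituted) and return the combined EquationSet.

    ``mechanism_sets`` is an ordered list of (name, EquationSet-or-text)
    pairs; order determines term order in combined linker expressions.
    """
    from .specification import PopulationSpec

    if isinstance(population_eqns, (str, list, tuple)):
        population_eqns = parse_equations(population_eqns, strict=False)
    names = [n for n, _ in mechanism_sets]
    spec = Specification(
        populations=[
            PopulationSpec(name=population_name, equations=population_eqns.copy(),
                           mechanism_list=names)
        ],
        mechanisms={n: m for n, m in mechanism_sets},
    )
    flat = build(spec)
    return EquationSet(
        parameters=dict(flat.parameters),
        fixed_variables=dict(flat.fixed_variables),
        functions=dict(flat.functions),
        odes=dict(flat.odes),
        ics=dict(flat.ics),
        conditionals=list(flat.conditionals),
        linkers=[],
        monitors=list(flat.monitors),
        name=population_name,
    )
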