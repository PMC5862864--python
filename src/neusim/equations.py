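"""Statement layer of the equation dialect.

A model object (a population or a mechanism) is described by a short program
in a line-oriented dialect::

    gna=120; Ena=50                      % parameters (numeric literals)
    am(v)=.1*(v+40)/(1-exp(-(v+40)/10))  % functions
    INa(v,m,h)=-gna*m^3*h*(v-Ena)        % functions may call functions
    dm/dt=am(v)*(1-m)-bm(v)*m            % ODEs ...
    m(0)=0.05                            % ... with initial conditions
    if(v>vpeak)(v=c; u=u+d)              % conditional updates
    @current += INa                      % linker statement (mechanisms)
    monitor INa                          % record a function during simulation
    monitor v.spikes(0)                  % record upward threshold crossings

Statements are delimited by ';' or newlines; '%' and '#' start comments.
``parse_equations`` turns such text into an :class:`EquationSet`;
``serialize`` is its inverse (round-trip identity, field by field).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from . import _expr
from ._expr import BUILTIN_FUNCTIONS, DSLSyntaxError, parse_expr, ser
from .errors import ModelError

__all__ = [
    "Conditional",
    "LinkerStatement",
    "Monitor",
    "EquationSet",
    "parse_equations",
    "parse_mechanism_file",
    "validate_expression",
    "serialize",
]

#: names that mechanisms and population equations may reference without
#: declaring; bound by the model builder / solver at build time.
RESERVED_NAMES = frozenset(
    {"N", "N_pre", "N_post", "netcon", "tspike_pre", "tspike_post"}
)


@dataclass
class Conditional:
    """``if(condition)(action; action; ...)`` — evaluated elementwise after
    each state update; actions execute left-to-right where the condition
    holds and each sees the effect of earlier ones."""

    condition: str
    actions: list[tuple[str, str]]  # (target name, expression)


@dataclass(frozen=True)
class LinkerStatement:
    """``@linker op payload`` inside a mechanism; payload names a local
    function or fixed variable to be inserted into host equations."""

    linker_name: str  # includes '@'
    operator: str  # one of += -= *= =
    payload: str


@dataclass(frozen=True)
class Monitor:
    """``monitor NAME`` (record a function/variable) or
    ``monitor NAME.spikes(THRESH)`` (record upward crossings of a state)."""

    name: str
    kind: str = "value"  # 'value' | 'spikes'
    threshold: float | None = None


@dataclass
class EquationSet:
    """Parsed content of one model object's equations."""

    parameters: dict = field(default_factory=dict)  # name -> float | list[float]
    fixed_variables: dict = field(default_factory=dict)  # name -> expr string
    functions: dict = field(default_factory=dict)  # name -> (args tuple, expr)
    odes: dict = field(default_factory=dict)  # state -> rhs expr
    ics: dict = field(default_factory=dict)  # state -> expr
    conditionals: list = field(default_factory=list)
    linkers: list = field(default_factory=list)
    monitors: list = field(default_factory=list)
    externals: set = field(default_factory=set)  # free names (lenient mode only)
    mechanism_list: list = field(default_factory=list)  # 'mechanisms a,b' directive
    name: str | None = None

    # -- helpers -----------------------------------------------------------
    def declared_names(self) -> set[str]:
        return (
            set(self.parameters)
            | set(self.fixed_variables)
            | set(self.functions)
            | set(self.odes)
        )

    def copy(self) -> "EquationSet":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Text pre-processing
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"[%#][^\n]*")


def _strip_comments(text: str) -> str:
    return _COMMENT_RE.sub("", text)


def _split_statements(text: str):
    """Split on ';' and newlines outside parentheses/brackets.

    Yields (statement, line_number) pairs.
    """
    stmts = []
    buf = []
    depth = 0
    line = 1
    start_line = 1
    for ch in text:
        if ch == "\n":
            line += 1
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        if depth == 0 and (ch == ";" or ch == "\n"):
            s = "".join(buf).strip()
            if s:
                stmts.append((s, start_line))
            buf = []
            start_line = line
            continue
        buf.append(ch)
    s = "".join(buf).strip()
    if s:
        stmts.append((s, start_line))
    return stmts


# ---------------------------------------------------------------------------
# Statement patterns
# ---------------------------------------------------------------------------

_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_ODE_RE = re.compile(rf"^d\(?({_IDENT})\)?/dt\s*=\s*(.+)$", re.S)
_ODE_PRIME_RE = re.compile(rf"^({_IDENT})'\s*=\s*(.+)$", re.S)
_IC_RE = re.compile(rf"^({_IDENT})\(\s*0\s*\)\s*=\s*(.+)$", re.S)
_FUNC_RE = re.compile(rf"^({_IDENT})\(\s*({_IDENT}(?:\s*,\s*{_IDENT})*)\s*\)\s*=\s*(.+)$", re.S)
_ASSIGN_RE = re.compile(rf"^({_IDENT})\s*=\s*(.+)$", re.S)
_LINKER_RE = re.compile(rf"^(@{_IDENT})\s*(\+=|-=|\*=|=)\s*({_IDENT})\s*$")
_LINKER_ANY_RE = re.compile(rf"^(@{_IDENT})\s*(\+=|-=|\*=|=)\s*(.+)$", re.S)
_MONITOR_RE = re.compile(rf"^monitor\s+({_IDENT})(?:\.spikes\(\s*([^)]*)\s*\))?\s*$")
_COND_RE = re.compile(r"^if\s*\((.*)$", re.S)
_ARRAY_RE = re.compile(r"^\[(.*)\]$", re.S)


def _match_paren(text: str, start: int) -> int:
    """Index of the ')' matching the '(' at ``start``."""
    depth = 0
    for i in range(start, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return i
    raise DSLSyntaxError("unbalanced parentheses", text=text)


def _canon(expr_text: str, line: int | None = None) -> str:
    """Parse and re-serialize an expression (canonical dialect form)."""
    try:
        return ser(parse_expr(expr_text))
    except DSLSyntaxError as e:
        raise DSLSyntaxError(str(e), line=line, text=expr_text) from None


# ---------------------------------------------------------------------------
# Main parser
# ---------------------------------------------------------------------------


def parse_equations(
    text,
    *,
    strict: bool = True,
    extra_scope=frozenset(),
    name: str | None = None,
) -> EquationSet:
    """Parse equation text (one string or a list of strings).

    With ``strict=True`` (the default, for self-contained models) every
    identifier must be declared; with ``strict=False`` (mechanism files)
    unresolved names are collected in ``EquationSet.externals`` and resolved
    later against the host population by the model builder.
    """
    if isinstance(text, (list, tuple)):
        text = "\n".join(text)
    if not isinstance(text, str):
        raise TypeError("equations must be a string or a list of strings")
    body = _strip_comments(text)
    stmts = _split_statements(body)
    if not stmts:
        raise DSLSyntaxError("no statements found (text empty after comments)")

    eqs = EquationSet(name=name)

    def _declare(nm, category, line):
        for cat, store in (
            ("parameter", eqs.parameters),
            ("fixed variable", eqs.fixed_variables),
            ("function", eqs.functions),
            ("state", eqs.odes),
        ):
            if nm in store:
                if cat == "parameter" and category == "state":
                    raise DSLSyntaxError(
                        f"state {nm!r} collides with a parameter of the same name",
                        line=line,
                    )
                raise DSLSyntaxError(
                    f"{nm!r} redeclared as {category} (already a {cat})", line=line
                )

    for stmt, line in stmts:
        # conditionals -----------------------------------------------------
        if _COND_RE.match(stmt):
            op = stmt.index("(")
            close = _match_paren(stmt, op)
            cond = stmt[op + 1 : close]
            rest = stmt[close + 1 :].strip()
            if not rest.startswith("("):
                raise DSLSyntaxError(
                    "conditional must have the form if(condition)(actions)", line=line
                )
            aclose = _match_paren(rest, 0)
            if rest[aclose + 1 :].strip():
                raise DSLSyntaxError("trailing text after conditional", line=line)
            actions = []
            for a in rest[1:aclose].split(";"):
                a = a.strip()
                if not a:
                    continue
                m = _ASSIGN_RE.match(a)
                if not m:
                    raise DSLSyntaxError(
                        f"conditional action must be an assignment: {a!r}", line=line
                    )
                actions.append((m.group(1), _canon(m.group(2), line)))
            if not actions:
                raise DSLSyntaxError("conditional with no actions", line=line)
            eqs.conditionals.append(Conditional(_canon(cond, line), actions))
            continue

        # monitor directives ----------------------------------------------
        if re.match(r"monitor\s", stmt):
            m = _MONITOR_RE.match(stmt)
            if not m:
                raise DSLSyntaxError(f"malformed monitor directive: {stmt!r}", line=line)
            if m.group(2) is not None:
                try:
                    thr = float(m.group(2))
                except ValueError:
                    raise DSLSyntaxError(
                        "spike monitor threshold must be a number", line=line
                    ) from None
                eqs.monitors.append(Monitor(m.group(1), "spikes", thr))
            else:
                eqs.monitors.append(Monitor(m.group(1), "value"))
            continue

        # mechanism-list directive (population files) ----------------------
        if re.match(r"mechanisms[\s:]", stmt):
            rest = stmt[len("mechanisms"):].lstrip(": \t")
            names = [n.strip() for n in rest.split(",") if n.strip()]
            if not names or not all(re.fullmatch(_IDENT, n) for n in names):
                raise DSLSyntaxError(
                    f"malformed mechanisms directive: {stmt!r}", line=line
                )
            eqs.mechanism_list.extend(names)
            continue

        # linker statements -------------------------------------------------
        if stmt.startswith("@"):
            m = _LINKER_RE.match(stmt)
            if not m:
                if _LINKER_ANY_RE.match(stmt):
                    raise DSLSyntaxError(
                        "linker payload must be a single identifier naming a local "
                        f"function or fixed variable: {stmt!r}",
                        line=line,
                    )
                raise DSLSyntaxError(f"malformed linker statement: {stmt!r}", line=line)
            eqs.linkers.append(LinkerStatement(m.group(1), m.group(2), m.group(3)))
            continue

        # ODEs ---------------------------------------------------------------
        m = _ODE_RE.match(stmt) or _ODE_PRIME_RE.match(stmt)
        if m:
            state, rhs = m.group(1), m.group(2)
            _declare(state, "state", line)
            eqs.odes[state] = _canon(rhs, line)
            continue

        # ICs ----------------------------------------------------------------
        m = _IC_RE.match(stmt)
        if m:
            eqs.ics[m.group(1)] = _canon(m.group(2), line)
            continue

        # functions ----------------------------------------------------------
        m = _FUNC_RE.match(stmt)
        if m:
            fname = m.group(1)
            args = tuple(a.strip() for a in m.group(2).split(","))
            _declare(fname, "function", line)
            eqs.functions[fname] = (args, _canon(m.group(3), line))
            continue

        # plain assignments: parameter (numeric) or fixed variable ----------
        m = _ASSIGN_RE.match(stmt)
        if m:
            nm, rhs = m.group(1), m.group(2).strip()
            _declare(nm, "parameter", line)
            arr = _ARRAY_RE.match(rhs)
            if arr:
                try:
                    vals = [float(v) for v in arr.group(1).split(",") if v.strip()]
                except ValueError:
                    raise DSLSyntaxError(
                        f"array parameter {nm!r} must contain numbers only", line=line
                    ) from None
                eqs.parameters[nm] = vals
                continue
            node = None
            try:
                node = parse_expr(rhs)
            except DSLSyntaxError as e:
                raise DSLSyntaxError(str(e), line=line, text=stmt) from None
            if _expr.is_numeric_literal(node):
                eqs.parameters[nm] = _expr.literal_value(node)
            else:
                eqs.fixed_variables[nm] = ser(node)
            continue

        raise DSLSyntaxError(f"cannot parse statement: {stmt!r}", line=line)

    _validate_set(eqs, strict=strict, extra_scope=set(extra_scope))
    return eqs


def _validate_set(eqs: EquationSet, *, strict: bool, extra_scope: set) -> None:
    scope = eqs.declared_names() | extra_scope | {"N"}
    known_fns = {f: len(args) for f, (args, _) in eqs.functions.items()}
    lenient_extra = set(RESERVED_NAMES)

    for state in eqs.ics:
        if state not in eqs.odes:
            raise DSLSyntaxError(
                f"initial condition for {state!r} but no ODE d{state}/dt"
            )

    def _check(expr_text, local=()):
        node = parse_expr(expr_text)
        names = _expr.free_names(node) - set(local)
        unknown = names - scope - known_fns.keys()
        if strict:
            if unknown:
                missing = sorted(unknown)[0]
                raise _expr.UnknownIdentifierError(
                    f"unknown identifier {missing!r}", text=expr_text
                )
        else:
            eqs.externals |= {u for u in unknown if u not in lenient_extra}
        # arity checks; external function calls (lenient mode) adopt the
        # arity observed at the call site
        ext_fns = {
            n.fn: len(n.args)
            for n in _expr.iter_nodes(node)
            if isinstance(n, _expr.Call)
            and n.fn not in BUILTIN_FUNCTIONS
            and n.fn not in known_fns
            and n.fn not in scope
            and n.fn not in local
        }
        _expr.check_scope(
            node,
            (scope | set(local) | names) - ext_fns.keys(),  # names vetted above
            {**known_fns, **ext_fns},
            text=expr_text,
        )

    for nm, expr_text in eqs.fixed_variables.items():
        _check(expr_text)
    for fname, (args, body) in eqs.functions.items():
        _check(body, local=args)
    for state, rhs in eqs.odes.items():
        _check(rhs)
    for state, ic in eqs.ics.items():
        _check(ic)
    for cond in eqs.conditionals:
        _check(cond.condition)
        for target, action in cond.actions:
            if strict and target not in eqs.odes and target not in eqs.parameters:
                raise DSLSyntaxError(
                    f"conditional action target {target!r} is not a declared "
                    "state or parameter"
                )
            _check(action)
    for lk in eqs.linkers:
        if lk.payload not in eqs.functions and lk.payload not in eqs.fixed_variables:
            raise DSLSyntaxError(
                f"linker payload {lk.payload!r} does not name a local function "
                "or fixed variable"
            )
    for mon in eqs.monitors:
        if mon.kind == "spikes":
            if mon.name not in eqs.odes and strict:
                raise DSLSyntaxError(
                    f"spike monitor target {mon.name!r} is not a state"
                )
        elif (
            strict
            and mon.name not in eqs.functions
            and mon.name not in eqs.fixed_variables
            and mon.name not in eqs.odes
        ):
            raise DSLSyntaxError(f"monitor target {mon.name!r} is not declared")


# ---------------------------------------------------------------------------
# Mechanism files
# ---------------------------------------------------------------------------


def parse_mechanism_file(path, search_paths=()) -> EquationSet:
    """Parse a ``.mech`` file; the mechanism name is the filename stem.

    Mechanism equations may reference host-population symbols (e.g., the
    postsynaptic voltage ``v`` or the reserved ``netcon``/``V_pre`` names);
    those are collected in ``externals`` and resolved during model building.
    """
    p = Path(path)
    if not p.exists():
        for d in search_paths:
            cand = Path(d) / p.name
            if cand.exists():
                p = cand
                break
        else:
            raise FileNotFoundError(f"mechanism file not found: {path}")
    text = p.read_text()
    if not _split_statements(_strip_comments(text)):
        raise ModelError(f"empty mechanism: {p.name}")
    eqs = parse_equations(text, strict=False, name=p.stem)
    if not eqs.linkers and not eqs.odes:
        raise ModelError(f"empty mechanism: {p.name} (no linkers and no ODEs)")
    return eqs


# ---------------------------------------------------------------------------
# validate_expression and serialization
# ---------------------------------------------------------------------------


def validate_expression(expr: str, scope) -> str:
    """Validate one expression against a scope of declared names.

    Returns the normalized form used by the evaluation backend (whitespace
    normalized, ``^`` mapped to ``**``). Raises on unknown identifiers,
    unbalanced parentheses, or call-arity mismatches.
    """
    node = parse_expr(expr)
    _expr.check_scope(node, set(scope), {}, text=expr)
    return _expr.to_python(node)


def _fmt_value(v) -> str:
    if isinstance(v, (list, tuple)):
        return "[" + ",".join(_fmt_value(x) for x in v) + "]"
    return repr(float(v))


def serialize(eqs: EquationSet) -> str:
    """Render an EquationSet back to dialect text (parse round-trip identity)."""
    lines = []
    if eqs.mechanism_list:
        lines.append("mechanisms " + ",".join(eqs.mechanism_list))
    for nm, v in eqs.parameters.items():
        lines.append(f"{nm}={_fmt_value(v)}")
    for nm, expr_text in eqs.fixed_variables.items():
        lines.append(f"{nm}={expr_text}")
    for fname, (args, body) in eqs.functions.items():
        lines.append(f"{fname}({','.join(args)})={body}")
    for state, rhs in eqs.odes.items():
        lines.append(f"d{state}/dt={rhs}")
        if state in eqs.ics:
            lines.append(f"{state}(0)={eqs.ics[state]}")
    for cond in eqs.conditionals:
        acts = "; ".join(f"{t}={e}" for t, e in cond.actions)
        lines.append(f"if({cond.condition})({acts})")
    for lk in eqs.linkers:
        lines.append(f"{lk.linker_name} {lk.operator} {lk.payload}")
    for mon in eqs.monitors:
        if mon.kind == "spikes":
            thr = mon.threshold
            thr_s = repr(float(thr)) if thr is not None else "0"
            lines.append(f"monitor {mon.name}.spikes({thr_s})")
        else:
            lines.append(f"monitor {mon.name}")
    return "\n".join(lines)
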