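"""Generation of standalone solver source from a FlatModel.

Fixed-step integration works by emitting a complete, human-readable Python
program (the *solve file*) that imports only numpy, and executing it. The
same text is returned by ``render_solver_source`` for inspection and re-use;
``integrate`` executes it in memory, so the emitted program and the in-memory
simulation are one and the same computation.

Code-generation choices:

* model functions are inlined (macro expansion), so Runge-Kutta stage states
  substitute cleanly and a bare reference to a function name expands to a
  call with its resolved formal arguments;
* random builtins (``rand``/``randn``) are hoisted out of expressions and
  drawn once per time step from a single seeded generator; multi-stage
  methods reuse the same draw in every stage so noise variance does not
  depend on the number of stages;
* a 2-D parameter (a connectivity matrix) on the left of ``*`` multiplies by
  matrix product, so ``netcon*s`` is the synaptic drive summed over sources;
* conditionals run after each state update, in declaration order; actions
  execute left-to-right under the mask captured when the condition was
  evaluated, and spike detection / recording happen afterwards.
"""

from __future__ import annotations

import io

import numpy as np

from . import _expr
from ._expr import Bin, Call, Name, parse_expr
from .errors import ModelError, SolverError

__all__ = ["render_solver_source", "render_adaptive_module"]

FIXED_STEP_METHODS = ("euler", "rk2", "rk4")

_HELPERS = '''
def _step(x):
    return (x > 0) * 1.0


def _rowsum(m):
    return np.sum(m, axis=1)
'''

_RAND_HELPERS = '''
    def _shape(s):
        s = tuple(int(v) for v in s)
        if len(s) == 2 and s[0] == 1:
            s = (s[1],)
        return s

    def _rand(*s):
        return rng.uniform(size=_shape(s))

    def _randn(*s):
        return rng.standard_normal(size=_shape(s))
'''


class _Ctx:
    """Shared expression-rendering context for one generated module."""

    def __init__(self, model):
        self.model = model
        self.matmul = {
            k for k, v in model.parameters.items()
            if isinstance(v, np.ndarray) and v.ndim == 2
        }
        self.hoisted: dict[str, str] = {}  # serialized call -> variable name
        self.hoist_order: list[tuple[str, str]] = []  # (var, python source)

    # -- function inlining -------------------------------------------------
    def inline(self, node, depth=0):
        if depth > 64:
            raise ModelError("function inlining exceeded depth 64 (recursive "
                             "function definitions are not supported)")
        fns = self.model.functions
        if isinstance(node, Name):
            if node.id in fns:
                args, _ = fns[node.id]
                return self.inline(Call(node.id, tuple(Name(a) for a in args)),
                                   depth + 1)
            return node
        if isinstance(node, Call):
            args = tuple(self.inline(a, depth) for a in node.args)
            if node.fn in fns:
                formals, body = fns[node.fn]
                if len(args) != len(formals):
                    raise ModelError(
                        f"{node.fn}() takes {len(formals)} arguments, "
                        f"got {len(args)}"
                    )
                tree = parse_expr(body)
                tree = _expr.substitute(tree, dict(zip(formals, args)))
                return self.inline(tree, depth + 1)
            return Call(node.fn, args)
        if isinstance(node, _expr.Un):
            return _expr.Un(node.op, self.inline(node.operand, depth))
        if isinstance(node, Bin):
            return Bin(node.op, self.inline(node.left, depth),
                       self.inline(node.right, depth))
        return node

    # -- random hoisting ---------------------------------------------------
    def hoist(self, node):
        if isinstance(node, Call) and node.fn in ("rand", "randn"):
            key = _expr.ser(node)
            if key not in self.hoisted:
                var = f"_rnd{len(self.hoisted)}"
                self.hoisted[key] = var
                src = self.render_node(node, {}, hoist=False)
                self.hoist_order.append((var, src))
            return Name(self.hoisted[key])
        if isinstance(node, Call):
            return Call(node.fn, tuple(self.hoist(a) for a in node.args))
        if isinstance(node, _expr.Un):
            return _expr.Un(node.op, self.hoist(node.operand))
        if isinstance(node, Bin):
            return Bin(node.op, self.hoist(node.left), self.hoist(node.right))
        return node

    # -- rendering ---------------------------------------------------------
    def render_node(self, node, name_map: dict, hoist=True):
        node = self.inline(node)
        if hoist:
            node = self.hoist(node)
        return _to_python_matmul(node, name_map, self.matmul)

    def render(self, expr_text: str, name_map: dict | None = None, hoist=True):
        return self.render_node(parse_expr(expr_text), name_map or {}, hoist)


def _to_python_matmul(node, name_map, matmul_names):
    nm = lambda s: name_map.get(s, s)  # noqa: E731
    if isinstance(node, Bin) and node.op == "*":
        left = node.left
        if isinstance(left, Name) and left.id in matmul_names:
            return (
                f"({_to_python_matmul(left, name_map, matmul_names)} @ "
                f"{_to_python_matmul(node.right, name_map, matmul_names)})"
            )
    if isinstance(node, Bin):
        op = "**" if node.op == "^" else node.op
        return (
            f"({_to_python_matmul(node.left, name_map, matmul_names)} {op} "
            f"{_to_python_matmul(node.right, name_map, matmul_names)})"
        )
    if isinstance(node, _expr.Un):
        op = {"-": "-", "+": "+", "!": "~"}[node.op]
        return f"({op}{_to_python_matmul(node.operand, name_map, matmul_names)})"
    if isinstance(node, Call):
        fn = (_expr._NUMPY_FN.get(node.fn)
              if node.fn in _expr.BUILTIN_FUNCTIONS else nm(node.fn))
        args = ", ".join(_to_python_matmul(a, name_map, matmul_names)
                         for a in node.args)
        return f"{fn}({args})"
    return _expr.to_python(node, nm)


def _fmt_param(value) -> str:
    if isinstance(value, np.ndarray):
        if value.ndim == 2 and np.all(value == 1.0):
            return f"np.ones({value.shape})"
        if value.ndim == 2 and not np.any(value):
            return f"np.zeros({value.shape})"
        return f"np.asarray({value.tolist()!r}, dtype=float)"
    return repr(float(value))


# ---------------------------------------------------------------------------
# fixed-step solve file
# ---------------------------------------------------------------------------


def render_solver_source(model, opts) -> str:
    """Emit a standalone fixed-step solver program for ``model``.

    The program defines ``solve(seed)`` returning a dict with keys ``time``,
    ``states``, ``monitors``, ``spikes``; run as a script it saves the
    results beside it. Only numpy is imported. Raises for non-fixed-step
    methods.
    """
    method = getattr(opts, "method", "rk4")
    if method not in FIXED_STEP_METHODS:
        raise ModelError(
            f"source emission requires a fixed-step method {FIXED_STEP_METHODS}, "
            f"got {method!r}"
        )
    return _render(model, opts, method)


def _render(model, opts, method) -> str:
    ctx = _Ctx(model)
    dt = float(opts.dt)
    t0, t1 = float(opts.tspan[0]), float(opts.tspan[1])
    n_steps = int(round((t1 - t0) / dt))
    rec = int(opts.downsample_factor)
    states = list(model.odes)
    sizes = {s: model.state_layout[s][1] for s in states}
    value_monitors = [m for m in model.monitors
                      if m.kind == "value" and m.name not in model.odes]
    # deduplicate monitors by name, preserve order
    seen = set()
    value_monitors = [m for m in value_monitors
                      if not (m.name in seen or seen.add(m.name))]

    pops = [p for p in model.populations if p.voltage_state is not None]
    default_thr = float(getattr(opts, "threshold", 0.0))

    w = io.StringIO()
    p = lambda s="": print(s, file=w)  # noqa: E731

    p('"""Auto-generated standalone solver.')
    p("")
    p(f"model hash : {model.hash()}")
    p(f"method     : {method}")
    p(f"dt         : {dt} ms")
    p(f"tspan      : ({t0}, {t1}) ms")
    p(f"downsample : {rec}")
    p('"""')
    p("import numpy as np")
    p()
    p(_HELPERS)
    p()
    p(f"def solve(seed={int(opts.seed)}):")
    p(f"    rng = np.random.default_rng(int(seed) % 2**31)")
    p(_RAND_HELPERS)
    p(f"    dt = {dt!r}")
    p(f"    t0 = {t0!r}")
    p(f"    n_steps = {n_steps}")
    p(f"    rec = {rec}")
    p()
    p("    # ---- parameters")
    for name, value in model.parameters.items():
        p(f"    {name} = {_fmt_param(value)}")
    p()
    if model.fixed_variables:
        p("    # ---- fixed variables (evaluated once, in declaration order)")
        for name, expr_text in model.fixed_variables.items():
            p(f"    {name} = {ctx.render(expr_text, hoist=False)}")
        p()
    p("    # ---- initial conditions")
    p("    t = t0")
    for s in states:
        n = sizes[s]
        p(f"    {s} = np.empty({n}); {s}[:] = {ctx.render(model.ics[s], hoist=False)}")
    for pop, K in model.spike_buffers.items():
        size = model.population(pop).size
        shape = f"{size}" if K == 1 else f"({K}, {size})"
        p(f"    _tspike_{pop} = np.full({shape}, -1e32)")
    p()
    p("    # ---- recording buffers")
    p("    n_rec = n_steps // rec + 1")
    for s in states:
        p(f"    _out_{s} = np.empty((n_rec, {sizes[s]})); _out_{s}[0] = {s}")

    # monitors need hoisted randoms available at step 0; collect rendering
    mon_exprs = {}
    for m in value_monitors:
        if m.name in model.fixed_variables:
            mon_exprs[m.name] = m.name
        else:
            mon_exprs[m.name] = ctx.render(m.name)  # function/auto-call, hoists
    for pop in pops:
        p(f"    _spk_{pop.name} = [[] for _ in range({pop.size})]")
        p(f"    _prev_{pop.voltage_state} = {pop.voltage_state}.copy()")

    # pre-render all step bodies (fills ctx.hoist_order)
    stage_src = _stage_code(ctx, model, states, method)
    cond_src = _conditional_code(ctx, model)
    mon_init = []
    mon_rec = []
    for m in value_monitors:
        nmon = sizes.get(m.name)  # unknown -> infer at runtime
        mon_init.append(
            f"    _m0_{m.name} = np.atleast_1d(np.asarray({mon_exprs[m.name]}, dtype=float))"
        )
        mon_init.append(
            f"    _mon_{m.name} = np.empty((n_rec,) + _m0_{m.name}.shape); "
            f"_mon_{m.name}[0] = _m0_{m.name}"
        )
        mon_rec.append(
            f"            _mon_{m.name}[_r] = np.atleast_1d({mon_exprs[m.name]})"
        )

    if ctx.hoist_order:
        p()
        p("    # per-step random draws (one draw per call site per step,")
        p("    # shared by all integration stages)")
        for var, src in ctx.hoist_order:
            p(f"    {var} = {src}")
    for line in mon_init:
        p(line)
    p()
    p("    # ---- integration loop")
    p("    for step in range(1, n_steps + 1):")
    p("        t_prev = t0 + (step - 1) * dt")
    for var, src in ctx.hoist_order:
        p(f"        {var} = {src}")
    for line in stage_src:
        p("        " + line if line else "")
    p("        t = t0 + step * dt")
    for line in cond_src:
        p("        " + line)
    # spike detection (post-conditional), buffers, recording
    for pop in pops:
        vs = pop.voltage_state
        thr = pop.spike_threshold if pop.spike_threshold is not None else default_thr
        p(f"        _x = (_prev_{vs} < {thr!r}) & ({vs} >= {thr!r})")
        p("        if _x.any():")
        p("            for _i in np.nonzero(_x)[0]:")
        p(f"                _spk_{pop.name}[_i].append(t)")
        if pop.name in model.spike_buffers:
            K = model.spike_buffers[pop.name]
            if K == 1:
                p(f"            _tspike_{pop.name} = "
                  f"np.where(_x, t, _tspike_{pop.name})")
            else:
                p("            for _i in np.nonzero(_x)[0]:")
                p(f"                _tspike_{pop.name}[1:, _i] = "
                  f"_tspike_{pop.name}[:-1, _i]")
                p(f"                _tspike_{pop.name}[0, _i] = t")
        p(f"        _prev_{vs} = {vs}.copy()")
    p("        if step % rec == 0:")
    p("            _r = step // rec")
    for s in states:
        p(f"            _out_{s}[_r] = {s}")
    for line in mon_rec:
        p(line)
    p("            " + _finite_check(states))
    p()
    p("    time = t0 + dt * rec * np.arange(n_rec)")
    p("    return {")
    p('        "time": time,')
    p('        "states": {' + ", ".join(f'"{s}": _out_{s}' for s in states) + "},")
    p('        "monitors": {'
      + ", ".join(f'"{m.name}": _mon_{m.name}' for m in value_monitors) + "},")
    p('        "spikes": {'
      + ", ".join(
          f'"{pop.name}": [np.asarray(c, dtype=float) for c in _spk_{pop.name}]'
          for pop in pops
      )
      + "},")
    p("    }")
    p()
    p()
    p('if __name__ == "__main__":')
    p("    import sys")
    p("    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0")
    p('    path = sys.argv[2] if len(sys.argv) > 2 else "simdata.npz"')
    p("    out = solve(seed)")
    p('    flat = {"time": out["time"]}')
    p('    flat.update({"state__" + k: v for k, v in out["states"].items()})')
    p('    flat.update({"monitor__" + k: v for k, v in out["monitors"].items()})')
    p('    for pop, cells in out["spikes"].items():')
    p('        for i, c in enumerate(cells):')
    p('            flat[f"spikes__{pop}__{i}"] = c')
    p("    np.savez(path, **flat)")
    p('    print(f"wrote {path}")')
    return w.getvalue()


def _finite_check(states) -> str:
    checks = " and ".join(f"np.isfinite({s}).all()" for s in states)
    return (
        f"if not ({checks}):\n"
        "                _bad = [n for n, a in ("
        + "".join(f'("{s}", {s}), ' for s in states)
        + ") if not np.isfinite(a).all()][0]\n"
        "                raise RuntimeError("
        "f\"non-finite state {_bad!r} at step {step} (t={t} ms)\")"
    )


def _stage_code(ctx, model, states, method) -> list[str]:
    """Lines computing one step of the chosen fixed-step method."""
    lines = []
    rhs = {s: parse_expr(model.odes[s]) for s in states}

    def deriv(tag, tvar, state_map):
        nm = dict(state_map)
        nm["t"] = tvar
        for s in states:
            lines.append(f"_d{tag}_{s} = {ctx.render_node(rhs[s], nm)}")

    def stage_state(tag, coeff, src_tag):
        for s in states:
            lines.append(f"_s{tag}_{s} = {s} + {coeff} * dt * _d{src_tag}_{s}")
        return {s: f"_s{tag}_{s}" for s in states}

    if method == "euler":
        lines.append("# Euler step")
        deriv("1", "t_prev", {})
        for s in states:
            lines.append(f"{s} = {s} + dt * _d1_{s}")
    elif method == "rk2":
        lines.append("# midpoint (2nd-order Runge-Kutta) step")
        deriv("1", "t_prev", {})
        m2 = stage_state("2", "0.5", "1")
        lines.append("_t2 = t_prev + 0.5 * dt")
        deriv("2", "_t2", m2)
        for s in states:
            lines.append(f"{s} = {s} + dt * _d2_{s}")
    elif method == "rk4":
        lines.append("# classic 4th-order Runge-Kutta step")
        deriv("1", "t_prev", {})
        m2 = stage_state("2", "0.5", "1")
        lines.append("_t2 = t_prev + 0.5 * dt")
        deriv("2", "_t2", m2)
        m3 = stage_state("3", "0.5", "2")
        deriv("3", "_t2", m3)
        m4 = stage_state("4", "1.0", "3")
        lines.append("_t4 = t_prev + dt")
        deriv("4", "_t4", m4)
        for s in states:
            lines.append(
                f"{s} = {s} + (dt / 6.0) * "
                f"(_d1_{s} + 2.0 * _d2_{s} + 2.0 * _d3_{s} + _d4_{s})"
            )
    else:  # pragma: no cover
        raise ModelError(f"unknown fixed-step method {method!r}")
    return lines


def _conditional_code(ctx, model) -> list[str]:
    lines = []
    if model.conditionals:
        lines.append("# conditional updates (declaration order; actions see")
        lines.append("# the mask captured when the condition was evaluated)")
    for i, cond in enumerate(model.conditionals):
        lines.append(f"_c{i} = {ctx.render(cond.condition)}")
        lines.append(f"if np.any(_c{i}):")
        for target, action in cond.actions:
            lines.append(
                f"    {target} = np.where(_c{i}, {ctx.render(action)}, {target})"
            )
    return lines


# ---------------------------------------------------------------------------
# adaptive-delegate module (internal; not part of render_solver_source)
# ---------------------------------------------------------------------------


def render_adaptive_module(model, opts) -> str:
    """Module delegating to scipy's variable-step integrator.

    Conditionals are applied by polling at the recording grid (reset timing
    is therefore grid-quantized); stochastic models are rejected because a
    variable-step method evaluates the right-hand side an unpredictable
    number of times.
    """
    ctx = _Ctx(model)
    for expr_text in list(model.odes.values()) + [
        c.condition for c in model.conditionals
    ] + [a for c in model.conditionals for _, a in c.actions]:
        node = ctx.inline(parse_expr(expr_text))
        for n in _expr.iter_nodes(node):
            if isinstance(n, Call) and n.fn in ("rand", "randn"):
                raise SolverError(
                    "the adaptive-delegate method does not support stochastic "
                    "models (random draws in dynamics); use a fixed-step method"
                )
    if model.spike_buffers:
        raise SolverError(
            "the adaptive-delegate method does not support spike-time buffers"
        )

    dt = float(opts.dt)
    t0, t1 = float(opts.tspan[0]), float(opts.tspan[1])
    n_steps = int(round((t1 - t0) / dt))
    rec = int(opts.downsample_factor)
    states = list(model.odes)
    sizes = {s: model.state_layout[s][1] for s in states}
    offsets = {}
    off = 0
    for s in states:
        offsets[s] = (off, off + sizes[s])
        off += sizes[s]
    unpack = {s: f"y[{offsets[s][0]}:{offsets[s][1]}]" for s in states}
    pops = [p for p in model.populations if p.voltage_state is not None]
    default_thr = float(getattr(opts, "threshold", 0.0))

    w = io.StringIO()
    p = lambda s="": print(s, file=w)  # noqa: E731
    p("import numpy as np")
    p("from scipy.integrate import solve_ivp")
    p()
    p(_HELPERS)
    p()
    p(f"def solve(seed={int(opts.seed)}):")
    p("    rng = np.random.default_rng(int(seed) % 2**31)")
    p(_RAND_HELPERS)
    p(f"    dt = {dt!r}; t0 = {t0!r}; rec = {rec}; n_steps = {n_steps}")
    for name, value in model.parameters.items():
        p(f"    {name} = {_fmt_param(value)}")
    for name, expr_text in model.fixed_variables.items():
        p(f"    {name} = {ctx.render(expr_text, hoist=False)}")
    p("    t = t0")
    for s in states:
        p(f"    {s} = np.empty({sizes[s]}); "
          f"{s}[:] = {ctx.render(model.ics[s], hoist=False)}")
    p()
    p("    def _rhs(t, y):")
    for s in states:
        p(f"        {s} = {unpack[s]}")
    for s in states:
        p(f"        _d_{s} = np.broadcast_to(np.asarray("
          f"{ctx.render(model.odes[s], hoist=False)}, dtype=float), "
          f"({sizes[s]},))")
    p("        return np.concatenate(["
      + ", ".join(f"_d_{s}" for s in states) + "])")
    p()
    p("    y = np.concatenate([" + ", ".join(states) + "])")
    p("    n_rec = n_steps // rec + 1")
    for s in states:
        p(f"    _out_{s} = np.empty((n_rec, {sizes[s]})); _out_{s}[0] = {s}")
    for pop in pops:
        p(f"    _spk_{pop.name} = [[] for _ in range({pop.size})]")
        p(f"    _prev_{pop.voltage_state} = {pop.voltage_state}.copy()")
    p("    _grid = t0 + dt * np.arange(n_steps + 1)")
    if not model.conditionals:
        # no resets: integrate the whole span in one call, sample on the grid
        p("    sol = solve_ivp(_rhs, (_grid[0], _grid[-1]), y, method='RK45',")
        p(f"                    rtol={float(opts.rtol)!r}, "
          f"atol={float(opts.atol)!r}, t_eval=_grid[::rec])")
        p("    if not sol.success:")
        p("        raise RuntimeError('adaptive integration failed: ' + sol.message)")
        for s in states:
            o0, o1 = offsets[s]
            p(f"    _out_{s} = sol.y[{o0}:{o1}, :].T.copy()")
        for pop in pops:
            vs = pop.voltage_state
            thr = (pop.spike_threshold if pop.spike_threshold is not None
                   else default_thr)
            p(f"    _v = _out_{vs}")
            p(f"    for _i in range({pop.size}):")
            p(f"        _k = np.nonzero((_v[:-1, _i] < {thr!r}) & "
              f"(_v[1:, _i] >= {thr!r}))[0] + 1")
            p(f"        _spk_{pop.name}[_i] = list(_grid[::rec][_k])")
    else:
        p("    for step in range(1, n_steps + 1):")
        p("        sol = solve_ivp(_rhs, (_grid[step - 1], _grid[step]), y,")
        p(f"                        method='RK45', rtol={float(opts.rtol)!r}, "
          f"atol={float(opts.atol)!r}, dense_output=False)")
        p("        if not sol.success:")
        p("            raise RuntimeError('adaptive integration failed: '"
          " + sol.message)")
        p("        y = sol.y[:, -1]")
        p("        t = _grid[step]")
        for s in states:
            p(f"        {s} = {unpack[s]}")
        for line in _conditional_code(ctx, model):
            p("        " + line)
        p("        y = np.concatenate([" + ", ".join(states) + "])")
        for pop in pops:
            vs = pop.voltage_state
            thr = (pop.spike_threshold if pop.spike_threshold is not None
                   else default_thr)
            p(f"        _x = (_prev_{vs} < {thr!r}) & ({vs} >= {thr!r})")
            p("        for _i in np.nonzero(_x)[0]:")
            p(f"            _spk_{pop.name}[_i].append(t)")
            p(f"        _prev_{vs} = {vs}.copy()")
        p("        if step % rec == 0:")
        p("            _r = step // rec")
        for s in states:
            p(f"            _out_{s}[_r] = {s}")
    p("    time = t0 + dt * rec * np.arange(n_rec)")
    p("    return {")
    p('        "time": time,')
    p('        "states": {' + ", ".join(f'"{s}": _out_{s}' for s in states) + "},")
    p('        "monitors": {},')
    p('        "spikes": {'
      + ", ".join(
          f'"{pop.name}": [np.asarray(c, dtype=float) for c in _spk_{pop.name}]'
          for pop in pops
      )
      + "},")
    p("    }")
    return w.getvalue()
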