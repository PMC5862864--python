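"""Parameter sweeps and batch simulation management.

A *vary* description is a set of (object, parameter, values) triplets; the
swept space is the Cartesian product of the value lists (``expand_vary``),
or an explicit list of modification sets (``zipped_plan``). ``run_batch``
applies each modification set to a base specification, simulates it with a
deterministic per-simulation seed, applies analysis hooks, and lays the
results out in a self-describing study directory::

    study_dir/
      spec.json            # base specification
      index.json           # plan, per-simulation status, seeds
      manifest.txt         # one runnable command line per simulation
      sim000__E_Iapp_0/
        data.h5            # SimData
        solve.py           # emitted solver source for this simulation
        results__<hook>.json

Any single simulation can be (re)run from the study directory alone with
``python -m neusim.batch <study_dir> <index>``, so the manifest can be
submitted to any scheduler. Serial and parallel execution give identical
results because seeds depend only on (master seed, simulation index).
"""

from __future__ import annotations

import json
import re
import traceback
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np

from . import analysis as _analysis
from .build import build
from .errors import ModelError
from .solver import SimData, SolverOptions, integrate, load_simdata, save_simdata
from .specification import Specification, load_spec, save_spec, standardize

__all__ = [
    "VaryTriplet",
    "SweepPlan",
    "SimEntry",
    "StudyResults",
    "expand_vary",
    "zipped_plan",
    "apply_modifications",
    "run_batch",
    "import_results",
    "write_job_manifest",
]


@dataclass(frozen=True)
class VaryTriplet:
    """One swept axis: ``object`` is a population name or a
    ``"source->target"`` connection token."""

    object: str
    parameter: str
    values: tuple

    def __post_init__(self):
        if not len(self.values):
            raise ValueError(
                f"vary triplet ({self.object}, {self.parameter}): empty values"
            )


@dataclass
class SweepPlan:
    """Ordered modification sets; each set is a list of
    (object, parameter, value) tuples."""

    modifications: list
    labels: list = field(default_factory=list)

    def __len__(self):
        return len(self.modifications)

    def varied(self, k: int) -> dict:
        return {f"{o}.{p}": v for o, p, v in self.modifications[k]}


@dataclass
class SimEntry:
    index: int
    varied: dict
    seed: int
    data: SimData | None = None
    results: dict = field(default_factory=dict)
    error: str | None = None
    directory: str | None = None


@dataclass
class StudyResults:
    entries: list
    labels: list = field(default_factory=list)
    study_dir: str | None = None

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, k) -> SimEntry:
        return self.entries[k]

    def ok(self):
        return [e for e in self.entries if e.error is None]

    def table(self) -> list:
        return [
            {"index": e.index, **e.varied,
             **{k: v for k, v in e.results.items()
                if isinstance(v, (int, float, str))}}
            for e in self.entries
        ]


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------


def expand_vary(triplets) -> SweepPlan:
    """Cartesian product of the triplets' value lists.

    The first triplet varies slowest (lexicographic order). An empty
    triplet list yields one empty modification set: the base model.
    """
    trips = [
        t if isinstance(t, VaryTriplet) else VaryTriplet(t[0], t[1], tuple(t[2]))
        for t in triplets
    ]
    if not trips:
        return SweepPlan(modifications=[[]], labels=[])
    labels = [f"{t.object}.{t.parameter}" for t in trips]
    mods = [
        [(t.object, t.parameter, v) for t, v in zip(trips, combo)]
        for combo in product(*(t.values for t in trips))
    ]
    return SweepPlan(modifications=mods, labels=labels)


def zipped_plan(modification_sets) -> SweepPlan:
    """Explicit list of modification sets (one simulation each)."""
    mods = [[(o, p, v) for o, p, v in ms] for ms in modification_sets]
    labels = sorted({f"{o}.{p}" for ms in mods for o, p, _ in ms})
    return SweepPlan(modifications=mods, labels=labels)


_CONN_RE = re.compile(r"^\s*(\w+)\s*->\s*(\w+)\s*$")


def apply_modifications(spec, modification_set) -> Specification:
    """Deep-copied specification with (object, parameter, value) overrides.

    ``object`` may be a population name or ``"source->target"``. The
    specifiers ``size`` and ``equations`` can be modified as well as
    parameters; parameter-name validity against the underlying equations is
    enforced when the model is built.
    """
    out = standardize(spec)
    for obj, param, value in modification_set:
        m = _CONN_RE.match(obj)
        if m:
            target = out.connection(m.group(1), m.group(2))
        else:
            target = out.population(obj)  # KeyError if unknown
        if param == "size":
            if m:
                raise ModelError("connections have no 'size' specifier")
            target.size = int(value)
        elif param == "equations":
            if m:
                raise ModelError("connections have no 'equations' specifier")
            target.equations = value
        else:
            target.parameters[param] = value
    return standardize(out)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


def simulation_seed(master_seed: int, index: int) -> int:
    """Deterministic per-simulation seed, independent of scheduling order."""
    return (1000003 * int(master_seed) + 10007 * int(index) + 1) % (2**31)


def _resolve_hooks(hooks) -> dict:
    out = {}
    for h in hooks or []:
        if callable(h):
            out[getattr(h, "__name__", f"hook{len(out)}")] = h
        elif isinstance(h, str) and h in _analysis.HOOKS:
            out[h] = _analysis.HOOKS[h]
        else:
            raise KeyError(
                f"unknown hook {h!r}; built-ins: {sorted(_analysis.HOOKS)}"
            )
    return out


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return repr(o)


def _dir_name(index: int, varied: dict) -> str:
    parts = [f"sim{index:03d}"]
    for k, v in varied.items():
        tok = f"{k}_{v:g}" if isinstance(v, (int, float)) else f"{k}_{v}"
        parts.append(re.sub(r"[^A-Za-z0-9_.-]", "-", tok.replace("->", "-")))
    return "__".join(parts)


def _run_one(spec_doc, modset, opts_dict, seed, hook_names, sim_dir):
    """Run one simulation; importable at module level for joblib."""
    from .specification import _from_dict

    spec = _from_dict(spec_doc)
    hooks = _resolve_hooks(hook_names)
    opts = SolverOptions(**{**opts_dict, "seed": seed})
    varied = {f"{o}.{p}": v for o, p, v in modset}
    entry = {"varied": varied, "seed": seed, "error": None, "results": {}}
    try:
        modified = apply_modifications(spec, modset)
        model = build(modified)
        data = integrate(model, opts, varied=varied)
    except Exception:
        entry["error"] = traceback.format_exc(limit=4)
        return entry, None
    for name, fn in hooks.items():
        try:
            entry["results"][name] = fn(data)
        except Exception:
            entry["results"][name] = {"error": traceback.format_exc(limit=2)}
    if sim_dir is not None:
        sim_dir = Path(sim_dir)
        sim_dir.mkdir(parents=True, exist_ok=True)
        save_simdata(data, sim_dir / "data.h5")
        try:
            from .solver import render_solver_source

            (sim_dir / "solve.py").write_text(render_solver_source(model, opts))
        except ModelError:
            pass  # adaptive method: no fixed-step source to save
        for name, res in entry["results"].items():
            (sim_dir / f"results__{name}.json").write_text(
                json.dumps(res, default=_json_default, indent=1)
            )
    return entry, data


def run_batch(spec, plan: SweepPlan | None = None, opts: SolverOptions | None = None,
              hooks=None, study_dir=None, parallel: int | bool = False,
              overwrite: bool = False, keep_data: bool = True) -> StudyResults:
    """Run every modification set of ``plan`` against the base ``spec``.

    ``hooks`` is a list of callables (SimData -> result dict) and/or names
    of built-in analyses. A failing hook (or simulation) is recorded in the
    corresponding entry and the batch continues. With ``parallel`` set to a
    worker count (or True for all cores), simulations run via joblib;
    results are identical to a serial run because per-simulation seeds are
    fixed by (master seed, index).
    """
    from .specification import to_dict

    base = standardize(spec)
    plan = plan if plan is not None else SweepPlan(modifications=[[]])
    opts = (opts or SolverOptions()).validated()
    hook_names = list(hooks or [])
    _resolve_hooks(hook_names)  # fail fast on unknown hooks

    sim_dirs = [None] * len(plan)
    if study_dir is not None:
        study_dir = Path(study_dir)
        if (study_dir.exists() and not overwrite
                and any(p.name != "study.log" for p in study_dir.iterdir())):
            raise FileExistsError(
                f"study directory {study_dir} exists; pass overwrite=True"
            )
        study_dir.mkdir(parents=True, exist_ok=True)
        save_spec(base, study_dir / "spec.json")
        sim_dirs = [
            study_dir / _dir_name(k, plan.varied(k)) for k in range(len(plan))
        ]

    spec_doc = to_dict(base)
    seeds = [simulation_seed(opts.seed, k) for k in range(len(plan))]
    opts_dict = {**asdict(opts), "tspan": tuple(opts.tspan)}
    jobs = [
        (spec_doc, plan.modifications[k], opts_dict, seeds[k], hook_names,
         sim_dirs[k])
        for k in range(len(plan))
    ]
    if parallel:
        from joblib import Parallel, delayed

        n_jobs = -1 if parallel is True else int(parallel)
        # custom hook callables must be picklable (module-level functions)
        raw = Parallel(n_jobs=n_jobs)(delayed(_run_one)(*job) for job in jobs)
    else:
        raw = [_run_one(*job) for job in jobs]

    entries = []
    for k, (entry, data) in enumerate(raw):
        entries.append(
            SimEntry(
                index=k,
                varied=entry["varied"],
                seed=seeds[k],
                data=data if keep_data else None,
                results=entry["results"],
                error=entry["error"],
                directory=str(sim_dirs[k]) if sim_dirs[k] is not None else None,
            )
        )

    results = StudyResults(entries=entries, labels=plan.labels,
                           study_dir=str(study_dir) if study_dir else None)
    if study_dir is not None:
        _write_index(study_dir, plan, opts, entries)
        write_job_manifest(study_dir)
    return results


def _write_index(study_dir: Path, plan, opts, entries) -> None:
    doc = {
        "labels": plan.labels,
        "master_seed": int(opts.seed),
        "solver_options": {**asdict(opts), "tspan": list(opts.tspan),
                           "record": (opts.record if opts.record == "all"
                                      else list(opts.record))},
        "modifications": plan.modifications,
        "simulations": [
            {
                "index": e.index,
                "directory": Path(e.directory).name,
                "seed": e.seed,
                "varied": e.varied,
                "status": "error" if e.error else "ok",
                "hooks": sorted(e.results),
            }
            for e in entries
        ],
    }
    (study_dir / "index.json").write_text(
        json.dumps(doc, default=_json_default, indent=1)
    )


def write_job_manifest(study_dir) -> Path:
    """One runnable command line per simulation (scheduler-agnostic
    replacement for native cluster submission)."""
    study_dir = Path(study_dir)
    doc = json.loads((study_dir / "index.json").read_text())
    lines = [
        f"python -m neusim.batch {study_dir} {sim['index']}"
        for sim in doc["simulations"]
    ]
    path = study_dir / "manifest.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------


def import_results(study_dir, what="data"):
    """Load a study from disk, in plan order.

    ``what``: ``"data"`` returns a StudyResults whose entries carry SimData;
    a hook name returns entries carrying that hook's saved results. Partial
    studies load with missing entries flagged in ``error``.
    """
    study_dir = Path(study_dir)
    index_path = study_dir / "index.json"
    if not index_path.exists():
        raise FileNotFoundError(f"no index.json in {study_dir}")
    try:
        doc = json.loads(index_path.read_text())
        sims = doc["simulations"]
    except (json.JSONDecodeError, KeyError) as e:
        raise ModelError(f"corrupt study index in {study_dir}: {e}") from None

    entries = []
    for sim in sims:
        entry = SimEntry(index=sim["index"], varied=sim["varied"],
                         seed=sim["seed"],
                         directory=str(study_dir / sim["directory"]))
        d = study_dir / sim["directory"]
        if sim.get("status") == "error":
            entry.error = "simulation failed (see study log)"
        elif what == "data":
            p = d / "data.h5"
            if p.exists():
                entry.data = load_simdata(p)
            else:
                entry.error = f"missing {p.name}"
        else:
            p = d / f"results__{what}.json"
            if p.exists():
                entry.results[what] = json.loads(p.read_text())
            else:
                entry.error = f"missing results for hook {what!r}"
        entries.append(entry)
    return StudyResults(entries=entries, labels=doc.get("labels", []),
                        study_dir=str(study_dir))


def run_indexed(study_dir, index: int):
    """(Re)run one simulation of a stored study from its directory alone."""
    study_dir = Path(study_dir)
    doc = json.loads((study_dir / "index.json").read_text())
    sim = doc["simulations"][int(index)]
    spec = load_spec(study_dir / "spec.json")
    opts_doc = dict(doc["solver_options"])
    opts_doc["tspan"] = tuple(opts_doc["tspan"])
    modset = [tuple(m) for m in doc["modifications"][int(index)]]
    from .specification import to_dict

    hooks = [h for h in sim.get("hooks", []) if h in _analysis.HOOKS]
    entry, _ = _run_one(
        to_dict(spec), modset, opts_doc, sim["seed"], hooks,
        study_dir / sim["directory"],
    )
    return entry


if __name__ == "__main__":  # pragma: no cover - exercised via manifest
    import sys

    entry = run_indexed(sys.argv[1], int(sys.argv[2]))
    status = "error" if entry["error"] else "ok"
    print(f"simulation {sys.argv[2]}: {status}")
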