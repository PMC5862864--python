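"""Numerical integration of a FlatModel and the simulated-data container.

``integrate`` drives the generated solve file (see :mod:`neusim.codegen`):
fixed variables are evaluated once before the loop; each step updates the
state with the chosen method, applies conditionals in declaration order,
detects spikes as upward threshold crossings, and records states/monitors at
the (optionally downsampled) recording grid. Identical (model, options,
seed) give bit-identical results.

Methods: ``euler``, ``rk2`` (midpoint), ``rk4``, and ``adaptive`` (delegates
to scipy's variable-step RK45 between recording-grid points; conditionals
are polled at the grid, so reset timing is grid-quantized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import codegen
from .build import FlatModel
from .errors import ModelError, SolverError

__all__ = [
    "SolverOptions",
    "SimData",
    "integrate",
    "detect_spikes",
    "downsample",
    "render_solver_source",
    "save_simdata",
    "load_simdata",
]

_METHOD_ALIASES = {"adaptive-delegate": "adaptive", "midpoint": "rk2"}


@dataclass
class SolverOptions:
    """Integration options.

    dt and tspan are in milliseconds. ``record`` is "all" or a list of
    fully-qualified state/monitor names. ``threshold`` (mV) is the default
    spike-detection level for populations that do not declare their own via
    a ``monitor v.spikes(...)`` directive.
    """

    method: str = "rk4"
    dt: float = 0.01
    tspan: tuple = (0.0, 100.0)
    downsample_factor: int = 1
    seed: int = 0
    record: object = "all"
    threshold: float = 0.0
    rtol: float = 1e-10  # adaptive-delegate only
    atol: float = 1e-12

    def validated(self) -> "SolverOptions":
        method = _METHOD_ALIASES.get(self.method, self.method)
        if method not in codegen.FIXED_STEP_METHODS + ("adaptive",):
            raise SolverError(f"unknown method {self.method!r}")
        if not float(self.dt) > 0:
            raise SolverError("dt must be > 0")
        if not float(self.tspan[1]) > float(self.tspan[0]):
            raise SolverError("tspan must satisfy t1 > t0")
        f = self.downsample_factor
        if int(f) != f or int(f) < 1:
            raise SolverError("downsample_factor must be an integer >= 1")
        out = SolverOptions(**{**asdict(self), "method": method,
                               "downsample_factor": int(f)})
        return out


@dataclass
class SimData:
    """Labeled time series of recorded states and monitors plus spikes.

    ``series`` maps fully-qualified names to (time, population-size) arrays;
    ``spikes`` maps population names to per-cell spike-time arrays (ms);
    ``metadata`` holds solver options, the model hash and any varied
    parameter values.
    """

    time: np.ndarray
    series: dict = field(default_factory=dict)
    spikes: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.series[name]

    def names(self):
        return list(self.series)

    @property
    def dt_record(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def equal(self, other: "SimData", atol: float = 0.0) -> bool:
        if sorted(self.series) != sorted(other.series):
            return False
        if not np.allclose(self.time, other.time, atol=atol, rtol=0):
            return False
        for k in self.series:
            if not np.allclose(self.series[k], other.series[k], atol=atol, rtol=0):
                return False
        for pop in set(self.spikes) | set(other.spikes):
            a, b = self.spikes.get(pop), other.spikes.get(pop)
            if a is None or b is None or len(a) != len(b):
                return False
            for ca, cb in zip(a, b):
                if len(ca) != len(cb) or not np.allclose(ca, cb, atol=atol, rtol=0):
                    return False
        return True


# ---------------------------------------------------------------------------
# integrate
# ---------------------------------------------------------------------------


def render_solver_source(model: FlatModel, opts: SolverOptions | None = None) -> str:
    """Emit the standalone fixed-step solve file for (model, options)."""
    opts = (opts or SolverOptions()).validated()
    return codegen.render_solver_source(model, opts)


def integrate(model: FlatModel, opts: SolverOptions | None = None,
              varied: dict | None = None) -> SimData:
    """Numerically integrate a flattened model.

    Executes the generated solve file (fixed-step) or the scipy delegate
    (adaptive). Raises SolverError on non-finite states, unknown record
    names, or an unsupported method/model combination.
    """
    opts = (opts or SolverOptions()).validated()
    if opts.method == "adaptive":
        src = codegen.render_adaptive_module(model, opts)
    else:
        src = codegen.render_solver_source(model, opts)
    namespace: dict = {}
    exec(compile(src, "<neusim solve file>", "exec"), namespace)
    try:
        raw = namespace["solve"](int(opts.seed))
    except RuntimeError as e:
        raise SolverError(str(e)) from None

    series = dict(raw["states"])
    series.update({k: v for k, v in raw["monitors"].items() if k not in series})
    if opts.record != "all":
        requested = list(opts.record)
        unknown = [r for r in requested if r not in series]
        if unknown:
            raise SolverError(
                f"unknown record name(s) {unknown}; available: {sorted(series)}"
            )
        series = {k: series[k] for k in requested}
    meta = {
        "solver_options": {**asdict(opts),
                           "tspan": [float(opts.tspan[0]), float(opts.tspan[1])],
                           "record": (opts.record if opts.record == "all"
                                      else list(opts.record))},
        "model_hash": model.hash(),
        "varied": dict(varied or {}),
    }
    return SimData(time=raw["time"], series=series, spikes=raw["spikes"],
                   metadata=meta)


# ---------------------------------------------------------------------------
# spike detection / downsampling
# ---------------------------------------------------------------------------


def detect_spikes(trace, threshold: float, time=None):
    """Upward threshold crossings: a spike at sample k iff
    ``v[k-1] < threshold <= v[k]``.

    ``trace`` is (time,) or (time, cells); returns a list of sorted per-cell
    spike-time arrays (sample indices if ``time`` is None).
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.size and not np.isfinite(arr).all():
        raise ValueError("trace contains non-finite values")
    out = []
    for c in range(arr.shape[1]):
        v = arr[:, c]
        idx = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
        if time is not None:
            out.append(np.asarray(time)[idx].astype(float))
        else:
            out.append(idx.astype(float))
    return out


def downsample(data: SimData, factor: int) -> SimData:
    """Keep every ``factor``-th recorded point; spike lists are unchanged
    (spikes are detected at full integration resolution)."""
    if int(factor) != factor or factor < 1:
        raise ValueError("downsample factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return data
    meta = json.loads(json.dumps(data.metadata))
    so = meta.get("solver_options", {})
    so["downsample_factor"] = so.get("downsample_factor", 1) * factor
    return SimData(
        time=data.time[::factor].copy(),
        series={k: v[::factor].copy() for k, v in data.series.items()},
        spikes={p: [c.copy() for c in cells] for p, cells in data.spikes.items()},
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------


def save_simdata(data: SimData, path) -> None:
    """Write a SimData to one HDF5 file (datasets per state, vlen spikes)."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=data.time)
        g = f.create_group("series")
        for k, v in data.series.items():
            g.create_dataset(k, data=v)
        s = f.create_group("spikes")
        vlen = h5py.vlen_dtype(np.float64)
        for pop, cells in data.spikes.items():
            ds = s.create_dataset(pop, (len(cells),), dtype=vlen)
            for i, c in enumerate(cells):
                ds[i] = np.asarray(c, dtype=float)
        f.attrs["metadata"] = json.dumps(data.metadata)


def load_simdata(path) -> SimData:
    import h5py

    with h5py.File(path, "r") as f:
        data = SimData(
            time=f["time"][()],
            series={k: f["series"][k][()] for k in f["series"]},
            spikes={
                pop: [np.asarray(c, dtype=float) for c in f["spikes"][pop][()]]
                for pop in f["spikes"]
            },
            metadata=json.loads(f.attrs["metadata"]),
        )
    return data


def export_csv(data: SimData, path) -> None:
    """Wide CSV export: time plus one column per state per cell."""
    cols = ["time"]
    arrays = [np.asarray(data.time)]
    for name, arr in data.series.items():
        arr = np.atleast_2d(np.asarray(arr).T).T
        for i in range(arr.shape[1]):
            cols.append(f"{name}[{i}]" if arr.shape[1] > 1 else name)
            arrays.append(arr[:, i])
    mat = np.column_stack(arrays)
    header = ",".join(cols)
    np.savetxt(path, mat, delimiter=",", header=header, comments="")
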