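# File formats

## Equation dialect

Statements are delimited by `;` or newlines; `%` and `#` start comments
that run to end of line. Identifiers are ASCII letters/digits/underscore,
not starting with a digit; `@`-prefixed tokens are linker names only.

| Statement | Form |
|---|---|
| parameter | `name = number` or `name = [n1, n2, ...]` |
| fixed variable | `name = expression` (non-numeric RHS; evaluated once) |
| function | `name(arg1, arg2) = expression` |
| ODE | `dNAME/dt = expression` (also `NAME' = expression`) |
| initial condition | `NAME(0) = expression` |
| conditional | `if(condition)(action1; action2; ...)` |
| linker statement | `@linker += payload` (`+=`, `-=`, `*=`, `=`) |
| monitor | `monitor NAME` or `monitor NAME.spikes(THRESHOLD)` |
| mechanism list | `mechanisms name1, name2` (population files) |

Expressions support `+ - * / ^` (with `^` exponentiation), comparisons,
elementwise logic `& | !`/`~`, and the builtins `exp log log10 sqrt sin
cos tan tanh floor ceil abs sign min max mod heaviside step sum mean
rowsum rand randn`, plus `t` (current time, ms), `dt`, and `pi`.
`rand(1,N)`/`randn(1,N)` draw population-sized vectors from the
simulation's seeded stream. A linker payload must be a single identifier
naming a local function or fixed variable.

## Mechanism (`.mech`) and population (`.pop`) files

One statement per line in the dialect above. The object name is the
filename stem. Header comment lines carry the citation (first line) and
the object kind (`% kind: input|intrinsic|connection|population`). A
mechanism must declare at least one linker statement or ODE; a file with
neither (e.g. comments only) is rejected as empty. Population files may
carry a `mechanisms` directive listing intrinsic mechanisms.

Mechanisms may reference host-population symbols by name (see
`docs/methods.md` for binding rules and the reserved names `netcon`,
`N_pre`, `N_post`, `tspike_pre`, `tspike_post`).

## Specification JSON

```json
{
  "populations": [
    {"name": "E", "size": 16,
     "equations": "dv/dt=(Iapp+@current)/Cm; Cm=1; Iapp=3; v(0)=-65",
     "mechanisms": ["iNaF", "iKDR"],
     "parameters": {"Iapp": 3.0}}
  ],
  "connections": [
    {"source": "I", "target": "E",
     "mechanisms": ["iGABAa"],
     "parameters": {"tauD": 10.0,
                    "netcon": [[1.0, 0.0], [0.0, 1.0]]}}
  ],
  "mechanisms": {"myCurrent": "f(v)=-v\n@current += f\ndz/dt=-z"}
}
```

* Top-level keys: `populations`, `connections`, `mechanisms` (inline
  definitions, which shadow same-named library files). Unknown keys are
  errors.
* `equations` is dialect text or the name of a library population
  (e.g. `"HH"`).
* `parameters` values: scalar, or an array of the population size;
  `netcon` is a nested (target × source) matrix.
* `mechanisms`/`mechanism_list` are accepted as synonyms.

## Study directory

```
study/
  spec.json        # standardized base specification
  index.json       # labels, master seed, solver options, modification
                   # sets, and per-simulation {directory, seed, status}
  manifest.txt     # one command line per simulation:
                   #   python -m neusim.batch <study_dir> <index>
  study.log        # CLI log (when run via `neusim sweep`)
  sim000__E_Iapp_1/
    data.h5              # SimData: /time, /series/<name>, /spikes/<pop>
    solve.py             # emitted standalone solver for this simulation
    results__<hook>.json # one file per analysis hook
```

`index.json` is the source of truth; directory names are cosmetic.
SimData HDF5 files carry the solver options, model hash and varied
parameter values in a JSON `metadata` attribute. `export_csv` writes a
wide CSV alternative (time plus one column per state per cell).
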