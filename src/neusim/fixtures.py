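"""Worked-example models, generated programmatically.

These are the study conditions used throughout the tests and examples: the
Lorenz system, the Izhikevich neuron (tonic and stochastically driven), an
intrinsically-bursting neuron built from ionic mechanisms, a noise-driven
Hodgkin-Huxley population, a Poisson-driven population, and the two-
population weak PING network (excitatory and inhibitory cells coupled by
AMPA and GABA-A synapses) whose inhibitory decay constant of 10 ms sets a
gamma-band rhythm near 40 Hz.

No external data is involved; every fixture is built from equations and the
packaged mechanism library.
"""

from __future__ import annotations

from .solver import SolverOptions
from .specification import ConnectionSpec, PopulationSpec, Specification

__all__ = [
    "lorenz",
    "izhikevich",
    "ib_neuron",
    "hh_noisy",
    "poisson_driven",
    "weak_ping",
    "lorenz_options",
    "izhikevich_options",
    "weak_ping_options",
]


def lorenz(s: float = 10.0, r: float = 27.0, b: float = 2.666) -> str:
    """Lorenz system as a bare equation string (classic chaotic parameters;
    'pop1' of size 1 after standardization)."""
    return (
        f"s={s}; r={r}; b={b}\n"
        "dx/dt=s*(y-x); x(0)=1\n"
        "dy/dt=r*x-y-x*z; y(0)=1\n"
        "dz/dt=-b*z+x*y; z(0)=1"
    )


def lorenz_options(**kw) -> SolverOptions:
    return SolverOptions(**{"method": "rk4", "dt": 0.001, "tspan": (0.0, 2.0), **kw})


def izhikevich(stochastic: bool = False, iapp: float = 100.0) -> list:
    """Izhikevich neuron (regular-spiking coefficients) with conditional
    reset, as a list of equation strings.

    With ``stochastic=True`` the drive is a noisy time-varying input using
    the uniform random builtin; otherwise a tonic current ``Iapp``.
    """
    drive = "I(t)=Iapp*(1+rand(1,N))" if stochastic else "I(t)=Iapp*(t>=0)"
    return [
        f"a=.03; b=-2; c=-50; d=100; vr=-60; vpeak=35; Iapp={iapp}",
        drive,
        "dv/dt=.01*(.7*(v-vr)*(v+40)-u+I(t))",
        "du/dt=a*(b*(v-vr)-u)",
        "v(0)=vr; u(0)=0",
        "if(v>vpeak)(v=c; u=u+d)",
        "monitor v.spikes(0)",
    ]


def izhikevich_options(**kw) -> SolverOptions:
    return SolverOptions(**{"method": "euler", "dt": 0.01, "tspan": (0.0, 500.0), **kw})


def izhikevich_from_library(iapp: float = 100.0) -> Specification:
    """The same neuron taken from the packaged 'Izh' population object."""
    return Specification(
        populations=[
            PopulationSpec(name="pop1", size=1, equations="Izh",
                           parameters={"Iapp": iapp})
        ]
    )


def ib_neuron(iapp: float = 6.0, g_m: float = 2.5, q_m: float = 1.0) -> Specification:
    """Intrinsically-bursting neuron: fast spike currents plus a slow
    M-type potassium current providing the second (burst) time scale.

    The defaults strengthen and slow the M-current relative to the library
    values so that tonic drive elicits spike clusters separated by long
    silent pauses (bimodal interspike intervals) rather than adapting
    tonic firing.
    """
    eqns = (
        f"dV/dt=(Iapp-gl*(V-El)+@current)/Cm; Cm=1; gl=.1; El=-65; Iapp={iapp}; "
        "V(0)=-65; monitor V.spikes(0)"
    )
    return Specification(
        populations=[
            PopulationSpec(name="pop1", size=1, equations=eqns,
                           mechanism_list=["iNaF", "iKDR", "iM"],
                           parameters={"gm": g_m, "Qs": q_m})
        ]
    )


def hh_noisy(size: int = 100, noise_amp: float = 1e3) -> Specification:
    """A population of noise-driven Hodgkin-Huxley neurons built entirely
    from library objects (no equations written)."""
    return Specification(
        populations=[
            PopulationSpec(name="pop1", size=size, equations="HH",
                           mechanism_list=["noise"],
                           parameters={"noise_amp": noise_amp})
        ]
    )


def poisson_driven(size: int = 100, rate: float = 10.0) -> Specification:
    """Cells that emit one spike per Poisson input event: a fast-decaying
    voltage kicked over threshold by impulses at the given rate (events/s)."""
    eqns = ("dv/dt=(El-v+@current)/taum; El=-65; taum=.5; v(0)=-65; "
            "monitor v.spikes(0)")
    return Specification(
        populations=[
            PopulationSpec(name="cells", size=size, equations=eqns,
                           mechanism_list=["poisson"],
                           parameters={"rate": rate, "gpsn": 100.0})
        ]
    )


def weak_ping(
    n_e: int = 16,
    n_i: int = 4,
    iapp_e: float = 3.0,
    g_ampa: float | None = None,
    g_gabaa: float | None = None,
    tau_d: float = 10.0,
    noise_amp: float = 60.0,
) -> Specification:
    """Weak PING network: E and I populations with fast-spiking kinetics,
    AMPA E->I and GABA-A I->E coupling.

    Tonic drive goes to the excitatory cells only; the inhibitory decay
    constant ``tau_d`` (ms) sets the rhythm period, landing in the gamma
    band (~40 Hz) at the 10 ms default. Synaptic conductances are scaled by
    the source population size so the rhythm does not depend on cell
    counts. Initial voltages are randomized uniformly over 10 mV and a
    small stochastic current keeps the E population desynchronized (weak
    PING: cells fire irregularly while the population oscillates).
    """
    if g_ampa is None:
        g_ampa = 1.0 / n_e
    if g_gabaa is None:
        g_gabaa = 0.5 / n_i
    e_eqns = (
        f"dv/dt=(Iapp-gl*(v-El)+@current)/Cm; Cm=1; gl=.1; El=-65; Iapp={iapp_e}; "
        "v(0)=-65+10*rand(1,N); monitor v.spikes(0)"
    )
    i_eqns = (
        "dv/dt=(Iapp-gl*(v-El)+@current)/Cm; Cm=1; gl=.1; El=-65; Iapp=0; "
        "v(0)=-65+10*rand(1,N); monitor v.spikes(0)"
    )
    return Specification(
        populations=[
            PopulationSpec(name="E", size=n_e, equations=e_eqns,
                           mechanism_list=["iNaF", "iKDR", "noise"],
                           parameters={"noise_amp": noise_amp}),
            PopulationSpec(name="I", size=n_i, equations=i_eqns,
                           mechanism_list=["iNaF", "iKDR"]),
        ],
        connections=[
            ConnectionSpec(source="I", target="E", mechanism_list=["iGABAa"],
                           parameters={"gGABAa": g_gabaa, "tauD": tau_d}),
            ConnectionSpec(source="E", target="I", mechanism_list=["iAMPA"],
                           parameters={"gAMPA": g_ampa}),
        ],
    )


def weak_ping_options(seed: int = 0, **kw) -> SolverOptions:
    """Solver settings for the weak-PING study conditions: 1 s at
    dt = 0.01 ms, midpoint method, recorded every 0.1 ms."""
    return SolverOptions(**{
        "method": "rk2",
        "dt": 0.01,
        "tspan": (0.0, 1000.0),
        "downsample_factor": 10,
        "seed": seed,
        **kw,
    })
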