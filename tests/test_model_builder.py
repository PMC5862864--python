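"""Specification standardization, namespacing, linkers, flattening."""

import numpy as np
import pytest

import neusim as ns
from neusim.build import build, link, qualify
from neusim.errors import ModelError
from neusim.specification import (
    ConnectionSpec,
    PopulationSpec,
    Specification,
    standardize,
)

NA = (
    "gna=120; Ena=50\n"
    "INa(v,m,h)=-gna*m^3*h*(v-Ena)\n"
    "dm/dt=.1*(1-m)\ndh/dt=.1*(1-h)\n"
    "@current += INa"
)
K = (
    "gk=36; Ek=-77\n"
    "IK(v,n)=-gk*n^4*(v-Ek)\n"
    "dn/dt=.1*(1-n)\n"
    "@current += IK"
)


def _nospace(s):
    return s.replace(" ", "")


class TestStandardize:
    def test_bare_string_becomes_pop1(self):
        spec = standardize(ns.fixtures.lorenz())
        (pop,) = spec.populations
        assert pop.name == "pop1"
        assert pop.size == 1
        assert len(pop.equations.odes) == 3

    def test_weak_ping_structure(self):
        spec = standardize(ns.fixtures.weak_ping())
        assert [p.name for p in spec.populations] == ["E", "I"]
        assert [(c.source, c.target) for c in spec.connections] == [
            ("I", "E"), ("E", "I")
        ]

    def test_idempotent(self):
        spec = standardize(ns.fixtures.weak_ping())
        again = standardize(spec)
        assert [p.name for p in again.populations] == [
            p.name for p in spec.populations
        ]
        assert again.population("E").parameters == spec.population("E").parameters

    def test_duplicate_population_names_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            standardize(
                Specification(populations=[PopulationSpec(name="a"),
                                           PopulationSpec(name="a")])
            )

    def test_unknown_fields_rejected(self):
        with pytest.raises(ModelError, match="unknown"):
            standardize({"populations": [{"name": "a", "wat": 1}]})

    def test_connection_to_missing_population_rejected(self):
        with pytest.raises(ModelError, match="unknown population"):
            standardize(
                Specification(
                    populations=[PopulationSpec(name="a", equations="dv/dt=0")],
                    connections=[ConnectionSpec(source="a", target="b")],
                )
            )

    def test_parameter_array_length_checked(self):
        with pytest.raises(ModelError, match="length"):
            standardize(
                Specification(populations=[
                    PopulationSpec(name="a", size=3, equations="dv/dt=-g*v; g=1",
                                   parameters={"g": [1.0, 2.0]})
                ])
            )

    def test_size_from_declared_N(self):
        spec = standardize("N=7; dv/dt=-v")
        assert spec.populations[0].size == 7


class TestQualify:
    def test_mechanism_state(self):
        assert qualify(["pop1", "Na"], "m") == "pop1_Na_m"

    def test_population_state(self):
        assert qualify(["pop1"], "V") == "pop1_V"

    def test_collision_detected(self):
        table = {}
        qualify(["E", "Na"], "m", table)
        with pytest.raises(ModelError, match="collision"):
            qualify(["E"], "Na_m", table)


class TestLink:
    def test_worked_example_additive_linkers(self):
        merged = link("dV/dt=@current; V(0)=-65", [("Na", NA), ("K", K)])
        assert _nospace(merged.odes["pop1_V"]) == "pop1_Na_INa+pop1_K_IK"
        assert "@" not in merged.odes["pop1_V"]

    def test_no_mechanisms_gives_additive_identity(self):
        merged = link("dV/dt=@current; V(0)=-65", [])
        assert merged.odes["pop1_V"] == "0"

    def test_term_order_follows_mechanism_list(self):
        merged = link("dV/dt=@current; V(0)=-65", [("K", K), ("Na", NA)])
        # oracle: hand-built concatenation in list order
        assert _nospace(merged.odes["pop1_V"]) == "pop1_K_IK+pop1_Na_INa"

    def test_subtractive_and_multiplicative_operators(self):
        mech = "w=2\nscale(v)=w*v\n@gain *= scale\n@drive -= scale\ndq/dt=0"
        merged = link("dV/dt=@drive + x*@gain; x=1; V(0)=0", [("m1", mech)])
        rhs = _nospace(merged.odes["pop1_V"])
        assert rhs == "-pop1_m1_scale+x*pop1_m1_scale".replace("x", "pop1_x")

    def test_double_assignment_is_ambiguous(self):
        m1 = "f(v)=v\n@out = f\ndq/dt=0"
        m2 = "g(v)=v\n@out = g\ndr/dt=0"
        with pytest.raises(ModelError, match="ambiguous"):
            link("dV/dt=@out; V(0)=0", [("a", m1), ("b", m2)])

    def test_unused_linker_contribution_warns_not_fatal(self):
        spec = Specification(
            populations=[PopulationSpec(name="pop1", equations="dV/dt=-V",
                                        mechanism_list=["Na"])],
            mechanisms={"Na": NA},
        )
        flat = build(spec)
        assert any("linker" in w for w in flat.warnings)


class TestBuild:
    def test_ib_neuron_state_count(self):
        flat = build(ns.fixtures.ib_neuron())
        assert len(flat.odes) >= 4  # V + gating variables h, n, mM
        assert "pop1_V" in flat.odes
        assert set(flat.odes) >= {"pop1_iNaF_h", "pop1_iKDR_n", "pop1_iM_mM"}

    def test_no_linker_tokens_anywhere(self):
        flat = build(ns.fixtures.weak_ping())
        for text in (
            list(flat.odes.values())
            + list(flat.ics.values())
            + list(flat.fixed_variables.values())
            + [b for _, b in flat.functions.values()]
        ):
            assert "@" not in text

    def test_ping_cross_population_references(self):
        flat = build(ns.fixtures.weak_ping())
        # E voltage dynamics include intrinsic currents and the inhibitory
        # synapse; the synaptic gate reads presynaptic (I) voltage
        e_rhs = flat.odes["E_v"]
        assert "E_iNaF_INaF" in e_rhs and "E_I_iGABAa_IGABAa" in e_rhs
        assert "I_v" in flat.odes["E_I_iGABAa_s"]
        assert flat.state_layout["E_I_iGABAa_s"] == ("I", 4)
        assert flat.parameters["E_I_iGABAa_netcon"].shape == (16, 4)

    def test_scalar_ic_broadcasts_to_population(self):
        flat = build(
            Specification(populations=[
                PopulationSpec(name="p", size=100, equations="dv/dt=-v; v(0)=0")
            ])
        )
        data = ns.integrate(flat, ns.SolverOptions(dt=0.1, tspan=(0, 1)))
        assert data["p_v"].shape[1] == 100
        assert np.all(data["p_v"][0] == 0)

    def test_default_ic_is_zero(self):
        flat = build("dx/dt=-x")
        assert flat.ics["pop1_x"] == "0"

    def test_missing_mechanism_errors(self):
        with pytest.raises(ModelError, match="not found"):
            build(
                Specification(populations=[
                    PopulationSpec(name="p", equations="dv/dt=@current",
                                   mechanism_list=["definitely_missing"])
                ])
            )

    def test_unresolved_identifier_errors(self):
        spec = Specification(
            populations=[PopulationSpec(name="p", equations="dv/dt=@current",
                                        mechanism_list=["m"])],
            mechanisms={"m": "f(v)=q_undeclared*v\n@current += f\ndz/dt=0"},
        )
        with pytest.raises(ModelError, match="unresolved"):
            build(spec)

    def test_connectivity_shape_mismatch(self):
        spec = ns.fixtures.weak_ping()
        spec.connections[0].parameters["netcon"] = np.ones((3, 3))
        with pytest.raises(ModelError, match="shape"):
            build(spec)

    def test_unknown_parameter_override_errors(self):
        spec = Specification(populations=[
            PopulationSpec(name="p", equations="dv/dt=-v",
                           parameters={"nonexistent": 1.0})
        ])
        with pytest.raises(ModelError, match="match no declared"):
            build(spec)

    def test_build_is_deterministic(self):
        a = build(ns.fixtures.weak_ping())
        b = build(ns.fixtures.weak_ping())
        assert a.hash() == b.hash()

    def test_inline_mechanism_overrides_library(self):
        spec = Specification(
            populations=[PopulationSpec(name="p", equations="dv/dt=@current",
                                        mechanism_list=["iGABAa"])],
            mechanisms={"iGABAa": "f(v)=-v\n@current += f\ndz/dt=-z"},
        )
        flat = build(spec)
        assert "p_iGABAa_z" in flat.odes  # inline version, not the library file


class TestEquivalenceOfRoutes:
    """A model given via mechanisms and the same model written as one
    explicit equation list integrate to identical trajectories."""

    def test_mechanism_vs_explicit_equations(self):
        spec = Specification(
            populations=[PopulationSpec(
                name="pop1", size=1,
                equations="dV/dt=(6-gl*(V-El)+@current)/Cm; Cm=1; gl=.1; "
                          "El=-65; V(0)=-65",
                mechanism_list=["Na"],
            )],
            mechanisms={"Na": NA},
        )
        explicit = (
            "Cm=1; gl=.1; El=-65; gna=120; Ena=50\n"
            "INa(V,m,h)=-gna*m^3*h*(V-Ena)\n"
            "dV/dt=(6-gl*(V-El)+INa(V,m,h))/Cm; V(0)=-65\n"
            "dm/dt=.1*(1-m)\ndh/dt=.1*(1-h)"
        )
        opts = ns.SolverOptions(method="rk4", dt=0.01, tspan=(0, 50))
        d1 = ns.integrate(build(spec), opts)
        d2 = ns.integrate(build(explicit), opts)
        v1, v2 = d1["pop1_V"], d2["pop1_V"]
        denom = np.maximum(np.abs(v2), 1.0)
        assert np.max(np.abs(v1 - v2) / denom) <= 1e-12
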