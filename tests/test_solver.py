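"""Fixed-step integration: accuracy, conditionals, spikes, reproducibility."""

import numpy as np
import pytest

import neusim as ns
from neusim.build import build
from neusim.errors import SolverError
from neusim.solver import SolverOptions, detect_spikes, downsample, integrate


DECAY = "dx/dt=-x; x(0)=1"


class TestIntegrate:
    def test_exponential_decay_closed_form(self):
        d = integrate(build(DECAY),
                      SolverOptions(method="rk4", dt=0.01, tspan=(0, 1)))
        assert abs(d["pop1_x"][-1, 0] - np.exp(-1)) < 1e-9

    def test_conditional_reset_sawtooth_matches_scalar_oracle(self):
        """dv/dt = 0.1 with reset at v > 1: compare the vectorized solver
        against an explicit step-by-step scalar loop with identical
        arithmetic, and count resets with a float-robust threshold."""
        model = build("dv/dt=.1; v(0)=0; if(v>1)(v=0)")
        d = integrate(model,
                      SolverOptions(method="euler", dt=0.01, tspan=(0, 100)))
        v = d["pop1_v"][:, 0]
        # scalar oracle
        vo, trace = 0.0, [0.0]
        for _ in range(10000):
            vo = vo + 0.01 * 0.1
            if vo > 1:
                vo = 0.0
            trace.append(vo)
        assert np.array_equal(v, np.asarray(trace))
        # 9 cycles complete strictly inside (0, 100] ms: the reset period is
        # threshold/slope plus up-to-one-step quantization (~10 ms here)
        resets_robust = int(np.sum((v[:-1] > 0.5) & (v[1:] < 0.5)))
        assert resets_robust in (9, 10)
        periods = np.diff(np.nonzero((v[:-1] > 0.5) & (v[1:] < 0.5))[0])
        assert np.all(np.abs(periods * 0.01 - 10.0) <= 0.02)

    def test_lorenz_rk4_agrees_with_adaptive_delegate(self):
        model = build(ns.fixtures.lorenz())
        opts = dict(dt=0.001, tspan=(0, 2))
        d1 = integrate(model, SolverOptions(method="rk4", **opts))
        d2 = integrate(model, SolverOptions(method="adaptive", **opts))
        err = max(
            np.abs(d1[k] - d2[k]).max()
            for k in ("pop1_x", "pop1_y", "pop1_z")
        )
        assert err < 1e-4

    def test_non_finite_state_aborts_with_location(self):
        model = build("dx/dt=x*x; x(0)=10")  # finite-time blow-up
        with pytest.raises(SolverError, match="pop1_x"):
            integrate(model, SolverOptions(method="euler", dt=0.1,
                                           tspan=(0, 50)))

    def test_unknown_record_name(self):
        with pytest.raises(SolverError, match="unknown record"):
            integrate(build(DECAY),
                      SolverOptions(dt=0.1, tspan=(0, 1), record=["nope"]))

    def test_record_subset(self):
        model = build("dx/dt=-x; dy/dt=-y; x(0)=1; y(0)=1")
        d = integrate(model, SolverOptions(dt=0.1, tspan=(0, 1),
                                           record=["pop1_y"]))
        assert d.names() == ["pop1_y"]

    @pytest.mark.parametrize("bad", [
        dict(dt=0), dict(tspan=(1, 0)), dict(downsample_factor=0),
        dict(downsample_factor=2.5), dict(method="simplectic"),
    ])
    def test_invalid_options(self, bad):
        with pytest.raises(SolverError):
            SolverOptions(**bad).validated()

    def test_monitored_function_recorded(self):
        model = build("f(x)=x^2; dx/dt=-x; x(0)=2; monitor f")
        d = integrate(model, SolverOptions(method="euler", dt=0.1, tspan=(0, 1)))
        assert np.allclose(d["pop1_f"][:, 0], d["pop1_x"][:, 0] ** 2)


class TestConvergenceOrder:
    """Global error on dx/dt=-x scales as dt^1 / dt^2 / dt^4."""

    @pytest.mark.parametrize("method, order", [
        ("euler", 1), ("rk2", 2), ("rk4", 4),
    ])
    def test_log_log_slope(self, method, order):
        dts = [0.2, 0.1, 0.05, 0.025]
        errs = []
        for dt in dts:
            d = integrate(build(DECAY),
                          SolverOptions(method=method, dt=dt, tspan=(0, 1)))
            errs.append(abs(d["pop1_x"][-1, 0] - np.exp(-1)))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert abs(slope - order) < 0.3


class TestDetectSpikes:
    def test_sinusoid_one_spike_per_cycle(self):
        t = np.arange(0, 1.0, 1e-4)  # seconds
        v = np.sin(2 * np.pi * 40 * t - 0.1)  # small phase offset so the
        # first upward crossing falls strictly inside the window
        (spk,) = detect_spikes(v, 0.0, time=t * 1000)
        assert len(spk) == 40

    def test_constant_below_threshold(self):
        (spk,) = detect_spikes(np.full(1000, -65.0), 0.0)
        assert len(spk) == 0

    @pytest.mark.parametrize("dt", [0.1, 0.01, 0.001])
    def test_ramp_single_crossing_any_dt(self, dt):
        t = np.arange(0, 10, dt)
        (spk,) = detect_spikes(t - 5.0, 0.0, time=t)
        assert len(spk) == 1

    def test_empty_input(self):
        assert detect_spikes(np.empty((0, 2)), 0.0) == [
            pytest.approx(np.array([])), pytest.approx(np.array([]))
        ] or all(len(c) == 0 for c in detect_spikes(np.empty((0, 2)), 0.0))

    def test_per_cell_lists_sorted(self):
        v = np.zeros((100, 2)) - 1
        v[10, 0] = 1; v[50, 0] = 1; v[30, 1] = 1
        out = detect_spikes(v, 0.0)
        assert list(out[0]) == [10, 50] and list(out[1]) == [30]


class TestDownsample:
    def test_factor_one_is_identity(self):
        d = integrate(build(DECAY), SolverOptions(dt=0.01, tspan=(0, 1)))
        assert downsample(d, 1) is d

    def test_index_arithmetic(self):
        d = integrate(build(DECAY), SolverOptions(dt=0.001, tspan=(0, 1)))
        assert len(d.time) == 1001
        d10 = downsample(d, 10)
        assert len(d10.time) == 101
        assert np.array_equal(d10["pop1_x"], d["pop1_x"][::10])

    def test_in_loop_downsampling_matches_posthoc(self):
        a = integrate(build(DECAY),
                      SolverOptions(dt=0.001, tspan=(0, 1),
                                    downsample_factor=10))
        b = downsample(
            integrate(build(DECAY), SolverOptions(dt=0.001, tspan=(0, 1))), 10
        )
        assert np.array_equal(a["pop1_x"], b["pop1_x"])

    def test_spikes_unchanged_by_downsampling(self):
        spec = ns.Specification(populations=[
            ns.PopulationSpec(name="p", size=1, equations="HH",
                              parameters={"Iapp": 10.0})
        ])
        model = build(spec)
        full = integrate(model, SolverOptions(method="rk4", dt=0.01,
                                              tspan=(0, 200)))
        deci = integrate(model, SolverOptions(method="rk4", dt=0.01,
                                              tspan=(0, 200),
                                              downsample_factor=50))
        assert [len(c) for c in full.spikes["p"]] == [
            len(c) for c in deci.spikes["p"]
        ]
        assert downsample(full, 7).spikes["p"][0] == pytest.approx(
            full.spikes["p"][0]
        )

    def test_non_integer_factor_rejected(self):
        d = integrate(build(DECAY), SolverOptions(dt=0.01, tspan=(0, 1)))
        with pytest.raises(ValueError):
            downsample(d, 2.5)


class TestReproducibility:
    def _noisy_model(self):
        return build(ns.Specification(populations=[
            ns.PopulationSpec(name="p", size=5, equations="HH",
                              mechanism_list=["noise"],
                              parameters={"noise_amp": 500.0})
        ]))

    def test_same_seed_bit_identical(self):
        model = self._noisy_model()
        opts = SolverOptions(method="rk2", dt=0.01, tspan=(0, 100), seed=42)
        a, b = integrate(model, opts), integrate(model, opts)
        assert np.array_equal(a["p_v"], b["p_v"])
        assert a.equal(b)

    def test_different_seeds_differ(self):
        model = self._noisy_model()
        a = integrate(model, SolverOptions(method="rk2", dt=0.01,
                                           tspan=(0, 100), seed=1))
        b = integrate(model, SolverOptions(method="rk2", dt=0.01,
                                           tspan=(0, 100), seed=2))
        assert not np.array_equal(a["p_v"], b["p_v"])

    def test_sparse_storage_identical_to_dense(self):
        """Clock-driven synapses: the same connectivity stored sparsely must
        give bit-identical trajectories (storage is a hint, not semantics)."""
        import scipy.sparse as sp

        rng = np.random.default_rng(0)
        mask = (rng.uniform(size=(16, 4)) < 0.3).astype(float)
        spec_dense = ns.fixtures.weak_ping()
        spec_dense.connections[0].parameters["netcon"] = mask
        spec_sparse = ns.fixtures.weak_ping()
        spec_sparse.connections[0].parameters["netcon"] = sp.csr_matrix(mask)
        opts = ns.fixtures.weak_ping_options(seed=7, tspan=(0, 50))
        a = integrate(build(spec_dense), opts)
        b = integrate(build(spec_sparse), opts)
        assert np.array_equal(a["E_v"], b["E_v"])


class TestSpikeBuffers:
    def test_tspike_pre_exposes_last_presynaptic_spike_time(self):
        """A connection mechanism can read the source population's most
        recent spike times; before any spike the buffer is far in the past
        so time-since-spike factors vanish."""
        spec = ns.Specification(
            populations=[
                ns.PopulationSpec(
                    name="S", size=2,
                    equations="dv/dt=(-(v-El)+Iapp)/tau; El=-70; Iapp=40; "
                              "tau=10; v0=[-70,-40]; v(0)=v0; "
                              "if(v>-30)(v=-70); monitor v.spikes(-35)"),
                ns.PopulationSpec(name="T", size=2,
                                  equations="dv/dt=-v/5+@current; v(0)=0"),
            ],
            connections=[ns.ConnectionSpec(source="S", target="T",
                                           mechanism_list=["syn"])],
            mechanisms={
                "syn": "g=1\n"
                       "f(t)=g*exp(-(t-tspike_pre)/20)*(tspike_pre>-1e30)\n"
                       "ds/dt=0\n@current += f"
            },
        )
        flat = build(spec)
        assert flat.spike_buffers == {"S": 1}
        d = integrate(flat, SolverOptions(method="euler", dt=0.05,
                                          tspan=(0, 100)))
        first_s = min(c[0] for c in d.spikes["S"])
        t_v = d["T_v"]
        # target is exactly silent until the first presynaptic spike ...
        assert np.all(t_v[d.time < first_s] == 0)
        # ... and driven afterwards
        assert t_v[d.time > first_s + 1].max() > 0.5


class TestConditionalSemantics:
    def test_declaration_order_matters_and_is_respected(self):
        """Two conditionals writing one state apply in declaration order:
        with the trigger first, the second conditional immediately undoes
        it within the same step; reversed, the set value survives."""
        first = build("dv/dt=0; v(0)=1; if(t>.55)(v=10); if(v>5)(v=-1)")
        second = build("dv/dt=0; v(0)=1; if(v>5)(v=-1); if(t>.55)(v=10)")
        opts = SolverOptions(method="euler", dt=0.1, tspan=(0, 1))
        va = integrate(first, opts)["pop1_v"][-1, 0]
        vb = integrate(second, opts)["pop1_v"][-1, 0]
        assert va == -1.0
        assert vb == 10.0

    def test_actions_see_earlier_actions(self):
        model = build("dv/dt=0; du/dt=0; v(0)=1; u(0)=3; "
                      "if((t>.95)&(t<1.05))(u=u+1; v=u*100)")
        d = integrate(model, SolverOptions(method="euler", dt=0.1, tspan=(0, 1)))
        assert d["pop1_u"][-1, 0] == 4.0
        assert d["pop1_v"][-1, 0] == 400.0  # v assigned from the updated u
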