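"""Sweep expansion, modification routing, study execution and import."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neusim as ns
from neusim.batch import (
    SweepPlan,
    VaryTriplet,
    apply_modifications,
    expand_vary,
    import_results,
    run_batch,
    simulation_seed,
    zipped_plan,
)
from neusim.errors import ModelError


def _izh_spec(iapp=100.0):
    return ns.fixtures.izhikevich_from_library(iapp=iapp)


FAST = ns.SolverOptions(method="euler", dt=0.01, tspan=(0, 100))


class TestExpandVary:
    def test_two_by_three_gives_nine(self):
        plan = expand_vary([
            ("E", "Iapp", (0, 5, 10)),
            ("I->E", "tauD", (5, 10, 20)),
        ])
        assert len(plan) == 9
        assert plan.labels == ["E.Iapp", "I->E.tauD"]

    def test_single_value_single_set(self):
        assert len(expand_vary([("p", "a", (1,))])) == 1

    def test_cardinality_is_product(self):
        plan = expand_vary([
            ("a", "x", (1, 2)), ("b", "y", (1, 2, 3)), ("c", "z", (1, 2, 3, 4))
        ])
        # brute-force enumeration oracle
        count = sum(1 for _ in range(2) for _ in range(3) for _ in range(4))
        assert len(plan) == count == 24

    def test_first_triplet_varies_slowest(self):
        plan = expand_vary([("p", "a", (1, 2)), ("p", "b", (10, 20))])
        a_values = [ms[0][2] for ms in plan.modifications]
        assert a_values == [1, 1, 2, 2]

    def test_empty_triplets_give_base_model(self):
        plan = expand_vary([])
        assert plan.modifications == [[]]

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            VaryTriplet("p", "a", ())

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 5), min_size=0, max_size=4))
    def test_cardinality_property(self, sizes):
        triplets = [
            (f"p{i}", "a", tuple(range(n))) for i, n in enumerate(sizes)
        ]
        expected = int(np.prod(sizes)) if sizes else 1
        assert len(expand_vary(triplets)) == expected

    def test_zipped_form(self):
        plan = zipped_plan([
            [("p", "a", 1), ("p", "b", 10)],
            [("p", "a", 2), ("p", "b", 20)],
        ])
        assert len(plan) == 2
        assert plan.varied(1) == {"p.a": 2, "p.b": 20}


class TestApplyModifications:
    def test_population_parameter_with_copy_semantics(self):
        base = ns.standardize(ns.fixtures.weak_ping())
        out = apply_modifications(base, [("E", "Iapp", 10)])
        assert out.population("E").parameters["Iapp"] == 10
        assert "Iapp" not in base.population("E").parameters

    def test_connection_routing(self):
        out = apply_modifications(ns.fixtures.weak_ping(),
                                  [("I->E", "tauD", 5)])
        assert out.connection("I", "E").parameters["tauD"] == 5
        assert "tauD" not in out.connection("E", "I").parameters

    def test_size_is_a_modifiable_specifier(self):
        out = apply_modifications(ns.fixtures.weak_ping(), [("E", "size", 4)])
        flat = ns.build(out)
        assert flat.state_layout["E_v"] == ("E", 4)

    def test_unknown_object(self):
        with pytest.raises(KeyError):
            apply_modifications(_izh_spec(), [("ghost", "Iapp", 1)])

    def test_unknown_parameter_caught_at_build(self):
        out = apply_modifications(_izh_spec(), [("pop1", "bogus", 1)])
        with pytest.raises(ModelError):
            ns.build(out)


class TestRunBatch:
    def test_study_layout_and_hooks(self, tmp_path):
        plan = expand_vary([("pop1", "Iapp", (80, 120, 160))])
        res = run_batch(_izh_spec(), plan, FAST, hooks=["firing_rate"],
                        study_dir=tmp_path / "study")
        assert len(res) == 3
        assert all(e.error is None for e in res.entries)
        index = json.loads((tmp_path / "study" / "index.json").read_text())
        assert len(index["simulations"]) == 3
        sim0 = tmp_path / "study" / index["simulations"][0]["directory"]
        assert (sim0 / "data.h5").exists()
        assert (sim0 / "solve.py").exists()
        assert (sim0 / "results__firing_rate.json").exists()
        assert (tmp_path / "study" / "manifest.txt").exists()

    def test_empty_plan_runs_base_model(self):
        res = run_batch(_izh_spec(), expand_vary([]), FAST)
        assert len(res) == 1
        assert res[0].varied == {}

    def test_failing_hook_recorded_batch_continues(self):
        def bad_hook(data):
            raise RuntimeError("boom")

        plan = expand_vary([("pop1", "Iapp", (80, 120))])
        res = run_batch(_izh_spec(), plan, FAST, hooks=[bad_hook, "firing_rate"])
        for e in res.entries:
            assert e.error is None
            assert "error" in e.results["bad_hook"]
            assert "pop1_mean_rate" in e.results["firing_rate"]

    def test_failing_simulation_flagged_batch_continues(self, tmp_path):
        plan = zipped_plan([[("pop1", "bogus_param", 1)], []])
        res = run_batch(_izh_spec(), plan, FAST, study_dir=tmp_path / "s")
        assert res[0].error is not None
        assert res[1].error is None
        imported = import_results(tmp_path / "s", "data")
        assert imported[0].error is not None
        assert imported[1].data is not None

    def test_existing_study_dir_needs_overwrite(self, tmp_path):
        d = tmp_path / "study"
        run_batch(_izh_spec(), expand_vary([]), FAST, study_dir=d)
        with pytest.raises(FileExistsError):
            run_batch(_izh_spec(), expand_vary([]), FAST, study_dir=d)
        run_batch(_izh_spec(), expand_vary([]), FAST, study_dir=d,
                  overwrite=True)

    def test_serial_vs_parallel_identical_for_stochastic_batch(self):
        spec = ns.standardize(ns.fixtures.izhikevich(stochastic=True))
        plan = expand_vary([("pop1", "Iapp", (60, 90, 120))])
        opts = ns.SolverOptions(method="euler", dt=0.01, tspan=(0, 150), seed=5)
        serial = run_batch(spec, plan, opts)
        par = run_batch(spec, plan, opts, parallel=2)
        for a, b in zip(serial.entries, par.entries):
            assert a.seed == b.seed
            assert a.data.equal(b.data)

    def test_cardinality_invariant(self, tmp_path):
        plan = expand_vary([("pop1", "Iapp", (80, 100)),
                            ("pop1", "a", (0.02, 0.03))])
        res = run_batch(_izh_spec(), plan, FAST, study_dir=tmp_path / "s")
        assert len(res) == len(plan) == 4

    def test_per_simulation_seeds_deterministic(self):
        seeds = [simulation_seed(5, k) for k in range(4)]
        assert seeds == [simulation_seed(5, k) for k in range(4)]
        assert len(set(seeds)) == 4
        assert all(0 <= s < 2**31 for s in seeds)


class TestImport:
    def test_round_trip_equals_in_memory(self, tmp_path):
        plan = expand_vary([("pop1", "Iapp", (90, 130))])
        res = run_batch(_izh_spec(), plan, FAST, study_dir=tmp_path / "s")
        imported = import_results(tmp_path / "s", "data")
        assert len(imported) == len(res)
        for a, b in zip(res.entries, imported.entries):
            assert b.data.equal(a.data)
            assert b.varied == a.varied

    def test_import_is_self_describing(self, tmp_path):
        """A study re-run from its directory alone reproduces the data."""
        from neusim.batch import run_indexed

        plan = expand_vary([("pop1", "Iapp", (110,))])
        res = run_batch(_izh_spec(), plan, FAST, hooks=["firing_rate"],
                        study_dir=tmp_path / "s")
        before = import_results(tmp_path / "s", "data")[0].data
        run_indexed(tmp_path / "s", 0)
        after = import_results(tmp_path / "s", "data")[0].data
        assert after.equal(before)

    def test_missing_index_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            import_results(tmp_path)

    def test_corrupt_index_errors(self, tmp_path):
        (tmp_path / "index.json").write_text("{not json")
        with pytest.raises(ModelError, match="corrupt"):
            import_results(tmp_path)
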