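"""Hybrid execution: calibration, result determinism, step order, sweeps."""

import pytest

from zukerfold import (
    AllocationPlan,
    WorkerProfile,
    calibrate,
    fill_matrices,
    generate_random_sequences,
    make_plan,
    run_hybrid,
    simple_params,
    sweep_ratio,
    traceback,
)


@pytest.fixture(scope="module")
def workload():
    return generate_random_sequences(12, 20, seed=42)


@pytest.fixture(scope="module")
def profiles():
    return {
        "slow": WorkerProfile("slow", {20: 8.0}, capacity=2),
        "fast": WorkerProfile("fast", {20: 1.0}, capacity=4),
    }


def sequential_results(seqs, params):
    out = {}
    for seq in seqs:
        m = fill_matrices(seq, params)
        out[seq.id] = (m.mfe(), traceback(m, seq, params))
    return out


class TestCalibrate:
    def test_simulated_cost_model(self, simple):
        seqs = generate_random_sequences(3, 10, seed=1)
        prof = calibrate("sim", seqs, simple, cost_coeff=2.0)
        assert prof.t_per_seq == {10: 2000.0}

    def test_simulated_speedup_regime(self, simple):
        # two classes whose cost constants differ 16x show speedup 16
        seqs = generate_random_sequences(2, 120, seed=1)
        slow = calibrate("cpu", seqs, simple, cost_coeff=16e-6)
        fast = calibrate("gpu", seqs, simple, cost_coeff=1e-6)
        assert slow.time_for(120) / fast.time_for(120) == pytest.approx(16.0)

    def test_real_mode_times_are_positive(self, simple):
        seqs = generate_random_sequences(2, 15, seed=2)
        prof = calibrate("real", seqs, simple, mode="real")
        assert all(t > 0 for t in prof.t_per_seq.values())

    def test_empty_samples_rejected(self, simple):
        with pytest.raises(ValueError):
            calibrate("x", [], simple)


class TestRunHybrid:
    def test_results_equal_sequential(self, workload, profiles, simple):
        plan = make_plan(len(workload), 8.0, 1.0)
        report = run_hybrid(workload, simple, plan, profiles=profiles)
        expected = sequential_results(workload, simple)
        assert report.energies() == {k: e for k, (e, _) in expected.items()}
        assert {k: s for k, (_, s) in report.results.items()} == {
            k: s for k, (_, s) in expected.items()
        }

    def test_all_to_one_class(self, workload, profiles, simple):
        plan = AllocationPlan(
            N=len(workload),
            batches={"slow": list(range(1, len(workload) + 1)), "fast": []},
        )
        report = run_hybrid(workload, simple, plan, profiles=profiles)
        assert report.energies() == {
            k: e for k, (e, _) in sequential_results(workload, simple).items()
        }

    def test_batch_order_does_not_change_results(self, workload, profiles, simple):
        N = len(workload)
        base = make_plan(N, 8.0, 1.0)
        shuffled = AllocationPlan(
            N=N,
            batches={
                "slow": list(reversed(base.batches["slow"])),
                "fast": list(reversed(base.batches["fast"])),
            },
        )
        a = run_hybrid(workload, simple, base, profiles=profiles)
        b = run_hybrid(workload, simple, shuffled, profiles=profiles)
        assert a.energies() == b.energies()

    def test_real_mode_matches_simulated_results(self, workload, simple):
        plan = make_plan(len(workload), 8.0, 1.0)
        sim = run_hybrid(
            workload, simple, plan,
            profiles={
                "slow": WorkerProfile("slow", {20: 8.0}),
                "fast": WorkerProfile("fast", {20: 1.0}),
            },
        )
        real = run_hybrid(workload, simple, plan, mode="real",
                          pool_sizes={"fast": 3, "slow": 1})
        assert sim.energies() == real.energies()

    def test_step_sequencing(self, workload, profiles, simple):
        """Dispatch fast batch -> process slow batch -> collect -> traceback."""
        plan = make_plan(len(workload), 8.0, 1.0)
        report = run_hybrid(workload, simple, plan, profiles=profiles)
        kinds = [kind for kind, _ in report.events]
        assert kinds == ["dispatch", "process", "collect", "traceback"]

    def test_virtual_clock_imbalance_bounded(self, simple):
        # constant per-task times: the boundary leaves at most one task
        # of imbalance between the classes
        N, t_slow, t_fast = 200, 5.0, 1.0
        seqs = generate_random_sequences(N, 8, seed=7)
        plan = make_plan(N, t_slow, t_fast)
        report = run_hybrid(
            seqs, simple, plan,
            profiles={
                "slow": WorkerProfile("slow", {8: t_slow}),
                "fast": WorkerProfile("fast", {8: t_fast}),
            },
        )
        assert report.imbalance <= max(t_slow, t_fast)

    def test_plan_mismatch_rejected(self, workload, profiles, simple):
        plan = make_plan(len(workload) + 1, 8.0, 1.0)
        with pytest.raises(ValueError):
            run_hybrid(workload, simple, plan, profiles=profiles)


class TestSweepRatio:
    GRID = [x / 100 for x in range(2, 31, 2)]

    def test_equal_speeds_favor_even_split(self):
        slow = WorkerProfile("slow", {100: 2.0})
        fast = WorkerProfile("fast", {100: 2.0})
        grid = [x / 100 for x in range(2, 99, 2)]
        rows = sweep_ratio((slow, fast), 1000, grid, length=100)
        best_ratio = min(rows, key=lambda r: r[1])[0]
        assert best_ratio == 0.50

    def test_makespan_curve_unimodal(self):
        slow = WorkerProfile("slow", {100: 19.059})
        fast = WorkerProfile("fast", {100: 3.270})
        rows = sweep_ratio((slow, fast), 20000, self.GRID, length=100)
        values = [ms for _, ms in rows]
        trough = values.index(min(values))
        assert all(values[i] >= values[i + 1] for i in range(trough))
        assert all(values[i] <= values[i + 1] for i in range(trough, len(values) - 1))

    def test_invalid_ratio_rejected(self):
        slow = WorkerProfile("slow", {100: 2.0})
        fast = WorkerProfile("fast", {100: 1.0})
        with pytest.raises(ValueError):
            sweep_ratio((slow, fast), 100, [0.0], length=100)
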