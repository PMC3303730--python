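"""End-to-end simulated hybrid run plus a ratio sweep.

A synthetic batch is split between two worker classes by the analytic
boundary; the virtual-clock executor then folds every sequence and reports
per-class busy times.  A sweep over slow-class shares shows the makespan
minimum sitting at the analytic ratio.

Run with:  python examples/hybrid_demo.py
"""

from zukerfold import (
    WorkerProfile,
    generate_random_sequences,
    make_plan,
    run_hybrid,
    simple_params,
    sweep_ratio,
)

T_SLOW, T_FAST = 19.059, 3.270  # per-sequence ms for the two classes


def main():
    seqs = generate_random_sequences(40, 30, seed=7)
    profiles = {
        "slow": WorkerProfile("slow", {30: T_SLOW}),
        "fast": WorkerProfile("fast", {30: T_FAST}),
    }
    plan = make_plan(len(seqs), T_SLOW, T_FAST)
    print(f"plan: K = {plan.K:.2f}, ratio = {100 * plan.ratio:.2f}%, "
          f"B = {plan.B} of {plan.N}")

    report = run_hybrid(seqs, simple_params(), plan, profiles=profiles)
    for name, busy in sorted(report.busy.items()):
        print(f"  {name}: busy {busy:.2f} ms")
    print(f"  makespan {report.makespan:.2f} ms, "
          f"imbalance {report.imbalance:.2f} ms")
    first = seqs[0].id
    energy, structure = report.results[first]
    print(f"  e.g. {first}: dG = {energy / 10:.1f}")

    print("\nsweep over slow-class share (N = 20000, L = 221):")
    grid = [x / 100 for x in range(2, 31, 2)]
    rows = sweep_ratio(
        (WorkerProfile("slow", {221: T_SLOW}),
         WorkerProfile("fast", {221: T_FAST})),
        20000, grid, length=221,
    )
    best = min(rows, key=lambda r: r[1])[0]
    for ratio, makespan in rows:
        mark = "  <- minimum" if ratio == best else ""
        print(f"  {100 * ratio:5.1f}%  {makespan:12.1f} ms{mark}")


if __name__ == "__main__":
    main()
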