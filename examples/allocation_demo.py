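"""Static task allocation between a slow and a fast worker class.

Given measured per-sequence fill times on each class, the allocation rule
computes the speedup K = t_slow / t_fast, the slow-class share
1 / (K + 1), and the integer boundary B that minimizes the makespan of an
N-sequence batch.  The numbers below are the published per-sequence times
for four benchmark length groups.

Run with:  python examples/allocation_demo.py
"""

from zukerfold import allocation_ratio, boundary, speedup

GROUPS = {
    "A (L=68)": (1.081, 0.068),
    "B (L=120)": (4.737, 0.293),
    "C (L=154)": (8.424, 0.754),
    "D (L=221)": (19.059, 3.270),
}
N = 20000


def main():
    print(f"{'group':<10} {'K':>7} {'ratio':>8} {'B':>6}  (N = {N})")
    for name, (t_slow, t_fast) in GROUPS.items():
        k = speedup(t_slow, t_fast)
        r = allocation_ratio(k)
        b = boundary(N, t_slow, t_fast)
        print(f"{name:<10} {k:7.2f} {100 * r:7.2f}% {b:6d}")


if __name__ == "__main__":
    main()
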