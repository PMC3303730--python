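"""Recurrence fill: worked examples, evaluation orders, matrix invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zukerfold import (
    INF,
    RnaSequence,
    fill_matrices,
    generate_random_sequences,
    validate_schedule,
    wavefront_order,
)
from zukerfold.dp import (
    ConfigurationError,
    compute_V,
    compute_VBI,
    compute_VM,
    compute_W,
    compute_WM,
)
from zukerfold.energy import INF_CAP


def finite(x):
    return int(x) < INF_CAP


class TestWorkedExamples:
    def test_no_pairs_means_zero_energy(self, params):
        seq = RnaSequence("a", "AAAA")
        m = fill_matrices(seq, params)
        assert list(m.W) == [0, 0, 0, 0, 0]
        assert not any(
            finite(m.V[i, j]) for i in range(1, 5) for j in range(i + 1, 5)
        )

    def test_triple_gc_hairpin(self, nussinov, hairpin_seq):
        # three nested G-C pairs, one per -10 deci-units
        assert fill_matrices(hairpin_seq, nussinov).mfe() == -30

    def test_min_hairpin_blocks_short_folds(self, nussinov):
        # GCGC admits G-C pairs but no geometry with a >=3 loop
        assert fill_matrices(RnaSequence("s", "GCGC"), nussinov).mfe() == 0

    def test_two_hairpin_multiloop(self, nussinov):
        # G(GGGAAACCC)(GGGAAACCC)C: enclosing pair + two 3-pair hairpins
        seq = RnaSequence("ml", "G" + "GGGAAACCC" * 2 + "C")
        m = fill_matrices(seq, nussinov)
        assert m.mfe() == -70
        # the enclosed-interval bifurcation equals the branch-energy sum
        assert int(m.VM[2, 19]) == -60


class TestMatrixInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_structural_invariants(self, params, seed):
        seq = generate_random_sequences(1, 25, seed=seed)[0]
        m = fill_matrices(seq, params)
        n = seq.n
        assert m.W[0] == 0
        assert all(m.W[j] <= m.W[j - 1] for j in range(1, n + 1))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if (seq[i], seq[j]) not in params.pairs:
                    assert not finite(m.V[i, j])
                if j - i < params.min_hairpin + 1:
                    assert not finite(m.V[i, j])
                assert m.WM[i, j] <= m.V[i, j] + params.multibranch_branch
                assert m.WM[i, j] <= m.VM[i, j]

    @pytest.mark.parametrize("seed", range(3))
    def test_recurrence_evaluators_match_fill(self, simple, seed):
        seq = generate_random_sequences(1, 18, seed=seed)[0]
        m = fill_matrices(seq, simple)
        for j in range(1, seq.n + 1):
            assert compute_W(j, m) == m.W[j]
        for i in range(1, seq.n + 1):
            for j in range(i + 1, seq.n + 1):
                assert compute_V(i, j, seq, simple, m) == m.V[i, j]
                assert compute_VBI(i, j, seq, simple, m) == m.VBI[i, j]
                assert compute_WM(i, j, m, simple) == min(m.WM[i, j], INF)

    def test_interior_bound_inactive_on_short_sequences(self, simple):
        # when no loop can exceed the span bound, bounding changes nothing
        unbounded = dataclasses.replace(simple, max_internal_span=1000)
        for seed in range(5):
            seq = generate_random_sequences(1, 20, seed=seed)[0]
            a = fill_matrices(seq, simple)
            b = fill_matrices(seq, unbounded)
            assert (a.V == b.V).all() and (a.W == b.W).all()


class TestStrategies:
    @pytest.mark.parametrize("strategy,tile", [
        ("wavefront", 1), ("wavefront", 4), ("tiled", 2), ("tiled", 8),
    ])
    def test_fill_orders_bit_identical(self, simple, strategy, tile):
        for seed in range(3):
            seq = generate_random_sequences(1, 32, seed=seed)[0]
            ref = fill_matrices(seq, simple, strategy="naive")
            m = fill_matrices(seq, simple, strategy=strategy, tile_size=tile)
            for name in ("W", "V", "VBI", "VM", "WM"):
                assert (getattr(m, name) == getattr(ref, name)).all()

    def test_vm_strategies_cross_check(self, simple):
        # the scalar loop is the reference for the vectorised and chunked forms
        for seed in range(5):
            seq = generate_random_sequences(1, 30, seed=seed)[0]
            m = fill_matrices(seq, simple)
            for i in range(1, seq.n + 1):
                for j in range(i + 2, seq.n + 1):
                    ref = compute_VM(i, j, m, strategy="naive")
                    assert compute_VM(i, j, m, strategy="two_step") == ref
                    assert compute_VM(i, j, m, strategy="tiled", tile_size=4) == ref

    def test_unknown_strategy_rejected(self, simple, hairpin_seq):
        with pytest.raises(ConfigurationError):
            fill_matrices(hairpin_seq, simple, strategy="zigzag")
        m = fill_matrices(hairpin_seq, simple)
        with pytest.raises(ConfigurationError):
            compute_VM(1, 9, m, strategy="warp")


class TestWavefrontOrder:
    def test_unit_tiles_are_anti_diagonals(self):
        sched = wavefront_order(4, tile_size=1)
        assert [list(p) for p in sched.phases] == [
            [(1, 2), (2, 3), (3, 4)],
            [(1, 3), (2, 4)],
            [(1, 4)],
        ]

    @pytest.mark.parametrize("n,tile", [(1, 1), (7, 2), (16, 4), (33, 8)])
    def test_schedule_covers_triangle(self, n, tile):
        sched = wavefront_order(n, tile_size=tile)
        assert sum(len(p) for p in sched.phases) == n * (n - 1) // 2

    @settings(max_examples=30, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=64),
        tile=st.sampled_from([1, 2, 4, 8]),
    )
    def test_dependencies_precede_every_cell(self, n, tile):
        sched = wavefront_order(n, tile_size=tile)
        assert validate_schedule(sched, exhaustive=(n <= 16))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            wavefront_order(0)
        with pytest.raises(ValueError):
            wavefront_order(5, tile_size=0)


def test_matrix_dump_round_trips_values(tmp_path, simple, hairpin_seq):
    from zukerfold.dp import dump_matrices

    m = fill_matrices(hairpin_seq, simple)
    out = tmp_path / "dump.txt"
    dump_matrices(m, out)
    text = out.read_text()
    assert f"9 {int(m.W[9])}" in text
    assert "1 9 " in text
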