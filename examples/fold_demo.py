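"""Fold a couple of short RNAs and print their minimum-free-energy structures.

Run with:  python examples/fold_demo.py
"""

from zukerfold import (
    RnaSequence,
    fill_matrices,
    format_energy,
    simple_params,
    to_dot_bracket,
    traceback,
)

SEQUENCES = [
    RnaSequence("hairpin", "GGGAAACCC"),
    RnaSequence.from_raw("trna_like",
                         "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUC"
                         "CUGUGUUCGAUCCACAGAAUUCGCACCA"),
]


def main():
    params = simple_params()
    for seq in SEQUENCES:
        matrices = fill_matrices(seq, params)
        structure = traceback(matrices, seq, params)
        print(f">{seq.id}  (n = {seq.n})")
        print(seq.bases)
        print(f"{to_dot_bracket(structure)}  dG = {format_energy(matrices.mfe())}")
        print()


if __name__ == "__main__":
    main()
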