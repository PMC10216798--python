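"""The 24-symbol alignment alphabet.

Twenty standard amino acids, the gap character ``-``, and the three
ambiguity codes found in public Ig sequence records: ``B`` (Asn or Asp),
``Z`` (Gln or Glu) and ``X`` (any amino acid).
"""

from __future__ import annotations

AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY: tuple[str, ...] = ("B", "Z", "X")
GAP: str = "-"

#: Fixed symbol order used everywhere a 24-wide axis appears (one-hot
#: blocks, frequency matrices): 20 amino acids alphabetically, then the
#: ambiguity codes, then the gap.
ALPHABET: tuple[str, ...] = AMINO_ACIDS + AMBIGUITY + (GAP,)

ALPHABET_SET = frozenset(ALPHABET)
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}

#: Residues each ambiguity code may stand for; used when a scale or a
#: column distribution needs a concrete amino-acid value.
AMBIGUITY_MEMBERS: dict[str, tuple[str, ...]] = {
    "B": ("N", "D"),
    "Z": ("Q", "E"),
    "X": AMINO_ACIDS,
}
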