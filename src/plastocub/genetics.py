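"""Genetic-code helpers for the bacterial/plant-plastid code (translation table 11).

Table 11 translates identically to the standard code; it differs only in the
set of permitted initiation codons. The synonymous-family structure (9 two-fold,
1 three-fold, 5 four-fold and 3 six-fold families plus Met and Trp) therefore
matches Wright's classic degeneracy classes.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

STOP_CODONS = frozenset(_TABLE11.stop_codons)  # {TAA, TAG, TGA}
START_CODONS_TABLE11 = frozenset({"ATG", "GTG", "TTG"})

#: codon -> one-letter amino acid, stops excluded
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)

#: amino acid -> sorted tuple of its codons (61 sense codons)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: synonymous family size per amino acid (1, 2, 3, 4 or 6)
FAMILY_SIZE: dict[str, int] = {aa: len(c) for aa, c in AA_TO_CODONS.items()}

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(COMPLEMENT)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def codons_of(seq: str) -> tuple[str, ...]:
    """Split an in-frame DNA string into codons; length must be a multiple of 3."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return tuple(seq[i : i + 3] for i in range(0, len(seq), 3))


def translate(seq: str) -> str:
    """Translate an in-frame DNA string under table 11; stops become '*'."""
    out = []
    for codon in codons_of(seq):
        if codon in STOP_CODONS:
            out.append("*")
        elif codon in CODON_TO_AA:
            out.append(CODON_TO_AA[codon])
        else:
            raise ValueError(f"untranslatable codon {codon!r}")
    return "".join(out)
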