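"""Genetic-code bookkeeping shared by every analysis stage.

The standard genetic code (NCBI translation table 1) is used throughout;
at the level of codon->amino-acid assignments it is identical to the
plastid/bacterial table 11, so chloroplast CDS are handled correctly.
Synonymous families follow the classical codon-usage convention: Leu, Ser
and Arg are single six-codon families, the three stop codons form one
three-member family, and Met/Trp are one-codon families.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "TCAG"

#: All 64 codons in TCAG enumeration order.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons.
GENETIC_CODE: dict[str, str] = {c: _table.forward_table.get(c, "*") for c in CODONS}

STOP_CODONS: tuple[str, ...] = tuple(c for c in CODONS if GENETIC_CODE[c] == "*")
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if GENETIC_CODE[c] != "*")
START_CODON = "ATG"

#: amino acid (or '*') -> tuple of synonymous codons, in CODONS order.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    FAMILIES.setdefault(GENETIC_CODE[_codon], ())
    FAMILIES[GENETIC_CODE[_codon]] += (_codon,)

#: amino acid (or '*') -> family size n_i (1..6; stop class is 3).
FAMILY_SIZE: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: codon -> its family label (amino acid letter or '*').
FAMILY_OF: dict[str, str] = dict(GENETIC_CODE)

#: The 59 degenerate sense codons: 61 sense codons minus ATG (Met) and TGG (Trp).
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if FAMILY_SIZE[GENETIC_CODE[c]] > 1
)

#: ENC degeneracy classes: class size k -> amino acids whose family has k codons
#: (sense families only; singletons Met/Trp and the stop family are excluded).
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _n in FAMILY_SIZE.items():
    if _aa != "*" and _n > 1:
        DEGENERACY_CLASSES.setdefault(_n, ())
        DEGENERACY_CLASSES[_n] += (_aa,)

#: Number of families per degeneracy class; the Wright combination
#: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 follows from these counts.
CLASS_SIZES: dict[int, int] = {k: len(v) for k, v in DEGENERACY_CLASSES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; stops render as '*'.

    Codons containing non-ACGT letters render as 'X'.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return "".join(
        GENETIC_CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3)
    )
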