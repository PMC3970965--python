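"""Standard genetic code helpers shared across modules.

The translation table is taken from Biopython's standard (NCBI table 1)
codon table; only the canonical DNA alphabet is accepted.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))  # 61 codons
BASES = "ACGT"

_AA = dict(_TABLE.forward_table)


def amino_acid(codon: str) -> str:
    """One-letter amino acid for a sense codon; ``*`` for a stop."""
    if codon in STOP_CODONS:
        return "*"
    try:
        return _AA[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def single_nt_neighbours(codon: str, position: int) -> list[str]:
    """The three codons reachable by mutating ``position`` (0-based)."""
    return [
        codon[:position] + b + codon[position + 1 :]
        for b in BASES
        if b != codon[position]
    ]


@lru_cache(maxsize=None)
def classify_changes(codon: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Partition the nine single-nucleotide mutants of a sense codon.

    Returns ``(synonymous, nonsynonymous)`` target codons.  Mutations that
    create a stop codon are classed nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no substitution classes: {codon}")
    aa = amino_acid(codon)
    syn: list[str] = []
    nonsyn: list[str] = []
    for pos in range(3):
        for mutant in single_nt_neighbours(codon, pos):
            if mutant in STOP_CODONS:
                nonsyn.append(mutant)
            elif amino_acid(mutant) == aa:
                syn.append(mutant)
            else:
                nonsyn.append(mutant)
    return tuple(syn), tuple(nonsyn)


def translate_codons(codons: list[str] | tuple[str, ...]) -> str:
    return "".join(amino_acid(c) for c in codons)


ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))
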