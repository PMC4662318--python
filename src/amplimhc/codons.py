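"""Genetic-code helpers shared by the simulator, the allele caller and the
selection statistics.

All coordinates in this package are frame 1 on the 195-bp (65-codon) DRB
exon-2 fragment; codon indices are 1-based.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the standard code

BASES = "ACGT"

#: codon -> amino acid (one letter), sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: Default antigen-binding-site mask: the 21 HLA-DR1 beta-chain
#: peptide-contact residues (Brown-homology) that fall inside a 65-codon
#: fragment whose first codon corresponds to beta-chain position 26.
#: 1-based codon indices on the fragment.
DEFAULT_ABS_MASK: frozenset[int] = frozenset(
    {1, 3, 5, 7, 12, 13, 22, 31, 32, 35, 36, 40, 42, 43, 45, 46, 49, 53, 56, 57, 61}
)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def codons_of(seq: str) -> list[str]:
    """Split a frame-1 nucleotide sequence into codons (length must be %3==0)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(seq: str) -> str:
    """Frame-1 standard-code translation; stop codons become '*'.

    Gap codons ('---') translate to '-'; codons containing a partial gap or
    an ambiguity code translate to 'X'.
    """
    out = []
    for codon in codons_of(seq.upper()):
        if codon == "---":
            out.append("-")
        elif codon in CODON_TO_AA:
            out.append(CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def has_internal_stop(seq: str) -> bool:
    aa = translate(seq)
    return "*" in aa[:-1] or (len(aa) > 0 and aa[-1] == "*")


def is_synonymous(c1: str, c2: str) -> bool:
    """True if two sense codons encode the same amino acid."""
    return CODON_TO_AA[c1] == CODON_TO_AA[c2]
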