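"""Codon translation and amino-acid polarity classes."""

from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

# three-class polarity scheme: nonpolar / polar uncharged / charged
_POLARITY = {
    "nonpolar": "GAVLIPFMWC",
    "polar": "STYNQ",
    "charged": "DEKRH",
}
POLARITY_CLASS: dict[str, str] = {
    aa: cls for cls, aas in _POLARITY.items() for aa in aas
}


def translate_codon(codon: str) -> str:
    """Translate one codon; returns '*' for stops, 'X' if ambiguous."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    return CODON_TABLE.get(codon, "X")


def polarity_differs(aa1: str, aa2: str) -> bool | None:
    """True if the two residues fall in different polarity classes.

    Returns None when either residue has no class (stop or ambiguous).
    """
    c1 = POLARITY_CLASS.get(aa1)
    c2 = POLARITY_CLASS.get(aa2)
    if c1 is None or c2 is None:
        return None
    return c1 != c2
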