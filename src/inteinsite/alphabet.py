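"""Amino-acid alphabet constants shared across the package.

All per-position probability vectors and one-hot blocks use the fixed
alphabetical one-letter ordering ``AMINO_ACIDS``; any consistent ordering
would do, fixing one makes SVM weights comparable across runs.
"""

#: The 20 standard residues, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Index of each standard residue within :data:`AMINO_ACIDS`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues that can act as the +1 nucleophile of an intein splice site.
NUCLEOPHILES: frozenset[str] = frozenset("CST")

#: Unknown / non-standard residue placeholder.
UNKNOWN: str = "X"


def canonical_residue(aa: str) -> str:
    """Map any residue letter to a standard residue or ``X``."""
    aa = aa.upper()
    return aa if aa in AA_INDEX else UNKNOWN
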