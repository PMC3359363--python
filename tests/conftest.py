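"""Shared fixtures: programmatic builders for the external text formats."""

from __future__ import annotations

import numpy as np
import pytest

from inteinsite import ExteinRecord, load_xynb_table

#: Column order of blastpgp ASCII PSSM files.
BLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def make_pssm_text(rows: list[tuple[str, dict[str, float]]]) -> str:
    """Build a blastpgp ``-Q`` style ASCII PSSM.

    ``rows`` holds (residue, {aa: weighted-observed-percentage}) per
    position; unmentioned amino acids get 0.  Log-odds are written as 0.
    """
    header = (
        "\n"
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    cols = "            " + "   ".join(BLAST_ORDER) + "   " + "   ".join(BLAST_ORDER)
    lines = [header, cols]
    for i, (aa, pct) in enumerate(rows, start=1):
        logodds = " ".join(["0"] * 20)
        pcts = " ".join(str(int(pct.get(a, 0))) for a in BLAST_ORDER)
        lines.append(f"{i:5d} {aa}   {logodds}   {pcts}  0.00 0.00")
    lines.append("")
    lines.append("                      K         Lambda")
    lines.append("Standard Ungapped    0.1347     0.3176")
    return "\n".join(lines)


def make_pdb_text(
    residues: list[tuple[int, str, tuple, tuple | None]], chain: str = "A"
) -> str:
    """PDB ATOM records from (resnum, resname, ca_xyz, cb_xyz-or-None)."""
    lines = []
    serial = 1
    for resnum, resname, ca, cb in residues:
        for name, xyz in (("CA", ca), ("CB", cb)):
            if xyz is None:
                continue
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  {name:<4s}{resname:>3s} {chain}"
                f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}"
                f"{0.00:6.2f}          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_stride_text(codes: list[tuple[int, str]]) -> str:
    """Stride ASG records from (resnum, one-letter code) pairs."""
    names = {"H": "AlphaHelix", "E": "Strand", "C": "Coil", "T": "Turn"}
    lines = [
        "REM  -------------------- Secondary structure summary ----------",
        "REM",
    ]
    for resnum, code in codes:
        lines.append(
            f"ASG  ALA A {resnum:4d} {resnum:4d}    {code}   "
            f"{names.get(code, 'Coil'):>11s}   -60.00    -45.00      30.0"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def xynb_rows():
    return load_xynb_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_extein(rng: np.random.Generator, length: int, ident: str = "rnd") -> ExteinRecord:
    """Uniform-composition random extein over the 20 standard residues."""
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return ExteinRecord(id=ident, sequence=seq)
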