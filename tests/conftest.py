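"""Shared fixtures: tiny hand-written PDB texts and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from conforma.structio import AtomRecord, Residue, Structure

# A small hand-written PDB: three protein residues (with an altloc pair on
# one CA), a water, an estradiol HETATM, and a second MODEL that must be
# ignored.  Column layout follows the fixed-column ATOM record format.
TINY_PDB = """\
HEADER    SYNTHETIC TEST STRUCTURE
MODEL        1
ATOM      1  N   ALA A  10      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A  10      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A  10      10.729   6.768  -4.123  1.00 10.00           C
ATOM      4  O   ALA A  10       9.580   7.104  -4.423  1.00 10.00           O
ATOM      5  N   GLY A  11      11.255   7.002  -2.915  1.00 10.00           N
ATOM      6  CA AGLY A  11      10.550   7.699  -1.838  0.60 10.00           C
ATOM      7  CA BGLY A  11      10.450   7.599  -1.738  0.40 10.00           C
ATOM      8  C   GLY A  11      11.163   7.431  -0.466  1.00 10.00           C
ATOM      9  O   GLY A  11      12.361   7.177  -0.340  1.00 10.00           O
ATOM     10  N   SER A  12      10.327   7.499   0.569  1.00 10.00           N
ATOM     11  CA  SER A  12      10.783   7.264   1.938  1.00 10.00           C
ATOM     12  C   SER A  12       9.810   6.349   2.679  1.00 10.00           C
ATOM     13  O   SER A  12       8.599   6.410   2.448  1.00 10.00           O
ATOM     14  OG  SER A  12      11.992   6.590   1.936  1.00 10.00           O
HETATM   15  O1  EST A 600       5.000   5.000   5.000  1.00 20.00           O
HETATM   16  O   HOH A 700       2.000   2.000   2.000  1.00 30.00           O
ENDMDL
MODEL        2
ATOM     17  CA  ALA A  10      99.000  99.000  99.000  1.00 10.00           C
ENDMDL
END
"""

MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
    "  1.00  0.00           C\n"
)


@pytest.fixture
def tiny_pdb_text() -> str:
    return TINY_PDB


@pytest.fixture
def minimal_pdb_text() -> str:
    return MINIMAL_PDB


def build_structure(residue_specs, pdb_id="SYNT", chain_id="A") -> Structure:
    """Build a structure from [(res_seq, res_name, {atom: (x, y, z)}), ...]."""
    residues = {}
    serial = 0
    for res_seq, res_name, atoms in residue_specs:
        res = Residue(res_name, res_seq, "")
        for name, pos in atoms.items():
            serial += 1
            elem = name.lstrip("0123456789")[0]
            res.atoms[name] = AtomRecord(
                serial=serial, name=name, altloc="", res_name=res_name,
                chain_id=chain_id, res_seq=res_seq, i_code="",
                position=np.asarray(pos, dtype=float), occupancy=1.0,
                b_factor=0.0, element=elem, is_hetero=False,
            )
        residues[(res_seq, "")] = res
    return Structure(pdb_id=pdb_id, chains={chain_id: residues})
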