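"""Shared fixtures: tiny hand-written format samples and builders."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from ssrobust.align_metrics import AnnotatedAlignment
from ssrobust.structcalc import ResidueAnnotation
from ssrobust.structio import PairAlignment


def _pdb_atom(serial, name, altloc, resname, chain, resseq, icode, x, y, z,
              occ, element):
    fname = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {fname:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
            f"{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def pdb_three_residues(tmp_path):
    """Hand-written 3-residue ATOM block with one altloc'd atom and a water."""
    lines = []
    coords = {
        1: [("N", 0.0, 0.0, 0.0), ("CA", 1.46, 0.0, 0.0), ("C", 2.0, 1.4, 0.0),
            ("O", 1.4, 2.4, 0.2)],
        2: [("N", 3.3, 1.5, 0.0), ("CA", 4.0, 2.7, 0.3), ("C", 5.5, 2.5, 0.4),
            ("O", 6.1, 1.5, 0.8)],
        3: [("N", 6.1, 3.6, 0.1), ("CA", 7.5, 3.7, 0.3), ("C", 8.2, 5.0, 0.1),
            ("O", 7.6, 6.1, 0.2)],
    }
    serial = 1
    for resseq, atoms in coords.items():
        resname = {1: "ALA", 2: "GLY", 3: "SER"}[resseq]
        for name, x, y, z in atoms:
            if resseq == 2 and name == "CA":
                # two altlocs: A wins on occupancy
                lines.append(_pdb_atom(serial, name, "A", resname, "A", resseq,
                                       " ", x, y, z, 0.60, name[0]))
                serial += 1
                lines.append(_pdb_atom(serial, name, "B", resname, "A", resseq,
                                       " ", x + 0.5, y, z, 0.40, name[0]))
            else:
                lines.append(_pdb_atom(serial, name, " ", resname, "A", resseq,
                                       " ", x, y, z, 1.00, name[0]))
            serial += 1
    lines.append(f"HETATM{serial:5d}  O   HOH A 101      10.000  10.000  10.000"
                 f"  1.00  0.00           O")
    lines += ["TER", "END"]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pdb_nonmonotonic(tmp_path):
    """Residues numbered 10, 12, 11: numbering is not monotonic."""
    lines = []
    serial = 1
    for resseq, x in ((10, 0.0), (12, 4.0), (11, 8.0)):
        for name, dx in (("N", 0.0), ("CA", 1.4), ("C", 2.4), ("O", 3.0)):
            lines.append(_pdb_atom(serial, name, " ", "ALA", "A", resseq, " ",
                                   x + dx, 0.0, 0.0, 1.00, name[0]))
            serial += 1
    path = tmp_path / "nonmono.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def _dssp_line(serial, resnum, chain, aa, ss, acc):
    # classic layout: aa at col 13, ss at col 16, acc right-aligned at 34-37
    line = f"{serial:5d}{resnum:5d} {chain:1s} {aa:1s}  {ss:1s}"
    return line.ljust(34) + f"{acc:4d}"


@pytest.fixture
def dssp_file(tmp_path):
    """Two residues plus a chain-break line."""
    body = "\n".join([
        "==== Secondary Structure Definition, synthetic test fixture ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
        _dssp_line(1, 1, "A", "M", "H", 97),
        "    2        !              0   0    0",
        _dssp_line(3, 2, "A", "V", "E", 12),
    ])
    path = tmp_path / "test.dssp"
    path.write_text(body + "\n")
    return path


@pytest.fixture
def tmalign_file(tmp_path):
    text = textwrap.dedent("""\
        **************************************************************
        Name of Chain_1: d1
        Name of Chain_2: d2

        Aligned length=4, RMSD=1.00, Seq_ID=n_identical/n_aligned=0.750
        TM-score= 0.71000 (if normalized by length of Chain_1)
        TM-score= 0.64000 (if normalized by length of Chain_2)

        (":" denotes residue pairs of d < 5.0 Angstrom, "." denotes other aligned residues)
        AC-D
        ::.:
        ACED
        """)
    path = tmp_path / "pair.tma"
    path.write_text(text)
    return path


@pytest.fixture
def fasta_pair_file(tmp_path):
    path = tmp_path / "pair.afa"
    path.write_text("#tm=0.8\n>d1\nAC-D\n>d2\nACED\n")
    return path


def make_annotated(ss1, ss2, rsa1=None, rsa2=None, seq1=None, seq2=None,
                   columns=None, tm=0.8):
    """AnnotatedAlignment from parallel ss3 strings, gapless by default."""
    n1, n2 = len(ss1), len(ss2)
    if columns is None:
        assert n1 == n2
        columns = [(i, i) for i in range(n1)]
    ann1 = [ResidueAnnotation(ss3=s, asa=0.0,
                              rsa=(rsa1[i] if rsa1 is not None else 0.5))
            for i, s in enumerate(ss1)]
    ann2 = [ResidueAnnotation(ss3=s, asa=0.0,
                              rsa=(rsa2[i] if rsa2 is not None else 0.5))
            for i, s in enumerate(ss2)]
    pa = PairAlignment("x1", "x2", tm, columns,
                       seq1=seq1 or "A" * n1, seq2=seq2 or "A" * n2)
    return AnnotatedAlignment(pa, ann1, ann2)
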