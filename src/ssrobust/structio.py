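"""Readers and writers for the external formats the pipeline touches.

Covers PDB coordinate files (via Biopython), classic DSSP text output,
SCOP ``dir.cla``-style classification tables, TMalign plain-text pairwise
alignments, and a minimal FASTA-pair alignment dialect.  All downstream
analysis operates on the containers defined here: :class:`DomainStructure`
(an ordered list of residues with heavy-atom coordinates) and
:class:`PairAlignment` (aligned column indices plus a TM-score).

Coordinates and residue regions use author numbering; alignment columns
use 0-based positional indices into each domain's residue list, which
decouples the metrics from PDB numbering quirks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GAP",
    "Atom",
    "Residue",
    "DomainStructure",
    "ScopRecord",
    "PairAlignment",
    "FormatError",
    "EmptyDomainError",
    "EmptyAlignmentError",
    "read_pdb",
    "write_pdb",
    "read_dssp",
    "read_tmalign_pair",
    "write_fasta_pair",
    "read_scop_cla",
    "group_families",
]

#: Sentinel marking a gap on one side of an alignment column.
GAP = None

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


class EmptyDomainError(ValueError):
    """A chain/region selection produced no residues."""


class EmptyAlignmentError(ValueError):
    """An alignment contains no columns after parsing or trimming."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]

    def __post_init__(self):
        if not self.element:
            raise ValueError("atom element must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    number: int           # author residue number
    icode: str            # insertion code, '' if none
    aa: str               # 1-letter code, 'X' for nonstandard
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class DomainStructure:
    """A protein domain: ordered residues with atoms plus SCOP metadata."""

    sid: str
    residues: list[Residue]
    sccs: str = ""
    chain: str = "A"

    def __post_init__(self):
        if len(self.residues) < 1:
            raise EmptyDomainError(f"domain {self.sid} has no residues")
        for r in self.residues:
            if r.aa not in AA_ALPHABET and r.aa != "X":
                raise ValueError(f"unexpected amino acid code {r.aa!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def is_monotonic(self) -> bool:
        """True if residue keys (number, icode) strictly increase.

        Domains violating this are excluded from comparative analyses.
        """
        keys = [r.key for r in self.residues]
        return all(a < b for a, b in zip(keys, keys[1:]))

    def coords(self, atom_names: Optional[Sequence[str]] = None) -> np.ndarray:
        pts = []
        for r in self.residues:
            for a in r.atoms:
                if atom_names is None or a.name in atom_names:
                    pts.append(a.coords)
        return np.asarray(pts, dtype=float)


@dataclass(frozen=True)
class ScopRecord:
    sid: str
    pdb_code: str
    region: str
    sccs: str

    _CLASS_NAMES = {"a": "all-alpha", "b": "all-beta", "c": "alpha/beta", "d": "alpha+beta"}

    @property
    def top_class(self) -> str:
        letter = self.sccs.split(".")[0]
        return self._CLASS_NAMES.get(letter, letter)

    @property
    def family(self) -> str:
        """4-level sccs prefix, e.g. ``b.1.1.1``."""
        return ".".join(self.sccs.split(".")[:4])


@dataclass
class PairAlignment:
    """Two domains plus aligned columns and a TM-score.

    ``columns`` holds 0-based residue indices into each domain's residue
    list, or :data:`GAP` on the unaligned side.  ``tm_score`` is the score
    normalized by the longer sequence.
    """

    id1: str
    id2: str
    tm_score: float
    columns: list[tuple[Optional[int], Optional[int]]]
    seq1: str = ""
    seq2: str = ""
    family1: str = ""
    family2: str = ""

    def __post_init__(self):
        if not self.columns:
            raise EmptyAlignmentError(f"alignment {self.id1}/{self.id2} has no columns")
        self.validate()

    def validate(self) -> None:
        last1 = last2 = -1
        for c1, c2 in self.columns:
            if c1 is GAP and c2 is GAP:
                raise FormatError("column with gaps on both sides")
            if c1 is not GAP:
                if c1 <= last1:
                    raise FormatError("side-1 indices not strictly increasing")
                last1 = c1
            if c2 is not GAP:
                if c2 <= last2:
                    raise FormatError("side-2 indices not strictly increasing")
                last2 = c2

    @property
    def n_columns(self) -> int:
        return len(self.columns)


# ---------------------------------------------------------------------------
# PDB

def _parse_region(region: str) -> tuple[Optional[str], Optional[int], Optional[int]]:
    """Parse a SCOP-style region descriptor: '-', 'A:', 'A:1-100', '1-100'."""
    region = region.strip()
    if region in ("", "-"):
        return None, None, None
    chain = None
    span = region
    if ":" in region:
        chain, span = region.split(":", 1)
        chain = chain or None
    if not span:
        return chain, None, None
    m = re.match(r"^(-?\d+)-(-?\d+)$", span)
    if not m:
        raise FormatError(f"cannot parse region descriptor {region!r}")
    return chain, int(m.group(1)), int(m.group(2))


def read_pdb(
    path,
    chain: Optional[str] = None,
    region: Optional[str] = None,
    sid: Optional[str] = None,
    sccs: str = "",
) -> DomainStructure:
    """Read a PDB-format file into a :class:`DomainStructure`.

    HETATM records (waters, ligands) are dropped; alternate locations are
    resolved to the highest-occupancy conformer; residues lacking any of
    the backbone atoms N, CA, C are dropped.  ``region`` is a SCOP-style
    descriptor in author numbering (e.g. ``"A:12-140"``) and overrides
    ``chain`` when it names one.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if region is not None:
        rchain, lo, hi = _parse_region(region)
        if rchain is not None:
            chain = rchain
    else:
        lo = hi = None

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises bare ValueError/Exception
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc

    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FormatError(f"no models in {path}")

    residues: list[Residue] = []
    sel_chain = chain
    for ch in model:
        if sel_chain is not None and ch.id != sel_chain:
            continue
        for res in ch:
            hetflag, resseq, icode = res.id
            if hetflag.strip():      # waters and ligands
                continue
            if lo is not None and not (lo <= resseq <= hi):
                continue
            aa = AA3_TO_1.get(res.get_resname().upper(), "X")
            atoms = []
            for atom in res:
                # DisorderedAtom already selects the highest-occupancy altloc
                element = (atom.element or atom.get_name()[0]).strip() or "C"
                atoms.append(Atom(atom.get_name(), element,
                                  tuple(float(v) for v in atom.coord)))
            r = Residue(resseq, icode.strip(), aa, tuple(atoms))
            if r.has_backbone():
                residues.append(r)
        if sel_chain is None and residues:
            sel_chain = ch.id  # first chain only when unspecified
            break

    if not residues:
        raise EmptyDomainError(f"no residues selected from {path} (chain={chain!r})")
    return DomainStructure(sid=sid or path.stem, residues=residues,
                           sccs=sccs, chain=sel_chain or "A")


def write_pdb(domain: DomainStructure, path) -> None:
    """Write a domain as minimal ATOM/TER records (fixed-width PDB text)."""
    lines = []
    serial = 1
    for res in domain.residues:
        resname = AA1_TO_3.get(res.aa, "UNK")
        for atom in res.atoms:
            name = atom.name
            # PDB atom-name column convention: element right-justified in 14-15
            fname = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {fname:<4s} {resname:<3s} {domain.chain:1s}"
                f"{res.number:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DSSP classic text

def read_dssp(path) -> list[tuple[tuple[str, int, str], str, float]]:
    """Parse classic DSSP output.

    Returns one record per residue: ``((chain, resnum, icode), ss8, acc)``
    with ``acc`` in Å².  Chain-break lines (``!`` in the AA column) are
    skipped.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines)
                     if ln.lstrip().startswith("#") and "RESIDUE" in ln) + 1
    except StopIteration:
        raise FormatError(f"{path}: no DSSP residue header line found")

    records = []
    for lineno, ln in enumerate(lines[start:], start + 1):
        if not ln.strip():
            continue
        if len(ln) < 38:
            raise FormatError(f"{path}:{lineno}: truncated DSSP line")
        aa = ln[13]
        if aa == "!":      # chain break marker
            continue
        try:
            resnum = int(ln[5:10])
            icode = ln[10].strip()
            chain_id = ln[11].strip()
            ss8 = ln[16]
            acc = float(ln[34:38])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed DSSP line: {exc}") from exc
        records.append(((chain_id, resnum, icode), ss8, acc))
    return records


# ---------------------------------------------------------------------------
# Pairwise alignments

def _columns_from_gapped(s1: str, s2: str):
    if len(s1) != len(s2):
        raise FormatError("aligned sequences have different lengths")
    cols = []
    i = j = 0
    for a, b in zip(s1, s2):
        ga, gb = a == "-", b == "-"
        if ga and gb:
            raise FormatError("column with gaps on both sides")
        cols.append((None if ga else i, None if gb else j))
        i += not ga
        j += not gb
    return cols


def read_tmalign_pair(path, id1: str = "", id2: str = "") -> PairAlignment:
    """Parse a pairwise alignment file.

    Accepts either TMalign plain-text output (two "TM-score=" headers and a
    three-line alignment block) or the package's FASTA-pair dialect::

        #tm=0.64
        >dom1
        AC-D
        >dom2
        ACED

    ``tm_score`` is the score normalized by the longer chain, i.e. the
    smaller of the two printed TM-scores.
    """
    text = Path(path).read_text()
    lines = text.splitlines()

    if any(ln.startswith("#tm=") for ln in lines):
        return _read_fasta_pair(lines, id1, id2)

    scores = [float(m) for m in re.findall(r"TM-score\s*=\s*([0-9.]+)", text)]
    if not scores:
        raise FormatError(f"{path}: no TM-score header found")
    tm = min(scores)

    # the alignment block is the three non-blank lines after the marker legend
    seqs = None
    for i, ln in enumerate(lines):
        if '":" denotes' in ln or ln.startswith("(\":\""):
            block = [l for l in lines[i + 1:] if l.strip()][:3]
            if len(block) == 3:
                seqs = (block[0].strip(), block[2].strip())
            break
    if seqs is None:
        raise FormatError(f"{path}: alignment block not found")
    s1, s2 = seqs
    cols = _columns_from_gapped(s1, s2)
    if not any(c1 is not None and c2 is not None for c1, c2 in cols):
        raise EmptyAlignmentError(f"{path}: no aligned columns")
    return PairAlignment(id1 or "chain1", id2 or "chain2", tm, cols,
                         seq1=s1.replace("-", ""), seq2=s2.replace("-", ""))


def _read_fasta_pair(lines: list[str], id1: str, id2: str) -> PairAlignment:
    tm = None
    names, seqs = [], []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#tm="):
            tm = float(ln[4:])
        elif ln.startswith(">"):
            names.append(ln[1:].split()[0] if len(ln) > 1 else f"seq{len(names) + 1}")
            seqs.append("")
        elif names:
            seqs[-1] += ln
    if tm is None:
        raise FormatError("FASTA-pair dialect requires a '#tm=' header")
    if len(seqs) != 2:
        raise FormatError(f"expected exactly 2 sequences, found {len(seqs)}")
    cols = _columns_from_gapped(seqs[0], seqs[1])
    if not any(c1 is not None and c2 is not None for c1, c2 in cols):
        raise EmptyAlignmentError("no aligned columns")
    return PairAlignment(id1 or names[0], id2 or names[1], tm, cols,
                         seq1=seqs[0].replace("-", ""), seq2=seqs[1].replace("-", ""))


def write_fasta_pair(pa: PairAlignment, path) -> None:
    """Write a PairAlignment in the 3-line FASTA-pair dialect."""
    def gapped(seq: str, side: int) -> str:
        out = []
        for col in pa.columns:
            idx = col[side]
            out.append("-" if idx is GAP else seq[idx])
        return "".join(out)

    body = (f"#tm={pa.tm_score}\n>{pa.id1}\n{gapped(pa.seq1, 0)}\n"
            f">{pa.id2}\n{gapped(pa.seq2, 1)}\n")
    Path(path).write_text(body)


# ---------------------------------------------------------------------------
# SCOP classification

def read_scop_cla(path) -> list[ScopRecord]:
    """Read a SCOP ``dir.cla``-style table (sid, pdb code, region, sccs).

    Lines starting with ``#`` are comments.  Records whose sccs string does
    not parse as a dotted class string are skipped with a warning.
    """
    records = []
    skipped = 0
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) < 4:
            skipped += 1
            continue
        sid, pdb_code, region, sccs = parts[0], parts[1], parts[2], parts[3]
        if not re.match(r"^[a-l](\.\d+){1,3}$", sccs):
            skipped += 1
            continue
        records.append(ScopRecord(sid, pdb_code, region, sccs))
    if skipped:
        warnings.warn(f"read_scop_cla: skipped {skipped} unparsable record(s)")
    return records


def group_families(records: Iterable[ScopRecord]) -> dict[str, list[str]]:
    """Group domain sids by family (4-level sccs prefix).

    Singleton families cannot contribute pairwise alignments; callers should
    drop them (use :func:`usable_families`).
    """
    fams: dict[str, list[str]] = {}
    for rec in records:
        fams.setdefault(rec.family, []).append(rec.sid)
    return fams


def usable_families(families: dict[str, list[str]]) -> dict[str, list[str]]:
    """Families with at least two domains (pairable)."""
    return {f: sids for f, sids in families.items() if len(sids) >= 2}
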