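"""Per-residue structural annotation from coordinates.

Everything downstream of raw structures lives here: 3-state secondary
structure via Kabsch–Sander hydrogen-bond patterns, solvent-accessible
surface area via a deterministic Shrake–Rupley integration, relative
solvent accessibility against extended Gly-X-Gly maxima, and heavy-atom
van-der-Waals contact maps with per-residue contact statistics.

The contact definition is a surface-gap rule: two residues are in contact
when any heavy-atom pair has an interatomic distance within 0.25 Å of the
sum of the van der Waals radii, with intra-residue pairs and the covalent
peptide bond excluded.  Because hydrogens are not modelled, absolute
contact counts are not comparable to hydrogen-aware tools; all analyses in
this package compare contact counts within a single run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structio import AA_ALPHABET, DomainStructure

__all__ = [
    "ResidueAnnotation",
    "ContactMap",
    "VDW_RADII",
    "assign_ss",
    "ss8_to_ss3",
    "compute_asa",
    "compute_rsa",
    "max_asa_table",
    "compute_contacts",
    "contact_stats",
    "annotate_domain",
]

#: van der Waals radii by element (Å); unknown elements fall back to 1.8 Å.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.8

# Kabsch-Sander electrostatic model constants (kcal/mol scale)
_KS_Q1Q2_F = 0.084 * 332.0
_KS_HBOND_CUTOFF = -0.5

SS3_MAPPING_DEFAULT = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
                       "T": "C", "S": "C", " ": "C", "-": "C", "C": "C"}


@dataclass
class ResidueAnnotation:
    """Per-residue structural annotation.

    rsa may exceed 1 for residues more exposed than the Gly-X-Gly
    reference; such values are kept and fall in the top RSA bin downstream.
    mean_contact_distance is None when the residue has no contacts.
    """

    ss3: str = "C"
    asa: float = float("nan")
    rsa: Optional[float] = None
    n_contacts: int = 0
    mean_contact_distance: Optional[float] = None

    def __post_init__(self):
        if self.ss3 not in "HEC":
            raise ValueError(f"ss3 must be H, E or C, got {self.ss3!r}")
        if self.rsa is not None and self.rsa < 0:
            raise ValueError("rsa must be >= 0")


class ContactMap:
    """Symmetric set of contacting residue-index pairs with surface gaps."""

    def __init__(self, n_residues: int):
        self.n_residues = n_residues
        self._gaps: dict[tuple[int, int], float] = {}

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def add(self, i: int, j: int, gap: float) -> None:
        if i == j:
            raise ValueError("self-contact not allowed")
        key = self._key(i, j)
        self._gaps[key] = min(gap, self._gaps.get(key, math.inf))

    def __contains__(self, pair) -> bool:
        return self._key(*pair) in self._gaps

    def __len__(self) -> int:
        return len(self._gaps)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self._gaps)

    def gap(self, i: int, j: int) -> float:
        return self._gaps[self._key(i, j)]

    def partners(self, i: int) -> list[int]:
        out = []
        for a, b in self._gaps:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander hydrogen bonds)

def _backbone_arrays(structure: DomainStructure):
    L = len(structure)
    coords = {name: np.full((L, 3), np.nan) for name in ("N", "CA", "C", "O")}
    ok = np.zeros(L, dtype=bool)
    for i, res in enumerate(structure.residues):
        atoms = {a.name: a.xyz for a in res.atoms}
        if all(n in atoms for n in ("N", "CA", "C", "O")):
            ok[i] = True
            for n in ("N", "CA", "C", "O"):
                coords[n][i] = atoms[n]
    return coords, ok


def _ks_hbond_matrix(structure: DomainStructure) -> np.ndarray:
    """hb[i, j] is True when CO of residue i accepts an H-bond from NH of j.

    The amide hydrogen is reconstructed on N along the C(i-1)->O(i-1)
    reverse direction at 1.0 Å, as in the original Kabsch-Sander scheme.
    Prolines and chain-leading residues have no donor H.
    """
    coords, ok = _backbone_arrays(structure)
    L = len(structure)
    N, C, O = coords["N"], coords["C"], coords["O"]

    H = np.full((L, 3), np.nan)
    has_h = np.zeros(L, dtype=bool)
    for j in range(1, L):
        if ok[j] and ok[j - 1] and structure.residues[j].aa != "P":
            d = C[j - 1] - O[j - 1]
            H[j] = N[j] + d / np.linalg.norm(d)
            has_h[j] = True

    hb = np.zeros((L, L), dtype=bool)
    for i in range(L):
        if not ok[i]:
            continue
        for j in range(L):
            if i == j or abs(i - j) < 2 or not has_h[j]:
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            if r_on > 5.2:          # energy cannot reach -0.5 beyond this
                continue
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue            # clashing geometry, treat as no bond
            e = _KS_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < _KS_HBOND_CUTOFF:
                hb[i, j] = True
    return hb


def assign_ss(structure: DomainStructure) -> list[str]:
    """3-state secondary structure (H/E/C) from Kabsch-Sander H-bonds.

    Helices are runs of consecutive n-turns (3-, 4- or 5-turns, covering
    3-10, alpha and pi patterns, all reduced to H); strands are residues in
    parallel or antiparallel bridges.  Residues matching no pattern,
    including chain termini without partners, are coil.  Residues with
    missing backbone atoms are annotated C with a warning.
    """
    L = len(structure)
    _, ok = _backbone_arrays(structure)
    if not ok.all():
        warnings.warn(f"{structure.sid}: {int((~ok).sum())} residue(s) missing "
                      "backbone atoms, annotated C")
    if L < 3:
        return ["C"] * L

    hb = _ks_hbond_matrix(structure)

    is_h = np.zeros(L, dtype=bool)
    # n-turns: CO(i) -- NH(i+n); two consecutive turns define a helix run
    for n in (4, 3, 5):
        turn = np.zeros(L, dtype=bool)
        for i in range(L - n):
            turn[i] = hb[i, i + n]
        for i in range(1, L - n):
            if turn[i - 1] and turn[i]:
                is_h[i:i + n] = True

    is_e = np.zeros(L, dtype=bool)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            antiparallel = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or antiparallel:
                is_e[i] = is_e[j] = True

    out = []
    for i in range(L):
        if is_h[i]:
            out.append("H")
        elif is_e[i]:
            out.append("E")
        else:
            out.append("C")
    return out


def ss8_to_ss3(ss8: str, mapping: Optional[dict] = None) -> str:
    """Reduce an 8-state DSSP letter to H/E/C.

    Default mapping: H,G,I -> H; E,B -> E; everything else -> C.  Unknown
    letters map to C with a warning.
    """
    mapping = mapping or SS3_MAPPING_DEFAULT
    if ss8 not in mapping:
        warnings.warn(f"unknown ss8 letter {ss8!r}, mapped to C")
        return "C"
    return mapping[ss8]


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)

@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def compute_asa(structure: DomainStructure, probe_radius: float = 1.4,
                n_points: int = 960) -> np.ndarray:
    """Accessible surface area per residue (Å²), Shrake-Rupley integration.

    Deterministic for a given point count: test points come from a fixed
    golden-spiral generator.  Per-atom areas are summed within residues.
    """
    atoms = []
    for ri, res in enumerate(structure.residues):
        for a in res.atoms:
            if a.element.upper() == "H":
                continue
            atoms.append((ri, a.xyz, _atom_radius(a.element)))
    n_res = len(structure)
    asa = np.zeros(n_res)
    if not atoms:
        return asa

    xyz = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms])
    res_idx = np.array([a[0] for a in atoms])
    ext = radii + probe_radius
    sphere = _sphere_points(n_points)

    tree = cKDTree(xyz)
    max_reach = 2 * ext.max()
    for ai in range(len(atoms)):
        pts = xyz[ai] + ext[ai] * sphere
        neighbors = [n for n in tree.query_ball_point(xyz[ai], ext[ai] + ext.max())
                     if n != ai]
        accessible = np.ones(n_points, dtype=bool)
        for nb in neighbors:
            d = np.linalg.norm(pts - xyz[nb], axis=1)
            accessible &= d >= ext[nb]
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        asa[res_idx[ai]] += frac * 4.0 * math.pi * ext[ai] ** 2
    return asa


@lru_cache(maxsize=4)
def max_asa_table(probe_radius: float = 1.4, n_points: int = 960) -> dict[str, float]:
    """Maximum ASA per amino acid from extended Gly-X-Gly tripeptides.

    The table is generated with the package's own geometry builder and ASA
    routine, so RSA values are self-consistent with the reduced heavy-atom
    representation used throughout.  A published table may be passed to
    :func:`compute_rsa` instead.
    """
    from ._geometry import PHI_PSI, build_backbone

    phi_psi = [PHI_PSI["strand"]] * 3
    table = {}
    for aa in AA_ALPHABET:
        tri = build_backbone("G" + aa + "G", phi_psi, sid=f"GXG_{aa}")
        asa = compute_asa(tri, probe_radius=probe_radius, n_points=n_points)
        table[aa] = float(asa[1])
    assert all(v > 0 for v in table.values())
    return table


def compute_rsa(asa: float, aa: str,
                table: Optional[dict[str, float]] = None) -> Optional[float]:
    """Relative solvent accessibility: asa / max_asa(aa).

    Values above 1 are retained (assigned to the top RSA bin downstream).
    Unknown amino acids return None and are excluded from RSA-binned
    analyses.
    """
    if table is None:
        table = max_asa_table()
    if aa not in table:
        return None
    return float(asa) / table[aa]


# ---------------------------------------------------------------------------
# Contacts

def compute_contacts(structure: DomainStructure, slack: float = 0.25,
                     _brute_force: bool = False) -> ContactMap:
    """Heavy-atom van-der-Waals contact map.

    Residues i and j are in contact when the minimum over their atom pairs
    of (distance - r_i - r_j) is below ``slack``.  Intra-residue pairs and
    the peptide-bond pair (C of i, N of i+1) are excluded as covalent.
    A k-d tree prunes the atom-pair search; results equal the brute-force
    double loop.
    """
    entries = []   # (residue index, atom name, xyz, radius)
    for ri, res in enumerate(structure.residues):
        for a in res.atoms:
            entries.append((ri, a.name, a.xyz, _atom_radius(a.element)))
    cmap = ContactMap(len(structure))
    if len(entries) < 2:
        return cmap

    xyz = np.array([e[2] for e in entries])
    radii = np.array([e[3] for e in entries])
    cutoff = 2 * radii.max() + slack

    if _brute_force:
        candidate_pairs = [(a, b) for a in range(len(entries))
                           for b in range(a + 1, len(entries))]
    else:
        tree = cKDTree(xyz)
        candidate_pairs = tree.query_pairs(cutoff)

    for a, b in candidate_pairs:
        ri, rj = entries[a][0], entries[b][0]
        if ri == rj:
            continue
        # covalent peptide bond C(i)-N(i+1)
        lo, hi = (a, b) if ri < rj else (b, a)
        if abs(ri - rj) == 1 and entries[lo][1] == "C" and entries[hi][1] == "N":
            continue
        gap = float(np.linalg.norm(xyz[a] - xyz[b])) - radii[a] - radii[b]
        if gap < slack:
            cmap.add(ri, rj, gap)
    return cmap


def contact_stats(cmap: ContactMap, residue_index: int) -> tuple[int, Optional[float]]:
    """(number of contacts, mean linear contact distance in residues).

    Contact distance is |i - j| along the chain; the mean is undefined
    (None) for residues with no contacts.
    """
    partners = cmap.partners(residue_index)
    if not partners:
        return 0, None
    dists = [abs(residue_index - j) for j in partners]
    return len(partners), float(np.mean(dists))


# ---------------------------------------------------------------------------
# Convenience

def annotate_domain(structure: DomainStructure, probe_radius: float = 1.4,
                    n_points: int = 960, slack: float = 0.25,
                    max_asa: Optional[dict[str, float]] = None) -> list[ResidueAnnotation]:
    """Full per-residue annotation: ss3, ASA, RSA, contacts, contact distance."""
    ss = assign_ss(structure)
    asa = compute_asa(structure, probe_radius=probe_radius, n_points=n_points)
    cmap = compute_contacts(structure, slack=slack)
    table = max_asa if max_asa is not None else max_asa_table(probe_radius, n_points)
    out = []
    for i, res in enumerate(structure.residues):
        n_c, mcd = contact_stats(cmap, i)
        out.append(ResidueAnnotation(
            ss3=ss[i],
            asa=float(asa[i]),
            rsa=compute_rsa(asa[i], res.aa, table),
            n_contacts=n_c,
            mean_contact_distance=mcd,
        ))
    return out
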