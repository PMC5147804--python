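"""Internal ideal-geometry backbone builder.

Places N, CA, C, O and CB atoms from ideal bond lengths/angles and a list
of (phi, psi) dihedrals using NeRF (natural extension reference frame)
chain extension.  Used to construct synthetic fixtures (ideal helices,
strands, sheets, coils) and the Gly-X-Gly tripeptides that normalize RSA.
"""

from __future__ import annotations

import math

import numpy as np

from .structio import Atom, DomainStructure, Residue

# ideal backbone geometry (Engh & Huber-style averages), Å and degrees
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position D bonded to C with B-C-D angle and A-B-C-D dihedral."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB branch off CA (L-configuration)."""
    u_n = _unit(n - ca)
    u_c = _unit(c - ca)
    bis = -_unit(u_n + u_c)            # points away from both backbone bonds
    perp = _unit(np.cross(u_c, u_n))   # sign selects the L-handed side
    # N-CA-CB angle ~110.5 deg determines the mix of bisector and normal
    cos_t = math.cos(math.radians(110.5))
    c0 = float(np.dot(u_n, u_c))
    alpha = -cos_t * math.sqrt(2 + 2 * c0) / (1 + c0)
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha))
    return ca + BOND_CA_CB * (alpha * bis + beta * perp)


def build_backbone(
    sequence: str,
    phi_psi: list[tuple[float, float]],
    start_number: int = 1,
    sid: str = "synthetic",
    with_cb: bool = True,
) -> DomainStructure:
    """Build an ideal-geometry chain from per-residue (phi, psi).

    phi of the first residue and psi of the last are used only to place the
    terminal O; the chain has one (phi, psi) pair per residue.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("need at least 2 residues")
    if len(phi_psi) != L:
        raise ValueError("phi_psi must have one pair per residue")

    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))

    # seed frame for residue 0
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])

    for i in range(L - 1):
        psi = phi_psi[i][1]
        phi_next = phi_psi[i + 1][0]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phi_next)

    residues = []
    for i, aa in enumerate(sequence):
        psi = phi_psi[i][1]
        o = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms = [
            Atom("N", "N", tuple(N[i])),
            Atom("CA", "C", tuple(CA[i])),
            Atom("C", "C", tuple(C[i])),
            Atom("O", "O", tuple(o)),
        ]
        if with_cb and aa != "G":
            atoms.append(Atom("CB", "C", tuple(_cb_position(N[i], CA[i], C[i]))))
        residues.append(Residue(start_number + i, "", aa, tuple(atoms)))
    return DomainStructure(sid=sid, residues=residues)


def transform_domain(domain: DomainStructure, rotation: np.ndarray,
                     translation: np.ndarray) -> DomainStructure:
    """Apply a rigid-body transform to every atom."""
    new_res = []
    for r in domain.residues:
        atoms = tuple(
            Atom(a.name, a.element, tuple(rotation @ a.xyz + translation))
            for a in r.atoms
        )
        new_res.append(Residue(r.number, r.icode, r.aa, atoms))
    return DomainStructure(sid=domain.sid, residues=new_res,
                           sccs=domain.sccs, chain=domain.chain)


def rotation_y(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), 0, math.sin(t)],
                     [0, 1, 0],
                     [-math.sin(t), 0, math.cos(t)]])


def rotation_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[1, 0, 0],
                     [0, math.cos(t), -math.sin(t)],
                     [0, math.sin(t), math.cos(t)]])
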