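"""Internal geometry engine: NeRF atom placement, idealized side-chain
templates, a coarse rotamer library, and backbone construction helpers.

All bond lengths are in Å, angles and dihedrals in degrees.  Side chains are
built heavy-atom-only from internal coordinates anchored on the backbone
(N, C, CA) frame; χ angles come from the rotamer library.  Rings are built
by successive dihedrals and close only approximately — adequate for clash
counting and a simplified force field, not for crystallography.
"""

from __future__ import annotations

import numpy as np

from .antibody_model import Atom, Residue

DEG = np.pi / 180.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position atom D given A, B, C with |CD|=bond, angle(B,C,D) and
    dihedral(A,B,C,D) — the standard NeRF construction."""
    ang = angle * DEG
    dih = dihedral * DEG
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:                      # colinear reference; pick any normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# side-chain templates
#
# Each entry: (atom, refA, refB, refC, bond, angle, tors)
# where tors is a float (fixed dihedral) or ("chi", k, offset): the dihedral
# is chi_k + offset.  Reference atoms may be backbone or previously placed
# side-chain atoms.  CB is placed from (N, C, CA) with a fixed improper that
# yields L-chirality.

CB_ENTRY = ("CB", "N", "C", "CA", 1.530, 110.5, 122.6)

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 114.4, ("chi", 1, 0.0))],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, -122.0))],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 120.0))],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0))],
    "MET": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0))],
    "PRO": [("CG", "N", "CA", "CB", 1.492, 104.5, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.503, 105.5, ("chi", 2, 0.0))],
    "PHE": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.390, 120.8, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.390, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.390, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.390, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, 0.0)],
    "TYR": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.390, 120.8, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.390, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.390, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.390, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.390, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0)],
    "TRP": [("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.433, 126.7, ("chi", 2, 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
            ("CE3", "CB", "CG", "CD2", 1.398, 133.9, 0.0),
            ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 180.0),
            ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, 180.0),
            ("CH2", "CD2", "CE3", "CZ3", 1.400, 121.1, 0.0)],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3, 0.0)),
            ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4, 0.0))],
    "ARG": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", "CB", "CG", "CD", 1.463, 112.0, ("chi", 3, 0.0)),
            ("CZ", "CG", "CD", "NE", 1.330, 124.2, ("chi", 4, 0.0)),
            ("NH1", "CD", "NE", "CZ", 1.330, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.330, 120.0, 180.0)],
    "HIS": [("CG", "N", "CA", "CB", 1.497, 113.8, ("chi", 1, 0.0)),
            ("ND1", "CA", "CB", "CG", 1.378, 122.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.356, 131.1, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.321, 109.3, 180.0),
            ("NE2", "CB", "CG", "CD2", 1.374, 107.2, 180.0)],
}

N_CHI = {"GLY": 0, "ALA": 0, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
         "PRO": 2, "LEU": 2, "ILE": 2, "PHE": 2, "TYR": 2, "TRP": 2,
         "HIS": 2, "ASP": 2, "ASN": 2, "MET": 3, "GLU": 3, "GLN": 3,
         "LYS": 4, "ARG": 4}

_STAGGER = (-60.0, 180.0, 60.0)
_RING = (90.0, -90.0)
_RING_CHI2 = {"PHE", "TYR", "TRP", "HIS"}


def _build_rotamer_library() -> dict[str, list[tuple[float, ...]]]:
    lib: dict[str, list[tuple[float, ...]]] = {}
    for res, nchi in N_CHI.items():
        if res == "PRO":                        # single fixed ring pucker
            lib[res] = [(29.0, -37.0)]
            continue
        if nchi == 0:
            lib[res] = [()]
            continue
        chi1 = _STAGGER
        if nchi == 1:
            lib[res] = [(c1,) for c1 in chi1]
            continue
        chi2 = _RING if res in _RING_CHI2 else _STAGGER
        if nchi == 2:
            lib[res] = [(c1, c2) for c1 in chi1 for c2 in chi2]
            continue
        if nchi == 3:
            lib[res] = [(c1, c2, c3) for c1 in chi1 for c2 in _STAGGER
                        for c3 in _STAGGER]
            continue
        # LYS/ARG: chi1 x chi2 staggered, chi3=chi4=180 to cap combinatorics
        lib[res] = [(c1, c2, 180.0, 180.0) for c1 in chi1 for c2 in _STAGGER]
    return lib


ROTAMER_LIBRARY = _build_rotamer_library()


def rotamer_count(resname: str) -> int:
    return len(ROTAMER_LIBRARY.get(resname, [()]))


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB position from backbone geometry (used for Gly targets too)."""
    return place_atom(n, c, ca, CB_ENTRY[4], CB_ENTRY[5], CB_ENTRY[6])


def build_sidechain_atoms(resname: str, n: np.ndarray, ca: np.ndarray,
                          c: np.ndarray, chis: tuple[float, ...]) -> list[Atom]:
    """Idealized side-chain heavy atoms (CB onward) for one residue."""
    if resname == "GLY":
        return []
    pos = {"N": n, "CA": ca, "C": c}
    pos["CB"] = ideal_cb(n, ca, c)
    atoms = [Atom("CB", "C", pos["CB"])]
    for name, ra, rb, rc, bond, angle, tors in SIDECHAIN_TEMPLATES[resname]:
        if isinstance(tors, tuple):
            _, k, offset = tors
            dihedral = chis[k - 1] + offset
        else:
            dihedral = tors
        xyz = place_atom(pos[ra], pos[rb], pos[rc], bond, angle, dihedral)
        pos[name] = xyz
        element = name[0] if name[0] in ("N", "O", "S") else "C"
        atoms.append(Atom(name, element, xyz))
    return atoms


# ---------------------------------------------------------------------------
# backbone construction

BB_GEOM = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
               ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7,
               ang_ca_c_o=120.8)


def build_backbone(n_res: int, phi_psi: list[tuple[float, float]],
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) coordinates for a chain from torsions.

    ``phi_psi[i]`` gives (phi_i, psi_i); phi of the first residue is unused.
    """
    g = BB_GEOM
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    ang = g["ang_n_ca_c"] * DEG
    c0 = ca0 + g["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0]) * -1.0
    # place C so that angle N-CA-C is ideal, in the xy plane
    c0 = place_atom(np.array([0.0, 0.0, 1.0]), n0, ca0, g["ca_c"],
                    g["ang_n_ca_c"], 57.0)
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         g["c_n"], g["ang_ca_c_n"], psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          g["n_ca"], g["ang_c_n_ca"], omega)
        phi_i = phi_psi[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i,
                         g["ca_c"], g["ang_n_ca_c"], phi_i)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: in the peptide plane, trans to the next N
    for i, r in enumerate(res):
        if i + 1 < len(res):
            r["O"] = place_atom(res[i + 1]["N"], r["CA"], r["C"],
                                g["c_o"], g["ang_ca_c_o"], 180.0)
        else:
            r["O"] = place_atom(r["N"], r["CA"], r["C"],
                                g["c_o"], g["ang_ca_c_o"], phi_psi[i][1] + 180.0)
    return res


def backbone_to_residues(frames: list[dict[str, np.ndarray]],
                         sequence: str, start_number: int = 1,
                         aa1_to_3=None) -> list[Residue]:
    from .antibody_model import AA1_TO_3
    out = []
    for i, (frame, aa) in enumerate(zip(frames, sequence)):
        rr = Residue(name=AA1_TO_3[aa], seq_number=start_number + i)
        for bb in ("N", "CA", "C", "O"):
            el = bb[0]
            rr.atoms.append(Atom(bb, el, np.asarray(frame[bb], dtype=float)))
        out.append(rr)
    return out
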