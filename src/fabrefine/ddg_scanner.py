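"""Simplified structure-based point-mutation folding-energy scanner.

Scores a substitution by the change in folding free energy,

    ΔΔG = [E_folded(mut) − E_unfolded(mut)] − [E_folded(wt) − E_unfolded(wt)],

positive = destabilizing, with the unfolded state approximated by an
extended tripeptide centered on the mutated site.  The energy function is a
deliberately small, deterministic, heavy-atom force field:

* van der Waals — Lennard-Jones 6-12, 8 Å cutoff with a switching function
  and a per-pair repulsion cap (idealized, unminimized geometry leaves
  residual overlaps; the cap keeps them finite without altering the
  attractive well);
* electrostatics — Coulomb with a distance-dependent dielectric ε(r) = 4r;
* polar solvation — pairwise Generalized-Born with Still-style effective
  radii from a coarse pairwise descreening sum;
* non-polar solvation — γ·SASA (Shrake–Rupley, fixed deterministic sphere
  points);
* side-chain entropy — RT·ln(n_rotamers) per residue, scaled by burial.

The reported mutation energy is a weighted sum of the five terms; weights
default to 1 and are exposed via :class:`TermWeights`.  The scanner is not a
reimplementation of any commercial force field and its absolute numbers are
not comparable to published molecular-mechanics energies; what carries over
is the sign convention and the decision logic applied downstream.

Mutant side chains are rebuilt with idealized geometry from a coarse rotamer
library, choosing the rotamer with the lowest heavy-atom clash count against
fixed neighbors (ties → lowest rotamer index); no minimization is performed,
trading accuracy for bitwise determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._geometry import (ROTAMER_LIBRARY, build_sidechain_atoms, ideal_cb,
                        build_backbone, backbone_to_residues)
from .antibody_model import (AA1_TO_3, FabStructure, PointMutation, Residue,
                             Atom, StructureError)

COULOMB = 332.0636          # kcal·Å/(mol·e²)

#: PDB chain ids for the heavy/light chains; explicit, never guessed.
DEFAULT_CHAIN_MAP = {"HC": "H", "LC": "L"}


class ParameterError(ValueError):
    """An atom has no force-field parameters."""


@dataclass(frozen=True)
class TermWeights:
    """Dimensionless weights applied to the five energy terms."""

    w_vdw: float = 1.0
    w_elec: float = 1.0
    w_polar: float = 1.0
    w_nonpolar: float = 1.0
    w_entropy: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.w_vdw, self.w_elec, self.w_polar,
                         self.w_nonpolar, self.w_entropy])


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies (kcal/mol); ``weighted_total`` is the weight-vector
    dot product of the five terms."""

    vdw: float
    electrostatic_coulomb: float
    polar_solvation_gb: float
    nonpolar_sasa: float
    sidechain_entropy: float
    weighted_total: float

    def terms(self) -> np.ndarray:
        return np.array([self.vdw, self.electrostatic_coulomb,
                         self.polar_solvation_gb, self.nonpolar_sasa,
                         self.sidechain_entropy])

    @classmethod
    def from_terms(cls, terms: np.ndarray, w: TermWeights) -> "EnergyBreakdown":
        return cls(*[float(t) for t in terms],
                   weighted_total=float(w.as_array() @ np.asarray(terms)))


@dataclass
class MutationEnergyRecord:
    """A point mutation with ΔΔG evaluated in one or two structural contexts
    (parental/murine structure vs humanized homology model)."""

    mutation: PointMutation
    ddg_murine_context: float | None = None
    ddg_humanized_context: float | None = None
    breakdown_murine: EnergyBreakdown | None = None
    breakdown_humanized: EnergyBreakdown | None = None
    direction: str = "humanizing"          # "back" | "humanizing"
    location: str = ""
    error: str | None = None


@dataclass(frozen=True)
class ScannerConfig:
    """Numerical knobs of the energy function (defaults documented here)."""

    cutoff: float = 8.0             # non-bonded cutoff, Å
    switch_on: float = 6.5          # switching starts, Å
    dielectric_factor: float = 4.0  # ε(r) = factor · r
    solvent_dielectric: float = 80.0
    gamma: float = 0.0054           # kcal/mol/Å² for SASA
    probe_radius: float = 1.4       # Å
    n_sphere_points: int = 960
    rt: float = 0.596               # kcal/mol at ~300 K
    gb_offset: float = 0.09         # Å subtracted from intrinsic GB radii
    gb_radius_max: float = 50.0
    clash_factor: float = 0.80      # clash if d < factor·(r_i + r_j)
    lj_cap: float = 10.0            # kcal/mol ceiling per LJ pair


DEFAULT_CONFIG = ScannerConfig()
DEFAULT_WEIGHTS = TermWeights()


# ---------------------------------------------------------------------------
# parameter tables (bundled CSV resources)

def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("fabrefine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


class _Params:
    def __init__(self) -> None:
        lj = _load_csv("lj_params.csv").set_index("element")
        gb = _load_csv("gb_radii.csv").set_index("element")
        ch = _load_csv("charges.csv")
        rot = _load_csv("rotamer_entropy.csv").set_index("residue")
        self.lj_rmin_half = lj["rmin_half"].to_dict()
        self.lj_eps = lj["epsilon"].to_dict()
        self.gb_radius = gb["gb_radius"].to_dict()
        self.sasa_radius = gb["sasa_radius"].to_dict()
        self.charge = {(r, a): q for r, a, q in
                       zip(ch["residue"], ch["atom"], ch["charge"])}
        self.n_rotamers = rot["n_rotamers"].to_dict()
        self.max_sasa = rot["max_sasa"].to_dict()

    def atom_charge(self, resname: str, atomname: str) -> float:
        q = self.charge.get((resname, atomname))
        if q is None:
            q = self.charge.get(("*", atomname))
        if q is None:
            raise ParameterError(f"no charge for atom type {resname}:{atomname}")
        return q


_PARAMS: _Params | None = None


def get_params() -> _Params:
    global _PARAMS
    if _PARAMS is None:
        _PARAMS = _Params()
    return _PARAMS


# ---------------------------------------------------------------------------
# flattening and core numerics


def _flatten(s: FabStructure):
    """Arrays for the energy kernels: coords, charges, LJ/GB/SASA params,
    residue indices and (chain, residue)-adjacency for bond detection."""
    p = get_params()
    coords, charges, eps, rmin_half, gbr, sar, res_idx, res_meta = \
        [], [], [], [], [], [], [], []
    ridx = -1
    for ci, chain in enumerate(s.chains):
        for rj, res in enumerate(chain.residues):
            ridx += 1
            res_meta.append((ci, rj, res))
            for a in res.atoms:
                el = a.element if a.element in p.lj_eps else a.name[0]
                if el not in p.lj_eps:
                    raise ParameterError(f"no LJ parameters for atom type {a.name} ({el})")
                coords.append(a.xyz)
                charges.append(p.atom_charge(res.name, a.name))
                eps.append(p.lj_eps[el])
                rmin_half.append(p.lj_rmin_half[el])
                gbr.append(p.gb_radius[el])
                sar.append(p.sasa_radius[el])
                res_idx.append(ridx)
    return (np.asarray(coords, float), np.asarray(charges, float),
            np.asarray(eps, float), np.asarray(rmin_half, float),
            np.asarray(gbr, float), np.asarray(sar, float),
            np.asarray(res_idx, int), res_meta)


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    sq = (coords ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (coords @ coords.T)
    return np.sqrt(np.maximum(d2, 0.0))


def _bond_list(coords, sar, res_idx, res_meta, elements_s_mask, d=None):
    """Bonds by distance (<1.95 Å heavy, <2.3 Å involving S), restricted to
    the same or sequence-adjacent residue of the same chain."""
    n = len(coords)
    if d is None:
        d = _distance_matrix(coords)
    thr = np.where(elements_s_mask[:, None] | elements_s_mask[None, :], 2.3, 1.95)
    cand = (d < thr) & ~np.eye(n, dtype=bool)
    chain_of = np.array([res_meta[r][0] for r in res_idx])
    pos_of = np.array([res_meta[r][1] for r in res_idx])
    adjacent = (chain_of[:, None] == chain_of[None, :]) & \
               (np.abs(pos_of[:, None] - pos_of[None, :]) <= 1)
    return cand & adjacent, d


def _exclusion_mask(bonds: np.ndarray) -> np.ndarray:
    """Pairs separated by ≤ 3 bonds (1-2, 1-3, 1-4) plus the diagonal."""
    n = bonds.shape[0]
    nbr = [np.flatnonzero(bonds[i]) for i in range(n)]
    excl = np.eye(n, dtype=bool) | bonds
    for i in range(n):
        second: set[int] = set()
        for j in nbr[i]:
            second.update(nbr[j].tolist())
        third: set[int] = set()
        for j in second:
            third.update(nbr[j].tolist())
        for j in second | third:
            excl[i, j] = True
    return excl


def _switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    s = np.zeros_like(r)
    s[r <= r_on] = 1.0
    mid = (r > r_on) & (r < r_off)
    r2, on2, off2 = r[mid] ** 2, r_on ** 2, r_off ** 2
    s[mid] = ((off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2)) / (off2 - on2) ** 3
    return s


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 960,
                       d: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å²."""
    pts = _sphere_points(n_points)
    rr = radii + probe
    n = len(coords)
    if d is None:
        d = _distance_matrix(coords)
    areas = np.empty(n)
    nbr_mask = (d < rr[:, None] + rr[None, :]) & ~np.eye(n, dtype=bool)
    c_sq = (coords ** 2).sum(axis=1)
    for i in range(n):
        nbr = np.flatnonzero(nbr_mask[i])
        if nbr.size:
            surface = coords[i] + rr[i] * pts
            s_sq = (surface ** 2).sum(axis=1)
            dist2 = s_sq[:, None] + c_sq[nbr][None, :] - 2.0 * surface @ coords[nbr].T
            buried = (dist2 < (rr[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * rr[i] ** 2 * frac
    return areas


def fold_energy(s: FabStructure, w: TermWeights = DEFAULT_WEIGHTS,
                config: ScannerConfig = DEFAULT_CONFIG) -> EnergyBreakdown:
    """Five-term folding energy of a structure (see module docstring)."""
    for chain in s.chains:
        for res in chain.residues:
            if not res.has_complete_backbone():
                raise StructureError(
                    f"incomplete backbone at {chain.chain_id}:{res.seq_number}")
    coords, q, eps, rmh, gbr, sar, res_idx, res_meta = _flatten(s)
    s_mask = gbr >= 1.75                                  # S atoms (radius 1.8)
    d = _distance_matrix(coords)
    bonds, d = _bond_list(coords, sar, res_idx, res_meta, s_mask, d)
    excl = _exclusion_mask(bonds)
    n = len(coords)
    iu = np.triu_indices(n, k=1)
    pair_ok = (~excl[iu]) & (d[iu] < config.cutoff) & (d[iu] > 1e-6)
    r = d[iu][pair_ok]
    ii, jj = iu[0][pair_ok], iu[1][pair_ok]
    sw = _switch(r, config.switch_on, config.cutoff)

    # Lennard-Jones 6-12 with Lorentz-style rmin combination
    rmin = rmh[ii] + rmh[jj]
    e_ij = np.sqrt(eps[ii] * eps[jj])
    ratio6 = (rmin / r) ** 6
    lj = np.minimum(e_ij * (ratio6 ** 2 - 2.0 * ratio6), config.lj_cap)
    vdw = float(np.sum(sw * lj))

    # Coulomb with distance-dependent dielectric ε(r) = factor · r
    elec = float(np.sum(sw * COULOMB * q[ii] * q[jj] /
                        (config.dielectric_factor * r ** 2)))

    # Generalized Born polar solvation (Still-style radii, coarse descreening)
    rho = gbr - config.gb_offset
    with np.errstate(divide="ignore"):
        inv_r4 = np.where(d > 1e-6, 1.0 / np.maximum(d, 1e-6) ** 4, 0.0)
    np.fill_diagonal(inv_r4, 0.0)
    inv_alpha = 1.0 / rho - (inv_r4 * (rho[None, :] ** 3 / 3.0)).sum(axis=1)
    alpha = 1.0 / np.maximum(inv_alpha, 1.0 / config.gb_radius_max)
    alpha = np.clip(alpha, rho, config.gb_radius_max)
    aa = alpha[:, None] * alpha[None, :]
    f_gb = np.sqrt(d ** 2 + aa * np.exp(-d ** 2 / (4.0 * aa)))
    tau = 1.0 - 1.0 / config.solvent_dielectric
    gb = float(-0.5 * COULOMB * tau * (np.outer(q, q) / f_gb).sum())

    # non-polar solvation: γ · SASA
    areas = shrake_rupley_sasa(coords, sar, config.probe_radius,
                               config.n_sphere_points, d=d)
    nonpolar = float(config.gamma * areas.sum())

    # side-chain entropy: RT ln(n_rot), scaled by burial
    p = get_params()
    entropy = 0.0
    for ridx, (_, _, res) in enumerate(res_meta):
        nrot = p.n_rotamers.get(res.name, 1)
        if nrot <= 1:
            continue
        res_area = float(areas[res_idx == ridx].sum())
        max_area = p.max_sasa.get(res.name, 200.0)
        burial = float(np.clip(1.0 - res_area / max_area, 0.0, 1.0))
        entropy += config.rt * np.log(nrot) * burial
    terms = np.array([vdw, elec, gb, nonpolar, entropy])
    return EnergyBreakdown.from_terms(terms, w)


def lj_pair_energy(r: float, eps_i: float, rmin_half_i: float,
                   eps_j: float, rmin_half_j: float) -> float:
    """Closed-form single-pair LJ energy (no switching), for reference: the
    minimum sits at r = rmin_half_i + rmin_half_j with depth −√(ε_i ε_j)."""
    rmin = rmin_half_i + rmin_half_j
    e = np.sqrt(eps_i * eps_j)
    ratio6 = (rmin / r) ** 6
    return float(e * (ratio6 ** 2 - 2.0 * ratio6))


# ---------------------------------------------------------------------------
# mutant construction


def _locate(s: FabStructure, m: PointMutation,
            chain_map: dict[str, str]) -> tuple[int, int, Residue]:
    cid = chain_map[m.chain]
    for ci, chain in enumerate(s.chains):
        if chain.chain_id == cid:
            if m.position > len(chain.residues):
                raise StructureError(
                    f"position {m.position} beyond chain {cid} "
                    f"({len(chain.residues)} residues)")
            res = chain.residues[m.position - 1]
            return ci, m.position - 1, res
    raise StructureError(f"no chain {cid!r} in structure")


def _clash_partners(s: FabStructure, ci: int, rj: int):
    """Coordinates/radii of every atom outside residue (ci, rj)."""
    p = get_params()
    coords, radii = [], []
    for xci, chain in enumerate(s.chains):
        for xrj, res in enumerate(chain.residues):
            if xci == ci and xrj == rj:
                continue
            for a in res.atoms:
                el = a.element if a.element in p.sasa_radius else a.name[0]
                coords.append(a.xyz)
                radii.append(p.sasa_radius.get(el, 1.7))
    return (np.asarray(coords, float) if coords else np.zeros((0, 3)),
            np.asarray(radii, float))


def _count_clashes(atoms: list[Atom], partner_xyz: np.ndarray,
                   partner_r: np.ndarray, config: ScannerConfig) -> int:
    if not atoms or partner_xyz.size == 0:
        return 0
    p = get_params()
    xyz = np.array([a.xyz for a in atoms])
    radii = np.array([p.sasa_radius.get(a.element, 1.7) for a in atoms])
    d = np.linalg.norm(xyz[:, None, :] - partner_xyz[None, :, :], axis=-1)
    thr = config.clash_factor * (radii[:, None] + partner_r[None, :])
    return int((d < thr).sum())


def rotamer_clash_counts(s: FabStructure, chain_id: str, position: int,
                         resname: str,
                         config: ScannerConfig = DEFAULT_CONFIG) -> list[int]:
    """Clash count of each library rotamer of ``resname`` placed at the site
    (backbone taken from the existing residue); used for placement and
    exposed for exhaustive-enumeration checks."""
    ci = [c.chain_id for c in s.chains].index(chain_id)
    rj = position - 1
    res = s.chains[ci].residues[rj]
    n, ca, c = res.atom("N").xyz, res.atom("CA").xyz, res.atom("C").xyz
    partner_xyz, partner_r = _clash_partners(s, ci, rj)
    counts = []
    for chis in ROTAMER_LIBRARY.get(resname, [()]):
        atoms = build_sidechain_atoms(resname, n, ca, c, chis)
        counts.append(_count_clashes(atoms, partner_xyz, partner_r, config))
    return counts


def build_mutant_structure(s: FabStructure, m: PointMutation,
                           chain_map: dict[str, str] = DEFAULT_CHAIN_MAP,
                           config: ScannerConfig = DEFAULT_CONFIG) -> FabStructure:
    """Replace one side chain with an idealized-geometry side chain of the
    mutant residue, keeping all backbone atoms fixed.

    The rotamer with the lowest heavy-atom clash count against all other
    residues is chosen; ties break to the lowest rotamer index.  Identity
    mutations (flagged) return an unchanged copy.  Glycine targets have CB
    reconstructed from backbone geometry; Gly mutants keep backbone only.
    """
    ci, rj, res = _locate(s, m, chain_map)
    if res.aa1 != m.wt_aa:
        raise StructureError(
            f"wild-type mismatch at {m.chain}:{m.position}: "
            f"expected {m.wt_aa}, found {res.aa1}")
    out = s.copy()
    if m.identity and m.wt_aa == m.mut_aa:
        return out
    new_name = AA1_TO_3[m.mut_aa]
    target = out.chains[ci].residues[rj]
    backbone = [a for a in target.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    target.name = new_name
    target.atoms = backbone
    nn, ca, cc = (target.atom("N").xyz, target.atom("CA").xyz,
                  target.atom("C").xyz)
    counts = rotamer_clash_counts(out, out.chains[ci].chain_id,
                                  m.position, new_name, config)
    best = int(np.argmin(counts))           # argmin takes the first minimum
    chis = ROTAMER_LIBRARY.get(new_name, [()])[best]
    target.atoms = backbone + build_sidechain_atoms(new_name, nn, ca, cc, chis)
    return out


def pack_sidechains(s: FabStructure,
                    config: ScannerConfig = DEFAULT_CONFIG) -> FabStructure:
    """Greedy deterministic side-chain packing: residues in chain order each
    get the minimum-clash rotamer against everything placed so far."""
    out = s.copy()
    for ci, chain in enumerate(out.chains):
        for rj, res in enumerate(chain.residues):
            if res.name in ("GLY", "ALA") and res.has_atom("CB"):
                continue
            backbone = [a for a in res.atoms
                        if a.name in ("N", "CA", "C", "O", "OXT")]
            res.atoms = backbone
            nn, ca, cc = (res.atom("N").xyz, res.atom("CA").xyz,
                          res.atom("C").xyz)
            counts = rotamer_clash_counts(out, chain.chain_id, rj + 1,
                                          res.name, config)
            chis = ROTAMER_LIBRARY.get(res.name, [()])[int(np.argmin(counts))]
            res.atoms = backbone + build_sidechain_atoms(res.name, nn, ca, cc, chis)
    return out


# ---------------------------------------------------------------------------
# ΔΔG


def _extended_peptide(sequence: str,
                      config: ScannerConfig = DEFAULT_CONFIG) -> FabStructure:
    """Isolated extended peptide (φ = ψ = 180°) used as the unfolded-state
    reference, side chains packed with the same deterministic builder."""
    frames = build_backbone(len(sequence), [(180.0, 180.0)] * len(sequence))
    residues = backbone_to_residues(frames, sequence)
    from .antibody_model import ChainModel
    s = FabStructure(chains=[ChainModel("A", residues)])
    return pack_sidechains(s, config)


def _site_window(chain_residues: list[Residue], idx: int) -> tuple[int, int]:
    lo = max(0, idx - 1)
    hi = min(len(chain_residues) - 1, idx + 1)
    return lo, hi


def _unfolded_reference_energy(s: FabStructure, sites: list[tuple[int, int, str]],
                               w: TermWeights, config: ScannerConfig) -> np.ndarray:
    """Sum of extended-tripeptide energies, one per mutated site.

    ``sites``: (chain_index, residue_index, center_aa1) triplets; the center
    residue letter may differ from the folded structure (mutant reference).
    """
    total = np.zeros(5)
    for ci, rj, center_aa in sites:
        residues = s.chains[ci].residues
        lo, hi = _site_window(residues, rj)
        seq = "".join(
            center_aa if k == rj else residues[k].aa1 for k in range(lo, hi + 1)
        )
        total += fold_energy(_extended_peptide(seq, config), w, config).terms()
    return total


def mutation_energy(s: FabStructure, m: PointMutation | list[PointMutation],
                    w: TermWeights = DEFAULT_WEIGHTS,
                    context: str = "murine",
                    chain_map: dict[str, str] = DEFAULT_CHAIN_MAP,
                    config: ScannerConfig = DEFAULT_CONFIG,
                    _wt_breakdown: EnergyBreakdown | None = None
                    ) -> MutationEnergyRecord:
    """ΔΔG of one mutation (or a list applied jointly) in one context.

    Multi-site lists use one tripeptide reference per site; sites are
    assumed non-adjacent.  ``_wt_breakdown`` lets a caller reuse the folded
    wild-type energy across a scan.
    """
    muts = m if isinstance(m, list) else [m]
    if context not in ("murine", "humanized"):
        raise ValueError(f"unknown context {context!r}")
    mutant = s
    sites = []
    for mm in muts:
        ci, rj, _ = _locate(s, mm, chain_map)
        sites.append((ci, rj, mm))
        mutant = build_mutant_structure(mutant, mm, chain_map, config)
    e_fold_wt = (_wt_breakdown or fold_energy(s, w, config)).terms()
    e_fold_mut = fold_energy(mutant, w, config).terms()
    e_unf_wt = _unfolded_reference_energy(
        s, [(ci, rj, mm.wt_aa) for ci, rj, mm in sites], w, config)
    e_unf_mut = _unfolded_reference_energy(
        s, [(ci, rj, mm.mut_aa) for ci, rj, mm in sites], w, config)
    delta = (e_fold_mut - e_unf_mut) - (e_fold_wt - e_unf_wt)
    breakdown = EnergyBreakdown.from_terms(delta, w)
    rec = MutationEnergyRecord(mutation=muts[0] if len(muts) == 1 else muts[0])
    rec.mutation = muts[0]
    if context == "murine":
        rec.ddg_murine_context = breakdown.weighted_total
        rec.breakdown_murine = breakdown
    else:
        rec.ddg_humanized_context = breakdown.weighted_total
        rec.breakdown_humanized = breakdown
    return rec


def scan_mutations(s_parental: FabStructure, s_humanized: FabStructure,
                   candidates: list[PointMutation],
                   w: TermWeights = DEFAULT_WEIGHTS,
                   chain_map: dict[str, str] = DEFAULT_CHAIN_MAP,
                   config: ScannerConfig = DEFAULT_CONFIG
                   ) -> list[MutationEnergyRecord]:
    """Dual-context scan: each candidate is scored in the parental (murine)
    structure and in the humanized model.  Per-candidate failures are
    collected on the record (``error`` field); the scan continues."""
    wt_par = fold_energy(s_parental, w, config)
    wt_hum = fold_energy(s_humanized, w, config)
    out: list[MutationEnergyRecord] = []
    for m in candidates:
        rec = MutationEnergyRecord(mutation=m, location=m.location_label)
        try:
            r1 = mutation_energy(s_parental, m, w, "murine", chain_map,
                                 config, _wt_breakdown=wt_par)
            r2 = mutation_energy(s_humanized, m, w, "humanized", chain_map,
                                 config, _wt_breakdown=wt_hum)
            rec.ddg_murine_context = r1.ddg_murine_context
            rec.breakdown_murine = r1.breakdown_murine
            rec.ddg_humanized_context = r2.ddg_humanized_context
            rec.breakdown_humanized = r2.breakdown_humanized
        except (StructureError, ParameterError, KeyError) as exc:
            rec.error = str(exc)
        out.append(rec)
    return out
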