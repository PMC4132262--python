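"""Synthetic inputs for every pipeline stage, all pure functions of a seed.

The generators emulate the *shape* of the real study's inputs at desk
scale: a small two-chain protein standing in for a Fab crystal structure, a
few-hundred-entry human V-sequence database standing in for the ~38,700
sequence reference set, and noisy assay data (a 50–1600 nM SPR dilution
series, 25–99 °C melt curves with Fab and Fc transitions, triplicate lysis
dose-response tables) for the fitters.

The toy structure is a designed four-helix bundle — two chains of two
antiparallel helices with a leucine-rich hydrophobic core — *not* an
immunoglobulin fold.  It exists so the mutation scanner has a compact,
deterministic structure with genuinely buried and exposed sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import build_backbone, backbone_to_residues
from .antibody_model import (AA1, ChainModel, FabStructure, VRegionSequence)
from .cytotoxicity import DoseResponse, four_pl
from .ddg_scanner import ScannerConfig, DEFAULT_CONFIG, pack_sidechains
from .kinetics import KineticParams, Sensorgram, simulate_bivalent
from .thermal import MeltCurve, simulate_melt

# ---------------------------------------------------------------------------
# toy Fab

HELIX_LEN = 26
_HEPTAD_CORE = {0, 3}                      # 'a' and 'd' positions
_CORE_AA = "LILFLIVL"                      # cycled over core positions
_SURFACE_AA = "SETQNAKD"                   # drawn per-seed for outer positions


def _helix_backbone() -> list[dict[str, np.ndarray]]:
    return build_backbone(HELIX_LEN, [(-57.0, -47.0)] * HELIX_LEN)


def _fit_axis(cas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    return center, axis


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _place_helix(frames, origin: np.ndarray, direction: np.ndarray,
                 roll: float) -> list[dict[str, np.ndarray]]:
    cas = np.array([f["CA"] for f in frames])
    center, axis = _fit_axis(cas)
    rot = _rotation_between(axis, direction / np.linalg.norm(direction))
    rot = _axis_rotation(direction, roll) @ rot
    out = []
    for f in frames:
        out.append({k: rot @ (v - center) + origin for k, v in f.items()})
    return out


def _best_roll(frames, origin, direction, core_positions,
               bundle_center) -> float:
    """Roll angle pointing the mean core-position radial vector at the
    bundle center (36 candidate angles, deterministic)."""
    best, best_score = 0.0, -np.inf
    target = np.asarray(bundle_center, float) - np.asarray(origin, float)
    target = target - np.dot(target, direction) * direction
    target /= np.linalg.norm(target)
    for k in range(36):
        roll = 2 * np.pi * k / 36
        placed = _place_helix(frames, origin, direction, roll)
        score = 0.0
        for i in core_positions:
            ca = placed[i]["CA"]
            radial = ca - origin
            radial = radial - np.dot(radial, direction) * direction
            nrm = np.linalg.norm(radial)
            if nrm > 1e-9:
                score += float(np.dot(radial / nrm, target))
        if score > best_score:
            best_score, best_roll = score, roll
            best = roll
    return best


def _helix_sequence(rng: np.random.Generator, core_offset: int) -> str:
    seq = []
    core_i = 0
    for i in range(HELIX_LEN):
        if (i + core_offset) % 7 in _HEPTAD_CORE:
            seq.append(_CORE_AA[core_i % len(_CORE_AA)])
            core_i += 1
        else:
            seq.append(_SURFACE_AA[rng.integers(len(_SURFACE_AA))])
    return "".join(seq)


def make_toy_fab(seed: int = 1, spacing: float = 10.2,
                 config: ScannerConfig = DEFAULT_CONFIG) -> FabStructure:
    """Deterministic two-chain four-helix bundle (~52 residues per chain).

    Chains are ``H`` and ``L``; each contributes two antiparallel helices.
    Heptad a/d positions carry large hydrophobics and are rolled to face
    the bundle core, giving reliably buried sites; the rest of the surface
    is polar, drawn from the seed.  One surface glycine per chain (position
    15) exercises the CB-reconstruction path of the mutation builder.
    Side chains are packed with the scanner's own deterministic builder.
    """
    rng = np.random.default_rng(seed)
    frames = _helix_backbone()
    d = spacing
    bundle_center = np.array([d / 2, d / 2, 0.0])
    layout = [  # (origin, direction) per helix: H1, H2, L1, L2
        (np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
        (np.array([0.0, d, 0.0]), np.array([0.0, 0.0, -1.0])),
        (np.array([d, 0.0, 0.0]), np.array([0.0, 0.0, -1.0])),
        (np.array([d, d, 0.0]), np.array([0.0, 0.0, 1.0])),
    ]
    core_positions = [i for i in range(HELIX_LEN) if i % 7 in _HEPTAD_CORE]
    chains = []
    for chain_id, helix_pair in (("H", layout[:2]), ("L", layout[2:])):
        residues = []
        for hk, (origin, direction) in enumerate(helix_pair):
            seq = list(_helix_sequence(rng, core_offset=0))
            if hk == 0:
                seq[14] = "G"              # surface glycine test site
            roll = _best_roll(frames, origin, direction, core_positions,
                              bundle_center)
            placed = _place_helix(frames, origin, direction, roll)
            residues.extend(backbone_to_residues(
                placed, "".join(seq), start_number=1 + hk * HELIX_LEN))
        chains.append(ChainModel(chain_id, residues))
    return pack_sidechains(FabStructure(chains=chains), config)


# ---------------------------------------------------------------------------
# human V-sequence database

HEAVY_TEMPLATE = (
    "QVQLVESGGGVVQPGRSLRLSCAASGFTFSSYGMHWVRQAPGKGLEWVAVIWYDGSNKYY"
    "ADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR"
)
HEAVY_REGIONS = (("FR1", 25), ("CDR1", 8), ("FR2", 17), ("CDR2", 8),
                 ("FR3", 38), ("CDR3", 2))
LIGHT_TEMPLATE = (
    "EIVMTQSPATLSVSPGERATLSCRASQSVSSNLAWYQQKPGQAPRLLIYGASTRATGIP"
    "ARFSGSGSGTEFTLTISSLQSEDFAVYYCQQYNNWP"
)
LIGHT_REGIONS = (("FR1", 26), ("CDR1", 6), ("FR2", 17), ("CDR2", 3),
                 ("FR3", 36), ("CDR3", 7))


def _region_map(spec) -> tuple[str, ...]:
    out: list[str] = []
    for label, n in spec:
        out.extend([label] * n)
    return tuple(out)


def default_templates() -> list[VRegionSequence]:
    """Germline-like heavy/light V-region templates with region maps."""
    return [
        VRegionSequence("heavy", HEAVY_TEMPLATE, _region_map(HEAVY_REGIONS),
                        name="heavy_template"),
        VRegionSequence("light", LIGHT_TEMPLATE, _region_map(LIGHT_REGIONS),
                        name="light_template"),
    ]


def make_human_v_db(n: int, template_set: list[VRegionSequence] | None = None,
                    substitution_rate: float = 0.05,
                    seed: int = 7) -> list[VRegionSequence]:
    """``n`` template-derived sequences with seeded point substitutions.

    Each entry picks a template round-robin and substitutes every position
    independently with probability ``substitution_rate`` (to a uniformly
    drawn different residue), emulating somatic diversity around germline.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= substitution_rate <= 0.3:
        raise ValueError("substitution_rate must be in [0, 0.3]")
    templates = template_set or default_templates()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        tpl = templates[i % len(templates)]
        res = list(tpl.residues)
        hits = rng.random(len(res)) < substitution_rate
        for j in np.flatnonzero(hits):
            choices = [aa for aa in AA1 if aa != res[j]]
            res[j] = choices[rng.integers(len(choices))]
        out.append(VRegionSequence(tpl.chain_kind, "".join(res),
                                   tpl.region_map,
                                   name=f"db{i:05d}_{tpl.chain_kind}"))
    return out


# ---------------------------------------------------------------------------
# assay bundle

NM = 1e-9
SPR_CONCENTRATIONS_NM = (50.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
T_ASSOC = 120.0      # s (2-min injection)
T_DISSOC = 300.0     # s

DEFAULT_KINETICS = KineticParams(k_on=1.09e5, k_off=1.25e-3,
                                 k_on2=1e-4, k_off2=1e-3, r_max=100.0)
DEFAULT_TM_TRANSITIONS = [(73.6, 100.0, 1.0), (81.6, 60.0, 1.2)]
DEFAULT_4PL = dict(bottom=0.0, top=60.0, log_ec50=float(np.log10(2.61e-3)),
                   hill=1.2)


@dataclass
class AssayBundle:
    sensorgrams: list[Sensorgram]
    melt_curves: list[MeltCurve]
    dose_response: DoseResponse
    true_kinetics: KineticParams = DEFAULT_KINETICS
    true_tm: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_TM_TRANSITIONS))
    true_4pl: dict = field(default_factory=lambda: dict(DEFAULT_4PL))


def make_sensorgrams(params: KineticParams = DEFAULT_KINETICS,
                     concentrations_nm=SPR_CONCENTRATIONS_NM,
                     noise_sd: float = 0.0, seed: int = 0,
                     dt: float = 1.0) -> list[Sensorgram]:
    """Twofold dilution series (50–1600 nM), 2-min association / 300-s
    dissociation, optional seeded Gaussian noise (RU)."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, T_ASSOC + T_DISSOC + 1e-9, dt)
    out = []
    for c_nm in concentrations_nm:
        sg = simulate_bivalent(params, c_nm * NM, grid, T_ASSOC)
        resp = sg.response
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=len(resp))
        out.append(Sensorgram(time=grid, response=resp,
                              concentration=c_nm * NM, t_assoc_end=T_ASSOC))
    return out


def make_melt_curves(transitions=None, noise_sd: float = 0.5,
                     n_replicates: int = 3, seed: int = 0,
                     sample: str = "construct") -> list[MeltCurve]:
    transitions = transitions if transitions is not None \
        else DEFAULT_TM_TRANSITIONS
    return [simulate_melt(transitions, baselines=(10.0, 0.05),
                          noise_sd=noise_sd, seed=seed * 1000 + rep,
                          replicate_id=rep, sample=sample)
            for rep in range(n_replicates)]


def make_dose_response(params: dict | None = None, noise_sd: float = 3.0,
                       n_replicates: int = 3, seed: int = 0,
                       concentrations=None,
                       sample: str = "construct") -> DoseResponse:
    """Triplicate lysis table over a log-spaced concentration series."""
    p = dict(DEFAULT_4PL)
    if params:
        p.update(params)
    conc = np.asarray(concentrations if concentrations is not None
                      else np.geomspace(1e-5, 1e-1, 8), float)
    rng = np.random.default_rng(seed)
    x = np.tile(conc, n_replicates)
    y = four_pl(x, p["bottom"], p["top"], p["log_ec50"], p["hill"])
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    reps = np.repeat(np.arange(n_replicates), len(conc))
    return DoseResponse(concentration=x, lysis=y, replicate_id=reps,
                        sample=sample)


def make_assay_bundle(kinetics_params: KineticParams = DEFAULT_KINETICS,
                      tm_transitions=None, fourpl_params: dict | None = None,
                      seed: int = 0, spr_noise_sd: float = 0.0,
                      melt_noise_sd: float = 0.5,
                      lysis_noise_sd: float = 3.0) -> AssayBundle:
    """Everything the three assay fitters consume, from one seed."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2 ** 31 - 1, size=3)
    return AssayBundle(
        sensorgrams=make_sensorgrams(kinetics_params, noise_sd=spr_noise_sd,
                                     seed=int(s1)),
        melt_curves=make_melt_curves(tm_transitions, noise_sd=melt_noise_sd,
                                     seed=int(s2)),
        dose_response=make_dose_response(fourpl_params,
                                         noise_sd=lysis_noise_sd,
                                         seed=int(s3)),
        true_kinetics=kinetics_params,
        true_tm=list(tm_transitions or DEFAULT_TM_TRANSITIONS),
        true_4pl={**DEFAULT_4PL, **(fourpl_params or {})},
    )
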