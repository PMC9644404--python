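"""Seeded synthetic nanodisc trajectories with ground-truth labels.

The generator emulates the statistical structure of coarse-grained
peptide/lipid nanodisc simulations so that every analysis stage has a
recoverable target:

* a two-leaflet DMPC-like disc of ``n_lipids`` (default 200) static
  10-bead lipids,
* ``n_peptides`` (default 28) rigid rod peptides tangent to the rim
  circle, with per-frame Gaussian tilt noise and charged side-chain
  beads offset from the backbone at D/E/K/R residues,
* optional antiparallel/parallel dimer subpopulations with controlled
  R13-R13 distance and inter-axis angle,
* an optional rigid stylized LCAT body placed at the rim with a
  controlled z/pitch joint distribution, random upside-down flips, and a
  two-state Markov binding schedule that parks one peptide in the site-A
  groove (PRO1-PRO232 < 1 nm, LEU21-TRP48 < 2 nm) in bound frames.

Lipids are static across frames (lipid dynamics is a non-goal); only
peptides and LCAT move.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model import (
    AA_1TO3,
    BeadTable,
    PEPTIDE_SEQUENCES,
    TopologyMap,
    Trajectory,
    charged_residues_of,
)
from .params import DEFAULT_PARAMS, AnalysisParameters

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: Per-frame bounded positional jitter of rim anchor points (arc, z,
#: radial; nm).  Chosen so the worst-case R13 approach of two
#: non-dimer peptides stays above the 1.0 nm dimer window: adjacent rim
#: slots are >= 1.31 nm apart in arc and 0.8 nm in z, so the closest
#: possible approach is sqrt((1.31 - 2*0.14)^2) = 1.03 nm.
_RIM_JITTER = (0.14, 0.12, 0.10)

_LIPID_NAMES = ["NC3", "PO4", "GL1", "GL2", "C1A", "C2A", "C3A", "C1B", "C2B", "C3B"]
_LIPID_ROLES = ["headgroup", "headgroup", "other", "other",
                "tail", "tail", "tail", "tail", "tail", "tail"]
_LIPID_SIZES = ["regular", "regular", "small", "small",
                "regular", "regular", "regular", "regular", "regular", "regular"]


class GenerationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions of one synthetic nanodisc system."""

    n_lipids: int = 200
    n_peptides: int = 28
    peptide_variant: str = "22A"
    rim_radius: float = 5.0
    bilayer_half_thickness: float = 1.75
    axis_tilt_sigma: float = 10.0          # deg, per-frame tilt noise
    axis_azimuth_sigma: float = 20.0       # deg, per-frame in-plane wobble
    antiparallel_fraction: float = 3.0 / 14.0   # -> 3 pairs of 28
    parallel_fraction: float = 1.0 / 14.0       # -> 1 pair of 28
    dimer_angle_mean: float = 155.0        # deg, antiparallel geometry
    dimer_angle_sigma: float = 5.0
    dimer_r13_range: tuple[float, float] = (0.5, 1.0)
    lcat_enabled: bool = False
    lcat_z_mean: float = 0.3               # nm, CYS31 height
    lcat_z_sigma: float = 0.3
    pitch_intercept: float = 90.0          # deg at z = 0
    pitch_slope: float = 40.0              # deg / nm
    pitch_noise_sigma: float = 10.0
    roll_flip_probability: float = 0.1
    occupancy_target: float = 0.3
    mean_event_length: float = 20.0        # frames
    n_frames: int = 1000
    dt: float = 1.0
    backbone_spacing: float = 0.35         # nm per residue
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_variant not in PEPTIDE_SEQUENCES:
            raise GenerationError(f"unknown variant {self.peptide_variant!r}")
        if self.antiparallel_fraction + self.parallel_fraction > 1.0 + 1e-12:
            raise GenerationError("dimer fractions must sum to <= 1")
        if min(self.antiparallel_fraction, self.parallel_fraction) < 0:
            raise GenerationError("dimer fractions must be >= 0")
        for s in (self.axis_tilt_sigma, self.dimer_angle_sigma,
                  self.pitch_noise_sigma, self.lcat_z_sigma):
            if s < 0:
                raise GenerationError("sigmas must be >= 0")
        if not (0.0 <= self.occupancy_target <= 1.0):
            raise GenerationError("occupancy_target must be in [0, 1]")
        if self.mean_event_length < 1:
            raise GenerationError("mean_event_length must be >= 1 frame")
        if not (0.0 <= self.roll_flip_probability <= 1.0):
            raise GenerationError("roll_flip_probability must be in [0, 1]")
        if self.n_frames < 1 or self.n_lipids < 1 or self.n_peptides < 1:
            raise GenerationError("counts must be positive")
        lo, hi = self.dimer_r13_range
        if not (0 < lo < hi):
            raise GenerationError("dimer_r13_range must be an increasing "
                                  "positive interval")

    @property
    def n_antiparallel_pairs(self) -> int:
        return int(round(self.antiparallel_fraction * self.n_peptides / 2.0))

    @property
    def n_parallel_pairs(self) -> int:
        return int(round(self.parallel_fraction * self.n_peptides / 2.0))


@dataclass
class GroundTruth:
    """Generator-side labels for recovery testing."""

    dimer_pair_ids: list[tuple[int, int]] = field(default_factory=list)
    dimer_r13: np.ndarray | None = None      # (F, n_pairs)
    dimer_angle: np.ndarray | None = None    # (F, n_pairs) deg
    dimer_class: np.ndarray | None = None    # (F, n_pairs)
    bound_peptide: np.ndarray | None = None  # (F,) molecule id, -1 = unbound
    pose_r_xy: np.ndarray | None = None
    pose_z: np.ndarray | None = None
    pose_pitch: np.ndarray | None = None
    pose_roll: np.ndarray | None = None
    flip: np.ndarray | None = None           # (F,) bool
    occupancy_fraction: float | None = None
    dimer_count_means: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "dimer_pair_ids": [list(p) for p in self.dimer_pair_ids],
            "dimer_r13": arr(self.dimer_r13),
            "dimer_angle": arr(self.dimer_angle),
            "dimer_class": arr(self.dimer_class),
            "bound_peptide": arr(self.bound_peptide),
            "pose_r_xy": arr(self.pose_r_xy),
            "pose_z": arr(self.pose_z),
            "pose_pitch": arr(self.pose_pitch),
            "pose_roll": arr(self.pose_roll),
            "flip": arr(self.flip),
            "occupancy_fraction": self.occupancy_fraction,
            "dimer_count_means": self.dimer_count_means,
        }


def classify_angle(angle_deg: np.ndarray,
                   params: AnalysisParameters = DEFAULT_PARAMS) -> np.ndarray:
    """Map inter-axis angles to parallel/antiparallel/unclassified."""
    angle_deg = np.asarray(angle_deg, dtype=float)
    out = np.full(angle_deg.shape, "unclassified", dtype="U12")
    p_lo, p_hi = params.parallel_class
    a_lo, a_hi = params.antiparallel_class
    out[(angle_deg >= p_lo) & (angle_deg <= p_hi)] = "parallel"
    out[(angle_deg >= a_lo) & (angle_deg <= a_hi)] = "antiparallel"
    return out


# ---------------------------------------------------------------------------
# stylized LCAT fixture (synthetic stand-in for a coarse-grained structure)
# ---------------------------------------------------------------------------

_N_LCAT_BEADS = 50
#: bead index -> landmark (residue name, residue index)
_LANDMARK_BEADS = {
    25: ("CYS", 31),    # pose center, near the body centroid
    49: ("ILE", 326),   # pose tip, one end of the body axis
    40: ("GLY", 308),   # roll reference, off-axis
    48: ("PRO", 232),   # site-A anchor 1
    1: ("TRP", 48),     # site-A anchor 2
}
_FILLER_RESNAMES = ["ALA", "LEU", "SER", "VAL", "THR", "GLN", "ASN"]


def lcat_fixture() -> tuple[np.ndarray, list[str], list[int], list[str]]:
    """Synthetic rigid LCAT-like body: a 50-bead coarse helical chain.

    Returns (coords nm, residue names, residue indices, size classes).
    The geometry is purely stylized — it is a synthetic stand-in with the
    five landmark residues placed so that the pose and site-A analyses
    have well-conditioned geometry (PRO232-TRP48 separation ~6 nm spans a
    bound 22-residue rod).
    """
    k = np.arange(_N_LCAT_BEADS)
    t = k / (_N_LCAT_BEADS - 1)
    coords = np.stack(
        [6.0 * t - 3.0, np.cos(1.7 * k), np.sin(1.7 * k)], axis=1
    )
    resnames = []
    resids = []
    sizes = []
    for i in range(_N_LCAT_BEADS):
        if i in _LANDMARK_BEADS:
            name, resid = _LANDMARK_BEADS[i]
        else:
            name = _FILLER_RESNAMES[i % len(_FILLER_RESNAMES)]
            resid = int(i) * 8 + 2
        resnames.append(name)
        resids.append(resid)
        if i % 11 == 3:
            sizes.append("tiny")
        elif i % 7 == 2:
            sizes.append("small")
        else:
            sizes.append("regular")
    return coords, resnames, resids, sizes


def load_user_lcat(path) -> tuple[np.ndarray, list[str], list[int], list[str]]:
    """Import path for a user-supplied coarse-grained LCAT structure.

    Reads backbone beads (name BB) from a GRO/PDB file; size classes
    default to regular.  Untested against real deposited structures.
    """
    from .io import load_trajectory

    traj = load_trajectory(path)
    b = traj.beads
    mask = b.bead_role == "backbone"
    coords = np.asarray(traj.coords[0][mask], dtype=float)
    return (
        coords,
        list(b.residue_name[mask]),
        [int(r) for r in b.residue_index[mask]],
        list(b.size_class[mask]),
    )


# ---------------------------------------------------------------------------
# internal geometry helpers
# ---------------------------------------------------------------------------

def _sunflower(n: int, radius: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    r = radius * np.sqrt(i / n)
    phi = GOLDEN_ANGLE * np.arange(n)
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


def _lipid_coords(cfg: SyntheticConfig) -> np.ndarray:
    """Static (n_lipids*10, 3) two-leaflet disc; belt width 0.5 nm."""
    r_lip = cfg.rim_radius - 0.5
    if r_lip <= 0:
        raise GenerationError("rim_radius too small for a lipid disc")
    n_top = cfg.n_lipids - cfg.n_lipids // 2
    h = cfg.bilayer_half_thickness
    out = np.empty((cfg.n_lipids, 10, 3))
    anchors_top = _sunflower(n_top, r_lip)
    anchors_bot = _sunflower(cfg.n_lipids // 2, r_lip * 0.999)
    zs = np.array([0.0, 0.28, 0.56, 0.56, 0.84, 1.12, 1.40, 0.84, 1.12, 1.40])
    dx = np.array([0.0, 0.0, 0.08, -0.08, 0.08, 0.08, 0.08, -0.08, -0.08, -0.08])
    li = 0
    for anchors, sign in ((anchors_top, 1.0), (anchors_bot, -1.0)):
        for a in anchors:
            out[li, :, 0] = a[0] + dx
            out[li, :, 1] = a[1]
            out[li, :, 2] = sign * (h - zs)
            li += 1
    return out.reshape(-1, 3)


def peptide_rod(
    n_res: int,
    r13_position: np.ndarray,
    axis: np.ndarray,
    spacing: float = 0.35,
) -> np.ndarray:
    """Backbone coordinates of a straight rod with residue 13 anchored.

    Bead ``k`` (0-based) sits at ``r13 + (k - 12) * spacing * axis``.
    Public so tests can construct controlled pair geometries.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.arange(n_res)[:, None]
    return np.asarray(r13_position, dtype=float) + (k - 12) * spacing * axis


def _build_bead_table(cfg: SyntheticConfig, with_lcat: bool) -> tuple[
    BeadTable, dict
]:
    """Bead table plus an index layout for fast coordinate assembly."""
    seq = PEPTIDE_SEQUENCES[cfg.peptide_variant]
    charged = charged_residues_of(seq)
    charged_set = dict(charged)
    n_res = len(seq)

    mol_id, mol_type, resi, resn, role, charge, size, variant, names = (
        [] for _ in range(9)
    )

    next_id = 1
    for _ in range(cfg.n_lipids):
        for j in range(10):
            mol_id.append(next_id)
            mol_type.append("lipid")
            resi.append(1)
            resn.append("DMPC")
            role.append(_LIPID_ROLES[j])
            charge.append(0.0)
            size.append(_LIPID_SIZES[j])
            variant.append("")
            names.append(_LIPID_NAMES[j])
        next_id += 1

    pep_layout = []  # per peptide: (bb bead indices, sc (res0idx, bead index))
    cursor = len(mol_id)
    peptide_ids = []
    for _ in range(cfg.n_peptides):
        bb_idx = []
        sc_pairs = []
        for r in range(1, n_res + 1):
            mol_id.append(next_id)
            mol_type.append("peptide")
            resi.append(r)
            resn.append(AA_1TO3[seq[r - 1]])
            role.append("backbone")
            charge.append(0.0)
            size.append("regular")
            variant.append(cfg.peptide_variant)
            names.append("BB")
            bb_idx.append(cursor)
            cursor += 1
            if r in charged_set:
                mol_id.append(next_id)
                mol_type.append("peptide")
                resi.append(r)
                resn.append(AA_1TO3[seq[r - 1]])
                role.append("sidechain")
                charge.append(float(charged_set[r]))
                size.append("small")
                variant.append(cfg.peptide_variant)
                names.append("SC1")
                sc_pairs.append((r - 1, cursor))
                cursor += 1
        pep_layout.append((np.asarray(bb_idx), sc_pairs))
        peptide_ids.append(next_id)
        next_id += 1

    lcat_slice = None
    if with_lcat:
        coords_body, l_resn, l_resid, l_size = lcat_fixture()
        start = cursor
        for j in range(len(coords_body)):
            mol_id.append(next_id)
            mol_type.append("lcat")
            resi.append(l_resid[j])
            resn.append(l_resn[j])
            role.append("backbone")
            charge.append(0.0)
            size.append(l_size[j])
            variant.append("")
            names.append("BB")
            cursor += 1
        lcat_slice = slice(start, cursor)
        next_id += 1

    beads = BeadTable(
        molecule_id=np.asarray(mol_id),
        molecule_type=np.asarray(mol_type),
        residue_index=np.asarray(resi),
        residue_name=np.asarray(resn),
        bead_role=np.asarray(role),
        charge=np.asarray(charge),
        size_class=np.asarray(size),
        bead_name=np.asarray(names),
        variant=np.asarray(variant),
    )
    layout = {
        "n_res": n_res,
        "pep_layout": pep_layout,
        "peptide_ids": np.asarray(peptide_ids),
        "lcat_slice": lcat_slice,
        "n_lipid_beads": cfg.n_lipids * 10,
    }
    return beads, layout


def _rim_slots(cfg: SyntheticConfig, n_units: int) -> list[tuple[float, float]]:
    """(angle, z) rim slots for independently placed peptides/pair leaders."""
    n_levels = 3
    z_levels = (-0.8, 0.0, 0.8)
    per_level = math.ceil(n_units / n_levels)
    spacing = 2 * math.pi * cfg.rim_radius / max(per_level, 1)
    if spacing < 1.2:
        raise GenerationError(
            f"too many peptides ({cfg.n_peptides}) for rim circumference "
            f"2*pi*{cfg.rim_radius} nm"
        )
    slots = []
    for u in range(n_units):
        level = u % n_levels
        k = u // n_levels
        phi = 2 * math.pi * k / per_level + level * (2 * math.pi / (3 * per_level))
        slots.append((phi, z_levels[level]))
    return slots


def _place_sidechains(
    coords_f: np.ndarray, bb_idx: np.ndarray, sc_pairs: Sequence[tuple[int, int]]
) -> None:
    """Charged SC beads 0.3 nm radially outward from their backbone bead."""
    for res0, sc_i in sc_pairs:
        p = coords_f[bb_idx[res0]]
        r = math.hypot(p[0], p[1])
        if r < 1e-9:
            d = np.array([1.0, 0.0, 0.0])
        else:
            d = np.array([p[0] / r, p[1] / r, 0.0])
        coords_f[sc_i] = p + 0.3 * d


def _place_sidechains_batch(
    coords: np.ndarray, bb_idx: np.ndarray, sc_pairs: Sequence[tuple[int, int]]
) -> None:
    """Vectorized over frames version of :func:`_place_sidechains`."""
    if not sc_pairs:
        return
    res0 = np.asarray([p[0] for p in sc_pairs])
    sc_i = np.asarray([p[1] for p in sc_pairs])
    p = coords[:, bb_idx[res0], :]  # (F, n_sc, 3)
    r = np.hypot(p[..., 0], p[..., 1])
    r = np.where(r < 1e-9, 1.0, r)
    d = np.stack([p[..., 0] / r, p[..., 1] / r, np.zeros_like(r)], axis=-1)
    coords[:, sc_i, :] = p + 0.3 * d


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_disc_system(cfg: SyntheticConfig) -> tuple[Trajectory, GroundTruth]:
    """Peptide/lipid nanodisc without LCAT."""
    return _generate(cfg, with_lcat=False)


def generate_lcat_system(cfg: SyntheticConfig) -> tuple[Trajectory, GroundTruth]:
    """Nanodisc with the rigid LCAT body and a site-A occupancy schedule."""
    if not cfg.lcat_enabled:
        raise GenerationError("generate_lcat_system requires lcat_enabled=True")
    return _generate(cfg, with_lcat=True)


def _generate(cfg: SyntheticConfig, with_lcat: bool) -> tuple[Trajectory, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    beads, layout = _build_bead_table(cfg, with_lcat)
    F = cfg.n_frames
    N = len(beads)
    n_res = layout["n_res"]
    spacing = cfg.backbone_spacing
    coords = np.empty((F, N, 3), dtype=np.float32)

    # static lipids
    lip = _lipid_coords(cfg).astype(np.float32)
    coords[:, : layout["n_lipid_beads"], :] = lip[None]

    # peptide roles: pair leaders + followers, then singles
    n_anti = cfg.n_antiparallel_pairs
    n_par = cfg.n_parallel_pairs
    if 2 * (n_anti + n_par) > cfg.n_peptides:
        raise GenerationError("dimer fractions exceed available peptides")
    pair_classes = ["antiparallel"] * n_anti + ["parallel"] * n_par
    n_pairs = len(pair_classes)
    leaders = list(range(0, 2 * n_pairs, 2))
    followers = list(range(1, 2 * n_pairs, 2))
    singles = list(range(2 * n_pairs, cfg.n_peptides))
    units = leaders + singles  # independently slotted peptides
    slots = _rim_slots(cfg, len(units))
    slot_of = dict(zip(units, slots))
    direction_sign = rng.choice([-1.0, 1.0], size=cfg.n_peptides)

    pep_layout = layout["pep_layout"]
    peptide_ids = layout["peptide_ids"]

    tilt = np.deg2rad(rng.normal(0.0, cfg.axis_tilt_sigma, size=(F, cfg.n_peptides)))
    wobble = np.deg2rad(
        rng.normal(0.0, cfg.axis_azimuth_sigma, size=(F, cfg.n_peptides))
    )
    j_arc, j_z, j_r = _RIM_JITTER
    jitter_arc = rng.uniform(-j_arc, j_arc, size=(F, cfg.n_peptides))
    jitter_z = rng.uniform(-j_z, j_z, size=(F, cfg.n_peptides))
    jitter_r = rng.uniform(-j_r, j_r, size=(F, cfg.n_peptides))

    # per-frame dimer geometry draws
    if n_pairs:
        means = np.array(
            [cfg.dimer_angle_mean if c == "antiparallel"
             else 180.0 - cfg.dimer_angle_mean for c in pair_classes]
        )
        pair_theta = rng.normal(means[None, :], cfg.dimer_angle_sigma, size=(F, n_pairs))
        pair_theta = np.clip(pair_theta, 0.0, 180.0)
        lo, hi = cfg.dimer_r13_range
        pair_d = rng.uniform(lo, hi, size=(F, n_pairs))
    else:
        pair_theta = np.zeros((F, 0))
        pair_d = np.zeros((F, 0))

    k_off = (np.arange(n_res) - 12.0)[:, None] * spacing  # (n_res, 1)

    # place independently slotted peptides (vectorized over frames);
    # the R13 bead is anchored on the (jittered) slot point so the
    # inter-peptide R13 spacing is controlled exactly by the slot layout
    axes = np.empty((F, cfg.n_peptides, 3))
    r13_of = np.empty((F, cfg.n_peptides, 3))
    for p in units:
        phi, z0 = slot_of[p]
        s = direction_sign[p]
        alpha = phi + math.pi / 2.0 + wobble[:, p]  # in-plane axis direction
        ct, st = np.cos(tilt[:, p]), np.sin(tilt[:, p])
        u = s * np.stack(
            [ct * np.cos(alpha), ct * np.sin(alpha), st], axis=1
        )
        axes[:, p] = u
        phi_f = phi + jitter_arc[:, p] / cfg.rim_radius
        rad = cfg.rim_radius + jitter_r[:, p]
        r13 = np.stack(
            [rad * np.cos(phi_f), rad * np.sin(phi_f), z0 + jitter_z[:, p]],
            axis=1,
        )
        r13_of[:, p] = r13
        bb_idx, sc_pairs = pep_layout[p]
        coords[:, bb_idx, :] = (
            r13[:, None, :] + k_off[None] * u[:, None, :]
        ).astype(np.float32)
        _place_sidechains_batch(coords, bb_idx, sc_pairs)

    # place pair followers relative to their leaders: the follower axis
    # is the leader axis rotated by the drawn inter-axis angle about a
    # perpendicular axis, so the pair angle is exact by construction
    for j, (lead, foll) in enumerate(zip(leaders, followers)):
        phi, _ = slot_of[lead]
        r_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
        u_a = axes[:, lead]
        perp = r_hat[None] - (u_a @ r_hat)[:, None] * u_a
        perp /= np.linalg.norm(perp, axis=1, keepdims=True)
        theta = np.deg2rad(pair_theta[:, j])
        ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]
        u_b = u_a * ct + np.cross(perp, u_a) * st
        axes[:, foll] = u_b
        r13_b = r13_of[:, lead] + pair_d[:, j, None] * np.array([0, 0, 1.0])[None]
        bb_idx, sc_pairs = pep_layout[foll]
        coords[:, bb_idx, :] = (
            r13_b[:, None, :] + k_off[None] * u_b[:, None, :]
        ).astype(np.float32)
        _place_sidechains_batch(coords, bb_idx, sc_pairs)

    gt = GroundTruth()
    gt.dimer_pair_ids = [
        (int(peptide_ids[a]), int(peptide_ids[b]))
        for a, b in zip(leaders, followers)
    ]
    gt.dimer_r13 = pair_d
    gt.dimer_angle = pair_theta
    gt.dimer_class = classify_angle(pair_theta)
    if n_pairs:
        counts = {
            c: float(np.mean(np.sum(gt.dimer_class == c, axis=1)))
            for c in ("parallel", "antiparallel", "unclassified")
        }
    else:
        counts = {"parallel": 0.0, "antiparallel": 0.0, "unclassified": 0.0}
    gt.dimer_count_means = counts

    if with_lcat:
        _place_lcat(cfg, rng, coords, layout, singles, peptide_ids, gt,
                    pep_layout, spacing, n_res)
    _verify_labels(cfg, coords, layout, gt)

    times = np.arange(F, dtype=float) * cfg.dt
    topo = TopologyMap.default()
    traj = Trajectory(beads, coords, times, topo, None, f"seed{cfg.seed}")
    return traj, gt


def _markov_schedule(
    rng: np.random.Generator, n_frames: int, occupancy: float, mean_len: float
) -> np.ndarray:
    """Two-state chain with stationary bound probability ``occupancy`` and
    mean bound-run length ``mean_len`` frames."""
    if occupancy <= 0.0:
        return np.zeros(n_frames, dtype=bool)
    if occupancy >= 1.0:
        return np.ones(n_frames, dtype=bool)
    p_leave = 1.0 / mean_len
    p_enter = occupancy * p_leave / (1.0 - occupancy)
    p_enter = min(p_enter, 1.0)
    draws = rng.random(n_frames)
    state = np.empty(n_frames, dtype=bool)
    state[0] = draws[0] < occupancy
    for i in range(1, n_frames):
        if state[i - 1]:
            state[i] = draws[i] >= p_leave
        else:
            state[i] = draws[i] < p_enter
    return state


def _place_lcat(cfg, rng, coords, layout, singles, peptide_ids, gt,
                pep_layout, spacing, n_res) -> None:
    F = coords.shape[0]
    body, _, _, _ = lcat_fixture()
    c31 = body[25]
    i326 = body[49]
    g308 = body[40]
    u_body = i326 - c31
    u_body = u_body / np.linalg.norm(u_body)
    w_body = g308 - c31
    w_body = w_body - (w_body @ u_body) * u_body
    w_body = w_body / np.linalg.norm(w_body)
    basis_body = np.stack([u_body, w_body, np.cross(u_body, w_body)], axis=1)

    r_fix = cfg.rim_radius + 2.5
    z = rng.normal(cfg.lcat_z_mean, cfg.lcat_z_sigma, size=F)
    pitch = (
        cfg.pitch_intercept
        + cfg.pitch_slope * z
        + rng.normal(0.0, cfg.pitch_noise_sigma, size=F)
    ) % 360.0
    flip = rng.random(F) < cfg.roll_flip_probability

    x_hat = np.array([1.0, 0.0, 0.0])
    y_hat = np.array([0.0, 1.0, 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    lcat_slice = layout["lcat_slice"]
    body_rel = body - c31

    pr = np.deg2rad(pitch)
    v_lab = (-np.cos(pr))[:, None] * x_hat + np.sin(pr)[:, None] * z_hat  # (F,3)
    l3 = np.cross(v_lab, np.broadcast_to(y_hat, v_lab.shape))
    basis_lab = np.stack([v_lab, np.broadcast_to(y_hat, v_lab.shape), l3], axis=2)
    rot = basis_lab @ basis_body.T[None]  # (F, 3, 3)
    origin = np.stack(
        [np.full(F, r_fix), np.zeros(F), z], axis=1
    )
    coords[:, lcat_slice, :] = (
        origin[:, None, :] + np.einsum("fij,nj->fni", rot, body_rel)
    ).astype(np.float32)

    # site-A occupancy schedule
    bound = _markov_schedule(rng, F, cfg.occupancy_target, cfg.mean_event_length)
    eligible = singles if singles else list(range(cfg.n_peptides))
    occupant = np.full(F, -1, dtype=np.int64)
    current = -1
    for f in range(F):
        if bound[f]:
            if current < 0:
                current = int(rng.choice(eligible))
            occupant[f] = current
        else:
            current = -1

    # anchor positions per frame
    a_pro232 = coords[:, lcat_slice, :][:, 48, :].astype(np.float64)
    b_trp48 = coords[:, lcat_slice, :][:, 1, :].astype(np.float64)
    d1_off = rng.uniform(0.3, 0.6, size=F)
    k_arange = np.arange(n_res)[None, :, None] * spacing
    for p in np.unique(occupant[occupant >= 0]):
        sel = np.flatnonzero(occupant == p)
        a, b = a_pro232[sel], b_trp48[sel]
        away = a - b
        away /= np.linalg.norm(away, axis=1, keepdims=True)
        p1 = a + d1_off[sel, None] * away
        u = b - p1
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        bb_idx, sc_pairs = pep_layout[p]
        rods = p1[:, None, :] + k_arange * u[:, None, :]
        coords[np.ix_(sel, bb_idx)] = rods.astype(np.float32)
        for res0, sc_i in sc_pairs:
            q = rods[:, res0, :]
            r = np.hypot(q[:, 0], q[:, 1])
            r = np.where(r < 1e-9, 1.0, r)
            d = np.stack([q[:, 0] / r, q[:, 1] / r, np.zeros_like(r)], axis=1)
            coords[sel, sc_i, :] = (q + 0.3 * d).astype(np.float32)

    # upside-down flips: rotate whole frame 180 deg about x
    if flip.any():
        coords[flip] = coords[flip] * np.array([1.0, -1.0, -1.0], dtype=np.float32)

    gt.bound_peptide = np.where(
        occupant >= 0, peptide_ids[np.maximum(occupant, 0)], -1
    )
    gt.occupancy_fraction = float(bound.mean())
    gt.pose_r_xy = np.full(F, r_fix)
    gt.pose_z = z
    gt.pose_pitch = pitch
    gt.pose_roll = np.zeros(F)
    gt.flip = flip


def _verify_labels(cfg, coords, layout, gt) -> None:
    """Labels must be reproducible from the emitted coordinates."""
    pep_layout = layout["pep_layout"]
    peptide_ids = layout["peptide_ids"]
    P = cfg.n_peptides
    r13 = np.stack(
        [coords[:, pep_layout[p][0][12], :] for p in range(P)], axis=1
    ).astype(np.float64)  # (F, P, 3)
    pair_index = {
        tuple(sorted(pid)): j for j, pid in enumerate(gt.dimer_pair_ids)
    }
    id_of = {p: int(peptide_ids[p]) for p in range(P)}
    bound = gt.bound_peptide
    iu = np.triu_indices(P, k=1)
    diff = r13[:, iu[0], :] - r13[:, iu[1], :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))  # (F, n_pairs)
    for k, (a, b) in enumerate(zip(*iu)):
        key = tuple(sorted((id_of[int(a)], id_of[int(b)])))
        d = dist[:, k]
        if key in pair_index:
            ok = d <= cfg.dimer_r13_range[1] + 1e-6
            if bound is not None:
                ok |= (bound == key[0]) | (bound == key[1])
            if not ok.all():
                raise GenerationError(
                    f"designated dimer {key} drifted outside its R13 window"
                )
        else:
            near = d <= 1.0
            if bound is not None:
                near &= (bound != key[0]) & (bound != key[1])
            if near.any():
                raise GenerationError(
                    f"accidental dimer between peptides {key}"
                )


def generate_water_reference(n_frames: int, seed: int) -> Trajectory:
    """The rigid LCAT fixture alone, randomly rotated each frame."""
    body, resn, resid, size = lcat_fixture()
    body = body - body.mean(axis=0)
    rng = np.random.default_rng(seed)
    rots = Rotation.random(num=n_frames, random_state=rng)
    coords = np.einsum("fij,nj->fni", rots.as_matrix(), body)
    n = len(body)
    beads = BeadTable(
        molecule_id=np.ones(n, dtype=int),
        molecule_type=np.full(n, "lcat"),
        residue_index=np.asarray(resid),
        residue_name=np.asarray(resn),
        bead_role=np.full(n, "backbone"),
        charge=np.zeros(n),
        size_class=np.asarray(size),
    )
    return Trajectory(
        beads, coords, np.arange(n_frames, dtype=float), TopologyMap.default(),
        None, f"water-seed{seed}"
    )
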