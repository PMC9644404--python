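"""Dimerization analysis: angle-distance landscapes, the free-energy
transform dG = -RT ln(rho_{r,theta} / rho_ref), dimer detection and
classification, and charged-bead contact maps.

The pair geometry is the inter-axis angle between first->last residue
vectors (0 deg = parallel, 180 deg = antiparallel) as a function of the
R13-R13 backbone bead distance.  Dimers are peptide pairs with R13-R13
distance within 0-1 nm, greedily matched in ascending distance so each
peptide belongs to at most one dimer, and classified parallel
(0-60 deg) or antiparallel (120-180 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Trajectory
from .params import DEFAULT_PARAMS, AnalysisParameters
from .peptides import peptide_axes
from .synthetic import classify_angle


def pair_angle(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Angle between two peptide axis vectors in degrees, in [0, 180]."""
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length axis vector")
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


def _r13_coords(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    pep_ids, bb = traj.beads.peptide_backbone_matrix()
    if bb.shape[1] < 13:
        raise ValueError("peptides shorter than 13 residues have no R13 bead")
    return pep_ids, traj.coords[:, bb[:, 12], :].astype(np.float64)


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

@dataclass
class PairLandscape:
    r_edges: np.ndarray        # nm
    theta_edges: np.ndarray    # degrees
    counts: np.ndarray         # (n_r, n_theta)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mode_bin(self) -> tuple[float, float]:
        i, j = np.unravel_index(int(np.argmax(self.counts)), self.counts.shape)
        rc = 0.5 * (self.r_edges[i] + self.r_edges[i + 1])
        tc = 0.5 * (self.theta_edges[j] + self.theta_edges[j + 1])
        return float(rc), float(tc)


@dataclass
class FreeEnergyLandscape:
    r_edges: np.ndarray
    theta_edges: np.ndarray
    delta_g: np.ma.MaskedArray  # kJ/mol; zero-count bins masked
    reference: tuple[float, float]
    temperature: float
    gas_constant: float
    reference_count: int


def pair_landscape(
    traj: Trajectory,
    r_bin: float | None = None,
    theta_bin: float | None = None,
    r_max: float | None = None,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> PairLandscape:
    """Every unordered peptide pair contributes one (r, theta) point per
    frame."""
    _, r13 = _r13_coords(traj)
    _, axes = peptide_axes(traj)
    P = r13.shape[1]
    iu, ju = np.triu_indices(P, k=1)
    diff = r13[:, iu, :] - r13[:, ju, :]
    r = np.sqrt((diff ** 2).sum(axis=-1)).ravel()
    dots = np.einsum("fpk,fpk->fp", axes[:, iu, :], axes[:, ju, :])
    theta = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0))).ravel()
    rb = r_bin or params.landscape_r_bin
    tb = theta_bin or params.landscape_theta_bin
    rmax = r_max if r_max is not None else float(r.max()) + rb
    r_edges = np.arange(0.0, rmax + rb, rb)
    theta_edges = np.arange(0.0, 180.0 + tb / 2, tb)
    if theta_edges[-1] < 180.0:
        theta_edges = np.append(theta_edges, 180.0)
    counts, _, _ = np.histogram2d(r, theta, bins=(r_edges, theta_edges))
    return PairLandscape(r_edges, theta_edges, counts.astype(np.int64))


def free_energy(
    landscape: PairLandscape, params: AnalysisParameters = DEFAULT_PARAMS
) -> FreeEnergyLandscape:
    """dG = -RT ln(rho / rho_ref) with the reference bin at
    (1.75 nm, 135 deg) by default; empty bins are masked, never +-inf."""
    r_ref, t_ref = params.fe_reference
    i = int(np.searchsorted(landscape.r_edges, r_ref, side="right")) - 1
    j = int(np.searchsorted(landscape.theta_edges, t_ref, side="right")) - 1
    if not (0 <= i < landscape.counts.shape[0] and 0 <= j < landscape.counts.shape[1]):
        raise ValueError("reference point outside the landscape range")
    rho_ref = landscape.counts[i, j]
    if rho_ref == 0:
        raise ValueError(
            f"reference bin ({r_ref} nm, {t_ref} deg) has zero counts; "
            "choose a different fe_reference"
        )
    mask = landscape.counts == 0
    with np.errstate(divide="ignore"):
        logp = np.log(np.where(mask, 1.0, landscape.counts))
    dg = -params.rt * (logp - np.log(rho_ref))
    dg = np.ma.MaskedArray(dg, mask=mask)
    return FreeEnergyLandscape(
        landscape.r_edges,
        landscape.theta_edges,
        dg,
        (r_ref, t_ref),
        params.temperature,
        params.gas_constant,
        int(rho_ref),
    )


# ---------------------------------------------------------------------------
# dimer detection
# ---------------------------------------------------------------------------

@dataclass
class DimerRecord:
    frame: int
    pair: tuple[int, int]    # peptide molecule ids, sorted
    r13: float               # nm
    angle: float             # degrees
    dimer_class: str         # parallel | antiparallel | unclassified


def _greedy_match(dist: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Ascending-distance greedy matching of index pairs within cutoff."""
    P = dist.shape[0]
    iu, ju = np.triu_indices(P, k=1)
    d = dist[iu, ju]
    order = np.argsort(d, kind="stable")
    used = np.zeros(P, dtype=bool)
    out = []
    for k in order:
        if d[k] > cutoff:
            break
        a, b = int(iu[k]), int(ju[k])
        if not used[a] and not used[b]:
            used[a] = used[b] = True
            out.append((a, b))
    return out


def detect_dimers(
    traj: Trajectory,
    params: AnalysisParameters = DEFAULT_PARAMS,
    frames: np.ndarray | None = None,
) -> list[DimerRecord]:
    """Greedy matching of R13-proximal peptide pairs, per frame."""
    pep_ids, r13 = _r13_coords(traj)
    _, axes = peptide_axes(traj)
    records: list[DimerRecord] = []
    frame_iter = range(traj.n_frames) if frames is None else frames
    for f in frame_iter:
        diff = r13[f][:, None, :] - r13[f][None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        for a, b in _greedy_match(dist, params.dimer_r13_max):
            dots = float(np.clip(axes[f, a] @ axes[f, b], -1.0, 1.0))
            ang = float(np.degrees(np.arccos(dots)))
            records.append(
                DimerRecord(
                    int(f),
                    (int(pep_ids[a]), int(pep_ids[b])),
                    float(dist[a, b]),
                    ang,
                    str(classify_angle(np.array(ang), params)),
                )
            )
    return records


@dataclass
class DimerCounts:
    frames: np.ndarray
    parallel: np.ndarray
    antiparallel: np.ndarray
    unclassified: np.ndarray

    @property
    def means(self) -> dict[str, float]:
        return {
            "parallel": float(self.parallel.mean()),
            "antiparallel": float(self.antiparallel.mean()),
            "unclassified": float(self.unclassified.mean()),
        }


def dimer_counts_per_frame(
    traj: Trajectory, params: AnalysisParameters = DEFAULT_PARAMS
) -> tuple[DimerCounts, list[DimerRecord]]:
    records = detect_dimers(traj, params)
    F = traj.n_frames
    counts = {c: np.zeros(F, dtype=int)
              for c in ("parallel", "antiparallel", "unclassified")}
    for rec in records:
        counts[rec.dimer_class][rec.frame] += 1
    return (
        DimerCounts(np.arange(F), counts["parallel"], counts["antiparallel"],
                    counts["unclassified"]),
        records,
    )


# ---------------------------------------------------------------------------
# charged contact maps
# ---------------------------------------------------------------------------

@dataclass
class ChargedContactMap:
    labels: list[str]                      # charged residues, e.g. D4 R7 ...
    raw: dict[str, np.ndarray] = field(default_factory=dict)
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    n_dimers: dict[str, int] = field(default_factory=dict)


def charged_contact_map(
    traj: Trajectory,
    params: AnalysisParameters = DEFAULT_PARAMS,
    records: list[DimerRecord] | None = None,
) -> ChargedContactMap:
    """Charged-bead contact maps per dimer class.

    For each dimer and frame, every charged bead of one peptide is
    compared with every charged bead of the other; a pair of residues is
    in contact if any such distance is below 0.6 nm.  Counts accumulate
    over both role assignments of the unordered dimer (so a symmetric
    heterogeneous contact like E8-K20 can reach a normalized value of
    two) while homogeneous pairs (e.g. E8-E8) count once per dimer;
    values are then divided by the number of dimers found in the class.
    Dimers with angles in the open (60, 120) band are excluded.
    """
    variant = traj.peptide_variant()
    seq = traj.topology.peptide_sequences[variant]
    charged = traj.topology.charged_residues[variant]
    labels = [f"{seq[r - 1]}{r}" for r, _ in charged]
    n_c = len(labels)
    pep_ids, _ = traj.beads.peptide_backbone_matrix()
    # charged (side-chain) bead index per peptide per charged residue
    b = traj.beads
    cb = np.empty((len(pep_ids), n_c), dtype=np.int64)
    for pi, mid in enumerate(pep_ids):
        for ci, (r, _) in enumerate(charged):
            idx = np.flatnonzero(
                (b.molecule_id == mid)
                & (b.residue_index == r)
                & (b.bead_role == "sidechain")
                & (b.charge != 0)
            )
            if len(idx) != 1:
                raise ValueError(
                    f"peptide {mid}: residue {r} should carry exactly one "
                    f"charged bead, found {len(idx)}"
                )
            cb[pi, ci] = idx[0]
    id_to_row = {int(m): i for i, m in enumerate(pep_ids)}

    if records is None:
        records = detect_dimers(traj, params)
    classes = ("parallel", "antiparallel")
    raw = {c: np.zeros((n_c, n_c)) for c in classes}
    n_dimers = {c: 0 for c in classes}
    cutoff = params.charged_contact_cutoff
    for rec in records:
        c = rec.dimer_class
        if c not in raw:
            continue
        n_dimers[c] += 1
        pa, pb = (id_to_row[m] for m in rec.pair)
        xa = traj.coords[rec.frame, cb[pa], :].astype(np.float64)
        xb = traj.coords[rec.frame, cb[pb], :].astype(np.float64)
        d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=-1))
        m = d < cutoff
        contrib = m.astype(float) + m.T.astype(float)
        np.fill_diagonal(contrib, np.diag(m).astype(float))
        raw[c] += contrib
    normalized = {
        c: (raw[c] / n_dimers[c] if n_dimers[c] > 0 else np.zeros_like(raw[c]))
        for c in classes
    }
    return ChargedContactMap(labels, raw, normalized, n_dimers)
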