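"""Peptide organization on the disc: radial profiles, orientation
distributions, rotational autocorrelation, spatial clustering.

All operations expect an aligned trajectory (disc normal along z, lipid
center of mass at the origin); the radial profile re-centers on the
per-frame lipid COM so small residual drifts are harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .model import Frame, TopologyError, Trajectory
from .params import DEFAULT_PARAMS, AnalysisParameters


class AxisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# peptide axes
# ---------------------------------------------------------------------------

def peptide_axes(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(peptide molecule ids, (F, P, 3) unit first->last residue vectors).

    The axis runs from the first-residue backbone bead to the
    last-residue backbone bead of each peptide (R1->R22, or R1->R21 for
    the 21-residue variant).
    """
    pep_ids, bb = traj.beads.peptide_backbone_matrix()
    variant = traj.peptide_variant()
    first, last = traj.topology.peptide_axis_endpoints[variant]
    head = traj.coords[:, bb[:, first - 1], :].astype(np.float64)
    tail = traj.coords[:, bb[:, last - 1], :].astype(np.float64)
    vec = tail - head
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise AxisError("coincident axis endpoints")
    return pep_ids, vec / norm


def peptide_axis(frame: Frame, molecule_id: int,
                 endpoints: tuple[int, int] | None = None) -> np.ndarray:
    """Unit axis vector of one peptide in one frame."""
    beads = frame.beads
    if endpoints is None:
        resi = beads.residue_index[beads.molecule_id == molecule_id]
        if len(resi) == 0:
            raise TopologyError(f"no molecule {molecule_id} in frame")
        endpoints = (int(resi.min()), int(resi.max()))
    i0 = beads.backbone_index(molecule_id, endpoints[0])
    i1 = beads.backbone_index(molecule_id, endpoints[1])
    v = np.asarray(frame.positions[i1], float) - np.asarray(frame.positions[i0], float)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise AxisError("coincident axis endpoints")
    return v / n


# ---------------------------------------------------------------------------
# radial profile
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    bin_edges: np.ndarray        # nm
    density: np.ndarray          # per-area (annulus) or per-volume (shell)
    normalization: str           # "annulus" | "shell"
    selection: str = ""
    mean_count: float = 0.0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode_radius(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.density))])


def radial_profile(
    traj: Trajectory,
    selection: np.ndarray | str,
    bin_width: float | None = None,
    normalization: str = "annulus",
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> RadialProfile:
    """Per-annulus (default) or per-shell density of a bead selection
    around the lipid center of mass."""
    if isinstance(selection, str):
        name = selection
        mask = traj.beads.mask(molecule_type=selection)
    else:
        name = "custom"
        mask = np.asarray(selection)
        if mask.dtype == bool and not mask.any():
            raise ValueError("empty selection")
    if mask.dtype == bool and not mask.any():
        raise ValueError("empty selection")
    bw = bin_width or params.radial_bin
    lip = traj.beads.mask(molecule_type="lipid")
    xyz = traj.coords[:, mask, :].astype(np.float64)
    if lip.any():
        com = traj.coords[:, lip, :].mean(axis=1, dtype=np.float64)
    else:
        com = np.zeros((traj.n_frames, 3))
    rel = xyz - com[:, None, :]
    if normalization == "annulus":
        r = np.hypot(rel[..., 0], rel[..., 1]).ravel()
    elif normalization == "shell":
        r = np.linalg.norm(rel, axis=-1).ravel()
    else:
        raise ValueError("normalization must be 'annulus' or 'shell'")
    r_max = float(r.max()) + bw
    edges = np.arange(0.0, r_max + bw, bw)
    counts, _ = np.histogram(r, bins=edges)
    mean_counts = counts / traj.n_frames
    if normalization == "annulus":
        area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    else:
        area = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return RadialProfile(edges, mean_counts / area, normalization, name,
                         float(mean_counts.sum()))


# ---------------------------------------------------------------------------
# orientation distribution
# ---------------------------------------------------------------------------

@dataclass
class AngleDistribution:
    bin_edges: np.ndarray    # degrees, [0, 180]
    probability: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def normal_angle_distribution(
    traj: Trajectory,
    bin_width: float | None = None,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> AngleDistribution:
    """Distribution of the angle between each peptide axis and +z."""
    _, axes = peptide_axes(traj)
    bw = bin_width or params.angle_bin
    cosz = np.clip(axes[..., 2], -1.0, 1.0)
    theta = np.degrees(np.arccos(cosz)).ravel()
    edges = np.arange(0.0, 180.0 + bw / 2, bw)
    if edges[-1] < 180.0:
        edges = np.append(edges, 180.0)
    counts, _ = np.histogram(theta, bins=edges)
    prob = counts / counts.sum()
    return AngleDistribution(edges, prob)


# ---------------------------------------------------------------------------
# rotational autocorrelation
# ---------------------------------------------------------------------------

@dataclass
class Rotacf:
    lags: np.ndarray        # time units of the trajectory
    values: np.ndarray
    order: int
    half_life: float        # first lag with C <= 0.5 (interpolated); nan if none


def _legendre(x: np.ndarray, order: int) -> np.ndarray:
    if order == 1:
        return x
    if order == 2:
        return 1.5 * x * x - 0.5
    raise ValueError("Legendre order must be 1 or 2")


def rotacf(
    traj: Trajectory, order: int = 1, max_lag: int | None = None
) -> Rotacf:
    """C(tau) = <P_order(u(t) . u(t+tau))> over peptides and time origins."""
    if traj.n_frames < 2:
        raise ValueError("rotacf needs at least 2 frames")
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("rotacf requires uniform time spacing")
    _, axes = peptide_axes(traj)  # (F, P, 3)
    F = axes.shape[0]
    if max_lag is None:
        max_lag = F - 1
    max_lag = min(max_lag, F - 1)
    values = np.empty(max_lag + 1)
    values[0] = 1.0
    for lag in range(1, max_lag + 1):
        dots = np.einsum("fpk,fpk->fp", axes[: F - lag], axes[lag:])
        values[lag] = _legendre(np.clip(dots, -1.0, 1.0), order).mean()
    lags = np.arange(max_lag + 1) * float(dt[0])
    below = np.flatnonzero(values <= 0.5)
    if len(below) == 0:
        half = float("nan")
    else:
        j = int(below[0])
        if j == 0:
            half = 0.0
        else:
            c0, c1 = values[j - 1], values[j]
            frac = (c0 - 0.5) / (c0 - c1) if c0 != c1 else 0.0
            half = float(lags[j - 1] + frac * (lags[j] - lags[j - 1]))
    return Rotacf(lags, values, order, half)


# ---------------------------------------------------------------------------
# spatial clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSummary:
    cutoff: float
    per_frame_counts: np.ndarray
    size_distribution: dict[int, int] = field(default_factory=dict)
    oligomer_fraction: float = 0.0   # mean fraction of peptides in size >= 2
    n_peptides: int = 0


def cluster_peptides(
    frame: Frame, cutoff: float, beads_used: str = "all"
) -> np.ndarray:
    """Single-linkage cluster labels per peptide for one frame.

    Two peptides are linked if their minimum inter-bead distance (over
    all beads, or backbone beads only) is <= cutoff.
    """
    beads = frame.beads
    if beads_used == "all":
        pep_mask = beads.molecule_type == "peptide"
    elif beads_used == "backbone":
        pep_mask = (beads.molecule_type == "peptide") & (
            beads.bead_role == "backbone"
        )
    else:
        raise ValueError("beads_used must be 'all' or 'backbone'")
    mol = beads.molecule_id[pep_mask]
    pep_ids = np.unique(mol)
    P = len(pep_ids)
    pos = np.asarray(frame.positions, np.float64)[pep_mask]
    d = cdist(pos, pos)
    owner = np.searchsorted(pep_ids, mol)
    adj = np.zeros((P, P), dtype=bool)
    within = d <= cutoff
    for a in range(P):
        ia = owner == a
        for b in range(a + 1, P):
            if within[np.ix_(ia, owner == b)].any():
                adj[a, b] = adj[b, a] = True
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def cluster_summary(
    traj: Trajectory, cutoff: float, beads_used: str = "all"
) -> ClusterSummary:
    counts = np.empty(traj.n_frames, dtype=int)
    sizes: dict[int, int] = {}
    olig = np.empty(traj.n_frames)
    n_pep = 0
    for i, frame in enumerate(traj):
        labels = cluster_peptides(frame, cutoff, beads_used)
        n_pep = len(labels)
        _, cluster_sizes = np.unique(labels, return_counts=True)
        counts[i] = len(cluster_sizes)
        for s in cluster_sizes:
            sizes[int(s)] = sizes.get(int(s), 0) + 1
        olig[i] = cluster_sizes[cluster_sizes >= 2].sum() / n_pep
    return ClusterSummary(cutoff, counts, sizes, float(olig.mean()), n_pep)
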