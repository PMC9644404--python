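"""Shrake-Rupley solvent-accessible surface area with coarse-grained
bead radii.

Bead van der Waals radii follow the three Martini size classes
(regular 0.264 nm, small 0.225 nm, tiny 0.185 nm) and the probe radius
is one regular bead (0.264 nm).  Each bead's accessible area is the
fraction of deterministic sphere points (default 960, Fibonacci
lattice) on its probe-expanded sphere that fall outside every
neighbour's probe-expanded sphere, times the full sphere area.  Water
is never modeled explicitly: "in water" means the analyzed molecule is
its own only occluder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import Trajectory
from .params import DEFAULT_PARAMS, AnalysisParameters


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * np.arange(n)
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def radii_from_size_classes(
    size_class: np.ndarray, params: AnalysisParameters = DEFAULT_PARAMS
) -> np.ndarray:
    try:
        return np.asarray([params.bead_radii[s] for s in size_class])
    except KeyError as exc:
        raise ValueError(f"unknown size class {exc.args[0]!r}") from exc


def shrake_rupley(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float | None = None,
    n_points: int | None = None,
    report: np.ndarray | None = None,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> np.ndarray:
    """Per-bead SASA in nm^2.

    ``report`` restricts which beads get an area (others return 0) while
    every bead still occludes; by default all beads are reported.
    """
    positions = np.asarray(positions, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    probe = params.probe_radius if probe_radius is None else probe_radius
    npts = params.sasa_points if n_points is None else n_points
    if len(positions) != len(radii):
        raise ValueError("positions and radii must have equal length")
    sphere = fibonacci_sphere(npts)
    expanded = radii + probe
    tree = cKDTree(positions)
    r_max = expanded.max()
    out = np.zeros(len(positions))
    indices = range(len(positions)) if report is None else np.flatnonzero(report)
    for i in indices:
        ri = expanded[i]
        neigh = tree.query_ball_point(positions[i], ri + r_max)
        neigh = [j for j in neigh if j != i]
        pts = positions[i] + ri * sphere
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((pts[:, None, :] - positions[nb][None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = npts
        out[i] = 4.0 * np.pi * ri * ri * accessible / npts
    return out


@dataclass
class SasaProfile:
    residue_index: np.ndarray
    residue_name: np.ndarray
    mean: np.ndarray          # nm^2 per residue
    sd: np.ndarray
    label: str = ""
    n_frames: int = 0


def per_residue_profile(
    traj: Trajectory,
    molecule_type: str = "lcat",
    start: int = 0,
    stride: int = 1,
    occluders: np.ndarray | None = None,
    label: str = "",
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> SasaProfile:
    """Mean +- SD of per-residue SASA of one molecule type over frames.

    Occluders default to every bead in the system (the analyzed molecule
    plus any lipids/peptides present); per-bead areas are summed within
    residues of the reported molecule.
    """
    b = traj.beads
    report = b.mask(molecule_type=molecule_type)
    if not report.any():
        raise ValueError(f"no {molecule_type} beads present")
    occ = np.ones(len(b), dtype=bool) if occluders is None else np.asarray(occluders)
    occ_idx = np.flatnonzero(occ | report)
    radii = radii_from_size_classes(b.size_class[occ_idx], params)
    report_local = report[occ_idx]
    resi = b.residue_index[occ_idx][report_local]
    uniq, inverse = np.unique(resi, return_inverse=True)
    frames = range(start, traj.n_frames, stride)
    per_frame = []
    for f in frames:
        areas = shrake_rupley(
            traj.coords[f][occ_idx], radii, report=report_local, params=params
        )
        per_frame.append(np.bincount(inverse, weights=areas[report_local],
                                     minlength=len(uniq)))
    stacked = np.asarray(per_frame)
    if stacked.shape[0] == 0:
        raise ValueError("no frames selected")
    names = np.empty(len(uniq), dtype="U8")
    rep_resi = b.residue_index[occ_idx][report_local]
    rep_resn = b.residue_name[occ_idx][report_local]
    for k, r in enumerate(uniq):
        names[k] = rep_resn[rep_resi == r][0]
    return SasaProfile(
        uniq,
        names,
        stacked.mean(axis=0),
        stacked.std(axis=0, ddof=1) if stacked.shape[0] > 1 else np.zeros(len(uniq)),
        label,
        stacked.shape[0],
    )


def combine_replicates(profiles: list[SasaProfile], label: str = "") -> SasaProfile:
    """Across-replicate mean and SD of per-residue means."""
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_index, first.residue_index):
            raise ValueError("replicates have mismatched residue sets")
    means = np.stack([p.mean for p in profiles])
    return SasaProfile(
        first.residue_index,
        first.residue_name,
        means.mean(axis=0),
        means.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(first.mean),
        label,
        sum(p.n_frames for p in profiles),
    )


def sasa_difference(reference: SasaProfile, bound: SasaProfile) -> np.ndarray:
    """Per-residue delta = reference - bound; positive values mark
    residues protected (buried) in the bound state."""
    if not np.array_equal(reference.residue_index, bound.residue_index):
        raise ValueError("profiles cover different residue sets")
    return reference.mean - bound.mean
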