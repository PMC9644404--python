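"""Site-A binding analysis: occupancy detection and event statistics,
peptide-LCAT residue contact heatmaps, and spatial density grids.

A peptide occupies site A (the groove flanked by the LCAT lid and
membrane-binding domain) when its first-residue backbone bead is within
1 nm of LCAT PRO232 and its residue-21 backbone bead within 2 nm of
LCAT TRP48.  Each frame, the candidate is the peptide with the minimum
combined distance d1 + d2; only that peptide is tested against the two
thresholds, so at most one peptide is bound per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import kabsch_fit
from .model import Frame, Trajectory
from .params import DEFAULT_PARAMS, AnalysisParameters

BOHR_PER_NM = 18.897259886


@dataclass
class SiteAState:
    frame: int
    bound: bool
    peptide_id: int | None
    d1: float    # nm, P1 backbone - LCAT PRO232 backbone
    d2: float    # nm, L21 backbone - LCAT TRP48 backbone


@dataclass
class SiteASeries:
    frames: np.ndarray
    bound: np.ndarray          # (F,) bool
    peptide_id: np.ndarray     # (F,) molecule id, -1 when unbound
    d1: np.ndarray             # of the selected candidate
    d2: np.ndarray
    n_satisfying: np.ndarray   # diagnostic: peptides meeting both thresholds

    def __len__(self) -> int:
        return len(self.frames)

    def state(self, f: int) -> SiteAState:
        return SiteAState(
            int(self.frames[f]),
            bool(self.bound[f]),
            int(self.peptide_id[f]) if self.bound[f] else None,
            float(self.d1[f]),
            float(self.d2[f]),
        )


def siteA_series(
    traj: Trajectory, params: AnalysisParameters = DEFAULT_PARAMS
) -> SiteASeries:
    """Per-frame site-A state from the minimum-combined-distance candidate."""
    pep_ids, bb = traj.beads.peptide_backbone_matrix()
    if bb.shape[1] < 21:
        raise ValueError("peptides need at least 21 residues for site-A "
                         "detection")
    a1 = traj.landmark_index("siteA_anchor_1")   # PRO232
    a2 = traj.landmark_index("siteA_anchor_2")   # TRP48
    p1 = traj.coords[:, bb[:, 0], :].astype(np.float64)    # (F, P, 3)
    l21 = traj.coords[:, bb[:, 20], :].astype(np.float64)
    xa1 = traj.coords[:, a1, :].astype(np.float64)[:, None, :]
    xa2 = traj.coords[:, a2, :].astype(np.float64)[:, None, :]
    d1 = np.linalg.norm(p1 - xa1, axis=-1)
    d2 = np.linalg.norm(l21 - xa2, axis=-1)
    best = np.argmin(d1 + d2, axis=1)
    rows = np.arange(traj.n_frames)
    sel_d1 = d1[rows, best]
    sel_d2 = d2[rows, best]
    bound = (sel_d1 < params.siteA_d1_max) & (sel_d2 < params.siteA_d2_max)
    satisfying = ((d1 < params.siteA_d1_max) & (d2 < params.siteA_d2_max)).sum(axis=1)
    pid = np.where(bound, pep_ids[best], -1)
    return SiteASeries(rows, bound, pid, sel_d1, sel_d2, satisfying)


def siteA_state(
    frame: Frame, frame_index: int = 0,
    params: AnalysisParameters = DEFAULT_PARAMS, topology=None,
) -> SiteAState:
    from .model import Trajectory as _T

    traj = _T(frame.beads, frame.positions[None, ...], [frame.time], topology)
    series = siteA_series(traj, params)
    st = series.state(0)
    return SiteAState(frame_index, st.bound, st.peptide_id, st.d1, st.d2)


# ---------------------------------------------------------------------------
# occupancy statistics
# ---------------------------------------------------------------------------

@dataclass
class OccupancyStats:
    occupancy_percent: float
    n_entries: int
    mean_event_length: float   # frames
    max_event_length: int
    n_peptide_changes: int
    n_frames: int
    event_lengths: np.ndarray


def occupancy_stats(series: SiteASeries) -> OccupancyStats:
    """Occupancy percentage plus binding-event statistics.

    Events are maximal runs of consecutive bound frames; an entry is an
    unbound->bound transition (a bound first frame counts); a peptide
    change is a bound frame whose occupant differs from the previous
    bound frame's occupant.
    """
    bound = np.asarray(series.bound, dtype=bool)
    n = len(bound)
    if n < 1:
        raise ValueError("need at least one frame")
    occupancy = 100.0 * bound.mean()
    padded = np.concatenate([[False], bound, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    lengths = ends - starts
    ids = series.peptide_id[bound]
    changes = int(np.sum(ids[1:] != ids[:-1])) if len(ids) > 1 else 0
    return OccupancyStats(
        float(occupancy),
        int(len(lengths)),
        float(lengths.mean()) if len(lengths) else 0.0,
        int(lengths.max()) if len(lengths) else 0,
        changes,
        n,
        lengths,
    )


# ---------------------------------------------------------------------------
# residue contact heatmaps
# ---------------------------------------------------------------------------

@dataclass
class ResidueContactHeatmap:
    peptide_rows: list[str]           # e.g. ["R7", "K22"]
    lcat_residues: list[str]          # e.g. ["TRP48", ...] ordered by resid
    raw: np.ndarray                   # (n_rows, n_lcat) replicate-summed
    normalized: np.ndarray            # raw / max (zeros if empty)


def residue_contact_heatmap(
    trajs: Trajectory | list[Trajectory],
    peptide_residues: tuple[int, ...] = (7, 22),
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> ResidueContactHeatmap:
    """Counts of frames x peptides with a peptide-residue backbone bead
    within 0.6 nm of each LCAT backbone bead; replicates are summed and
    the map normalized by its maximum.  Rows for residues absent from
    the variant (e.g. residue 22 of the 21-residue variant) are omitted.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    first = trajs[0]
    variant = first.peptide_variant()
    seq = first.topology.peptide_sequences[variant]
    rows = [r for r in peptide_residues if r <= len(seq)]
    row_labels = [f"{seq[r - 1]}{r}" for r in rows]
    b = first.beads
    lcat_sel = np.flatnonzero(b.mask(molecule_type="lcat", bead_role="backbone"))
    if len(lcat_sel) == 0:
        raise ValueError("no LCAT backbone beads present")
    order = np.argsort(b.residue_index[lcat_sel], kind="stable")
    lcat_sel = lcat_sel[order]
    lcat_labels = [
        f"{b.residue_name[i]}{b.residue_index[i]}" for i in lcat_sel
    ]
    raw = np.zeros((len(rows), len(lcat_sel)))
    cutoff = params.heatmap_cutoff
    for traj in trajs:
        _, bb = traj.beads.peptide_backbone_matrix()
        xl = traj.coords[:, lcat_sel, :].astype(np.float64)
        for k, r in enumerate(rows):
            xp = traj.coords[:, bb[:, r - 1], :].astype(np.float64)
            d = np.linalg.norm(
                xp[:, :, None, :] - xl[:, None, :, :], axis=-1
            )
            raw[k] += (d < cutoff).sum(axis=(0, 1))
    peak = raw.max()
    normalized = raw / peak if peak > 0 else np.zeros_like(raw)
    return ResidueContactHeatmap(row_labels, lcat_labels, raw, normalized)


# ---------------------------------------------------------------------------
# spatial density
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    origin: np.ndarray       # nm
    bin_width: float         # nm
    counts: np.ndarray       # (nx, ny, nz) int64

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def argmax_position(self) -> np.ndarray:
        idx = np.unravel_index(int(np.argmax(self.counts)), self.counts.shape)
        return self.origin + (np.asarray(idx) + 0.5) * self.bin_width

    def write_cube(self, path, comment: str = "peptide density") -> None:
        """Gaussian cube file (atomic units) with the grid counts."""
        nx, ny, nz = self.counts.shape
        o = self.origin * BOHR_PER_NM
        s = self.bin_width * BOHR_PER_NM
        lines = [comment, "occupancy counts on a 0.2 nm-class grid"]
        lines.append(f"{1:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
        lines.append(f"{nx:5d}{s:12.6f}{0.0:12.6f}{0.0:12.6f}")
        lines.append(f"{ny:5d}{0.0:12.6f}{s:12.6f}{0.0:12.6f}")
        lines.append(f"{nz:5d}{0.0:12.6f}{0.0:12.6f}{s:12.6f}")
        lines.append(f"{6:5d}{0.0:12.6f}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
        flat = self.counts.astype(float).reshape(nx * ny, nz)
        for row in flat:
            for i in range(0, nz, 6):
                lines.append("".join(f"{v:13.5E}" for v in row[i:i + 6]))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def spatial_density(
    traj: Trajectory,
    reference: Frame | None = None,
    params: AnalysisParameters = DEFAULT_PARAMS,
    padding: float = 3.0,
) -> DensityGrid:
    """Peptide-bead occupancy grid after rigid superposition onto the
    reference LCAT backbone.

    The grid covers the reference LCAT bounding box padded by 3 nm with
    0.2 nm voxels; beads falling outside are clipped into the edge
    voxels so the total count equals peptide beads x frames exactly.
    """
    b = traj.beads
    lcat = np.flatnonzero(b.mask(molecule_type="lcat", bead_role="backbone"))
    pep = b.mask(molecule_type="peptide")
    if len(lcat) < 3:
        raise ValueError("need at least 3 LCAT backbone beads for fitting")
    if not pep.any():
        raise ValueError("no peptide beads to grid")
    if reference is None:
        reference = traj.frame(0)
    ref_xyz = np.asarray(reference.positions, np.float64)[lcat]
    lo = ref_xyz.min(axis=0) - padding
    hi = ref_xyz.max(axis=0) + padding
    bw = params.density_bin
    shape = np.maximum(np.ceil((hi - lo) / bw).astype(int), 1)
    counts = np.zeros(tuple(shape), dtype=np.int64)
    for i in range(traj.n_frames):
        fitted, _ = kabsch_fit(traj.frame(i), reference, lcat)
        xyz = np.asarray(fitted.positions, np.float64)[pep]
        idx = np.floor((xyz - lo) / bw).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
    return DensityGrid(lo, bw, counts)
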