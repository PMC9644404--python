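"""LCAT attachment monitoring and pose determination.

The pose of the rigid LCAT body relative to the aligned disc is read off
three landmark backbone beads: CYS31 (body center), ILE326 (body tip)
and GLY308 (roll reference).  With the disc normal along z and the lipid
COM at the origin, a vertical plane is spanned by the COM, CYS31 and the
z axis.  The pitch is the polar angle of the CYS31->ILE326 vector
projected on that plane: 0 deg points horizontally toward the z-axis
line, 90 deg toward +z, 180 deg away from the line and 270 deg toward
-z.  The yaw is the out-of-plane angle of the same vector, and the roll
is the signed rotation of CYS31->GLY308 about the body axis measured
from the plane normal.  A roll beyond 90 deg flags an upside-down disc
orientation; such frames are flip-corrected (z negated, pitch
reflected, roll re-measured) before any statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import Frame, Trajectory
from .params import DEFAULT_PARAMS, AnalysisParameters

logger = logging.getLogger(__name__)


class PoseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# contact series
# ---------------------------------------------------------------------------

@dataclass
class ContactSeries:
    times: np.ndarray
    counts: np.ndarray   # peptide backbone beads within cutoff of LCAT

    def plateau_frame(self, window: int = 50, tol: float = 0.05) -> int:
        """First frame after which the sliding-window mean changes < tol
        (relative).  A crude equilibration heuristic; pose statistics
        accept an explicit start frame instead."""
        n = len(self.counts)
        if n <= 2 * window:
            return 0
        means = np.convolve(self.counts, np.ones(window) / window, mode="valid")
        ref = np.abs(means).max() or 1.0
        for i in range(len(means) - window):
            if abs(means[i + window] - means[i]) / ref < tol:
                return i
        return 0


def lcat_contact_series(
    traj: Trajectory,
    params: AnalysisParameters = DEFAULT_PARAMS,
    chunk: int = 200,
) -> ContactSeries:
    """Per frame, the number of peptide backbone beads within the 3 nm
    cutoff of any LCAT backbone bead."""
    b = traj.beads
    lcat = b.mask(molecule_type="lcat", bead_role="backbone")
    pep = b.mask(molecule_type="peptide", bead_role="backbone")
    if not lcat.any():
        raise PoseError("no LCAT molecule in topology")
    if not pep.any():
        raise PoseError("no peptide molecules in topology")
    cut2 = params.lcat_contact_cutoff ** 2
    F = traj.n_frames
    counts = np.empty(F, dtype=int)
    for start in range(0, F, chunk):
        stop = min(start + chunk, F)
        xp = traj.coords[start:stop][:, pep, :].astype(np.float64)
        xl = traj.coords[start:stop][:, lcat, :].astype(np.float64)
        d2 = ((xp[:, :, None, :] - xl[:, None, :, :]) ** 2).sum(axis=-1)
        counts[start:stop] = (d2.min(axis=2) <= cut2).sum(axis=1)
    return ContactSeries(np.array(traj.times), counts)


# ---------------------------------------------------------------------------
# pose
# ---------------------------------------------------------------------------

@dataclass
class LcatPose:
    frame: int
    r_xy: float      # nm, CYS31 in-plane distance from disc COM
    z: float         # nm, CYS31 height
    pitch: float     # degrees in [0, 360)
    yaw: float       # degrees
    roll: float      # degrees in (-180, 180]
    flip_applied: bool


@dataclass
class PoseSeries:
    frames: np.ndarray
    times: np.ndarray
    r_xy: np.ndarray
    z: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray
    flip_applied: np.ndarray
    skipped_frames: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)


def _raw_pose(c31, i326, g308):
    """Vectorized pose from landmark positions relative to the disc COM.

    Inputs are (..., 3); returns (r_xy, z, pitch, yaw, roll) arrays.
    """
    r_xy = np.hypot(c31[..., 0], c31[..., 1])
    z = c31[..., 2]
    r_hat = np.stack(
        [c31[..., 0] / r_xy, c31[..., 1] / r_xy, np.zeros_like(r_xy)], axis=-1
    )
    n_hat = np.stack(
        [-r_hat[..., 1], r_hat[..., 0], np.zeros_like(r_xy)], axis=-1
    )  # z x r_hat
    v = i326 - c31
    a = -(v * r_hat).sum(axis=-1)         # toward the z-axis line
    bz = v[..., 2]
    pitch = np.degrees(np.arctan2(bz, a)) % 360.0
    vn = np.linalg.norm(v, axis=-1)
    yaw = np.degrees(np.arcsin(np.clip((v * n_hat).sum(axis=-1) / vn, -1, 1)))
    u = v / vn[..., None]
    ref = n_hat - (n_hat * u).sum(axis=-1)[..., None] * u
    ref /= np.linalg.norm(ref, axis=-1)[..., None]
    w = g308 - c31
    w_perp = w - (w * u).sum(axis=-1)[..., None] * u
    cross = np.cross(ref, w_perp)
    roll = np.degrees(
        np.arctan2((u * cross).sum(axis=-1), (ref * w_perp).sum(axis=-1))
    )
    return r_xy, z, pitch, yaw, roll


def _flip_about_rhat(points, r_hat):
    """Rotate points 180 deg about the in-plane axis r_hat through the
    origin: p -> 2 (r_hat . p) r_hat - p."""
    return 2.0 * (points * r_hat).sum(axis=-1)[..., None] * r_hat - points


def pose_series(
    traj: Trajectory,
    params: AnalysisParameters = DEFAULT_PARAMS,
) -> PoseSeries:
    """Per-frame LCAT pose with flip correction, for an aligned trajectory."""
    ic = traj.landmark_index("pose_center")
    ii = traj.landmark_index("pose_tip")
    ig = traj.landmark_index("roll_reference")
    lip = traj.beads.mask(molecule_type="lipid")
    if not lip.any():
        raise PoseError("pose requires a lipid disc (COM reference)")
    com = traj.coords[:, lip, :].mean(axis=1, dtype=np.float64)
    c31 = traj.coords[:, ic, :].astype(np.float64) - com
    i326 = traj.coords[:, ii, :].astype(np.float64) - com
    g308 = traj.coords[:, ig, :].astype(np.float64) - com

    r_xy_all = np.hypot(c31[:, 0], c31[:, 1])
    valid = r_xy_all > 1e-9
    skipped = np.flatnonzero(~valid)
    if len(skipped):
        logger.warning(
            "pose undefined (CYS31 on the z axis) in %d frame(s); skipped",
            len(skipped),
        )
    c31, i326, g308 = c31[valid], i326[valid], g308[valid]
    r_xy, z, pitch, yaw, roll = _raw_pose(c31, i326, g308)
    flip = np.abs(roll) > params.roll_flip_threshold
    if flip.any():
        r_hat = np.stack(
            [c31[flip, 0] / r_xy[flip], c31[flip, 1] / r_xy[flip],
             np.zeros(flip.sum())], axis=-1
        )
        fc = _flip_about_rhat(c31[flip], r_hat)
        fi = _flip_about_rhat(i326[flip], r_hat)
        fg = _flip_about_rhat(g308[flip], r_hat)
        r2, z2, p2, y2, ro2 = _raw_pose(fc, fi, fg)
        r_xy[flip], z[flip], pitch[flip], yaw[flip], roll[flip] = r2, z2, p2, y2, ro2
    frames = np.flatnonzero(valid)
    return PoseSeries(
        frames,
        np.array(traj.times)[valid],
        r_xy,
        z,
        pitch,
        yaw,
        roll,
        flip,
        skipped,
    )


def compute_pose(
    frame: Frame,
    frame_index: int = 0,
    params: AnalysisParameters = DEFAULT_PARAMS,
    topology=None,
) -> LcatPose:
    """Pose of one aligned frame; raises :class:`PoseError` when CYS31
    sits on the z-axis line through the disc COM."""
    from .model import Trajectory as _T

    traj = _T(
        frame.beads,
        frame.positions[None, ...],
        [frame.time],
        topology,
    )
    series = pose_series(traj, params)
    if len(series) == 0:
        raise PoseError("CYS31 on the z axis: pose undefined")
    return LcatPose(
        frame_index,
        float(series.r_xy[0]),
        float(series.z[0]),
        float(series.pitch[0]),
        float(series.yaw[0]),
        float(series.roll[0]),
        bool(series.flip_applied[0]),
    )


# ---------------------------------------------------------------------------
# z-pitch correlation
# ---------------------------------------------------------------------------

@dataclass
class PoseCorrelation:
    slope: float          # degrees / nm
    intercept: float      # degrees
    r_squared: float
    slope_stderr: float
    z_mean: float
    z_sd: float
    n: int
    degenerate: bool = False


def _circular_unwrap(pitch_deg: np.ndarray) -> np.ndarray:
    """Center pitch angles on their circular mean to linearize them."""
    rad = np.deg2rad(pitch_deg)
    mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    return mean + ((pitch_deg - mean + 180.0) % 360.0) - 180.0


def pose_correlation(poses: PoseSeries, start: int = 0) -> PoseCorrelation:
    """OLS of (circularly unwrapped) pitch on z, plus z mean +- SD."""
    sel = poses.frames >= start
    z = poses.z[sel]
    pitch = _circular_unwrap(poses.pitch[sel])
    if len(z) < 3:
        raise PoseError("pose correlation needs at least 3 frames")
    if np.ptp(z) < 1e-12:
        return PoseCorrelation(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float(z.mean()), 0.0, len(z), degenerate=True,
        )
    res = stats.linregress(z, pitch)
    return PoseCorrelation(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue ** 2),
        float(res.stderr),
        float(z.mean()),
        float(z.std(ddof=1)),
        len(z),
    )
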