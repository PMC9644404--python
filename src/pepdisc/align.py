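"""Disc alignment and rigid-body (Kabsch) superposition.

``align_disc`` puts every frame in the canonical nanodisc frame: the
lipid center of mass at the origin and the disc normal — the
smallest-eigenvalue eigenvector of the lipid coordinate covariance —
parallel to z.  The rotation applied is the *minimal* rotation taking the
normal to z; the in-plane eigendirections of a circular disc are nearly
degenerate, so using the full eigenbasis would make the operation
unstable (and non-idempotent).  The normal's sign is chosen for
frame-to-frame continuity; the first frame takes the sign with a
non-negative z component (recorded on the returned trajectory).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Frame, Trajectory


class AlignmentError(ValueError):
    pass


def _minimal_rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix of the minimal rotation taking ``normal`` to +z."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 deg about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(n, z)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    return Rotation.from_rotvec(axis * angle).as_matrix()


def disc_normal(lipid_xyz: np.ndarray) -> np.ndarray:
    """Unit normal of a disc of points: smallest-variance eigenvector."""
    centered = lipid_xyz - lipid_xyz.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1e-30):
        raise AlignmentError("degenerate (collinear) lipid geometry")
    return evecs[:, 0]


def align_disc(traj: Trajectory) -> Trajectory:
    """Canonical disc frame per frame; sign continuity across frames."""
    lipid_mask = traj.beads.mask(molecule_type="lipid")
    if lipid_mask.sum() < 3:
        raise AlignmentError("need at least 3 lipid beads to define a disc")
    out = np.empty_like(traj.coords)
    prev_normal: np.ndarray | None = None
    first_sign = None
    for i in range(traj.n_frames):
        xyz = np.asarray(traj.coords[i], dtype=np.float64)
        lip = xyz[lipid_mask]
        com = lip.mean(axis=0)
        normal = disc_normal(lip)
        if prev_normal is None:
            if normal[2] < 0:
                normal = -normal
            first_sign = int(np.sign(normal[2]) or 1)
        elif float(np.dot(normal, prev_normal)) < 0:
            normal = -normal
        prev_normal = normal
        rot = _minimal_rotation_to_z(normal)
        out[i] = (xyz - com) @ rot.T
    aligned = Trajectory(
        traj.beads,
        out.astype(traj.coords.dtype, copy=False),
        np.array(traj.times),
        traj.topology,
        None,  # alignment breaks the periodic box
        traj.replicate_id,
    )
    aligned.first_frame_normal_sign = first_sign  # type: ignore[attr-defined]
    return aligned


def kabsch_fit(
    frame: Frame, reference: Frame, selection: np.ndarray
) -> tuple[Frame, float]:
    """Rigidly superpose ``frame`` onto ``reference`` over ``selection``.

    ``selection`` is a boolean mask or index array over beads, applied to
    both frames.  The whole frame is transformed with the optimal
    (proper) rotation + translation minimizing the selection RMSD, which
    is returned in nm.
    """
    sel = np.asarray(selection)
    mobile = np.asarray(frame.positions, dtype=np.float64)[sel]
    target = np.asarray(reference.positions, dtype=np.float64)[sel]
    if mobile.shape != target.shape:
        raise ValueError("selection differs between frame and reference")
    if len(mobile) < 3:
        raise ValueError("kabsch_fit needs at least 3 beads (rotation is "
                         "under-determined otherwise)")
    mob_com = mobile.mean(axis=0)
    tgt_com = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tgt_com, mobile - mob_com)
    rmsd = float(rssd) / np.sqrt(len(mobile))
    xyz = np.asarray(frame.positions, dtype=np.float64)
    fitted = rot.apply(xyz - mob_com) + tgt_com
    return Frame(frame.time, fitted, frame.beads, None), rmsd
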