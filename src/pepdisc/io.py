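"""Trajectory and topology I/O.

Three text formats are supported:

* the *fixture* format — one tab-separated record per bead per frame with
  columns ``frame time molecule_id molecule_type residue_index residue_name
  bead_role size_class charge x y z`` (coordinates in nm, 5 decimals);
* GRO (fixed column, single frame per file; a sequence of GRO paths loads
  as consecutive frames);
* multi-model PDB (MODEL/ENDMDL delimited).

Binary trajectory formats (XTC/TRR/DCD) are read through MDAnalysis when a
structure file is supplied; this path is feature-flagged by file suffix.
Coordinate files carry names/resids only, so a :class:`TopologyMap` with
``molecule_blocks`` supplies the molecule-type / charge / size-class
annotation.  Ground-truth labels travel as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    BeadTable,
    MoleculeBlock,
    TopologyMap,
    TopologyError,
    Trajectory,
)

FIXTURE_COLUMNS = [
    "frame",
    "time",
    "molecule_id",
    "molecule_type",
    "residue_index",
    "residue_name",
    "bead_role",
    "size_class",
    "charge",
    "x",
    "y",
    "z",
]

_BINARY_SUFFIXES = {".xtc", ".trr", ".dcd"}


class TrajectoryIOError(IOError):
    pass


# ---------------------------------------------------------------------------
# fixture TSV
# ---------------------------------------------------------------------------

def write_fixture_tsv(traj: Trajectory, path: str | Path) -> None:
    b = traj.beads
    n = traj.n_beads
    frames = []
    for i in range(traj.n_frames):
        df = pd.DataFrame(
            {
                "frame": np.full(n, i, dtype=int),
                "time": np.full(n, traj.times[i]),
                "molecule_id": b.molecule_id,
                "molecule_type": b.molecule_type,
                "residue_index": b.residue_index,
                "residue_name": b.residue_name,
                "bead_role": b.bead_role,
                "size_class": b.size_class,
                "charge": b.charge,
                "x": traj.coords[i, :, 0],
                "y": traj.coords[i, :, 1],
                "z": traj.coords[i, :, 2],
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_fixture_tsv(path: str | Path, topology: TopologyMap | None = None) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    missing = set(FIXTURE_COLUMNS) - set(df.columns)
    if missing:
        raise TrajectoryIOError(f"fixture file {path} missing columns {missing}")
    frame_ids = df["frame"].to_numpy()
    order = np.unique(frame_ids)
    counts = {int(f): int((frame_ids == f).sum()) for f in order}
    if len(set(counts.values())) != 1:
        bad = [f for f, c in counts.items() if c != counts[int(order[0])]]
        raise TrajectoryIOError(
            f"inconsistent bead count across frames (first offending frame: "
            f"{bad[0]})"
        )
    first = df[frame_ids == order[0]]
    beads = BeadTable(
        molecule_id=first["molecule_id"].to_numpy(),
        molecule_type=first["molecule_type"].to_numpy(dtype="U12"),
        residue_index=first["residue_index"].to_numpy(),
        residue_name=first["residue_name"].to_numpy(dtype="U12"),
        bead_role=first["bead_role"].to_numpy(dtype="U12"),
        charge=first["charge"].to_numpy(dtype=float),
        size_class=first["size_class"].to_numpy(dtype="U12"),
    )
    n = len(beads)
    coords = np.empty((len(order), n, 3))
    times = np.empty(len(order))
    for k, f in enumerate(order):
        sub = df[frame_ids == f]
        # labels must be identical across frames
        if not (
            np.array_equal(sub["molecule_id"].to_numpy(), beads.molecule_id)
            and np.array_equal(sub["residue_index"].to_numpy(), beads.residue_index)
        ):
            raise TrajectoryIOError(f"frame {int(f)} bead labeling differs")
        coords[k] = sub[["x", "y", "z"]].to_numpy()
        times[k] = sub["time"].iloc[0]
    traj = Trajectory(beads, coords, times, topology)
    return traj


# ---------------------------------------------------------------------------
# GRO / PDB via MDAnalysis
# ---------------------------------------------------------------------------

def _annotate_from_blocks(
    names: np.ndarray,
    resnames: np.ndarray,
    resids: np.ndarray,
    topology: TopologyMap,
) -> BeadTable:
    n = len(names)
    blocks = topology.molecule_blocks
    mol_id = np.zeros(n, dtype=np.int32)
    mol_type = np.full(n, "other", dtype="U12")
    variant = np.full(n, "", dtype="U12")
    cursor = 0
    next_id = 1
    if blocks:
        for blk in blocks:
            for _ in range(blk.count):
                stop = cursor + blk.beads_per_molecule
                if stop > n:
                    raise TrajectoryIOError(
                        f"molecule block {blk.name!r} overruns the coordinate "
                        f"file ({n} beads)"
                    )
                mol_id[cursor:stop] = next_id
                mol_type[cursor:stop] = blk.molecule_type
                if blk.molecule_type == "peptide":
                    variant[cursor:stop] = blk.name
                cursor = stop
                next_id += 1
    # leftover beads: molecule_type "other", one molecule each
    for i in range(cursor, n):
        mol_id[i] = next_id
        next_id += 1

    role = np.full(n, "other", dtype="U12")
    role[np.char.startswith(names, "BB")] = "backbone"
    role[np.char.startswith(names, "SC")] = "sidechain"
    role[np.isin(names, ("NC3", "PO4", "HD1"))] = "headgroup"
    is_tail = np.char.startswith(names, "C") & np.isin(mol_type, ("lipid",))
    role[is_tail | (names == "TL1")] = "tail"

    size = np.asarray(
        [topology.bead_size_assignment.get(nm, "regular") for nm in names],
        dtype="U12",
    )
    charge = np.zeros(n, dtype=float)
    # peptide side-chain charges from the declared charged residues
    for var, charged in topology.charged_residues.items():
        sel = variant == var
        if not sel.any():
            continue
        for resi, sign in charged:
            m = sel & (resids == resi) & (role == "sidechain")
            charge[m] = float(sign)
    # residue_index: use file resids (per-molecule numbering expected)
    return BeadTable(
        molecule_id=mol_id,
        molecule_type=mol_type,
        residue_index=np.maximum(resids, 1),
        residue_name=resnames,
        bead_role=role,
        charge=charge,
        size_class=size,
        bead_name=names,
        variant=variant,
    )


def _read_with_mdanalysis(
    paths: Sequence[Path], topology: TopologyMap, structure: Path | None = None
) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if structure is not None:
            u = mda.Universe(str(structure), *[str(p) for p in paths])
        elif len(paths) == 1:
            u = mda.Universe(str(paths[0]))
        else:
            u = mda.Universe(str(paths[0]), *[str(p) for p in paths])
        names = u.atoms.names.astype("U8")
        resnames = u.atoms.resnames.astype("U8")
        resids = u.atoms.resids.astype(np.int32)
        n = len(u.atoms)
        coords = np.empty((len(u.trajectory), n, 3))
        times = np.empty(len(u.trajectory))
        boxes = []
        for k, ts in enumerate(u.trajectory):
            coords[k] = u.atoms.positions / 10.0  # A -> nm
            times[k] = k if not np.isfinite(ts.time) else ts.time
            boxes.append(None if ts.dimensions is None else ts.dimensions[:3] / 10.0)
    beads = _annotate_from_blocks(names, resnames, resids, topology)
    box_arr = None
    if all(b is not None for b in boxes):
        box_arr = np.asarray(boxes)
    return Trajectory(beads, coords, times, topology, box_arr)


def write_gro(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as GRO (3-decimal nm; the format's own precision)."""
    import warnings

    import MDAnalysis as mda

    b = traj.beads
    n = traj.n_beads
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # unique residue per (molecule, residue_index) pair, in bead order
        res_key = b.molecule_id.astype(np.int64) << 20 | b.residue_index.astype(
            np.int64
        )
        _, res_idx, inverse = np.unique(res_key, return_index=True, return_inverse=True)
        u = mda.Universe.empty(
            n, n_residues=len(res_idx), atom_resindex=inverse, trajectory=True
        )
        u.add_TopologyAttr("names", b.bead_name)
        u.add_TopologyAttr("resnames", b.residue_name[np.sort(res_idx)])
        u.add_TopologyAttr("resids", b.residue_index[np.sort(res_idx)])
        u.atoms.positions = np.asarray(traj.coords[frame], dtype=np.float64) * 10.0
        if traj.boxes is not None:
            u.dimensions = [*(traj.boxes[frame] * 10.0), 90.0, 90.0, 90.0]
        else:
            span = np.ptp(traj.coords[frame], axis=0) + 2.0
            u.dimensions = [*(span * 10.0), 90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    import warnings

    import MDAnalysis as mda

    b = traj.beads
    n = traj.n_beads
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res_key = b.molecule_id.astype(np.int64) << 20 | b.residue_index.astype(
            np.int64
        )
        _, res_idx, inverse = np.unique(res_key, return_index=True, return_inverse=True)
        u = mda.Universe.empty(
            n, n_residues=len(res_idx), atom_resindex=inverse, trajectory=True
        )
        u.add_TopologyAttr("names", b.bead_name)
        u.add_TopologyAttr("resnames", b.residue_name[np.sort(res_idx)])
        u.add_TopologyAttr("resids", b.residue_index[np.sort(res_idx)])
        u.trajectory.ts.dt = 1.0
        with mda.Writer(str(path), n, multiframe=True) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = (
                    np.asarray(traj.coords[i], dtype=np.float64) * 10.0
                )
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def load_trajectory(
    coordinate_source: str | Path | Sequence[str | Path],
    topology_map: str | Path | TopologyMap | None = None,
    structure: str | Path | None = None,
) -> Trajectory:
    """Load a labeled trajectory from a supported coordinate source.

    ``topology_map`` may be a :class:`TopologyMap`, a YAML path, or None
    (shipped defaults).  Landmark residues named by the topology must be
    resolvable whenever an LCAT molecule is present; otherwise loading
    fails hard.
    """
    if isinstance(topology_map, TopologyMap):
        topology = topology_map
    elif topology_map is None:
        topology = TopologyMap.default()
    else:
        tm_path = Path(topology_map)
        if not tm_path.exists():
            raise TrajectoryIOError(f"topology map not found: {tm_path}")
        topology = TopologyMap.from_yaml(tm_path)

    if isinstance(coordinate_source, (str, Path)):
        paths = [Path(coordinate_source)]
    else:
        paths = [Path(p) for p in coordinate_source]
    for p in paths:
        if not p.exists():
            raise TrajectoryIOError(f"coordinate source not found: {p}")

    suffix = paths[0].suffix.lower()
    if suffix in (".tsv", ".txt"):
        traj = read_fixture_tsv(paths[0], topology)
    elif suffix in (".gro", ".pdb"):
        traj = _read_with_mdanalysis(paths, topology)
    elif suffix in _BINARY_SUFFIXES:
        if structure is None:
            raise TrajectoryIOError(
                f"{suffix} trajectories need a structure file (GRO/PDB)"
            )
        traj = _read_with_mdanalysis(paths, topology, Path(structure))
    else:
        raise TrajectoryIOError(f"unsupported coordinate format {suffix!r}")
    traj.validate_landmarks()
    return traj


# ---------------------------------------------------------------------------
# ground truth JSON
# ---------------------------------------------------------------------------

def write_ground_truth(gt, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(gt.to_dict(), fh, indent=1)


def read_ground_truth_dict(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
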