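"""Domain model: labeled beads, frames, trajectories and the topology map.

A trajectory stores one static per-bead annotation table (:class:`BeadTable`)
shared by all frames plus a ``(n_frames, n_beads, 3)`` coordinate array in
nm.  Frames are lightweight views.  The :class:`TopologyMap` is the
declarative layer binding bead labels to analysis roles: peptide sequences
and axis endpoints, charged residues, LCAT landmark residues (CYS31,
ILE326, GLY308, PRO232, TRP48) and the bead-name -> size-class table used
for SASA radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

MOLECULE_TYPES = ("lipid", "peptide", "lcat", "other")
BEAD_ROLES = ("backbone", "sidechain", "headgroup", "tail", "other")
SIZE_CLASSES = ("regular", "small", "tiny")

#: Peptide variants studied: a 22-residue apoA-I-mimetic helix and
#: charge-modified derivatives (C-terminal lysine deleted or neutralized,
#: R7 neutralized).
PEPTIDE_SEQUENCES = {
    "22A": "PVLDLFRELLNELLEALKQKLK",
    "22A-K": "PVLDLFRELLNELLEALKQKL",
    "22A-K22Q": "PVLDLFRELLNELLEALKQKLQ",
    "22A-R7Q": "PVLDLFQELLNELLEALKQKLK",
}

#: Landmark roles -> (residue name, residue index) on the LCAT body.
LCAT_LANDMARKS = {
    "pose_center": ("CYS", 31),
    "pose_tip": ("ILE", 326),
    "roll_reference": ("GLY", 308),
    "siteA_anchor_1": ("PRO", 232),
    "siteA_anchor_2": ("TRP", 48),
}

AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

_CHARGE_OF = {"D": -1, "E": -1, "K": 1, "R": 1}


def charged_residues_of(sequence: str) -> list[tuple[int, int]]:
    """(1-based residue index, sign) for every D/E/K/R in ``sequence``."""
    return [
        (i + 1, _CHARGE_OF[aa])
        for i, aa in enumerate(sequence)
        if aa in _CHARGE_OF
    ]


class TopologyError(ValueError):
    """A bead label could not be resolved against the topology map."""


@dataclass
class MoleculeBlock:
    """One contiguous block of identical molecules in a coordinate file."""

    name: str
    molecule_type: str
    count: int
    beads_per_molecule: int


@dataclass
class TopologyMap:
    peptide_sequences: dict[str, str] = field(
        default_factory=lambda: dict(PEPTIDE_SEQUENCES)
    )
    peptide_axis_endpoints: dict[str, tuple[int, int]] = field(default_factory=dict)
    charged_residues: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    lcat_landmarks: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(LCAT_LANDMARKS)
    )
    bead_size_assignment: dict[str, str] = field(default_factory=dict)
    molecule_blocks: list[MoleculeBlock] | None = None

    def __post_init__(self) -> None:
        for variant, seq in self.peptide_sequences.items():
            self.peptide_axis_endpoints.setdefault(variant, (1, len(seq)))
            self.charged_residues.setdefault(variant, charged_residues_of(seq))
        for variant, (first, last) in self.peptide_axis_endpoints.items():
            n = len(self.peptide_sequences[variant])
            if not (1 <= first <= n and 1 <= last <= n and first != last):
                raise TopologyError(
                    f"axis endpoints {first, last} invalid for variant "
                    f"{variant!r} of length {n}"
                )
        for cls in self.bead_size_assignment.values():
            if cls not in SIZE_CLASSES:
                raise TopologyError(f"unknown size class {cls!r}")

    # -- serialization --------------------------------------------------
    @classmethod
    def default(cls) -> "TopologyMap":
        return cls(bead_size_assignment=dict(DEFAULT_SIZE_ASSIGNMENT))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TopologyMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        blocks = None
        if raw.get("molecule_blocks"):
            blocks = [MoleculeBlock(**b) for b in raw["molecule_blocks"]]
        kwargs = dict(
            peptide_sequences=raw.get("peptide_sequences", dict(PEPTIDE_SEQUENCES)),
            lcat_landmarks={
                k: (v[0], int(v[1]))
                for k, v in raw.get("lcat_landmarks", LCAT_LANDMARKS).items()
            },
            bead_size_assignment=raw.get(
                "bead_size_assignment", dict(DEFAULT_SIZE_ASSIGNMENT)
            ),
            molecule_blocks=blocks,
        )
        if "peptide_axis_endpoints" in raw:
            kwargs["peptide_axis_endpoints"] = {
                k: (int(v[0]), int(v[1]))
                for k, v in raw["peptide_axis_endpoints"].items()
            }
        if "charged_residues" in raw:
            kwargs["charged_residues"] = {
                k: [(int(i), int(s)) for i, s in v]
                for k, v in raw["charged_residues"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "peptide_sequences": self.peptide_sequences,
            "peptide_axis_endpoints": {
                k: list(v) for k, v in self.peptide_axis_endpoints.items()
            },
            "charged_residues": {
                k: [list(t) for t in v] for k, v in self.charged_residues.items()
            },
            "lcat_landmarks": {k: list(v) for k, v in self.lcat_landmarks.items()},
            "bead_size_assignment": self.bead_size_assignment,
        }
        if self.molecule_blocks:
            raw["molecule_blocks"] = [vars(b) for b in self.molecule_blocks]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


#: Default bead-name -> size-class table for the shipped synthetic systems.
DEFAULT_SIZE_ASSIGNMENT = {
    "BB": "regular",
    "SC1": "small",
    "NC3": "regular",
    "PO4": "regular",
    "GL1": "small",
    "GL2": "small",
    "C1A": "regular",
    "C2A": "regular",
    "C3A": "regular",
    "C1B": "regular",
    "C2B": "regular",
    "C3B": "regular",
}


@dataclass
class BeadTable:
    """Static per-bead annotations shared by every frame of a trajectory."""

    molecule_id: np.ndarray
    molecule_type: np.ndarray
    residue_index: np.ndarray
    residue_name: np.ndarray
    bead_role: np.ndarray
    charge: np.ndarray
    size_class: np.ndarray
    bead_name: np.ndarray | None = None
    variant: np.ndarray | None = None  # peptide variant label per bead, "" elsewhere

    def __post_init__(self) -> None:
        n = len(self.molecule_id)
        arrays = {
            "molecule_id": np.asarray(self.molecule_id, dtype=np.int32),
            "residue_index": np.asarray(self.residue_index, dtype=np.int32),
            "charge": np.asarray(self.charge, dtype=np.float64),
        }
        for name, arr in arrays.items():
            setattr(self, name, arr)
        for name in ("molecule_type", "residue_name", "bead_role", "size_class"):
            setattr(self, name, np.asarray(getattr(self, name), dtype="U12"))
        for name in ("molecule_type", "residue_name", "bead_role", "size_class"):
            if len(getattr(self, name)) != n:
                raise ValueError("bead annotation arrays must share one length")
        bad = ~np.isin(self.molecule_type, MOLECULE_TYPES)
        if bad.any():
            raise ValueError(
                f"unknown molecule types: {set(self.molecule_type[bad])}"
            )
        bad = ~np.isin(self.size_class, SIZE_CLASSES)
        if bad.any():
            raise ValueError(f"unknown size classes: {set(self.size_class[bad])}")
        if (self.residue_index < 1).any():
            raise ValueError("residue_index must be 1-based (>= 1)")
        if self.bead_name is None:
            self.bead_name = _synthesize_names(self.bead_role)
        else:
            self.bead_name = np.asarray(self.bead_name, dtype="U12")
        if self.variant is None:
            self.variant = np.full(n, "", dtype="U12")
        else:
            self.variant = np.asarray(self.variant, dtype="U12")

    def __len__(self) -> int:
        return len(self.molecule_id)

    # -- selections -----------------------------------------------------
    def mask(
        self,
        molecule_type: str | None = None,
        bead_role: str | None = None,
        residue_index: int | None = None,
        molecule_id: int | None = None,
    ) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if molecule_type is not None:
            m &= self.molecule_type == molecule_type
        if bead_role is not None:
            m &= self.bead_role == bead_role
        if residue_index is not None:
            m &= self.residue_index == residue_index
        if molecule_id is not None:
            m &= self.molecule_id == molecule_id
        return m

    def molecule_ids(self, molecule_type: str) -> np.ndarray:
        return np.unique(self.molecule_id[self.molecule_type == molecule_type])

    def backbone_index(self, molecule_id: int, residue_index: int) -> int:
        """Index of the unique backbone bead of one residue of one molecule."""
        idx = np.flatnonzero(
            (self.molecule_id == molecule_id)
            & (self.residue_index == residue_index)
            & (self.bead_role == "backbone")
        )
        if len(idx) != 1:
            raise TopologyError(
                f"expected exactly one backbone bead for molecule {molecule_id} "
                f"residue {residue_index}, found {len(idx)}"
            )
        return int(idx[0])

    def peptide_backbone_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(peptide molecule ids, (n_pep, n_res) bead-index matrix).

        Requires all peptides to share one residue count (one variant per
        system, as in the studied nanodiscs).
        """
        pep_ids = self.molecule_ids("peptide")
        if len(pep_ids) == 0:
            raise TopologyError("no peptide molecules in topology")
        rows = []
        for mid in pep_ids:
            sel = np.flatnonzero(
                (self.molecule_id == mid) & (self.bead_role == "backbone")
            )
            order = np.argsort(self.residue_index[sel], kind="stable")
            rows.append(sel[order])
        n_res = {len(r) for r in rows}
        if len(n_res) != 1:
            raise TopologyError("peptides have differing backbone lengths")
        return pep_ids, np.asarray(rows, dtype=np.int64)


def _synthesize_names(roles: np.ndarray) -> np.ndarray:
    table = {
        "backbone": "BB",
        "sidechain": "SC1",
        "headgroup": "HD1",
        "tail": "TL1",
        "other": "XX1",
    }
    return np.asarray([table.get(r, "XX1") for r in roles], dtype="U12")


@dataclass(frozen=True)
class Bead:
    """Single-bead record (convenience accessor; analyses use arrays)."""

    molecule_id: int
    molecule_type: str
    residue_index: int
    residue_name: str
    bead_role: str
    charge: float
    size_class: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError("bead position must be finite")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


class Frame:
    """One time point: a positions view plus the shared bead table."""

    __slots__ = ("time", "positions", "beads", "box")

    def __init__(
        self,
        time: float,
        positions: np.ndarray,
        beads: BeadTable,
        box: np.ndarray | None = None,
    ) -> None:
        positions = np.asarray(positions)
        if positions.shape != (len(beads), 3):
            raise ValueError(
                f"positions shape {positions.shape} inconsistent with "
                f"{len(beads)} beads"
            )
        self.time = float(time)
        self.positions = positions
        self.beads = beads
        self.box = None if box is None else np.asarray(box, dtype=float)

    def bead(self, i: int) -> Bead:
        b = self.beads
        return Bead(
            int(b.molecule_id[i]),
            str(b.molecule_type[i]),
            int(b.residue_index[i]),
            str(b.residue_name[i]),
            str(b.bead_role[i]),
            float(b.charge[i]),
            str(b.size_class[i]),
            np.array(self.positions[i], dtype=float),
        )

    def copy(self) -> "Frame":
        return Frame(
            self.time,
            np.array(self.positions),
            self.beads,
            None if self.box is None else np.array(self.box),
        )


class Trajectory:
    """Time-ordered frames over one shared :class:`BeadTable`."""

    def __init__(
        self,
        beads: BeadTable,
        coords: np.ndarray,
        times: np.ndarray | Sequence[float] | None = None,
        topology: TopologyMap | None = None,
        boxes: np.ndarray | None = None,
        replicate_id: str = "rep1",
    ) -> None:
        coords = np.asarray(coords)
        if coords.ndim != 3 or coords.shape[1:] != (len(beads), 3):
            raise ValueError(
                f"coords must have shape (n_frames, {len(beads)}, 3); "
                f"got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.beads = beads
        self.coords = coords
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        self.times = np.asarray(times, dtype=float)
        if len(self.times) != coords.shape[0]:
            raise ValueError("times length must match frame count")
        self.topology = topology or TopologyMap.default()
        self.boxes = boxes
        self.replicate_id = replicate_id

    # -- basic access ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        box = None if self.boxes is None else self.boxes[i]
        return Frame(self.times[i], self.coords[i], self.beads, box)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.beads,
            np.array(self.coords),
            np.array(self.times),
            self.topology,
            None if self.boxes is None else np.array(self.boxes),
            self.replicate_id,
        )

    # -- topology-aware selections -------------------------------------
    def landmark_index(self, landmark: str) -> int:
        """Bead index of an LCAT landmark (e.g. ``pose_center`` = CYS31)."""
        try:
            resname, resid = self.topology.lcat_landmarks[landmark]
        except KeyError as exc:
            raise TopologyError(f"unknown landmark {landmark!r}") from exc
        b = self.beads
        idx = np.flatnonzero(
            (b.molecule_type == "lcat")
            & (b.residue_index == resid)
            & (b.residue_name == resname)
            & (b.bead_role == "backbone")
        )
        if len(idx) != 1:
            raise TopologyError(
                f"landmark {landmark!r} ({resname}{resid}) resolves to "
                f"{len(idx)} beads; expected exactly one"
            )
        return int(idx[0])

    def validate_landmarks(self) -> None:
        if (self.beads.molecule_type == "lcat").any():
            for name in self.topology.lcat_landmarks:
                self.landmark_index(name)

    def peptide_variant(self) -> str:
        """The single peptide variant present (systems are one-variant)."""
        variants = {
            v for v in self.beads.variant[self.beads.molecule_type == "peptide"] if v
        }
        if len(variants) == 1:
            return variants.pop()
        # fall back to sequence length matching
        pep_ids, bb = self.beads.peptide_backbone_matrix()
        n = bb.shape[1]
        for name, seq in self.topology.peptide_sequences.items():
            if len(seq) == n:
                return name
        raise TopologyError("cannot determine peptide variant")
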