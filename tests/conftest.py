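"""Shared fixtures: small seeded synthetic systems and hand-built frames."""

from __future__ import annotations

import numpy as np
import pytest

from pepdisc.model import BeadTable, TopologyMap, Trajectory
from pepdisc.synthetic import (
    SyntheticConfig,
    generate_disc_system,
    generate_lcat_system,
)


@pytest.fixture(scope="session")
def small_disc():
    """20-frame disc of 30 lipids + 8 peptides with one pair per class."""
    cfg = SyntheticConfig(
        n_lipids=30,
        n_peptides=8,
        n_frames=20,
        seed=42,
        antiparallel_fraction=0.25,
        parallel_fraction=0.25,
    )
    return generate_disc_system(cfg)


@pytest.fixture(scope="session")
def small_lcat():
    """Short LCAT-bearing system with a binding schedule."""
    cfg = SyntheticConfig(
        n_lipids=30,
        n_peptides=8,
        n_frames=150,
        seed=9,
        lcat_enabled=True,
        antiparallel_fraction=0.25,
        parallel_fraction=0.0,
        occupancy_target=0.4,
        mean_event_length=8.0,
        roll_flip_probability=0.2,
    )
    return generate_lcat_system(cfg)


def ring_lipid_table(n: int = 12) -> BeadTable:
    """Minimal lipid annotation for hand-built disc frames."""
    return BeadTable(
        molecule_id=np.arange(1, n + 1),
        molecule_type=np.full(n, "lipid"),
        residue_index=np.ones(n, dtype=int),
        residue_name=np.full(n, "DMPC"),
        bead_role=np.full(n, "headgroup"),
        charge=np.zeros(n),
        size_class=np.full(n, "regular"),
    )


def ring_lipid_coords(n: int = 12, radius: float = 3.0) -> np.ndarray:
    """Flat two-level ring: a well-conditioned disc of lipid beads."""
    phi = 2 * np.pi * np.arange(n) / n
    z = np.where(np.arange(n) % 2 == 0, 0.2, -0.2)
    return np.stack([radius * np.cos(phi), radius * np.sin(phi), z], axis=1)


def lcat_pose_system(
    c31: np.ndarray, i326: np.ndarray, g308: np.ndarray
) -> Trajectory:
    """A disc plus a 3-bead LCAT carrying only the pose landmarks."""
    lip = ring_lipid_table()
    lip_xyz = ring_lipid_coords()
    n_lip = len(lip)
    beads = BeadTable(
        molecule_id=np.concatenate([lip.molecule_id, [99, 99, 99]]),
        molecule_type=np.concatenate([lip.molecule_type, ["lcat"] * 3]),
        residue_index=np.concatenate([lip.residue_index, [31, 326, 308]]),
        residue_name=np.concatenate([lip.residue_name, ["CYS", "ILE", "GLY"]]),
        bead_role=np.concatenate([lip.bead_role, ["backbone"] * 3]),
        charge=np.zeros(n_lip + 3),
        size_class=np.concatenate([lip.size_class, ["regular"] * 3]),
    )
    coords = np.vstack([lip_xyz, c31, i326, g308])[None, ...]
    return Trajectory(beads, coords, [0.0], TopologyMap.default())


def straight_peptide_table(n_peptides: int, n_res: int = 22,
                           variant: str = "22A") -> BeadTable:
    """Backbone-only peptides (no side chains) for geometry tests."""
    n = n_peptides * n_res
    return BeadTable(
        molecule_id=np.repeat(np.arange(1, n_peptides + 1), n_res),
        molecule_type=np.full(n, "peptide"),
        residue_index=np.tile(np.arange(1, n_res + 1), n_peptides),
        residue_name=np.full(n, "LEU"),
        bead_role=np.full(n, "backbone"),
        charge=np.zeros(n),
        size_class=np.full(n, "regular"),
        variant=np.full(n, variant),
    )
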