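"""Site-A state detection, occupancy statistics, residue heatmaps, and
spatial density grids."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pepdisc as pd
from pepdisc.binding import (
    occupancy_stats,
    residue_contact_heatmap,
    siteA_series,
    spatial_density,
)
from pepdisc.model import Trajectory


class TestSiteAState:
    def test_candidate_inside_both_thresholds_is_bound(self, small_lcat):
        traj, gt = small_lcat
        series = siteA_series(traj)
        f = int(np.flatnonzero(gt.bound_peptide >= 0)[0])
        st_ = series.state(f)
        assert st_.bound
        assert st_.d1 < 1.0 and st_.d2 < 2.0
        assert st_.peptide_id == gt.bound_peptide[f]

    def test_candidate_selection_matches_exhaustive_scan(self, small_lcat):
        """The min-combined-distance candidate, and only it, is threshold
        tested (oracle: explicit per-peptide loop)."""
        traj, _ = small_lcat
        sub = Trajectory(traj.beads, traj.coords[:40], traj.times[:40],
                         traj.topology)
        series = siteA_series(sub)
        pep_ids, bb = sub.beads.peptide_backbone_matrix()
        a1 = sub.landmark_index("siteA_anchor_1")
        a2 = sub.landmark_index("siteA_anchor_2")
        for f in range(sub.n_frames):
            best, best_sum = None, np.inf
            for k, mid in enumerate(pep_ids):
                d1 = np.linalg.norm(sub.coords[f, bb[k, 0]].astype(float)
                                    - sub.coords[f, a1].astype(float))
                d2 = np.linalg.norm(sub.coords[f, bb[k, 20]].astype(float)
                                    - sub.coords[f, a2].astype(float))
                if d1 + d2 < best_sum:
                    best, best_sum = (mid, d1, d2), d1 + d2
            mid, d1, d2 = best
            bound = d1 < 1.0 and d2 < 2.0
            assert series.bound[f] == bound
            if bound:
                assert series.peptide_id[f] == mid

    def test_invariant_to_peptide_enumeration_order(self, small_lcat):
        traj, _ = small_lcat
        sub = Trajectory(traj.beads, traj.coords[:10], traj.times[:10],
                         traj.topology)
        series = siteA_series(sub)
        # reverse the peptide bead blocks
        b = sub.beads
        order = np.arange(sub.n_beads)
        pep = b.molecule_type == "peptide"
        pep_idx = np.flatnonzero(pep)
        blocks = np.split(pep_idx, np.flatnonzero(
            np.diff(b.molecule_id[pep_idx]) != 0) + 1)
        order[pep_idx] = np.concatenate(blocks[::-1])
        from pepdisc.model import BeadTable

        table = BeadTable(
            molecule_id=b.molecule_id[order],
            molecule_type=b.molecule_type[order],
            residue_index=b.residue_index[order],
            residue_name=b.residue_name[order],
            bead_role=b.bead_role[order],
            charge=b.charge[order],
            size_class=b.size_class[order],
            variant=b.variant[order],
        )
        swapped = Trajectory(table, sub.coords[:, order, :], sub.times,
                             sub.topology)
        series2 = siteA_series(swapped)
        assert np.array_equal(series.bound, series2.bound)
        assert np.array_equal(series.peptide_id, series2.peptide_id)


def _series(bound, ids=None):
    bound = np.asarray(bound, dtype=bool)
    n = len(bound)
    ids = np.where(bound, 1 if ids is None else np.asarray(ids), -1)
    return pd.SiteASeries(np.arange(n), bound, ids, np.zeros(n), np.zeros(n),
                          bound.astype(int))


class TestOccupancyStats:
    def test_fully_bound_single_peptide(self):
        stats = occupancy_stats(_series([True] * 10))
        assert stats.occupancy_percent == 100.0
        assert stats.n_entries == 1
        assert stats.n_peptide_changes == 0

    def test_four_runs_of_ten(self):
        bound = ([True] * 10 + [False] * 15) * 4
        stats = occupancy_stats(_series(bound))
        assert stats.occupancy_percent == pytest.approx(40.0)
        assert stats.n_entries == 4
        assert stats.mean_event_length == pytest.approx(10.0)
        assert stats.max_event_length == 10

    def test_peptide_change_within_run(self):
        ids = [3, 3, 5, -1, 5]
        bound = [True, True, True, False, True]
        stats = occupancy_stats(_series(bound, ids))
        assert stats.n_entries == 2
        assert stats.n_peptide_changes == 1  # 3 -> 5 within the first run

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_event_bookkeeping_invariants(self, bound):
        stats = occupancy_stats(_series(bound))
        assert stats.event_lengths.sum() == sum(bound)
        assert stats.n_entries == len(stats.event_lengths)
        assert 0.0 <= stats.occupancy_percent <= 100.0


class TestHeatmap:
    def test_raw_counts_and_normalization(self, small_lcat):
        traj, _ = small_lcat
        sub = Trajectory(traj.beads, traj.coords[:30], traj.times[:30],
                         traj.topology)
        hm = residue_contact_heatmap(sub, peptide_residues=(7, 22))
        assert hm.peptide_rows == ["R7", "K22"]
        if hm.raw.max() > 0:
            assert hm.normalized.max() == pytest.approx(1.0)
        # brute-force one row
        b = sub.beads
        pep_ids, bb = b.peptide_backbone_matrix()
        lcat = np.flatnonzero(b.mask(molecule_type="lcat",
                                     bead_role="backbone"))
        lcat = lcat[np.argsort(b.residue_index[lcat], kind="stable")]
        expected = np.zeros(len(lcat))
        for f in range(sub.n_frames):
            for k in range(len(pep_ids)):
                x = sub.coords[f, bb[k, 6]].astype(float)  # residue 7
                d = np.linalg.norm(sub.coords[f, lcat].astype(float) - x,
                                   axis=1)
                expected += d < 0.6
        np.testing.assert_allclose(hm.raw[0], expected)

    def test_replicates_are_summed(self, small_lcat):
        traj, _ = small_lcat
        sub = Trajectory(traj.beads, traj.coords[:20], traj.times[:20],
                         traj.topology)
        one = residue_contact_heatmap(sub)
        two = residue_contact_heatmap([sub, sub])
        np.testing.assert_allclose(two.raw, 2 * one.raw)

    def test_21_residue_variant_has_no_k22_row(self):
        cfg = pd.SyntheticConfig(n_lipids=10, n_peptides=4, n_frames=2,
                                 seed=3, lcat_enabled=True,
                                 peptide_variant="22A-K",
                                 antiparallel_fraction=0,
                                 parallel_fraction=0)
        traj, _ = pd.generate_lcat_system(cfg)
        hm = residue_contact_heatmap(traj, peptide_residues=(7, 22))
        assert hm.peptide_rows == ["R7"]


class TestSpatialDensity:
    def test_count_conservation(self, small_lcat):
        traj, _ = small_lcat
        sub = Trajectory(traj.beads, traj.coords[:15], traj.times[:15],
                         traj.topology)
        grid = spatial_density(sub)
        n_pep = int(sub.beads.mask(molecule_type="peptide").sum())
        assert grid.total == n_pep * sub.n_frames

    def test_rigidly_comoving_peptides_fill_one_voxel(self):
        """Peptide beads rigidly locked to LCAT collapse onto single
        voxels after superposition."""
        from pepdisc.model import BeadTable
        from pepdisc.synthetic import lcat_fixture
        from scipy.spatial.transform import Rotation

        body, resn, resid, size = lcat_fixture()
        n_l = len(body)
        pep_offsets = np.array([[4.0, 0.2, 0.1]])
        table = BeadTable(
            molecule_id=np.concatenate([np.full(n_l, 1),
                                        [2]]),
            molecule_type=np.concatenate([np.full(n_l, "lcat"), ["peptide"]]),
            residue_index=np.concatenate([resid, [1]]),
            residue_name=np.concatenate([resn, ["PRO"]]),
            bead_role=np.concatenate([np.full(n_l, "backbone"), ["backbone"]]),
            charge=np.zeros(n_l + 1),
            size_class=np.concatenate([size, ["regular"]]),
        )
        F = 6
        rng = np.random.default_rng(5)
        coords = np.empty((F, n_l + 1, 3))
        for f in range(F):
            rot = Rotation.random(random_state=rng)
            shift = rng.normal(0, 2, 3)
            coords[f, :n_l] = rot.apply(body) + shift
            coords[f, n_l:] = rot.apply(pep_offsets) + shift
        traj = Trajectory(table, coords)
        grid = spatial_density(traj)
        assert grid.total == F
        assert grid.counts.max() == F  # one voxel holds every count

    def test_bound_density_peaks_near_site_anchors(self):
        cfg = pd.SyntheticConfig(n_lipids=20, n_peptides=6, n_frames=80,
                                 seed=12, lcat_enabled=True,
                                 occupancy_target=1.0,
                                 antiparallel_fraction=0,
                                 parallel_fraction=0)
        traj, _ = pd.generate_lcat_system(cfg)
        # grid only the bound peptide's first residue: its density must sit
        # by the PRO232 anchor after superposition
        states = siteA_series(traj)
        assert states.bound.all()
        bead_mask = traj.beads.mask(molecule_type="peptide")
        bid = states.peptide_id[0]
        keep = traj.beads.mask(molecule_id=int(bid), residue_index=1,
                               bead_role="backbone") | ~bead_mask
        sub_idx = np.flatnonzero(keep)
        from pepdisc.model import BeadTable

        b = traj.beads
        table = BeadTable(
            molecule_id=b.molecule_id[sub_idx],
            molecule_type=b.molecule_type[sub_idx],
            residue_index=b.residue_index[sub_idx],
            residue_name=b.residue_name[sub_idx],
            bead_role=b.bead_role[sub_idx],
            charge=b.charge[sub_idx],
            size_class=b.size_class[sub_idx],
        )
        sub = Trajectory(table, traj.coords[:, sub_idx, :], traj.times,
                         traj.topology)
        grid = spatial_density(sub)
        anchor = sub.coords[0, np.flatnonzero(
            (table.residue_index == 232) & (table.molecule_type == "lcat"))[0]]
        assert np.linalg.norm(grid.argmax_position()
                              - anchor.astype(float)) < 1.0

    def test_cube_output_parses(self, tmp_path, small_lcat):
        traj, _ = small_lcat
        sub = Trajectory(traj.beads, traj.coords[:3], traj.times[:3],
                         traj.topology)
        grid = spatial_density(sub)
        path = tmp_path / "density.cube"
        grid.write_cube(path)
        lines = path.read_text().splitlines()
        nx = int(lines[3].split()[0])
        assert nx == grid.counts.shape[0]
        total = sum(float(v) for line in lines[7:] for v in line.split())
        assert total == pytest.approx(grid.total)
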