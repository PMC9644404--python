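"""Pair angles, angle-distance landscapes, the free-energy transform,
dimer matching, and charged contact maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import pepdisc as pd
from pepdisc.dimers import (
    PairLandscape,
    _greedy_match,
    charged_contact_map,
    detect_dimers,
    dimer_counts_per_frame,
    free_energy,
    pair_angle,
    pair_landscape,
)
from pepdisc.model import BeadTable, Trajectory
from pepdisc.params import DEFAULT_PARAMS
from pepdisc.synthetic import peptide_rod

from test_peptides import rod_trajectory


class TestPairAngle:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0, 0], [1, 0, 0], 0.0),
            ([1, 0, 0], [-1, 0, 0], 180.0),
            ([1, 0, 0], [0, 1, 0], 90.0),
        ],
    )
    def test_reference_orientations(self, a, b, expected):
        assert pair_angle(np.array(a, float), np.array(b, float)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pair_angle(np.zeros(3), np.array([1.0, 0, 0]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(arrays(float, 3, elements=st.floats(-1, 1)),
           arrays(float, 3, elements=st.floats(-1, 1)))
    def test_range_and_symmetry(self, a, b):
        if np.linalg.norm(a) < 1e-6 or np.linalg.norm(b) < 1e-6:
            return
        ang = pair_angle(a, b)
        assert 0.0 <= ang <= 180.0
        assert pair_angle(b, a) == pytest.approx(ang, abs=1e-9)
        assert pair_angle(a, -b) == pytest.approx(180.0 - ang, abs=1e-7)


def two_state_trajectory(n_frames, p_state_a, seed, state_a=(0.7, 155.0),
                         state_b=(1.75, 135.0)):
    """Two peptides toggling between two (r13, angle) geometries."""
    rng = np.random.default_rng(seed)
    in_a = rng.random(n_frames) < p_state_a
    axes = np.empty((n_frames, 2, 3))
    r13 = np.empty((n_frames, 2, 3))
    for f in range(n_frames):
        d, theta = state_a if in_a[f] else state_b
        t = np.deg2rad(theta)
        axes[f, 0] = [1.0, 0, 0]
        axes[f, 1] = [np.cos(t), np.sin(t), 0]
        r13[f, 0] = 0.0
        r13[f, 1] = [0, 0, d]
    return rod_trajectory(axes, r13), in_a


class TestPairLandscape:
    def test_total_counts_one_pair(self):
        traj, _ = two_state_trajectory(10, 1.0, seed=0)
        land = pair_landscape(traj)
        assert land.total == 10

    def test_total_counts_all_pairs_of_28(self):
        cfg = pd.SyntheticConfig(n_frames=1, seed=2)
        traj, _ = pd.generate_disc_system(cfg)
        land = pair_landscape(traj)
        assert land.total == 28 * 27 // 2

    def test_mode_at_configured_dimer_geometry(self):
        traj, _ = two_state_trajectory(200, 0.8, seed=1)
        land = pair_landscape(traj)
        r_mode, t_mode = land.mode_bin()
        assert abs(r_mode - 0.725) <= 0.05  # bin [0.70, 0.75)
        assert abs(t_mode - 157.5) <= 5.0   # bin [155, 160)


class TestFreeEnergy:
    def _landscape(self, counts):
        counts = np.asarray(counts, dtype=np.int64)
        r_edges = np.arange(0.0, 2.0001, 0.05)
        t_edges = np.arange(0.0, 181.0, 5.0)
        full = np.zeros((len(r_edges) - 1, len(t_edges) - 1), dtype=np.int64)
        full[: counts.shape[0], : counts.shape[1]] = counts
        # put reference mass at (1.75, 135)
        i = np.searchsorted(r_edges, 1.75, side="right") - 1
        j = np.searchsorted(t_edges, 135.0, side="right") - 1
        full[i, j] = max(full[i, j], 50)
        return PairLandscape(r_edges, t_edges, full), (i, j)

    def test_reference_bin_is_exactly_zero(self):
        land, (i, j) = self._landscape(np.arange(12).reshape(3, 4))
        fel = free_energy(land)
        assert fel.delta_g[i, j] == 0.0

    def test_known_ratio_gives_minus_rt(self):
        land, (i, j) = self._landscape(np.zeros((1, 1)))
        ref = land.counts[i, j]
        land.counts[0, 0] = int(round(ref * np.e))
        fel = free_energy(land)
        rt = DEFAULT_PARAMS.rt
        # rho/rho_ref = e  ->  dG = -RT = -2.6605 kJ/mol
        assert fel.delta_g[0, 0] == pytest.approx(-rt, rel=5e-3)
        assert rt == pytest.approx(2.66048 / 1000 * 1000, abs=1e-4)

    def test_zero_bins_masked_not_infinite(self):
        land, _ = self._landscape(np.zeros((2, 2)))
        fel = free_energy(land)
        assert fel.delta_g.mask[0, 0]
        assert np.isfinite(fel.delta_g.filled(0.0)).all()

    def test_empty_reference_errors(self):
        r_edges = np.arange(0.0, 1.0, 0.05)
        t_edges = np.arange(0.0, 181.0, 5.0)
        counts = np.ones((len(r_edges) - 1, len(t_edges) - 1), dtype=np.int64)
        with pytest.raises(ValueError, match="outside|zero counts"):
            free_energy(PairLandscape(r_edges, t_edges, counts))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(1, 10_000), st.integers(0, 3), st.integers(0, 35))
    def test_reference_zero_for_arbitrary_landscapes(self, ref_count, i, j):
        rng = np.random.default_rng(ref_count)
        counts = rng.integers(0, 50, size=(40, 36))
        r_edges = np.arange(0.0, 0.05 * 41, 0.05)
        t_edges = np.arange(0.0, 181.0, 5.0)
        ri = np.searchsorted(r_edges, 1.75, side="right") - 1
        tj = np.searchsorted(t_edges, 135.0, side="right") - 1
        counts[ri, tj] = ref_count
        fel = free_energy(PairLandscape(r_edges, t_edges, counts))
        assert fel.delta_g[ri, tj] == 0.0

    def test_two_state_population_ratio_recovered(self):
        """dG difference between two configured populations matches
        -RT ln(p/q) within 3 standard errors."""
        p = 0.7
        traj, in_a = two_state_trajectory(4000, p, seed=5)
        land = pair_landscape(traj)
        fel = free_energy(land)  # reference = state B bin
        ia = np.searchsorted(land.r_edges, 0.7, side="right") - 1
        ja = np.searchsorted(land.theta_edges, 155.0, side="right") - 1
        n_a = int(in_a.sum())
        n_b = len(in_a) - n_a
        expected = -DEFAULT_PARAMS.rt * np.log(n_a / n_b)
        se = DEFAULT_PARAMS.rt * np.sqrt(1 / n_a + 1 / n_b)
        assert abs(fel.delta_g[ia, ja] - expected) < 3 * se


class TestDetectDimers:
    def _traj(self, r13_list, axes=None):
        P = len(r13_list)
        if axes is None:
            axes = [[np.array([1.0, 0, 0])] * P]
        return rod_trajectory(axes, [r13_list])

    def test_pair_within_window_found(self):
        traj = self._traj([(0, 0, 0), (0, 0, 0.8)])
        recs = detect_dimers(traj)
        assert len(recs) == 1
        assert recs[0].r13 == pytest.approx(0.8, abs=1e-6)
        assert recs[0].dimer_class == "parallel"

    def test_pair_beyond_window_ignored(self):
        traj = self._traj([(0, 0, 0), (0, 0, 1.2)])
        assert detect_dimers(traj) == []

    def test_triplet_resolves_to_closest_pair(self):
        traj = self._traj([(0, 0, 0), (0, 0, 0.6), (0, 0.7, 0.3)])
        recs = detect_dimers(traj)
        assert len(recs) == 1
        assert recs[0].pair == (1, 2)

    def test_matching_no_peptide_twice(self, small_disc):
        traj, _ = small_disc
        recs = detect_dimers(traj)
        for f in range(traj.n_frames):
            seen = [m for r in recs if r.frame == f for m in r.pair]
            assert len(seen) == len(set(seen))

    def test_greedy_matches_independent_oracle(self):
        """Brute-force re-implementation of ascending-distance matching
        agrees on random frames."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            P = rng.integers(3, 8)
            pts = rng.uniform(0, 3.0, size=(P, 3))
            dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            got = _greedy_match(dist, 1.0)
            # oracle: plain python greedy over sorted pair list
            pairs = sorted(
                ((dist[i, j], i, j) for i in range(P) for j in range(i + 1, P)
                 if dist[i, j] <= 1.0)
            )
            used, expected = set(), []
            for _, i, j in pairs:
                if i not in used and j not in used:
                    used |= {i, j}
                    expected.append((i, j))
            assert got == expected


class TestDimerCounts:
    def test_counts_match_ground_truth_labels(self, small_disc):
        traj, gt = small_disc
        counts, recs = dimer_counts_per_frame(traj)
        for cls in ("parallel", "antiparallel"):
            expected = np.sum(gt.dimer_class == cls, axis=1)
            got = getattr(counts, cls)
            assert np.array_equal(got, expected)

    def test_no_dimers_configured_gives_zero(self):
        cfg = pd.SyntheticConfig(n_lipids=10, n_peptides=6, n_frames=3,
                                 seed=23, antiparallel_fraction=0,
                                 parallel_fraction=0)
        traj, _ = pd.generate_disc_system(cfg)
        counts, _ = dimer_counts_per_frame(traj)
        assert counts.parallel.sum() == 0
        assert counts.antiparallel.sum() == 0


def _charged_pair_system(mirror_contacts: bool):
    """Two antiparallel 22A peptides with exact E8-K20 register.

    With ``mirror_contacts`` both symmetric E8(A)-K20(B) and K20(A)-E8(B)
    contacts exist each frame; otherwise only one of them.
    """
    seq = "PVLDLFRELLNELLEALKQKLK"
    charged = {4: -1, 7: 1, 8: -1, 12: -1, 15: -1, 18: 1, 20: 1, 22: 1}
    rows = {k: [] for k in ("mol", "resi", "resn", "role", "charge")}
    from pepdisc.model import AA_1TO3

    for mol in (1, 2):
        for r in range(1, 23):
            rows["mol"].append(mol)
            rows["resi"].append(r)
            rows["resn"].append(AA_1TO3[seq[r - 1]])
            rows["role"].append("backbone")
            rows["charge"].append(0.0)
            if r in charged:
                rows["mol"].append(mol)
                rows["resi"].append(r)
                rows["resn"].append(AA_1TO3[seq[r - 1]])
                rows["role"].append("sidechain")
                rows["charge"].append(float(charged[r]))
    n = len(rows["mol"])
    table = BeadTable(
        molecule_id=rows["mol"],
        molecule_type=np.full(n, "peptide"),
        residue_index=rows["resi"],
        residue_name=rows["resn"],
        bead_role=rows["role"],
        charge=rows["charge"],
        size_class=np.full(n, "regular"),
        variant=np.full(n, "22A"),
    )
    coords = np.zeros((1, n, 3))
    k = 0
    for mol in (1, 2):
        for r in range(1, 23):
            if mol == 1:
                x = (r - 13) * 0.35
                pos = np.array([x, 0.0, 0.0])
            else:
                x = -(r - 13) * 0.35 + 0.7
                pos = np.array([x, 0.0, 0.5])
            coords[0, k] = pos
            k += 1
            if r in charged:
                sc = pos.copy()
                if not mirror_contacts and mol == 2 and r == 20:
                    sc[1] = 5.0  # push K20(B) away: only E8(A)-K20(B)... gone
                coords[0, k] = sc
                k += 1
    return Trajectory(table, coords)


class TestChargedContactMap:
    def test_symmetric_e8_k20_reaches_two(self):
        traj = _charged_pair_system(mirror_contacts=True)
        cmap = charged_contact_map(traj)
        e8 = cmap.labels.index("E8")
        k20 = cmap.labels.index("K20")
        assert cmap.n_dimers["antiparallel"] == 1
        assert cmap.normalized["antiparallel"][e8, k20] == pytest.approx(2.0)
        assert cmap.normalized["antiparallel"][k20, e8] == pytest.approx(2.0)

    def test_one_sided_contact_gives_one(self):
        traj = _charged_pair_system(mirror_contacts=False)
        cmap = charged_contact_map(traj)
        e8 = cmap.labels.index("E8")
        k20 = cmap.labels.index("K20")
        # K20 of B displaced: only K20(A)-E8(B) remains
        assert cmap.normalized["antiparallel"][e8, k20] == pytest.approx(1.0)

    def test_no_contacts_gives_zero_map(self):
        cfg = pd.SyntheticConfig(n_lipids=10, n_peptides=6, n_frames=2,
                                 seed=31, antiparallel_fraction=0,
                                 parallel_fraction=0)
        traj, _ = pd.generate_disc_system(cfg)
        cmap = charged_contact_map(traj)
        assert cmap.normalized["antiparallel"].max() == 0.0
        assert cmap.normalized["parallel"].max() == 0.0

    def test_heterogeneous_cells_bounded_by_two(self, small_disc):
        traj, _ = small_disc
        cmap = charged_contact_map(traj)
        for cls in ("parallel", "antiparallel"):
            assert cmap.normalized[cls].max() <= 2.0 + 1e-12
            assert (cmap.normalized[cls] >= 0).all()

    def test_brute_force_contact_counting(self):
        """0.6 nm contact detection equals an explicit double loop."""
        traj = _charged_pair_system(mirror_contacts=True)
        b = traj.beads
        cutoff = DEFAULT_PARAMS.charged_contact_cutoff
        sc = np.flatnonzero((b.bead_role == "sidechain") & (b.charge != 0))
        a_beads = [i for i in sc if b.molecule_id[i] == 1]
        b_beads = [i for i in sc if b.molecule_id[i] == 2]
        expected = 0
        for i in a_beads:
            for j in b_beads:
                d = np.linalg.norm(traj.coords[0, i] - traj.coords[0, j])
                if d < cutoff:
                    expected += 1
        cmap = charged_contact_map(traj)
        # raw map counted both role assignments minus the diagonal rule;
        # with no homogeneous contacts present, total = 2x one-directional
        assert cmap.raw["antiparallel"].sum() == 2 * expected
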