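# pepdisc

Analysis of coarse-grained peptide–lipid nanodisc simulations.

Discoidal HDL mimetics are built from a small lipid bilayer patch whose
rim is stabilized by amphipathic apoA-I-mimetic peptides such as the
22-residue helix 22A (`PVLDLFRELLNELLEALKQKLK`) and its charge-modified
variants (22A-K, 22A-K22Q, 22A-R7Q).  How these peptides organize on the
rim — and how the enzyme LCAT (lecithin–cholesterol acyltransferase)
docks onto the disc and engages the peptides in the groove between its
lid and membrane-binding domain ("site A") — controls how well such
nanodiscs activate cholesterol esterification.  `pepdisc` implements the
trajectory analyses needed to characterize this system from labeled
coarse-grained bead trajectories (Martini-style resolution), together
with a seeded synthetic-trajectory generator that emulates the
statistical structure of those simulations so every analysis stage has a
recoverable ground truth.

## What it computes

With the disc aligned so its normal is the z axis and the lipid center
of mass at the origin:

* **Peptide organization** — in-plane radial density profiles of lipids
  and peptides around the disc COM, the distribution of the angle
  between each peptide axis (the unit vector from the first- to the
  last-residue backbone bead, R1→R22) and the disc normal, rotational
  autocorrelation functions C(τ) = ⟨P_ℓ(û(t)·û(t+τ))⟩ with half-lives,
  and single-linkage peptide cluster counts at 1.0/1.25 nm cutoffs.
* **Dimerization** — for every peptide pair, the inter-axis angle θ
  (0° parallel, 180° antiparallel) as a function of the distance r
  between residue-13 backbone beads; the free-energy transform
  ΔG(r, θ) = −RT ln(ρ_{r,θ}/ρ_ref) with the reference state at
  (1.75 nm, 135°) and T = 320 K; dimer detection (r ≤ 1 nm, greedy
  minimum-distance matching) with parallel (0–60°) / antiparallel
  (120–180°) classification; and charged-bead contact maps normalized
  per dimer class, where a symmetric heterogeneous contact such as
  E8–K20 can reach the theoretical maximum of 2.
* **LCAT pose** — peptide–LCAT backbone contact series (3 nm cutoff);
  the pose (r_xy, z, pitch, yaw, roll) of the rigid LCAT body read off
  the CYS31 (center), ILE326 (tip) and GLY308 (roll reference) backbone
  beads, with pitch measured in the plane spanned by the disc COM,
  CYS31 and the z axis (0° toward the axis, 90° toward +z, 270° toward
  −z); automatic flip correction of upside-down frames (|roll| > 90°);
  and ordinary least squares of pitch on z with R².
* **Site-A binding** — per frame, the peptide minimizing
  d(P1, PRO232) + d(L21, TRP48) is bound when both distances fall below
  1 nm and 2 nm; occupancy percentage, entries, mean/max event lengths
  and occupant changes; residue contact heatmaps (R7/K22 vs all LCAT
  residues, 0.6 nm cutoff); and 0.2 nm spatial density grids of peptide
  beads after Kabsch superposition onto the LCAT backbone (Gaussian
  cube output).
* **SASA** — Shrake–Rupley solvent-accessible surface areas with
  Martini bead radii (regular/small/tiny = 0.264/0.225/0.185 nm) and a
  0.264 nm probe, per-residue profiles with replicate statistics, and
  bound-vs-water difference profiles.

## Worked example

```python
import pepdisc as pd

cfg = pd.SyntheticConfig(n_frames=2000, seed=11, lcat_enabled=True)
traj, truth = pd.generate_lcat_system(cfg)
traj = pd.align_disc(traj)

occ = pd.occupancy_stats(pd.siteA_series(traj))
corr = pd.pose_correlation(pd.pose_series(traj))
counts, _ = pd.dimer_counts_per_frame(traj)
fel = pd.free_energy(pd.pair_landscape(traj, r_max=2.0))
```

prints, via the obvious format strings:

```
site-A occupancy: 27.2% (27 entries, mean event 20.1 frames, max 68, 24 peptide changes)
LCAT pose: z = 0.30 +/- 0.30 nm, pitch-z slope = 39.2 deg/nm (R^2 = 0.58), 206 flip-corrected frames
dimers per frame: 3.00 antiparallel, 1.00 parallel
dG minimum: -5.77 kJ/mol at 1.52 nm, 158 deg (reference bin count 54)
peptide radial mode: 5.05 nm
```

The generator was configured for 30% site-A occupancy with mean bound
runs of 20 frames, a pitch–z slope of 40°/nm under 10° pitch noise,
three antiparallel plus one parallel dimer pair among the 28 rim
peptides, and a 5 nm rim radius — the analyses recover each of these
from the emitted coordinates alone (the finite-trajectory occupancy of
27.2% equals the realized fraction of bound frames exactly).

The same stages run from the shell:

```sh
pepdisc --seed 11 --output-dir out report     # every stage + summary.json
pepdisc --seed 11 --output-dir out occupancy  # one stage
pepdisc --output-dir out synth --n-frames 500 # trajectory + ground truth
```

Every output file embeds the full parameter set and seed in its header.

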