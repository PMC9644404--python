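# Methods

## System and conventions

All analyses operate on labeled coarse-grained bead trajectories of
discoidal peptide–lipid particles: a DMPC-like bilayer patch whose rim
is bound by 22-residue amphipathic peptides, optionally with a rigid
LCAT-like body attached at the rim.  Units are nm and degrees
throughout; residue indices are 1-based; energies are kJ/mol.  Every
frame is first brought into the canonical disc frame: the lipid center
of mass at the origin and the disc normal along +z.  The normal is the
smallest-eigenvalue eigenvector of the lipid coordinate covariance; the
applied rotation is the *minimal* rotation taking that normal to z
rather than the full eigenbasis, because the two in-plane eigenvalues of
a near-circular disc are almost degenerate and a full-eigenbasis
rotation would be numerically unstable (and would break idempotency of
the alignment).  The normal's sign is chosen for continuity with the
previous frame (first frame: non-negative z component, recorded).
Physically upside-down frames are therefore *preserved* by alignment;
they are recognized and corrected downstream through the LCAT roll
angle, exactly where the information is available.

## Analysis stages

**Peptide organization.**  The peptide axis is the unit vector between
the first- and last-residue backbone beads (R1→R22; R1→R21 for the
21-residue variant).  Radial profiles histogram the in-plane distance
√(x²+y²) from the lipid COM and are normalized per annulus area and per
frame, so that Σ density·area equals the mean bead count; a 3D
spherical-shell normalization is available by flag, but the in-plane
reading matches rim-profile geometry and is the default.  Orientation
distributions histogram the angle between each axis and +z on [0°, 180°]
(2.5° bins).  The rotational autocorrelation is
C(τ) = ⟨P_ℓ(û(t)·û(t+τ))⟩ over peptides and time origins; the Legendre
order defaults to 1 (plain cosine correlation) with order 2 by flag,
and the half-life is the first lag with C ≤ 0.5, linearly interpolated.
Clustering links two peptides when their minimum inter-bead distance
(all beads by default, backbone-only by flag) is within the cutoff and
takes single-linkage connected components.

**Dimerization.**  Every unordered peptide pair contributes one
(r, θ) observation per frame, where r is the residue-13 backbone
distance and θ the inter-axis angle.  Landscape bins default to
0.05 nm × 5°.  The free-energy transform is ΔG = −RT ln(ρ_{r,θ}/ρ_ref)
with R = 0.008314 kJ/(mol·K) and T = 320 K (the thermostat temperature
of the simulations this pipeline targets); the reference bin contains
(1.75 nm, 135°), ΔG there is exactly zero, zero-count bins are masked
rather than ±∞, and an empty reference bin is a hard error instructing
a different reference.  Dimers are peptide pairs with r ≤ 1.0 nm,
greedily matched in ascending distance so no peptide joins two dimers
(an all-pairs mode without matching exists), and classified parallel
(0–60°), antiparallel (120–180°), or unclassified (excluded from
contact maps).  Charged-bead contact maps compare every charged
side-chain bead of one peptide against those of the other (0.6 nm
cutoff) and accumulate both role assignments of the unordered pair, so
a symmetric heterogeneous contact (e.g. E8–K20) can reach a normalized
value of two after division by the class's dimer count; homogeneous
pairs are counted once per dimer-frame to avoid artificial doubling.

**LCAT pose.**  The contact series counts peptide backbone beads within
3 nm of any LCAT backbone bead; a sliding-window plateau heuristic
(window mean change < 5%) is offered, but all pose statistics accept an
explicit start frame because equilibration judgment is left to the
analyst.  The pose derives from three landmarks: CYS31 gives r_xy and z
relative to the disc COM; the CYS31→ILE326 vector, projected on the
vertical plane through the COM, CYS31 and the z axis, gives the pitch
(0° pointing horizontally toward the z-axis line, 90° toward +z, 180°
away, 270° toward −z — the zero direction and sense are fixed by these
four anchor cases); its out-of-plane component gives the yaw; and the
CYS31→GLY308 vector measured about the body axis from the plane normal
gives the roll.  |roll| > 90° flags an upside-down frame: the frame's
landmarks are rotated 180° about the in-plane COM→CYS31 axis (an
involution), which negates z, reflects pitch to 360°−pitch and
re-measures roll; the flip is recorded.  The pitch–z correlation is
ordinary least squares of pitch on z after centering pitch on its
circular mean (the regression is meaningless across a 0/360 seam
otherwise), reporting slope, intercept, R² and per-replicate z mean ± SD.

**Site-A binding.**  Each frame, the peptide minimizing
d(P1, PRO232) + d(L21, TRP48) over backbone beads is the sole
candidate; it is bound when d1 < 1 nm and d2 < 2 nm, so at most one
peptide is bound per frame (a diagnostic reports how many peptides
would independently satisfy both thresholds).  Occupancy statistics
follow one consistent reading: events are maximal bound runs; entries
are unbound→bound transitions with a bound first frame counting; and
occupant changes are bound frames whose peptide differs from the
previous bound frame's, counted separately from entries.  Residue
contact heatmaps count (frame, peptide) pairs with a backbone–backbone
distance under 0.6 nm between a chosen peptide residue (7 and 22 by
default; the 22-row is omitted for the 21-residue variant) and each
LCAT residue, sum replicates, then normalize by the maximum cell.
Spatial density grids Kabsch-fit each frame onto the reference LCAT
backbone and histogram peptide beads on a 0.2 nm grid covering the
reference bounding box padded by 3 nm; out-of-range beads are clipped
into edge voxels so the total count equals peptide beads × frames
exactly.  Grids export as Gaussian cube.

**SASA.**  Shrake–Rupley sphere-point sampling with bead radii by size
class (regular 0.264, small 0.225, tiny 0.185 nm) and a regular-bead
probe (0.264 nm).  Each bead's area is the accessible fraction of a
deterministic Fibonacci lattice (default 960 points) on its
probe-expanded sphere times 4π(r+r_probe)².  Water is never explicit:
"in water" means the analyzed molecule occludes itself only, while
disc-bound profiles use every system bead as an occluder.  Per-residue
profiles average over frames (and replicates, with SD).  Single-frame
per-bead values carry ≈1% lattice discretization error at 960 points;
profile values — across-frame means over a tumbling body — converge
below 0.5% on point doubling, which is the level the reported
quantities need.

## Synthetic data

The generator emits the study conditions the analyses target: 200
ten-bead DMPC-like lipids on a two-leaflet disc (static across frames —
lipid dynamics is out of scope), 28 rigid-rod peptides of a chosen
variant with one backbone bead per residue (0.35 nm spacing, a typical
coarse-grained backbone bond length) and charged side-chain beads
offset 0.3 nm outward at D/E/K/R residues, a 5 nm rim radius and
1.75 nm bilayer half-thickness.  Peptides sit on staggered rim slots in
three z levels with their R13 bead anchored on the slot point; each
frame they receive Gaussian tilt noise away from the tangent
(σ = 10°), Gaussian in-plane wobble (σ = 20° — rim peptides reorient,
which is what gives the rotational autocorrelation something to decay
with), and bounded uniform positional jitter (±0.14 nm arc, ±0.12 nm z,
±0.10 nm radial).  The jitter bounds are chosen so the worst-case R13
approach of two non-dimer peptides stays above the 1.0 nm dimer window
(adjacent slots are ≥ 1.31 nm apart in arc), making ground-truth dimer
labels exact by construction, while still letting background pairs
populate the (1.75 nm, 135°) reference region.  Designated dimer pairs
place a follower peptide whose R13 sits a drawn distance (default
U(0.5, 1.0) nm) above the leader's and whose axis is the leader's
rotated by a drawn angle (antiparallel mean 155°, σ 5°; parallel pairs
use the supplementary angle).  Default pair numbers (3 antiparallel,
1 parallel out of 28 peptides) mirror the per-frame dimer counts such
systems exhibit.

The LCAT stand-in is a stylized 50-bead rigid helical chain (synthetic;
not a deposited structure — an import path for user-supplied
coarse-grained structures exists but is untested against real
entries) whose five landmark beads are placed for well-conditioned
geometry: CYS31 near the centroid, ILE326 at a tip, GLY308 off-axis,
and PRO232/TRP48 about 6 nm apart so a bound 22-residue rod spans both
site anchors within the 1 nm / 2 nm thresholds.  Each frame the body is
placed at the rim with z ~ N(0.3, 0.3) nm and
pitch = 90° + 40°/nm · z + N(0, 10°) — a built-in z–pitch coupling for
the correlation analysis to recover — and with probability 0.1 the
whole frame is rotated 180° about an in-plane axis, emulating the
disc-normal sign ambiguity that the roll-based flip correction must
undo.  Site-A occupancy follows a two-state Markov chain parameterized
by its stationary bound probability (default 0.3) and mean bound-run
length (default 20 frames); in bound frames one non-dimer peptide is
re-seated so P1 sits 0.3–0.6 nm from PRO232 with its rod aimed at
TRP48.  After assembly the generator re-derives every label from the
emitted coordinates and refuses to return a trajectory whose labels are
not exactly recoverable.

What the generator does **not** emulate: lipid or peptide internal
dynamics, excluded volume, realistic kinetics of dimer formation
(pairs persist by construction), force-field energetics, or solvent.
Passing recovery tests therefore demonstrates that the analysis
operations measure what they claim on data with known structure — not
that real simulations behave this way.

## Numerical choices and scales

Coordinates are stored as float32 (well below the 10⁻³ nm precision of
the text formats); all reductions run in float64.  Ties in greedy dimer
matching resolve by stable sort order; angles at class boundaries
(60°, 120°) belong to the closed classes.  The free-energy reference
bin is located by right-continuous bin search, so reference values
lying exactly on bin edges fall in the upper bin.  Degenerate inputs
raise: collinear lipids (no disc plane), CYS31 on the z axis (no pose
plane; skipped with a warning in batch mode), fewer than 3 beads for a
rigid fit, an empty free-energy reference bin.

Desk-scale defaults: 1,000 generated frames for pipeline runs, with
recovery tests using 10,000 frames and triplicate replicates (matching
the triplicate-simulation design of the targeted studies; the
occupancy estimator's autocorrelated standard error at a single
10,000-frame chain is ~2 percentage points, so triplicates bring the
check comfortably inside its ±2-point band).  The pipeline's cluster,
density and SASA stages subsample to ≤200 (respectively ~20) frames,
chosen as the point where their summary statistics stop changing at
these system sizes.

## Known limitations

* The synthetic rim is a jittered lattice, so the background pair
  landscape is far smoother than real data only within the jitter
  range; very long-range pair statistics remain partly structured.
* The pose convention fixes the rotation sense from four anchor cases;
  yaw is emitted but has no recovery target (the generator places the
  body in-plane, yaw ≈ 0).
* GRO files round-trip to their native 10⁻³ nm precision only; the
  fixture TSV (10⁻⁵ nm) or multi-model PDB should be used when
  round-trip fidelity matters.
* The equilibration plateau heuristic is deliberately crude; explicit
  start frames are the supported path.
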