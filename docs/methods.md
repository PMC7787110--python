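# Methods

## The torsion-space painter

### Model and assumptions

A backbone chain is represented residue-by-residue with atoms N, Cα, C
(and the carbonyl O, placed for output validity).  Covalent geometry is
fixed at standard restraint-dictionary ideal values:

| quantity | default | unit |
|---|---|---|
| N–Cα | 1.458 | Å |
| Cα–C | 1.525 | Å |
| C–N (peptide) | 1.329 | Å |
| C–N–Cα | 121.7 | ° |
| N–Cα–C | 111.2 | ° |
| Cα–C–N | 116.2 | ° |
| ω (peptide torsion) | 180.0 | ° |
| C=O | 1.231 | ° → Å |
| Cα–C=O | 120.8 | ° |

All are configurable through `IdealGeometry`.  With these frozen, the
only degrees of freedom are φ/ψ; ω is enforced trans (planar amides).
Cis-prolines and non-ideal geometry are out of scope: the painter can
never emit distorted covalent geometry by construction (atoms are placed
by internal-to-Cartesian NeRF steps, so bond lengths and angles are
satisfied to roundoff, verified at 1e-6 tolerance in the tests).

### Which torsions move the controlled Cα

Under the standard residue-*i* indexing, a residue's own (φ<sub>i</sub>,
ψ<sub>i</sub>) cannot move its own Cα.  The unique two-torsion pair that
moves Cα<sub>i</sub> while leaving the already-built prefix fixed and ω
planar is (φ<sub>i−1</sub>, ψ<sub>i−1</sub>) — rotations about the
preceding N–Cα and Cα–C axes.  While residue *i* is "under hand control"
those two angles are free; a consequence is that the carbonyl C/O of
residue *i−1* (the linking amide plane) keep moving until residue *i* is
committed.  Committing appends residue *i+1* with provisional α-helical
torsions (−57, −47) and freezes residue *i*'s N/Cα permanently.  Undo
restores the exact previous state (states are immutable snapshots, so
restoration is bit-exact).

The first residue has no real φ reference atom; a virtual predecessor
carbonyl is placed trans to its own C, making the first φ a well-defined
internal dihedral (its value is an azimuth convention, exactly 180° at
start, and is never reported as a real torsion).

### The solver and the two-solution structure

The objective ‖Cα(φ, ψ) − target‖ is scanned on a 5°×5° torus grid
(vectorized forward kinematics, ~5k evaluations), the best ≤4 local
basins are refined by Levenberg–Marquardt on the 3-vector residual to
xtol/ftol 1e-14, and refined minima closer than 0.5° in both torsions are
merged.  The refined optimum is never worse than an exhaustive 1°×1°
grid (asserted in the tests over reachable and unreachable targets).

Both free-torsion axes pass through Cα<sub>i−1</sub>, so every reachable
point lies on a sphere about it (radius ≈3.804 Å for the defaults) and —
because for fixed φ the map ψ → −ψ reflects through the plane of
(N<sub>i−1</sub>, Cα<sub>i−1</sub>, C<sub>i−1</sub>), which contains the
φ axis — every point of the zone is covered exactly twice: by (φ, ψ) and
by (φ′, −ψ).  Equal-distance solution pairs are therefore *generic*, for
unreachable targets too (the nearest surface point is doubly covered).
This is precisely why an interactive tool needs a solution-toggle button;
`toggle_solution` cycles through the candidate list.

Tie-breaking among equal-distance candidates (equal at 1e-6 Å) is by
Ramachandran plausibility of the candidate pair — alpha, then beta, then
left-alpha, then other — and by ascending ψ within a class.  A pure
ascending-ψ rule was rejected: it systematically picks the −ψ mirror
branch for extended (β) conformations, which silently derails torsion
recovery when tracing a known Cα path even though every target is still
hit exactly.  The plausibility rank is deterministic, and the mirror of
any α/β-box torsion pair falls outside all boxes (checked empirically
over the boxes), so schedule recovery is unambiguous there.

### Path tracing and what it cannot determine

`trace_path` is the batch driver: start at the first target, then
extend + solve greedily for each subsequent target.  It is best-effort:
targets spaced beyond the ~3.8 Å reachable step are not an error, the
achieved |Cα − target| distances are reported instead.  Tracing the Cα
positions of an ideal-geometry chain recovers every *constrained*
torsion (φ of residues 2..n−1, ψ of residues 1..n−1) to well under 0.5°
and the Cα trace to RMSD < 0.01 Å.  The final residue's φ only spins the
terminal carbonyl about the last N–Cα axis and is not determined by any
Cα target; it stays at the provisional default and is excluded from
round-trip comparisons as mathematically undetermined, not as a
tolerance concession.

## Selection geometry

Sphere and frustum containment use closed conditions (≤), so an atom
exactly on a boundary is selected/visible.  The frustum is parameterized
by eye, an orthonormal (right, up, forward) frame, near/far depths and
the near-rectangle corner offsets; containment scales the rectangle
linearly with depth from the apex, equivalent to the 6-half-space test
used as the oracle in the tests.  Corner-handle updates follow the
linked-handle rules: horizontal drags propagate down the column and
mirror across the vertical symmetry axis; vertical drags keep the top
and bottom edges horizontal but independent (the most literal reading of
the linked-cube behaviour); depth drags translate the whole slab,
preserving thickness, with a separate explicit thickness setter.  Drags
that would push the near plane behind the eye or collapse/flip the
rectangle are clamped (minimum 1e-6 Å) and flagged to the caller.

## Rigid mover

`grab_transform` is the conjugation T = P_new · P_old⁻¹ of hand poses, so
the model stays fixed in the hand frame; it is path-independent by
construction.  `two_hand_transform` scales by the inter-hand distance
ratio about the right-hand position (the fixed point), aligns the old
inter-hand direction to the new one by the minimal rotation, and adds
the twist of the right hand's orientation change about the inter-hand
axis (swing–twist decomposition) — the "bottle-unscrewing" gesture.  The
exact rotational convention is a design choice documented here; it is
the minimal rotation consistent with both anchor constraints.  Scale is
applied to transforms only; `apply_rigid` refuses scaled transforms so
file coordinates stay in Å.

## Density meshes

`synthetic_map` emulates a density map as a sum of unit-height isotropic
Gaussians at atom centers on a regular grid (default spacing 0.5 Å,
σ 1.0 Å, padding 6σ so boundary values are < 1e-6).  It reproduces the
geometry of map contouring — isosurface radius σ√(2 ln 2) at level 0.5
for an isolated unit Gaussian, closed genus-0 surfaces, translation
equivariance — but not the noise, anisotropy, Fourier truncation ripples
or resolution-dependent blurring of experimental maps; passing tests
demonstrate correct contouring geometry, not realism of density.
Contouring is scikit-image marching cubes with vertices mapped to world
coordinates.  The hybrid representation classifies whole triangles by
centroid depth against a split plane parallel to the front clipping
plane at `near + fraction·(far − near)` (default fraction 0.5,
configurable; the wire/solid boundary position within the slab is a free
parameter).  Centroid classification was chosen over exact plane
splitting because the split is a rendering style, not a geometric clip;
it is deterministic, a strict partition, and conserves triangle counts.
Frustum clipping of meshes likewise keeps whole triangles by centroid
containment.  CCP4/MRC I/O goes through gemmi (mode 2, axis order
normalized to X-fastest on read; world origin in the MRC ORIGIN header).

## Gap harness

`make_gap_puzzle` deletes a seeded, uniformly chosen interior run of
residues (anchors always survive).  `rebuild_gap` adopts the prefix up
to the N-side anchor, then paints one residue per missing position using
the true Cα positions as targets, plus one final residue aimed at the
C-side anchor's Cα; it reports per-residue |Cα − truth| distances, gap
Cα RMSD in the shared frame (no superposition — both chains live in the
same coordinates), and the closure miss distance.  The harness measures
geometric accuracy of the kernel, not build speed, and its numbers are
not comparable to interactive human build times.  Noise emulating an
imprecise hand path is isotropic Gaussian per target coordinate; the
closure anchor stays exact (it is a known atom, not a guess).  Rebuild
error grows monotonically with noise; at σ = 0.3 Å per coordinate the
mean gap RMSD over 20 seeds is ≈0.65 Å (regression band 0.3–1.0 Å,
frozen from harness calibration runs).

## Problem sizes and numerical choices

Default test/verification sizes: 50-residue painted chains (10 random
schedules), 30-residue round-trip chains over four presets, 1000-point
selection clouds, 1°×1° exhaustive grids over 50 targets, gap sizes
4/8/25 and 20-seed noise sweeps — sizes at which every check runs in
seconds while exercising the full torsion range.  Angle comparisons wrap
through ±180°; dihedrals are IUPAC-signed with cis = 0°; degenerate
(collinear) dihedral and placement inputs raise instead of returning
NaN; long transform compositions re-orthonormalize via SVD.

## Known limitations

Building is N→C only; no side chains beyond a Cβ/pass-through; no
insertion codes or altLocs; no map-aware fitting (the target point is
the only signal, matching the rough-fit-then-refine workflow); no loop
closure against the downstream anchor (the closure distance is reported,
not enforced); exact mesh/plane polygon splitting is not implemented.
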